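"""Shared fixtures: one default synthetic study per session.

The study conditions are the generator defaults (two 500 kb chromosomes,
20 methylated TE islands at 0.80 CG methylation, 4.5-fold knockout depletion,
30X Poisson coverage); the session seed is fixed for reproducibility.
"""

from __future__ import annotations

from types import SimpleNamespace

import pandas as pd
import pytest

import diatmeth as dm

SESSION_SEED = 7


@pytest.fixture(scope="session")
def sim_config() -> dm.SimulationConfig:
    return dm.SimulationConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def study(sim_config):
    """Genome + annotations + truth + simulated samples (incl. a second WT
    replicate sharing the WT truth, for null calibration)."""
    genome, annotations, truth = dm.generate_genome(sim_config)
    contexts = dm.assign_contexts(genome)
    truth.add_replicate("WT2", like="WT")
    samples = {
        label: dm.simulate_methylome(genome, truth, label, sim_config, contexts)
        for label in ("WT", "KO1", "KO2", "WT2")
    }
    expr = dm.simulate_expression(annotations, truth, sim_config)
    return SimpleNamespace(
        config=sim_config,
        genome=genome,
        genome_lengths={c: len(s) for c, s in genome.items()},
        annotations=annotations,
        truth=truth,
        contexts=contexts,
        samples=samples,
        expr=expr,
    )


@pytest.fixture(scope="session")
def position_filter(study):
    """The 5X-in-all-three-lines CG filter of the main comparison."""
    return dm.filter_by_coverage(
        [study.samples["WT"], study.samples["KO1"], study.samples["KO2"]], 5, "CG"
    )


@pytest.fixture(scope="session")
def dmr_results(study, position_filter):
    params = dm.DmrParams()
    sets = {
        ko: dm.call_dmrs(
            study.samples["WT"], study.samples[ko], study.genome_lengths,
            params, position_filter,
        )
        for ko in ("KO1", "KO2")
    }
    consensus = dm.consensus_dmrs(sets["KO1"], sets["KO2"], "hypo")
    return SimpleNamespace(sets=sets, consensus=consensus, params=params)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    """The full on-disk fixture set plus its manifest."""
    outdir = tmp_path_factory.mktemp("fixture") / "fx"
    manifest = dm.write_fixture_set(outdir, sim_config)
    return SimpleNamespace(path=outdir, manifest=manifest)


def make_sample(rows, sample_id="S") -> dm.MethylomeSample:
    """Small in-memory methylome from (chrom, pos, strand, m, u, context) rows."""
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "m", "u", "context"]
    )
    return dm.MethylomeSample(sample_id, frame)
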