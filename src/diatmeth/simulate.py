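"""Synthetic methylome generator with known ground truth.

Emulates the data structure of a diatom-like genome: isolated, highly
CG-methylated transposable-element islands embedded in an otherwise
unmethylated genome; a wild-type sample plus two "knockout" samples whose
island methylation is divided by a depletion factor (default 4.5, matching a
4-5-fold global loss); binomial read sampling at Poisson coverage (default
30X); three histone-mark peak sets co-marking most islands; and per-mutant
differential-expression tables with planted upregulation of the methylated
TEs.  Everything is driven by one master seed with deterministic per-purpose
child streams, so any subset of samples reproduces bit-identically.

What is *not* modeled: read-level FASTQ simulation, bisulfite conversion
error, sequencing error, paired-end mechanics, and site-level overdispersion
(sampling is pure binomial; a beta-binomial hook is deliberately left out).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .methylome import (
    AnnotationSet,
    GenomicInterval,
    MethylomeSample,
    assign_contexts,
    write_bed,
    write_cytosine_report,
)


class PlacementError(RuntimeError):
    """Raised when non-overlapping island placement fails within the retry cap."""


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic child stream for one purpose/sample under a master seed."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study (defaults are the study conditions).

    Methylation fractions are per-read probabilities; ``ko_depletion_factor``
    divides the island methylation in knockout samples; ``mean_coverage`` is
    the Poisson mean read depth per cytosine.
    """

    genome_length_per_chrom: int = 500_000
    n_chromosomes: int = 2
    gc_content: float = 0.48
    te_island_count: int = 20
    te_island_length_range: tuple[int, int] = (2_000, 5_000)
    decoy_te_count: int = 20
    decoy_te_length_range: tuple[int, int] = (200, 500)
    island_cg_methylation: float = 0.80
    background_cg_methylation: float = 0.02
    noncg_methylation: float = 0.005
    ko_depletion_factor: float = 4.5
    mean_coverage: float = 30.0
    planted_upregulated_fraction: float = 0.8
    decoy_upregulated_fraction: float = 0.5
    planted_stable_fraction: float = 0.2
    planted_lfc_mean: float = 3.0
    planted_lfc_sd: float = 0.5
    lfc_noise_sd: float = 0.3
    fdr_threshold: float = 0.01
    gene_length: int = 1_500
    gene_gap: int = 1_000
    te_family_labels: tuple[str, ...] = ("CoDi1", "CoDi2", "CoDi4", "CoDi5", "PiggyBack")
    histone_mark_fractions: tuple[tuple[str, float], ...] = (
        ("H3K27me3", 0.90),
        ("H3K9me2", 0.85),
        ("H3K9me3", 0.80),
    )
    reference_label: str = "WT"
    knockout_labels: tuple[str, str] = ("KO1", "KO2")
    max_placement_retries: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "gc_content": self.gc_content,
            "island_cg_methylation": self.island_cg_methylation,
            "background_cg_methylation": self.background_cg_methylation,
            "noncg_methylation": self.noncg_methylation,
            "planted_upregulated_fraction": self.planted_upregulated_fraction,
            "decoy_upregulated_fraction": self.decoy_upregulated_fraction,
            "planted_stable_fraction": self.planted_stable_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.ko_depletion_factor <= 0:
            raise ValueError("ko_depletion_factor must be > 0")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        lo, hi = self.te_island_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad te_island_length_range")
        if hi + 4_000 > self.genome_length_per_chrom:
            raise ValueError("islands do not fit inside chromosomes")
        if self.n_chromosomes < 1 or self.genome_length_per_chrom < 1:
            raise ValueError("need >= 1 chromosome of positive length")

    @property
    def sample_labels(self) -> tuple[str, ...]:
        return (self.reference_label, *self.knockout_labels)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["te_island_length_range"] = list(self.te_island_length_range)
        d["decoy_te_length_range"] = list(self.decoy_te_length_range)
        d["te_family_labels"] = list(self.te_family_labels)
        d["histone_mark_fractions"] = [list(x) for x in self.histone_mark_fractions]
        d["knockout_labels"] = list(self.knockout_labels)
        return d


@dataclass
class SyntheticTruth:
    """Planted methylation architecture and expression effects.

    ``island_levels`` maps sample label -> per-island true CG methylation
    (aligned with ``islands``); ``true_lfc`` maps feature id -> planted log2
    fold change (shared direction across mutants)."""

    islands: list[GenomicInterval]
    island_levels: dict[str, list[float]]
    background_levels: dict[str, float]
    noncg_level: float
    upregulated_te_ids: set[str]
    decoy_upregulated_ids: set[str]
    stable_ids: set[str]
    true_lfc: dict[str, float]

    @property
    def sample_labels(self) -> tuple[str, ...]:
        return tuple(self.island_levels)

    def add_replicate(self, label: str, like: str) -> None:
        """Register an extra sample sharing another sample's true levels
        (e.g. a second wild-type replicate for null calibration)."""
        if like not in self.island_levels:
            raise KeyError(f"unknown sample {like!r}")
        self.island_levels[label] = list(self.island_levels[like])
        self.background_levels[label] = self.background_levels[like]

    def to_dict(self) -> dict:
        return {
            "islands": [
                [iv.chrom, iv.start, iv.end, iv.name, iv.feature_class, iv.family]
                for iv in self.islands
            ],
            "island_levels": {k: list(v) for k, v in self.island_levels.items()},
            "background_levels": dict(self.background_levels),
            "noncg_level": self.noncg_level,
            "upregulated_te_ids": sorted(self.upregulated_te_ids),
            "decoy_upregulated_ids": sorted(self.decoy_upregulated_ids),
            "stable_ids": sorted(self.stable_ids),
            "true_lfc": {k: self.true_lfc[k] for k in sorted(self.true_lfc)},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            islands=[
                GenomicInterval(c, s, e, n, fc, fam)
                for c, s, e, n, fc, fam in d["islands"]
            ],
            island_levels={k: list(v) for k, v in d["island_levels"].items()},
            background_levels=dict(d["background_levels"]),
            noncg_level=float(d["noncg_level"]),
            upregulated_te_ids=set(d["upregulated_te_ids"]),
            decoy_upregulated_ids=set(d["decoy_upregulated_ids"]),
            stable_ids=set(d["stable_ids"]),
            true_lfc={k: float(v) for k, v in d["true_lfc"].items()},
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Genome and annotations
# ---------------------------------------------------------------------------


def _place_intervals(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    lengths: Sequence[int],
    occupied: list[GenomicInterval],
    buffer: int,
    margin: int,
    retries: int,
) -> list[tuple[str, int, int]]:
    """Rejection-sample non-overlapping placements (round-robin chromosomes)."""
    chroms = list(chrom_lengths)
    placed: list[tuple[str, int, int]] = []
    blocked = list(occupied)
    for i, length in enumerate(lengths):
        length = int(length)
        chrom = chroms[i % len(chroms)]
        clen = chrom_lengths[chrom]
        for attempt in range(retries):
            start = int(rng.integers(margin, clen - length - margin))
            cand = GenomicInterval(chrom, start, start + length)
            buffered = GenomicInterval(chrom, max(0, start - buffer), start + length + buffer)
            if not any(buffered.overlaps(o) for o in blocked if o.chrom == chrom):
                placed.append((chrom, start, start + length))
                blocked.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place interval of {length} bp on {chrom} "
                f"after {retries} retries"
            )
    return placed


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], AnnotationSet, SyntheticTruth]:
    """Generate the genome sequence, annotations and planted ground truth.

    TE intervals sit exactly on the methylated islands, plus unmethylated
    decoy TEs elsewhere; every TE carries a TE-gene annotation over its open
    reading frame (here: the full element); genes tile the remaining space
    with >= ``gene_gap`` bp gaps; three histone-mark peak sets cover
    configured fractions of the islands.
    """
    rng = child_rng(config.seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.genome_length_per_chrom for c in chroms}

    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    genome = {
        c: "".join(
            np.array(list("ACGT"))[rng.choice(4, size=chrom_lengths[c], p=probs)]
        )
        for c in chroms
    }

    lo, hi = config.te_island_length_range
    island_lengths = rng.integers(lo, hi + 1, size=config.te_island_count)
    island_pos = _place_intervals(
        rng, chrom_lengths, island_lengths, [], buffer=1_000, margin=2_000,
        retries=config.max_placement_retries,
    )
    families = config.te_family_labels
    islands: list[GenomicInterval] = []
    tes: list[GenomicInterval] = []
    te_genes: list[GenomicInterval] = []
    for i, (chrom, start, end) in enumerate(island_pos):
        fam = families[int(rng.integers(len(families)))]
        islands.append(GenomicInterval(chrom, start, end, f"island_{i}", "island"))
        tes.append(GenomicInterval(chrom, start, end, f"TE_{i}", "TE", fam))
        te_genes.append(GenomicInterval(chrom, start, end, f"TEG_{i}", "TE_gene", fam))

    dlo, dhi = config.decoy_te_length_range
    decoy_lengths = rng.integers(dlo, dhi + 1, size=config.decoy_te_count)
    decoy_pos = _place_intervals(
        rng, chrom_lengths, decoy_lengths,
        [iv.extended(300) for iv in islands], buffer=300, margin=2_000,
        retries=config.max_placement_retries,
    )
    for i, (chrom, start, end) in enumerate(decoy_pos):
        fam = families[int(rng.integers(len(families)))]
        tes.append(GenomicInterval(chrom, start, end, f"TE_D{i}", "TE", fam))
        te_genes.append(GenomicInterval(chrom, start, end, f"TEG_D{i}", "TE_gene", fam))

    genes: list[GenomicInterval] = []
    gid = 0
    blocked = sorted(tes)
    for chrom in chroms:
        spans = [(iv.start, iv.end) for iv in blocked if iv.chrom == chrom]
        cursor = config.gene_gap
        for bstart, bend in spans + [(chrom_lengths[chrom], chrom_lengths[chrom])]:
            while cursor + config.gene_length + config.gene_gap <= bstart:
                genes.append(
                    GenomicInterval(chrom, cursor, cursor + config.gene_length,
                                    f"G_{gid}", "gene")
                )
                gid += 1
                cursor += config.gene_length + config.gene_gap
            cursor = max(cursor, bend + config.gene_gap)

    peaks: dict[str, list[GenomicInterval]] = {}
    for mark, fraction in config.histone_mark_fractions:
        mark_rng = child_rng(config.seed, f"peaks:{mark}")
        n_cover = int(round(fraction * len(islands)))
        chosen = sorted(mark_rng.permutation(len(islands))[:n_cover])
        peaks[mark] = [
            dataclasses.replace(
                islands[i].extended(200, chrom_lengths[islands[i].chrom]),
                name=f"{mark}_{k}", feature_class="peak", family=None,
            )
            for k, i in enumerate(chosen)
        ]

    wt, ko1, ko2 = config.sample_labels
    level = config.island_cg_methylation
    depleted = level / config.ko_depletion_factor
    island_levels = {
        wt: [level] * len(islands),
        ko1: [depleted] * len(islands),
        ko2: [depleted] * len(islands),
    }
    background = {s: config.background_cg_methylation for s in config.sample_labels}

    expr_rng = child_rng(config.seed, "truth:expression")
    methylated_tegs = [tg.name for tg in te_genes if tg.name.startswith("TEG_") and
                       not tg.name.startswith("TEG_D")]
    n_up = int(round(config.planted_upregulated_fraction * len(methylated_tegs)))
    upregulated = set(
        np.array(methylated_tegs)[sorted(expr_rng.permutation(len(methylated_tegs))[:n_up])]
    ) if methylated_tegs else set()
    decoy_tegs = [tg.name for tg in te_genes if tg.name.startswith("TEG_D")]
    n_dup = int(round(config.decoy_upregulated_fraction * len(decoy_tegs)))
    decoy_up = set(
        np.array(decoy_tegs)[sorted(expr_rng.permutation(len(decoy_tegs))[:n_dup])]
    ) if decoy_tegs else set()

    remaining = [f.name for f in [*te_genes, *genes]
                 if f.name not in upregulated and f.name not in decoy_up]
    n_stable = int(round(config.planted_stable_fraction * len(remaining)))
    stable = set(
        np.array(remaining)[sorted(expr_rng.permutation(len(remaining))[:n_stable])]
    ) if remaining else set()

    true_lfc: dict[str, float] = {}
    for fid in sorted(upregulated | decoy_up):
        true_lfc[fid] = float(
            expr_rng.normal(config.planted_lfc_mean, config.planted_lfc_sd)
        )
    for fid in sorted(stable):
        true_lfc[fid] = 0.0

    truth = SyntheticTruth(
        islands=islands,
        island_levels=island_levels,
        background_levels=background,
        noncg_level=config.noncg_methylation,
        upregulated_te_ids=upregulated,
        decoy_upregulated_ids=decoy_up,
        stable_ids=stable,
        true_lfc=true_lfc,
    )
    annotations = AnnotationSet(genes=genes, tes=tes, te_genes=te_genes, peaks=peaks)
    return genome, annotations, truth


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------


def simulate_methylome(
    genome: Mapping[str, str],
    truth: SyntheticTruth,
    sample_label: str,
    config: SimulationConfig,
    contexts: Mapping[str, pd.DataFrame] | None = None,
) -> MethylomeSample:
    """Simulate a per-cytosine report for one sample.

    Every cytosine on both strands is emitted (including zero-coverage
    sites). Coverage ~ Poisson(mean_coverage); methylated reads ~
    Binomial(coverage, site-level truth): the island level for CG sites
    inside a planted island, the background CG level for other CG sites, and
    a small constant for non-CG sites.
    """
    if sample_label not in truth.island_levels:
        raise KeyError(
            f"unknown sample {sample_label!r}; known: {sorted(truth.island_levels)}"
        )
    rng = child_rng(config.seed, f"methylome:{sample_label}")
    if contexts is None:
        contexts = assign_contexts(genome)
    levels_by_island = truth.island_levels[sample_label]
    background = truth.background_levels[sample_label]

    frames = []
    for chrom in genome:
        ctx = contexts[chrom]
        pos = ctx["pos"].to_numpy(dtype=np.int64)
        level = np.full(len(pos), truth.noncg_level)
        is_cg = (ctx["context"] == "CG").to_numpy()
        level[is_cg] = background
        chrom_islands = [
            (i, iv) for i, iv in enumerate(truth.islands) if iv.chrom == chrom
        ]
        for i, iv in chrom_islands:
            inside = is_cg & (pos > iv.start) & (pos <= iv.end)
            level[inside] = levels_by_island[i]
        coverage = rng.poisson(config.mean_coverage, size=len(pos))
        m = rng.binomial(coverage, level)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": ctx["strand"].to_numpy(),
                    "m": m,
                    "u": coverage - m,
                    "context": ctx["context"].to_numpy(),
                    "trinucleotide": ctx["trinucleotide"].to_numpy(),
                }
            )
        )
    return MethylomeSample(sample_label, pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    annotations: AnnotationSet,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Per-mutant DE summary tables with planted, direction-shared effects.

    Observed LFC = true LFC + Gaussian noise per mutant; FDR is drawn below
    the significance threshold for planted features (upregulated and stable)
    and uniform above it otherwise. The negative-binomial differential model
    that would produce such tables in a real study is out of scope by design:
    these tables exercise the downstream integration logic only.
    """
    features = [*annotations.te_genes, *annotations.genes]
    out: dict[str, pd.DataFrame] = {}
    for mutant in config.knockout_labels:
        rng = child_rng(config.seed, f"expression:{mutant}")
        rows = []
        for f in features:
            true = truth.true_lfc.get(f.name)
            if true is not None:
                lfc = true + rng.normal(0.0, config.lfc_noise_sd)
                fdr = float(rng.uniform(1e-8, config.fdr_threshold * 0.5))
            else:
                lfc = float(rng.normal(0.0, 0.2))
                fdr = float(rng.uniform(config.fdr_threshold, 1.0))
            rows.append((f.name, float(lfc), fdr))
        table = pd.DataFrame(rows, columns=["feature_id", "log2FoldChange", "padj"])
        table.attrs["mutant"] = mutant
        out[mutant] = table
    return out


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(
    outdir: str | Path,
    config: SimulationConfig,
    force: bool = False,
) -> dict[str, str]:
    """Write the complete fixture set and return {filename: sha256}.

    Files: genome FASTA; genes/TEs/TE-genes BED (TE names carry ``id|family``);
    one BED per histone mark; one cytosine report per sample; one DE table per
    mutant; truth and config JSON; a ready-to-run pipeline config YAML; and a
    manifest TSV with checksums. Refuses a non-empty directory unless
    ``force`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)

    genome, annotations, truth = generate_genome(config)
    contexts = assign_contexts(genome)

    files: list[Path] = []

    fasta = outdir / "genome.fa"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()],
        fasta,
        "fasta",
    )
    files.append(fasta)

    for name, ivs in (
        ("genes.bed", annotations.genes),
        ("tes.bed", annotations.tes),
        ("te_genes.bed", annotations.te_genes),
    ):
        path = outdir / name
        write_bed(ivs, path)
        files.append(path)
    for mark, peaks in annotations.peaks.items():
        path = outdir / f"peaks_{mark}.bed"
        write_bed(peaks, path)
        files.append(path)

    for label in config.sample_labels:
        sample = simulate_methylome(genome, truth, label, config, contexts)
        path = outdir / f"{label}.CX_report.tsv"
        write_cytosine_report(sample, path)
        files.append(path)

    for mutant, table in simulate_expression(annotations, truth, config).items():
        path = outdir / f"de_{mutant}.tsv"
        table.to_csv(path, sep="\t", index=False)
        files.append(path)

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    files.append(truth_path)

    config_path = outdir / "sim_config.json"
    with open(config_path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    files.append(config_path)

    pipeline_cfg = outdir / "pipeline.yaml"
    _write_pipeline_config(pipeline_cfg, outdir, config)
    files.append(pipeline_cfg)

    manifest = {p.name: _sha256(p) for p in files}
    with open(outdir / "manifest.tsv", "w") as fh:
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\n")
    return manifest


def _write_pipeline_config(path: Path, fixture_dir: Path, config: SimulationConfig) -> None:
    # paths are written relative to the config file, so the fixture directory
    # is relocatable and bit-identical across output locations
    import yaml

    wt = config.reference_label
    ko1, ko2 = config.knockout_labels
    d = {
        "seed": config.seed,
        "outdir": "out",
        "genome": "genome.fa",
        "samples": {
            "reference": {"id": wt, "report": f"{wt}.CX_report.tsv"},
            "knockouts": [
                {"id": ko, "report": f"{ko}.CX_report.tsv"} for ko in (ko1, ko2)
            ],
        },
        "annotations": {
            "genes": "genes.bed",
            "tes": "tes.bed",
            "te_genes": "te_genes.bed",
            "histone_peaks": {
                mark: f"peaks_{mark}.bed" for mark, _ in config.histone_mark_fractions
            },
        },
        "expression": [{"id": ko, "table": f"de_{ko}.tsv"} for ko in (ko1, ko2)],
        "truth": "truth.json",
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
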