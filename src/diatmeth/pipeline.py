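"""End-to-end orchestration: methylation -> DMRs -> consensus -> overlap ->
expression integration, from a single YAML config, with a JSON run report.

Every output file carries a header with the tool version, a hash of the
normalized config and the active thresholds, so the analysis (including the
FDR-threshold choice) is traceable from any artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .dmr import ConsensusDmrs, DmrParams, DmrSet, call_dmrs, consensus_dmrs, genome_fraction
from .expression import classify_expression, compare_te_lengths, link_dmr_expression, read_de_table
from .methylome import (
    AnnotationSet,
    GenomicInterval,
    MethylomeSample,
    PositionFilter,
    feature_methylation_matrix,
    filter_by_coverage,
    read_bed,
    read_cytosine_report,
    write_bed,
    write_bedgraph,
)
from .overlap import histone_membership, summarize_te_families, windowed_overlap
from .simulate import SyntheticTruth

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "outdir", "genome", "samples", "annotations", "expression",
    "dmr", "expr_thresholds", "windows", "truth",
}
_KNOWN_DMR_KEYS = {
    "bin_width", "context", "min_cov", "min_delta", "max_p",
    "min_ref_meth_cpg", "min_m",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class PipelineConfig:
    """Validated, default-filled configuration of one pipeline run."""

    genome: str
    reference_id: str
    reference_report: str
    knockout_ids: tuple[str, str]
    knockout_reports: tuple[str, str]
    genes_bed: str
    tes_bed: str
    te_genes_bed: str
    histone_peaks: dict[str, str]
    expression_tables: dict[str, str]
    outdir: str
    dmr_params: DmrParams = field(default_factory=DmrParams)
    lfc_thr: float = 1.0
    fdr_thr: float = 0.01
    windows: tuple[int, ...] = (0, 500, 1000)
    seed: int = 0
    truth: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dmr_params"] = dataclasses.asdict(self.dmr_params)
        d["knockout_ids"] = list(self.knockout_ids)
        d["knockout_reports"] = list(self.knockout_reports)
        d["windows"] = list(self.windows)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def header_lines(self) -> list[str]:
        p = self.dmr_params
        return [
            f"diatmeth {__version__}",
            f"config_hash={self.config_hash}",
            f"dmr: bin_width={p.bin_width} context={p.context} min_cov={p.min_cov} "
            f"min_delta={p.min_delta} max_p={p.max_p} min_ref_meth_cpg={p.min_ref_meth_cpg}",
            f"expression: lfc_thr={self.lfc_thr} fdr_thr={self.fdr_thr}",
        ]


def config_from_dict(raw: Mapping, base: Path | None = None) -> PipelineConfig:
    """Normalize a raw config mapping, collecting *all* errors before raising."""
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config key(s): {sorted(unknown)}")

    def resolve(p) -> str:
        p = Path(p)
        if base is not None and not p.is_absolute():
            p = base / p
        return str(p)

    def need(path_s, what) -> str:
        p = resolve(path_s)
        if not Path(p).exists():
            errors.append(f"{what}: path does not exist: {p}")
        return p

    dmr_raw = dict(raw.get("dmr") or {})
    unknown_dmr = set(dmr_raw) - _KNOWN_DMR_KEYS
    if unknown_dmr:
        errors.append(f"unknown dmr key(s): {sorted(unknown_dmr)}")
        for k in unknown_dmr:
            dmr_raw.pop(k)
    if dmr_raw.get("min_cov", 0) is not None and dmr_raw.get("min_cov", 0) < 0:
        errors.append("min_cov must be >= 0")
        dmr_raw.pop("min_cov")
    try:
        dmr_params = DmrParams(**dmr_raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"dmr params: {exc}")
        dmr_params = DmrParams()

    expr_raw = raw.get("expr_thresholds") or {}
    lfc_thr = float(expr_raw.get("lfc", 1.0))
    fdr_thr = float(expr_raw.get("fdr", 0.01))
    if lfc_thr <= 0:
        errors.append("expr_thresholds.lfc must be > 0")
    if not (0 < fdr_thr <= 1):
        errors.append("expr_thresholds.fdr must be in (0, 1]")

    windows = tuple(raw.get("windows", (0, 500, 1000)))
    if any(w < 0 for w in windows):
        errors.append("windows must be >= 0")

    genome = need(raw.get("genome", ""), "genome") if raw.get("genome") else ""
    if not raw.get("genome"):
        errors.append("genome path is required")

    samples = raw.get("samples") or {}
    ref = samples.get("reference") or {}
    kos = samples.get("knockouts") or []
    if len(kos) != 2:
        errors.append("samples.knockouts must list exactly two knockout samples")
        kos = (kos + [{}, {}])[:2]
    reference_report = need(ref.get("report", ""), "reference report") if ref.get("report") else ""
    if not ref.get("report"):
        errors.append("samples.reference.report is required")
    ko_reports = []
    for ko in kos:
        if ko.get("report"):
            ko_reports.append(need(ko["report"], f"knockout report {ko.get('id')}"))
        else:
            errors.append("each knockout needs a report path")
            ko_reports.append("")

    ann = raw.get("annotations") or {}
    genes_bed = need(ann.get("genes", ""), "genes bed") if ann.get("genes") else ""
    tes_bed = need(ann.get("tes", ""), "tes bed") if ann.get("tes") else ""
    te_genes_bed = need(ann.get("te_genes", ""), "te_genes bed") if ann.get("te_genes") else ""
    for key in ("genes", "tes", "te_genes"):
        if not ann.get(key):
            errors.append(f"annotations.{key} is required")
    peaks = {
        mark: need(path, f"peaks {mark}")
        for mark, path in (ann.get("histone_peaks") or {}).items()
    }

    expr_tables = {}
    for entry in raw.get("expression") or []:
        if not entry.get("id") or not entry.get("table"):
            errors.append("each expression entry needs id and table")
            continue
        expr_tables[entry["id"]] = need(entry["table"], f"expression table {entry['id']}")

    truth = resolve(raw["truth"]) if raw.get("truth") else None
    if truth and not Path(truth).exists():
        errors.append(f"truth: path does not exist: {truth}")

    if errors:
        raise ConfigError(errors)

    return PipelineConfig(
        genome=genome,
        reference_id=ref.get("id", "WT"),
        reference_report=reference_report,
        knockout_ids=tuple(ko.get("id", f"KO{i+1}") for i, ko in enumerate(kos)),
        knockout_reports=tuple(ko_reports),
        genes_bed=genes_bed,
        tes_bed=tes_bed,
        te_genes_bed=te_genes_bed,
        histone_peaks=peaks,
        expression_tables=expr_tables,
        outdir=resolve(raw.get("outdir", "out")),
        dmr_params=dmr_params,
        lfc_thr=lfc_thr,
        fdr_thr=fdr_thr,
        windows=windows,
        seed=int(raw.get("seed", 0)),
        truth=truth,
    )


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config (all errors collected)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, base=path.parent)


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Serializable summary of one pipeline run."""

    data: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.data, indent=1, sort_keys=True, allow_nan=True)
        text = text + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def __getitem__(self, key):
        return self.data[key]


def _read_genome_lengths(path: str) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def island_bin_recovery(
    dmrs: DmrSet,
    islands: Sequence[GenomicInterval],
    position_filter: PositionFilter,
    min_cg: int = 5,
) -> dict:
    """Fraction of planted island bins recovered as hypoDMRs.

    The denominator is the set of grid bins lying fully inside an island and
    containing >= ``min_cg`` retained CG cytosines; edge bins only partially
    inside an island are excluded (their true level difference is diluted).
    """
    filt = position_filter.frame
    eligible: list[tuple[str, int, int]] = []
    w = dmrs.bin_width
    for iv in islands:
        sub = filt[(filt["chrom"] == iv.chrom)]
        pos = sub["pos"].to_numpy()
        first = ((iv.start + w - 1) // w) * w  # first grid start fully inside
        for start in range(first, iv.end - w + 1, w):
            n_cg = int(((pos > start) & (pos <= start + w)).sum())
            if n_cg >= min_cg:
                eligible.append((iv.chrom, start, start + w))
    called = {
        (d.interval.chrom, d.interval.start, d.interval.end) for d in dmrs.hypo
    }
    hit = sum(1 for b in eligible if b in called)
    return {
        "eligible_island_bins": len(eligible),
        "recovered": hit,
        "fraction": hit / len(eligible) if eligible else float("nan"),
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write DMR BEDs, matrices, tables and report JSON."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()

    logger.info("reading genome and annotations")
    genome_lengths = _read_genome_lengths(config.genome)
    genes = read_bed(config.genes_bed, "gene")
    tes = read_bed(config.tes_bed, "TE")
    te_genes = read_bed(config.te_genes_bed, "TE_gene")
    peaks = {m: read_bed(p, "peak") for m, p in config.histone_peaks.items()}

    logger.info("reading cytosine reports")
    ref = read_cytosine_report(config.reference_report, config.reference_id)
    kos = [
        read_cytosine_report(path, kid)
        for kid, path in zip(config.knockout_ids, config.knockout_reports)
    ]

    p = config.dmr_params
    position_filter = filter_by_coverage([ref, *kos], p.min_cov, p.context)
    logger.info("%d cytosines pass the %dX filter in all lines",
                len(position_filter), p.min_cov)

    # methylation matrices and tracks
    features = [*tes, *genes]
    matrix = feature_methylation_matrix([ref, *kos], features, p.context, position_filter)
    matrix_path = outdir / "methylation_matrix.tsv"
    with open(matrix_path, "w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        matrix.to_csv(fh, sep="\t", index_label="feature")
    for sample in (ref, *kos):
        write_bedgraph(sample, p.context, outdir / f"{sample.sample_id}.{p.context}.bedgraph")

    # DMRs per knockout + consensus
    dmr_sets: dict[str, DmrSet] = {}
    for ko in kos:
        dmr_sets[ko.sample_id] = call_dmrs(ref, ko, genome_lengths, p, position_filter)
        dmr_sets[ko.sample_id].write_bed(outdir / f"dmrs_{ko.sample_id}.bed", tuple(header))
    a_id, b_id = config.knockout_ids
    consensus = consensus_dmrs(dmr_sets[a_id], dmr_sets[b_id], "hypo")
    common_ivs = consensus.intervals
    write_bed(common_ivs, outdir / "dmrs_common_hypo.bed", header)
    frac = genome_fraction(consensus, genome_lengths)

    # annotation overlap
    overlap_report: dict = {}
    for label, feats in (("TE", tes), ("gene", genes), ("TE_gene", te_genes)):
        overlap_report[label] = {
            str(w): windowed_overlap(feats, common_ivs, w, genome_lengths).percent
            for w in config.windows
        }
    membership = histone_membership(common_ivs, peaks) if peaks else None
    combo_counts = (
        {"".join(map(str, k)): v for k, v in membership.combination_counts().items()}
        if membership
        else {}
    )

    # expression integration
    expr_report: dict = {}
    link_table = None
    te_len = None
    classification = None
    if config.expression_tables:
        tables = {
            m: read_de_table(path, m) for m, path in config.expression_tables.items()
        }
        classification = classify_expression(tables, config.lfc_thr, config.fdr_thr)
        cat_path = outdir / "expression_categories.tsv"
        with open(cat_path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            classification.categories.to_csv(fh, sep="\t", index_label="feature_id")
        feature_map = {f.name: f for f in [*te_genes, *genes]}
        link = link_dmr_expression(
            classification, common_ivs, feature_map, config.windows,
            genome_lengths, feature_class="TE_gene",
        )
        link_table = link.table
        link_path = outdir / "dmr_expression_link.tsv"
        with open(link_path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            link.table.to_csv(fh, sep="\t", index_label="category")

        up_both = classification.consensus["up_both"]
        up_te_map = {fid: feature_map[fid] for fid in sorted(up_both)
                     if fid in feature_map and feature_map[fid].feature_class == "TE_gene"}
        # length comparison runs on the TEs covered by the upregulated TE-genes
        up_tes = []
        for fid, teg in up_te_map.items():
            hits = [t for t in tes if t.overlaps(teg)]
            up_tes.extend(hits if hits else [teg])
        te_len = compare_te_lengths(up_tes, common_ivs)
        up_te_hit = windowed_overlap(up_tes, common_ivs, 0).hit if up_tes else np.zeros(0, bool)
        fam = summarize_te_families(
            [t for t, h in zip(up_tes, up_te_hit) if h],
            [t for t, h in zip(up_tes, up_te_hit) if not h],
        )
        expr_report = {
            "mutants": list(classification.mutants),
            "category_counts": {
                m: classification.categories[m].value_counts().to_dict()
                for m in classification.mutants
            },
            "consensus_sizes": {
                k: len(v) for k, v in classification.consensus.items()
            },
            "link_percent": {
                cat: {str(w): _nan_to_none(link.table.loc[cat, w]) for w in config.windows}
                for cat in link.table.index
            },
            "regulatory_attribution": {
                str(w): sorted(ids) for w, ids in link.regulatory.items()
            },
            "te_length": {
                "n_overlapping": int(len(te_len.overlapping_lengths)),
                "n_non_overlapping": int(len(te_len.non_overlapping_lengths)),
                "median_overlapping": _nan_to_none(
                    float(np.median(te_len.overlapping_lengths))
                    if len(te_len.overlapping_lengths) else float("nan")
                ),
                "median_non_overlapping": _nan_to_none(
                    float(np.median(te_len.non_overlapping_lengths))
                    if len(te_len.non_overlapping_lengths) else float("nan")
                ),
                "wilcoxon_W": _nan_to_none(te_len.test.statistic),
                "wilcoxon_p": _nan_to_none(te_len.test.p),
                "method": te_len.test.method,
            },
            "te_families": {"hit": fam.hit, "non_hit": fam.complement},
        }

    # truth recovery
    recovery = None
    if config.truth:
        truth = SyntheticTruth.from_json(config.truth)
        recovery = {
            ko_id: island_bin_recovery(dmr_sets[ko_id], truth.islands, position_filter)
            for ko_id in config.knockout_ids
        }
        if classification is not None:
            planted = sorted(truth.upregulated_te_ids)
            feature_map = {f.name: f for f in te_genes}
            planted_ivs = [feature_map[fid] for fid in planted if fid in feature_map]
            decoy_ivs = [
                feature_map[fid]
                for fid in sorted(truth.decoy_upregulated_ids)
                if fid in feature_map
            ]
            recovery["planted_up_overlap_pct"] = (
                windowed_overlap(planted_ivs, common_ivs, 0, genome_lengths).percent
                if planted_ivs else None
            )
            recovery["decoy_up_overlap_pct"] = (
                windowed_overlap(decoy_ivs, common_ivs, 0, genome_lengths).percent
                if decoy_ivs else None
            )

    report = RunReport(
        {
            "version": __version__,
            "config_hash": config.config_hash,
            "config": config.to_dict(),
            "n_retained_cytosines": len(position_filter),
            "genome_lengths": genome_lengths,
            "dmr": {
                ko_id: {
                    "n_dmrs": len(dmr_sets[ko_id]),
                    "n_hypo": len(dmr_sets[ko_id].hypo),
                    "n_hyper": len(dmr_sets[ko_id].hyper),
                    "n_testable_bins": dmr_sets[ko_id].n_testable,
                    "n_untestable_bins": dmr_sets[ko_id].n_untestable,
                    "n_hypo_filtered": dmr_sets[ko_id].n_hypo_filtered,
                }
                for ko_id in config.knockout_ids
            },
            "consensus": {
                "n_common_hypo": len(consensus.common),
                "shared_fraction_a": _nan_to_none(consensus.shared_a),
                "shared_fraction_b": _nan_to_none(consensus.shared_b),
                "genome_fraction_pct": frac,
            },
            "overlap_percent": overlap_report,
            "histone_membership": {
                "labels": membership.labels if membership else [],
                "combination_counts": combo_counts,
                "marginals": membership.marginals() if membership else {},
            },
            "expression": expr_report,
            "recovery": recovery,
        }
    )
    report.to_json(outdir / "report.json")
    return report


def _nan_to_none(x):
    if x is None:
        return None
    try:
        if isinstance(x, float) and np.isnan(x):
            return None
    except TypeError:
        pass
    return x
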