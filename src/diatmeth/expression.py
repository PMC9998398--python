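"""Differential-expression classification and methylation-expression linking.

Takes per-mutant differential-expression summary tables (feature id, log2
fold change, BH-adjusted p), classifies each feature per mutant, builds
cross-mutant consensus sets, standardizes LFCs (z-scores), links expression
categories to consensus hypoDMRs directly and through regulatory-region
windows, and compares TE lengths by DMR status with a Wilcoxon rank-sum test.

Thresholds are strict inequalities: upregulated means lfc > lfc_thr *and*
fdr < fdr_thr; "stable" means significant but small change
(-lfc_thr < lfc < lfc_thr with fdr < fdr_thr), as distinct from
"not_significant". The FDR threshold is a single knob (default 0.01) echoed
into every report.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .methylome import GenomicInterval
from .overlap import windowed_overlap

logger = logging.getLogger(__name__)

CATEGORIES = ("upregulated", "downregulated", "stable", "not_significant")


# ---------------------------------------------------------------------------
# DE table I/O
# ---------------------------------------------------------------------------


def read_de_table(path: str | Path, mutant_label: str) -> pd.DataFrame:
    """Read a DESeq2-style summary table (feature_id, log2FoldChange, padj).

    Returns a frame with columns ``feature_id, lfc, fdr`` (fdr NaN where
    missing); ``frame.attrs['mutant']`` records the label."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = ["feature_id", "log2FoldChange", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame(
        {
            "feature_id": df["feature_id"].astype(str),
            "lfc": pd.to_numeric(df["log2FoldChange"], errors="coerce"),
            "fdr": pd.to_numeric(df["padj"], errors="coerce"),
        }
    )
    if out["lfc"].isna().any():
        bad = df.loc[out["lfc"].isna(), "feature_id"].iloc[0]
        raise ValueError(f"{path}: non-numeric log2FoldChange for {bad!r}")
    dup = out["feature_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate feature_id {out.loc[dup, 'feature_id'].iloc[0]!r}")
    bad_fdr = out["fdr"].notna() & ((out["fdr"] < 0) | (out["fdr"] > 1))
    if bad_fdr.any():
        raise ValueError(f"{path}: padj outside [0, 1]")
    out.attrs["mutant"] = mutant_label
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class ExpressionClassification:
    """Per-mutant expression categories plus cross-mutant consensus sets.

    ``categories`` is a feature x mutant frame of category labels; the
    consensus sets (keys ``up_both``, ``up_a_only``, ``up_b_only`` and the
    ``down``/``stable`` analogs, a/b in mutant order) are disjoint by
    construction."""

    categories: pd.DataFrame
    mutants: tuple[str, str]
    consensus: dict[str, set[str]]
    lfc: pd.DataFrame
    fdr: pd.DataFrame
    lfc_thr: float
    fdr_thr: float

    def category(self, mutant: str) -> pd.Series:
        return self.categories[mutant]


def _normalize_table(t: pd.DataFrame) -> pd.DataFrame:
    """Accept either the normalized (lfc/fdr) or the on-disk
    (log2FoldChange/padj) column dialect."""
    if "lfc" not in t.columns:
        t = t.rename(columns={"log2FoldChange": "lfc", "padj": "fdr"})
    missing = [c for c in ("feature_id", "lfc", "fdr") if c not in t.columns]
    if missing:
        raise ValueError(f"expression table missing column(s) {missing}")
    return t


def _classify_one(lfc: pd.Series, fdr: pd.Series, lfc_thr: float, fdr_thr: float) -> pd.Series:
    sig = fdr.notna() & (fdr < fdr_thr)
    cat = pd.Series("not_significant", index=lfc.index, dtype=object)
    cat[sig & (lfc > lfc_thr)] = "upregulated"
    cat[sig & (lfc < -lfc_thr)] = "downregulated"
    cat[sig & (lfc > -lfc_thr) & (lfc < lfc_thr)] = "stable"
    cat[lfc.isna()] = "not_significant"
    return cat


def classify_expression(
    tables: Mapping[str, pd.DataFrame],
    lfc_thr: float = 1.0,
    fdr_thr: float = 0.01,
) -> ExpressionClassification:
    """Classify features per mutant and intersect across the two mutants.

    ``tables`` maps mutant label -> frame from :func:`read_de_table`.
    Features absent from one table are not_significant there."""
    if lfc_thr <= 0:
        raise ValueError("lfc_thr must be > 0")
    if not (0 < fdr_thr <= 1):
        raise ValueError("fdr_thr must be in (0, 1]")
    if len(tables) != 2:
        raise ValueError("consensus classification needs exactly two mutants")
    tables = {m: _normalize_table(t) for m, t in tables.items()}
    mutants = tuple(tables.keys())
    ids = sorted(set().union(*(t["feature_id"] for t in tables.values())))
    lfc = pd.DataFrame(index=ids, columns=mutants, dtype=float)
    fdr = pd.DataFrame(index=ids, columns=mutants, dtype=float)
    for mutant, t in tables.items():
        lfc.loc[t["feature_id"].to_numpy(), mutant] = t["lfc"].to_numpy()
        fdr.loc[t["feature_id"].to_numpy(), mutant] = t["fdr"].to_numpy()
    categories = pd.DataFrame(
        {m: _classify_one(lfc[m], fdr[m], lfc_thr, fdr_thr) for m in mutants}
    )
    a, b = mutants
    consensus: dict[str, set[str]] = {}
    for short, cat in (("up", "upregulated"), ("down", "downregulated"), ("stable", "stable")):
        in_a = set(categories.index[categories[a] == cat])
        in_b = set(categories.index[categories[b] == cat])
        consensus[f"{short}_both"] = in_a & in_b
        consensus[f"{short}_a_only"] = in_a - in_b
        consensus[f"{short}_b_only"] = in_b - in_a
    return ExpressionClassification(
        categories, (a, b), consensus, lfc, fdr, lfc_thr, fdr_thr
    )


def lfc_zscore(
    table: pd.DataFrame,
    feature_subset: Sequence[str] | None = None,
    flag_threshold: float = 2.0,
) -> pd.Series:
    """Mean-centered, sample-sd-normalized LFC over a feature subset.

    Returns z per feature; ``result.attrs['high']`` lists features with
    z > ``flag_threshold``. All-NaN when the subset sd is zero."""
    t = table.set_index("feature_id")["lfc"]
    if feature_subset is not None:
        missing = sorted(set(feature_subset) - set(t.index))
        if missing:
            raise KeyError(f"features absent from table: {missing[:5]}")
        t = t.loc[list(feature_subset)]
    if len(t) < 2:
        raise ValueError("z-score needs a subset of size >= 2")
    sd = t.std(ddof=1)
    if sd == 0 or math.isnan(sd):
        z = pd.Series(float("nan"), index=t.index)
    else:
        z = (t - t.mean()) / sd
    z.attrs["high"] = set(z.index[z > flag_threshold])
    return z


# ---------------------------------------------------------------------------
# DMR linkage
# ---------------------------------------------------------------------------


@dataclass
class DmrExpressionLink:
    """Percent of each expression category overlapping consensus hypoDMRs per
    window, plus regulatory-region attributions.

    ``table`` rows are category names, columns the windows (bp); values are
    percentages (NaN for empty categories). ``regulatory`` maps each nonzero
    window to the consensus-upregulated features that miss the DMRs at window
    0 but are hit once extended — methylation loss attributable to their
    regulatory region rather than the feature body."""

    table: pd.DataFrame
    regulatory: dict[int, set[str]]
    category_sizes: dict[str, int]


def link_dmr_expression(
    classification: ExpressionClassification,
    common_hypodmrs: Sequence[GenomicInterval],
    features: Mapping[str, GenomicInterval],
    windows: Sequence[int] = (0, 500, 1000),
    chrom_lengths: Mapping[str, int] | None = None,
    feature_class: str | None = "TE_gene",
) -> DmrExpressionLink:
    """Link expression categories to consensus hypoDMRs at several windows.

    ``features`` maps feature id -> coordinates; only features of
    ``feature_class`` (all when None) present in the classification are
    considered. Classified features of the right class lacking coordinates
    raise."""
    if any(w < 0 for w in windows):
        raise ValueError("windows must be >= 0")
    all_features = dict(features)
    if feature_class is not None:
        features = {
            fid: iv for fid, iv in features.items() if iv.feature_class == feature_class
        }
    # classified consensus features with no coordinates anywhere are an error;
    # features of another class are silently out of scope for this report
    missing = sorted(
        (classification.consensus["up_both"] | classification.consensus["down_both"])
        - set(all_features)
    )
    if missing:
        raise ValueError(f"classified features without coordinates: {missing[:10]}")
    groups = {
        "up_both": classification.consensus["up_both"],
        "up_a_only": classification.consensus["up_a_only"],
        "up_b_only": classification.consensus["up_b_only"],
        "down_both": classification.consensus["down_both"],
        "stable_both": classification.consensus["stable_both"],
    }
    universe = set(features)
    groups = {k: sorted(v & universe) for k, v in groups.items()}

    table = pd.DataFrame(index=list(groups), columns=list(windows), dtype=float)
    hits_by_window: dict[int, set[str]] = {}
    for w in windows:
        all_ids = sorted(set(itertools.chain.from_iterable(groups.values())))
        ivs = [features[fid] for fid in all_ids]
        res = windowed_overlap(ivs, list(common_hypodmrs), w, chrom_lengths)
        hit_ids = {all_ids[i] for i in np.nonzero(res.hit)[0]}
        hits_by_window[w] = hit_ids
        for g, ids in groups.items():
            table.loc[g, w] = (
                100.0 * len(hit_ids & set(ids)) / len(ids) if ids else float("nan")
            )
    base = hits_by_window.get(0, set())
    regulatory = {
        w: (hits_by_window[w] & set(groups["up_both"])) - base
        for w in windows
        if w > 0
    }
    return DmrExpressionLink(table, regulatory, {g: len(ids) for g, ids in groups.items()})


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided Wilcoxon rank-sum result; W is the rank-sum of the first
    sample (midranks for ties)."""

    statistic: float
    p: float
    method: str  # "exact" | "normal_approx" | "undefined"


_EXACT_LIMIT = 12


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by full enumeration of rank assignments when n1+n2 <= 12 and
    there are no ties; otherwise a normal approximation with tie-corrected
    variance and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= _EXACT_LIMIT and not has_ties:
        # null distribution of the rank-sum by enumeration of all C(n, n1)
        # assignments of ranks 1..n to the first sample
        sums = [sum(c) for c in itertools.combinations(range(1, n + 1), n1)]
        total = len(sums)
        le = sum(1 for s in sums if s <= w)
        ge = sum(1 for s in sums if s >= w)
        p = min(1.0, 2.0 * min(le, ge) / total)
        return WilcoxonResult(w, p, "exact")

    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return WilcoxonResult(w, 1.0, "normal_approx")
    d = w - mean
    d_cc = math.copysign(max(0.0, abs(d) - 0.5), d)
    z = d_cc / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return WilcoxonResult(w, p, "normal_approx")


@dataclass
class TeLengthComparison:
    """Length distributions of DMR-overlapping vs non-overlapping TEs."""

    overlapping_lengths: np.ndarray
    non_overlapping_lengths: np.ndarray
    test: WilcoxonResult


def compare_te_lengths(
    upregulated_tes: Sequence[GenomicInterval],
    common_hypodmrs: Sequence[GenomicInterval],
) -> TeLengthComparison:
    """Partition consensus-upregulated TE features by direct hypoDMR overlap
    and test their length distributions (end - start) for a shift."""
    res = windowed_overlap(list(upregulated_tes), list(common_hypodmrs), 0)
    lengths = np.array([iv.length for iv in upregulated_tes], dtype=float)
    in_dmr = lengths[res.hit]
    out_dmr = lengths[~res.hit]
    if len(in_dmr) == 0 or len(out_dmr) == 0:
        logger.warning("one TE-length partition is empty; Wilcoxon p undefined")
        test = WilcoxonResult(float("nan"), float("nan"), "undefined")
    else:
        test = wilcoxon_rank_sum(in_dmr, out_dmr)
    return TeLengthComparison(in_dmr, out_dmr, test)
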