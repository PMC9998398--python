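"""Binned differential-methylation calling with a two-proportion score test.

The caller tiles each chromosome with fixed-width bins (default 100 bp),
pools methylated/total read counts of the retained in-context cytosines per
bin, and tests equality of methylation proportions between a reference and a
treatment sample with the pooled-variance score statistic

    z = (p1 - p2) / sqrt( p_hat (1 - p_hat) (1/n1 + 1/n2) ),
    p_hat = (m1 + m2) / (n1 + n2),

with a two-sided normal p-value.  A bin is a DMR when the absolute level
difference clears ``min_delta`` and p <= ``max_p``; hypoDMRs (loss in the
treatment) must additionally contain at least ``min_ref_meth_cpg`` methylated
reference cytosines, separating regional loss from isolated methylated sites.

Adjacent significant bins are deliberately *not* merged: DMRs stay fixed
bin-width regions so counts remain bin-denominated. ``merge_adjacent`` is
available for callers who want joined regions. Raw p-values are thresholded
without multiple-testing correction by default; pass ``fdr=True`` to
:func:`call_dmrs` for Benjamini-Hochberg adjusted thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .methylome import (
    GenomicInterval,
    MethylomeSample,
    PositionFilter,
    filter_by_coverage,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreTestResult:
    """Score statistic and two-sided p-value; NaN marks an untestable bin."""

    z: float
    p: float

    @property
    def testable(self) -> bool:
        return not math.isnan(self.p)


@dataclass(frozen=True)
class BinCounts:
    """Aggregated read counts of one bin for a reference/treatment pair."""

    interval: GenomicInterval
    m_ref: int
    n_ref: int
    m_treat: int
    n_treat: int
    n_cytosines: int
    n_meth_ref: int  # retained ref cytosines with m >= min_m reads

    @property
    def level_ref(self) -> float:
        return self.m_ref / self.n_ref if self.n_ref else float("nan")

    @property
    def level_treat(self) -> float:
        return self.m_treat / self.n_treat if self.n_treat else float("nan")


@dataclass(frozen=True)
class Dmr:
    """A called differentially methylated bin with supporting statistics."""

    interval: GenomicInterval
    direction: str  # "hypo" (loss in treatment) or "hyper"
    delta: float  # level_ref - level_treat
    level_ref: float
    level_treat: float
    test: ScoreTestResult
    n_cytosines: int
    n_meth_ref: int


@dataclass(frozen=True)
class DmrParams:
    """Thresholds of the binned caller (defaults follow the study design)."""

    bin_width: int = 100
    context: str = "CG"
    min_cov: int = 5
    min_delta: float = 0.20
    max_p: float = 0.01
    min_ref_meth_cpg: int = 2
    min_m: int = 1  # read support defining a "methylated" reference cytosine

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.min_cov < 0:
            raise ValueError("min_cov must be >= 0")
        if not (0 <= self.min_delta <= 1.01):
            raise ValueError("min_delta must be in [0, 1]")
        if not (0 < self.max_p <= 1):
            raise ValueError("max_p must be in (0, 1]")
        if self.min_ref_meth_cpg < 0:
            raise ValueError("min_ref_meth_cpg must be >= 0")


@dataclass
class DmrSet:
    """DMRs called on one reference/treatment pair over a fixed bin grid."""

    dmrs: list[Dmr]
    bin_width: int
    genome_lengths: dict[str, int]
    params: DmrParams
    ref_id: str = ""
    treat_id: str = ""
    n_testable: int = 0
    n_untestable: int = 0
    n_hypo_filtered: int = 0  # dropped by the min_ref_meth_cpg rule

    def __len__(self) -> int:
        return len(self.dmrs)

    def __iter__(self):
        return iter(self.dmrs)

    def by_direction(self, direction: str) -> list[Dmr]:
        return [d for d in self.dmrs if d.direction == direction]

    @property
    def hypo(self) -> list[Dmr]:
        return self.by_direction("hypo")

    @property
    def hyper(self) -> list[Dmr]:
        return self.by_direction("hyper")

    def intervals(self, direction: str | None = None) -> list[GenomicInterval]:
        dmrs = self.dmrs if direction is None else self.by_direction(direction)
        return [d.interval for d in dmrs]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "direction": d.direction,
                "level_ref": d.level_ref,
                "level_treat": d.level_treat,
                "delta": d.delta,
                "z": d.test.z,
                "p": d.test.p,
                "n_cytosines": d.n_cytosines,
                "n_meth_ref": d.n_meth_ref,
            }
            for d in self.dmrs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "direction", "level_ref", "level_treat",
                "delta", "z", "p", "n_cytosines", "n_meth_ref",
            ],
        )

    def write_bed(self, path, header: tuple[str, ...] = ()) -> None:
        """BED6+ with score = -log10(p) (capped at 300) and the supporting
        statistics in extra columns; readable back via :func:`read_dmr_bed`."""
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            fh.write(
                "#chrom\tstart\tend\tname\tscore\tstrand\tdirection\t"
                "level_ref\tlevel_treat\tdelta\tz\tp\tn_cytosines\tn_meth_ref\n"
            )
            for d in sorted(self.dmrs, key=lambda d: d.interval):
                iv = d.interval
                score = 300.0 if d.test.p <= 0 else min(300.0, -math.log10(d.test.p))
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.chrom}:{iv.start}-{iv.end}\t{score:.4g}\t.\t"
                    f"{d.direction}\t{d.level_ref:.6g}\t{d.level_treat:.6g}\t"
                    f"{d.delta:.6g}\t{d.test.z:.6g}\t{d.test.p:.6g}\t"
                    f"{d.n_cytosines}\t{d.n_meth_ref}\n"
                )


def read_dmr_bed(path) -> list[Dmr]:
    """Read a DMR BED written by :meth:`DmrSet.write_bed`."""
    out: list[Dmr] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[3], "DMR")
            out.append(
                Dmr(
                    iv,
                    f[6],
                    float(f[9]),
                    float(f[7]),
                    float(f[8]),
                    ScoreTestResult(float(f[10]), float(f[11])),
                    int(f[12]),
                    int(f[13]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def make_bins(genome_lengths: dict[str, int], width: int = 100) -> list[GenomicInterval]:
    """Tile each chromosome with ``[0,w), [w,2w), ...``; the final partial bin
    keeps its true (shorter) length."""
    if width < 1:
        raise ValueError("bin width must be >= 1")
    bins: list[GenomicInterval] = []
    for chrom, length in genome_lengths.items():
        if length < 0:
            raise ValueError(f"negative length for {chrom}")
        for start in range(0, length, width):
            bins.append(
                GenomicInterval(chrom, start, min(start + width, length), feature_class="bin")
            )
    return bins


def score_test(m1: int, n1: int, m2: int, n2: int) -> ScoreTestResult:
    """Two-proportion score test of equal methylation rates.

    Returns z = 0, p = 1 when the pooled proportion is 0 or 1 (zero
    variance), and an untestable NaN result when either total is zero.
    """
    for v in (m1, n1, m2, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if m1 > n1 or m2 > n2:
        raise ValueError("methylated count exceeds total")
    if n1 == 0 or n2 == 0:
        return ScoreTestResult(float("nan"), float("nan"))
    pooled = (m1 + m2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return ScoreTestResult(0.0, 1.0)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (m1 / n1 - m2 / n2) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return ScoreTestResult(z, min(p, 1.0))


def score_test_arrays(
    m1: np.ndarray, n1: np.ndarray, m2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`score_test`; NaN where a bin is untestable."""
    m1 = np.asarray(m1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    z = np.full(m1.shape, np.nan)
    p = np.full(m1.shape, np.nan)
    ok = (n1 > 0) & (n2 > 0)
    pooled = np.divide(m1 + m2, n1 + n2, out=np.zeros_like(m1), where=(n1 + n2) > 0)
    degenerate = ok & ((pooled <= 0) | (pooled >= 1))
    z[degenerate] = 0.0
    p[degenerate] = 1.0
    live = ok & ~degenerate
    if live.any():
        se = np.sqrt(pooled[live] * (1 - pooled[live]) * (1 / n1[live] + 1 / n2[live]))
        zl = (m1[live] / n1[live] - m2[live] / n2[live]) / se
        z[live] = zl
        p[live] = np.minimum(2 * norm.sf(np.abs(zl)), 1.0)
    return z, p


def aggregate_counts(
    bins: list[GenomicInterval],
    ref: MethylomeSample,
    treat: MethylomeSample,
    context: str | None = "CG",
    position_filter: PositionFilter | None = None,
    min_m: int = 1,
) -> list[BinCounts]:
    """Pool per-cytosine counts into bins for a reference/treatment pair.

    The cytosine universe per bin is the position filter when supplied,
    otherwise the union of in-context positions seen in either sample.
    Bins must be sorted and non-overlapping per chromosome (grid bins are).
    """

    def in_context(sample: MethylomeSample) -> pd.DataFrame:
        f = sample.frame
        if context is not None:
            f = f[f["context"] == context]
        if position_filter is not None:
            f = position_filter.restrict(f)
        return f[["chrom", "pos", "strand", "m", "u"]]

    fr = in_context(ref)
    ft = in_context(treat)
    uni = fr.merge(
        ft, on=["chrom", "pos", "strand"], how="outer", suffixes=("_ref", "_treat")
    ).fillna(0)

    nbins = len(bins)
    m_ref = np.zeros(nbins, dtype=np.int64)
    n_ref = np.zeros(nbins, dtype=np.int64)
    m_treat = np.zeros(nbins, dtype=np.int64)
    n_treat = np.zeros(nbins, dtype=np.int64)
    n_cyt = np.zeros(nbins, dtype=np.int64)
    n_meth = np.zeros(nbins, dtype=np.int64)

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for gi, b in enumerate(bins):
        per_chrom.setdefault(b.chrom, ([], [], []))  # type: ignore[arg-type]
        starts, ends, gidx = per_chrom[b.chrom]
        starts.append(b.start)  # type: ignore[union-attr]
        ends.append(b.end)  # type: ignore[union-attr]
        gidx.append(gi)  # type: ignore[union-attr]
    per_chrom = {
        c: (np.asarray(s), np.asarray(e), np.asarray(g)) for c, (s, e, g) in per_chrom.items()
    }

    for chrom, grp in uni.groupby("chrom", sort=False):
        entry = per_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends, gidx = entry
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1
        bi = np.searchsorted(starts, pos0, side="right") - 1
        valid = (bi >= 0) & (pos0 < ends[np.clip(bi, 0, len(ends) - 1)])
        bi = gidx[bi[valid]]
        mr = grp["m_ref"].to_numpy(dtype=np.int64)[valid]
        ur = grp["u_ref"].to_numpy(dtype=np.int64)[valid]
        mt = grp["m_treat"].to_numpy(dtype=np.int64)[valid]
        ut = grp["u_treat"].to_numpy(dtype=np.int64)[valid]
        np.add.at(m_ref, bi, mr)
        np.add.at(n_ref, bi, mr + ur)
        np.add.at(m_treat, bi, mt)
        np.add.at(n_treat, bi, mt + ut)
        np.add.at(n_cyt, bi, 1)
        np.add.at(n_meth, bi, (mr >= min_m).astype(np.int64))

    return [
        BinCounts(
            bins[i],
            int(m_ref[i]),
            int(n_ref[i]),
            int(m_treat[i]),
            int(n_treat[i]),
            int(n_cyt[i]),
            int(n_meth[i]),
        )
        for i in range(nbins)
    ]


def call_dmrs(
    ref: MethylomeSample,
    treat: MethylomeSample,
    genome_lengths: dict[str, int],
    params: DmrParams = DmrParams(),
    position_filter: PositionFilter | None = None,
    fdr: bool = False,
) -> DmrSet:
    """Call fixed-width DMR bins between a reference and a treatment sample.

    ``position_filter`` should come from :func:`filter_by_coverage` over all
    study samples; when omitted it is computed from the given pair alone.
    With ``fdr=True`` the p threshold is applied to Benjamini-Hochberg
    adjusted p-values instead of raw ones.
    """
    if position_filter is None:
        position_filter = filter_by_coverage([ref, treat], params.min_cov, params.context)
    if len(position_filter) == 0:
        logger.warning("empty position filter: no cytosine passes the coverage filter")
        return DmrSet([], params.bin_width, dict(genome_lengths), params,
                      ref.sample_id, treat.sample_id)

    bins = make_bins(genome_lengths, params.bin_width)
    counts = aggregate_counts(
        bins, ref, treat, params.context, position_filter, params.min_m
    )
    m1 = np.array([c.m_ref for c in counts])
    n1 = np.array([c.n_ref for c in counts])
    m2 = np.array([c.m_treat for c in counts])
    n2 = np.array([c.n_treat for c in counts])
    ncyt = np.array([c.n_cytosines for c in counts])
    z, p = score_test_arrays(m1, n1, m2, n2)

    occupied = ncyt >= 1
    testable = occupied & (n1 > 0) & (n2 > 0)
    n_untestable = int((occupied & ~testable).sum())

    p_eff = p.copy()
    if fdr:
        idx = np.nonzero(testable)[0]
        p_eff[idx] = _benjamini_hochberg(p[idx])

    with np.errstate(invalid="ignore", divide="ignore"):
        lev1 = np.divide(m1, n1, out=np.full(len(m1), np.nan), where=n1 > 0)
        lev2 = np.divide(m2, n2, out=np.full(len(m2), np.nan), where=n2 > 0)
    delta = lev1 - lev2

    dmrs: list[Dmr] = []
    n_hypo_filtered = 0
    cand = np.nonzero(
        testable & (np.abs(delta) >= params.min_delta) & (p_eff <= params.max_p)
    )[0]
    for i in cand:
        c = counts[i]
        direction = "hypo" if delta[i] > 0 else "hyper"
        if direction == "hypo" and c.n_meth_ref < params.min_ref_meth_cpg:
            n_hypo_filtered += 1
            continue
        iv = c.interval
        dmrs.append(
            Dmr(
                GenomicInterval(iv.chrom, iv.start, iv.end,
                                f"{iv.chrom}:{iv.start}-{iv.end}", "DMR"),
                direction,
                float(delta[i]),
                float(lev1[i]),
                float(lev2[i]),
                ScoreTestResult(float(z[i]), float(p[i])),
                c.n_cytosines,
                c.n_meth_ref,
            )
        )
    logger.info(
        "%s vs %s: %d bins occupied, %d testable, %d untestable (skipped), "
        "%d DMRs (%d dropped by min_ref_meth_cpg)",
        ref.sample_id, treat.sample_id, int(occupied.sum()), int(testable.sum()),
        n_untestable, len(dmrs), n_hypo_filtered,
    )
    return DmrSet(
        dmrs,
        params.bin_width,
        dict(genome_lengths),
        params,
        ref.sample_id,
        treat.sample_id,
        n_testable=int(testable.sum()),
        n_untestable=n_untestable,
        n_hypo_filtered=n_hypo_filtered,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Consensus and genome coverage
# ---------------------------------------------------------------------------


@dataclass
class ConsensusDmrs:
    """Bins called with the same direction in both replicate comparisons."""

    common: list[Dmr]  # statistics from set A's call
    a_only: list[Dmr]
    b_only: list[Dmr]
    shared_a: float  # |common| / |A|, NaN when A is empty
    shared_b: float
    direction: str
    bin_width: int = 100
    genome_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [d.interval for d in self.common]


def consensus_dmrs(set_a: DmrSet, set_b: DmrSet, direction: str = "hypo") -> ConsensusDmrs:
    """Intersect two DMR sets on identical bin coordinates and direction."""
    if set_a.bin_width != set_b.bin_width or set_a.genome_lengths != set_b.genome_lengths:
        raise ValueError("DMR sets are on different bin grids")
    a = {(d.interval.chrom, d.interval.start, d.interval.end): d
         for d in set_a.by_direction(direction)}
    b = {(d.interval.chrom, d.interval.start, d.interval.end): d
         for d in set_b.by_direction(direction)}
    common_keys = sorted(a.keys() & b.keys())
    common = [a[k] for k in common_keys]
    a_only = [a[k] for k in sorted(a.keys() - b.keys())]
    b_only = [b[k] for k in sorted(b.keys() - a.keys())]
    shared_a = len(common) / len(a) if a else float("nan")
    shared_b = len(common) / len(b) if b else float("nan")
    return ConsensusDmrs(
        common, a_only, b_only, shared_a, shared_b, direction,
        set_a.bin_width, dict(set_a.genome_lengths),
    )


def genome_fraction(
    dmrs: DmrSet | ConsensusDmrs | list[GenomicInterval],
    genome_lengths: dict[str, int],
) -> float:
    """Percent of the genome covered by the (disjoint, grid-aligned) DMRs."""
    total = sum(genome_lengths.values())
    if total <= 0:
        raise ValueError("zero total genome length")
    if isinstance(dmrs, DmrSet):
        intervals = dmrs.intervals()
    elif isinstance(dmrs, ConsensusDmrs):
        intervals = dmrs.intervals
    else:
        intervals = list(dmrs)
    covered = sum(iv.length for iv in intervals)
    return 100.0 * covered / total


def merge_adjacent(dmrs: list[Dmr], max_gap: int = 0) -> list[GenomicInterval]:
    """Join same-direction DMR bins separated by <= ``max_gap`` bp. Optional;
    the default pipeline reports fixed-width bins unmerged."""
    out: list[GenomicInterval] = []
    for d in sorted(dmrs, key=lambda d: d.interval):
        iv = d.interval
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= max_gap:
            out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end,
                                      feature_class="DMR")
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end, feature_class="DMR"))
    return out
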