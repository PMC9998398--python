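"""Interval-overlap engine: direct and windowed feature/DMR overlap, histone
mark membership (UpSet-style exclusive combination counts) and TE-family
summaries.

Overlap semantics follow bedtools defaults: half-open intervals, >= 1 bp of
shared sequence, strand ignored. Window extension clips at 0 and, when
chromosome lengths are supplied, at the chromosome end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .methylome import GenomicInterval

logger = logging.getLogger(__name__)


def _trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


@dataclass
class OverlapResult:
    """All overlapping (query, subject) index pairs plus per-query hit flags."""

    pairs: list[tuple[int, int, int]]  # (query index, subject index, overlap bp)
    query_hit: np.ndarray  # bool, aligned to the input query order


def overlap(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> OverlapResult:
    """Report every query/subject pair sharing >= ``min_bp`` bases.

    Pairs are ordered by query coordinate then subject coordinate."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _trees(subject)
    pairs: list[tuple[int, int, int]] = []
    hit = np.zeros(len(query), dtype=bool)
    order = sorted(range(len(query)), key=lambda i: query[i])
    for qi in order:
        q = query[qi]
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        found = []
        for entry in tree.overlap(q.start, q.end):
            bp = min(q.end, entry.end) - max(q.start, entry.begin)
            if bp >= min_bp:
                found.append((entry.begin, entry.end, entry.data, bp))
        for _, _, si, bp in sorted(found):
            pairs.append((qi, si, bp))
            hit[qi] = True
    return OverlapResult(pairs, hit)


@dataclass
class WindowedOverlap:
    """Features hit by >= 1 DMR within +/- window bp of their span."""

    hit: np.ndarray  # bool per feature, input order
    hit_ids: set[str]
    percent: float  # 100 * hits / #features (NaN when no features)


def windowed_overlap(
    features: Sequence[GenomicInterval],
    dmrs: Sequence[GenomicInterval],
    window: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> WindowedOverlap:
    """Count features whose +/- ``window`` bp extension overlaps any DMR.

    ``window=0`` reduces to direct overlap. Extensions clip at 0 and at the
    chromosome end when ``chrom_lengths`` is given."""
    if window < 0:
        raise ValueError("window must be >= 0")
    trees = _trees(dmrs)
    hit = np.zeros(len(features), dtype=bool)
    for i, f in enumerate(features):
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        length = chrom_lengths.get(f.chrom) if chrom_lengths else None
        ext = f.extended(window, length)
        hit[i] = bool(tree.overlap(ext.start, ext.end))
    ids = {features[i].name or repr(features[i]) for i in np.nonzero(hit)[0]}
    percent = 100.0 * hit.sum() / len(features) if len(features) else float("nan")
    return WindowedOverlap(hit, ids, percent)


@dataclass
class MembershipMatrix:
    """Boolean DMR x peak-set membership with UpSet-style combination counts."""

    row_ids: list[str]
    labels: list[str]
    values: np.ndarray  # bool, shape (#rows, #labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.labels)

    def combination_counts(self) -> dict[tuple[int, ...], int]:
        """Count rows per *exclusive* membership pattern (including all-zero);
        the counts partition the rows."""
        counts: dict[tuple[int, ...], int] = {}
        for row in self.values:
            key = tuple(int(v) for v in row)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def marginals(self) -> dict[str, int]:
        return {
            label: int(self.values[:, j].sum()) for j, label in enumerate(self.labels)
        }


def histone_membership(
    dmrs: Sequence[GenomicInterval],
    peak_sets: Mapping[str, Sequence[GenomicInterval]] | Sequence[tuple[str, Sequence[GenomicInterval]]],
) -> MembershipMatrix:
    """Membership of each DMR in each labeled peak set (>= 1 bp overlap)."""
    items = list(peak_sets.items()) if isinstance(peak_sets, Mapping) else list(peak_sets)
    if not items:
        raise ValueError("need at least one peak set")
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate peak-set labels in {labels}")
    values = np.zeros((len(dmrs), len(items)), dtype=bool)
    for j, (_, peaks) in enumerate(items):
        trees = _trees(peaks)
        for i, d in enumerate(dmrs):
            tree = trees.get(d.chrom)
            values[i, j] = bool(tree and tree.overlap(d.start, d.end))
    row_ids = [d.name or f"{d.chrom}:{d.start}-{d.end}" for d in dmrs]
    return MembershipMatrix(row_ids, labels, values)


@dataclass
class TeFamilySummary:
    """Per-family TE counts for a hit set and (optionally) its complement.

    Families represented by fewer than ``min_members`` TEs in a set are
    dropped from that set's table."""

    hit: dict[str, int]
    complement: dict[str, int] | None
    min_members: int


def _family_counts(
    tes: Sequence[GenomicInterval],
    family_map: Mapping[str, str] | None,
    min_members: int,
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for te in tes:
        family = te.family
        if family_map is not None:
            family = family_map.get(te.name, family)
        if not family:
            family = "unknown"
            logger.warning("TE %s has no family; assigned 'unknown'", te.name or te)
        counts[family] = counts.get(family, 0) + 1
    return {f: c for f, c in sorted(counts.items()) if c >= min_members}


def summarize_te_families(
    te_hits: Sequence[GenomicInterval],
    te_complement: Sequence[GenomicInterval] | None = None,
    min_members: int = 3,
    family_map: Mapping[str, str] | None = None,
) -> TeFamilySummary:
    """Count hit TEs per family, discarding families with < ``min_members``;
    the complement (non-hit) set is summarized the same way when supplied."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    hit = _family_counts(te_hits, family_map, min_members)
    comp = (
        _family_counts(te_complement, family_map, min_members)
        if te_complement is not None
        else None
    )
    return TeFamilySummary(hit, comp, min_members)
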