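"""Methylome and annotation I/O, cytosine contexts, and region methylation.

Conventions
-----------
* Genomic intervals are 0-based, half-open ``[start, end)`` (BED semantics).
* Cytosine reports are 1-based, one row per cytosine per strand, in the
  seven-column Bismark-like dialect::

      chrom  pos  strand  count_methylated  count_unmethylated  context  trinucleotide

* CG sites are kept per strand and are *not* collapsed into symmetric CpG
  dyads; the coverage filter and all level computations operate on individual
  cytosines. :func:`pool_symmetric_cg` is available for callers who want
  dyad-pooled counts, but nothing in the default pipeline uses it.
* A region with zero retained coverage has an *undefined* methylation level,
  reported as NaN — never as 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

_REPORT_COLUMNS = ["chrom", "pos", "strand", "m", "u", "context", "trinucleotide"]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


class ReportParseError(ValueError):
    """Raised when a cytosine report or table row cannot be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with an optional feature class and family.

    ``feature_class`` is one of ``gene``, ``TE``, ``TE_gene``, ``peak``,
    ``DMR``, ``island`` or ``bin``; ``family`` carries the TE family label
    when the interval is a transposable element.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    feature_class: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def extended(self, window: int, chrom_length: int | None = None) -> "GenomicInterval":
        """Interval extended by ``window`` bp on both sides, clipped at the
        chromosome bounds (left at 0; right at ``chrom_length`` if given)."""
        if window < 0:
            raise ValueError("window must be >= 0")
        start = max(0, self.start - window)
        end = self.end + window
        if chrom_length is not None:
            end = min(end, chrom_length)
        return dataclasses.replace(self, start=start, end=end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AnnotationSet:
    """Genes, TEs, TE-genes and labeled histone-peak sets for one genome."""

    genes: list[GenomicInterval] = field(default_factory=list)
    tes: list[GenomicInterval] = field(default_factory=list)
    te_genes: list[GenomicInterval] = field(default_factory=list)
    peaks: dict[str, list[GenomicInterval]] = field(default_factory=dict)


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine on one strand with methylated / unmethylated read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    m: int
    u: int
    context: str
    trinucleotide: str = "NNN"

    def __post_init__(self) -> None:
        if self.m < 0 or self.u < 0:
            raise ValueError("read counts must be non-negative")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.m + self.u

    @property
    def level(self) -> float:
        n = self.coverage
        return self.m / n if n else float("nan")


class MethylomeSample:
    """Per-cytosine methylation counts of one sample over one genome.

    Thin wrapper around a pandas frame with columns
    ``chrom, pos, strand, m, u, context, trinucleotide``; rows are unique per
    (chrom, pos, strand) and kept sorted for deterministic iteration.
    """

    def __init__(self, sample_id: str, frame: pd.DataFrame):
        missing = [c for c in _REPORT_COLUMNS[:-1] if c not in frame.columns]
        if missing:
            raise ValueError(f"methylome frame missing columns {missing}")
        frame = frame.copy()
        if "trinucleotide" not in frame.columns:
            frame["trinucleotide"] = "NNN"
        frame = frame[_REPORT_COLUMNS]
        frame = frame.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        dup = frame.duplicated(["chrom", "pos", "strand"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValueError(
                f"duplicate cytosine {row.chrom}:{row.pos}({row.strand}) "
                f"in sample {sample_id!r}"
            )
        if (frame["m"] < 0).any() or (frame["u"] < 0).any():
            raise ValueError("negative read counts")
        self.sample_id = sample_id
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[CytosineRecord]:
        for row in self.frame.itertuples(index=False):
            yield CytosineRecord(
                row.chrom, int(row.pos), row.strand, int(row.m), int(row.u),
                row.context, row.trinucleotide,
            )

    def select(self, chrom: str | None = None, context: str | None = None) -> pd.DataFrame:
        f = self.frame
        if chrom is not None:
            f = f[f["chrom"] == chrom]
        if context is not None:
            f = f[f["context"] == context]
        return f

    @property
    def coverage(self) -> pd.Series:
        return self.frame["m"] + self.frame["u"]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_cytosine_report(path: str | Path, sample_id: str | None = None) -> MethylomeSample:
    """Parse a 7-column cytosine report into a :class:`MethylomeSample`.

    Errors name the 1-based line number of the first offending row.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ReportParseError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, got {len(parts)}"
                )
            chrom, pos_s, strand, m_s, u_s, context, trinuc = parts
            try:
                pos, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise ReportParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            if pos < 1:
                raise ReportParseError(f"{path}:{lineno}: position must be >= 1")
            if m < 0 or u < 0:
                raise ReportParseError(f"{path}:{lineno}: negative read count")
            if strand not in STRANDS:
                raise ReportParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if context not in CONTEXTS:
                raise ReportParseError(f"{path}:{lineno}: unknown context {context!r}")
            rows.append((chrom, pos, strand, m, u, context, trinuc))
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    try:
        return MethylomeSample(sample_id, frame)
    except ValueError as exc:
        raise ReportParseError(f"{path}: {exc}") from exc


def write_cytosine_report(sample: MethylomeSample, path: str | Path) -> None:
    sample.frame.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, feature_class: str = "") -> list[GenomicInterval]:
    """Read BED (>=3 columns); a name of the form ``id|family`` populates the
    interval's family label. Lines starting with ``#``, ``track`` or
    ``browser`` are skipped."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ReportParseError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            family = None
            if "|" in name:
                name, family = name.split("|", 1)
            out.append(GenomicInterval(chrom, start, end, name, feature_class, family))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    header: Sequence[str] = (),
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6; TE families are folded back into the name as ``id|family``."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        for i, iv in enumerate(sorted(intervals)):
            name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
            if iv.family:
                name = f"{name}|{iv.family}"
            score = 0.0 if scores is None else scores[i]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.\n")


# ---------------------------------------------------------------------------
# Context assignment
# ---------------------------------------------------------------------------


def assign_contexts(genome: Mapping[str, str]) -> dict[str, pd.DataFrame]:
    """Assign CG/CHG/CHH context to every cytosine on both strands.

    For each chromosome returns a frame with columns
    ``pos`` (1-based), ``strand``, ``context``, ``trinucleotide``. The context
    is determined by the next one or two bases read 5'→3' on the cytosine's
    own strand: ``CG`` if the next base is G, ``CHG`` if the base after next
    is G, else ``CHH``. H covers A/C/T and, conservatively, N; positions too
    close to a contig end to decide default to CHH.
    """
    out: dict[str, pd.DataFrame] = {}
    for chrom, seq in genome.items():
        raw = seq.upper().encode("ascii")
        arr = np.frombuffer(raw, dtype="S1")
        bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype="S1"))
        if bad.any():
            pos = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"{chrom}: non-ACGTN base {arr[pos].tobytes().decode()!r} at position {pos + 1}"
            )
        padded = np.concatenate(
            [np.frombuffer(b"NN", dtype="S1"), arr, np.frombuffer(b"NN", dtype="S1")]
        )
        frames = []
        # plus strand: cytosines, context read rightwards
        idx = np.nonzero(arr == b"C")[0]
        if idx.size:
            n1 = padded[idx + 3]  # offset +2 pad, +1 next base
            n2 = padded[idx + 4]
            ctx = np.where(n1 == b"G", "CG", np.where(n2 == b"G", "CHG", "CHH"))
            trinuc = np.char.add(
                np.char.add("C", n1.astype("U1")), n2.astype("U1")
            )
            frames.append(
                pd.DataFrame(
                    {"pos": idx + 1, "strand": "+", "context": ctx, "trinucleotide": trinuc}
                )
            )
        # minus strand: guanines, context read leftwards on the complement
        idx = np.nonzero(arr == b"G")[0]
        if idx.size:
            comp = padded.tobytes().translate(_COMPLEMENT)
            comp_arr = np.frombuffer(comp, dtype="S1")
            n1 = comp_arr[idx + 1]  # base at idx-1, complemented
            n2 = comp_arr[idx + 0]  # base at idx-2, complemented
            ctx = np.where(n1 == b"G", "CG", np.where(n2 == b"G", "CHG", "CHH"))
            trinuc = np.char.add(
                np.char.add("C", n1.astype("U1")), n2.astype("U1")
            )
            frames.append(
                pd.DataFrame(
                    {"pos": idx + 1, "strand": "-", "context": ctx, "trinucleotide": trinuc}
                )
            )
        if frames:
            frame = pd.concat(frames, ignore_index=True)
            frame = frame.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)
        else:
            frame = pd.DataFrame(columns=["pos", "strand", "context", "trinucleotide"])
        out[chrom] = frame
    return out


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------


class PositionFilter:
    """A set of (chrom, pos, strand) cytosine positions retained by a filter."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame[["chrom", "pos", "strand"]].drop_duplicates()
        frame = frame.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        self.frame = frame.reset_index(drop=True)
        self._set: set[tuple[str, int, str]] | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def _as_set(self) -> set[tuple[str, int, str]]:
        if self._set is None:
            self._set = set(
                zip(self.frame["chrom"], self.frame["pos"].astype(int), self.frame["strand"])
            )
        return self._set

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._as_set()

    def __iter__(self):
        return iter(self._as_set())

    def restrict(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Inner-join a methylome frame onto the retained positions."""
        return frame.merge(self.frame, on=["chrom", "pos", "strand"], how="inner")


def filter_by_coverage(
    samples: Sequence[MethylomeSample],
    min_cov: int,
    context: str | None = "CG",
) -> PositionFilter:
    """Positions with coverage >= ``min_cov`` in *every* sample, in-context.

    Mirrors the multi-sample filter used before DMR calling: a cytosine is
    retained only if it clears the coverage threshold in all supplied lines.
    """
    if not samples:
        raise ValueError("need at least one sample")
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    shared: pd.DataFrame | None = None
    for sample in samples:
        f = sample.frame
        mask = (f["m"] + f["u"]) >= min_cov
        if context is not None:
            mask &= f["context"] == context
        sub = f.loc[mask, ["chrom", "pos", "strand"]]
        shared = sub if shared is None else shared.merge(
            sub, on=["chrom", "pos", "strand"], how="inner"
        )
    return PositionFilter(shared)


# ---------------------------------------------------------------------------
# Region methylation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionMethylation:
    """Weighted methylation of a region: total m over total (m+u) reads.

    ``level`` is NaN when no retained in-context cytosine has coverage."""

    level: float
    m: int
    n: int
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.n > 0


class _RegionAggregator:
    """Prefix-sum index over one sample's retained in-context cytosines,
    answering (sum m, sum n, site count, methylated-site count) per window."""

    def __init__(
        self,
        sample: MethylomeSample,
        context: str | None = "CG",
        position_filter: PositionFilter | None = None,
        min_m: int = 1,
    ):
        f = sample.frame
        if context is not None:
            f = f[f["context"] == context]
        if position_filter is not None:
            f = position_filter.restrict(f)
        self._per_chrom: dict[str, tuple[np.ndarray, ...]] = {}
        for chrom, grp in f.groupby("chrom", sort=True):
            pos = grp["pos"].to_numpy(dtype=np.int64)  # sorted within chrom
            m = grp["m"].to_numpy(dtype=np.int64)
            n = m + grp["u"].to_numpy(dtype=np.int64)
            meth = (m >= min_m).astype(np.int64)
            self._per_chrom[chrom] = (
                pos,
                np.concatenate([[0], np.cumsum(m)]),
                np.concatenate([[0], np.cumsum(n)]),
                np.concatenate([[0], np.cumsum(meth)]),
            )

    def query(self, chrom: str, start: int, end: int) -> tuple[int, int, int, int]:
        entry = self._per_chrom.get(chrom)
        if entry is None:
            return 0, 0, 0, 0
        pos, cm, cn, cmeth = entry
        lo = int(np.searchsorted(pos, start + 1, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return (
            int(cm[hi] - cm[lo]),
            int(cn[hi] - cn[lo]),
            hi - lo,
            int(cmeth[hi] - cmeth[lo]),
        )


def region_methylation(
    sample: MethylomeSample,
    interval: GenomicInterval,
    context: str | None = "CG",
    position_filter: PositionFilter | None = None,
) -> RegionMethylation:
    """Weighted methylation level of one interval (both strands pooled)."""
    agg = _RegionAggregator(sample, context, position_filter)
    m, n, sites, _ = agg.query(interval.chrom, interval.start, interval.end)
    level = m / n if n > 0 else float("nan")
    return RegionMethylation(level, m, n, sites)


def feature_methylation_matrix(
    samples: Sequence[MethylomeSample],
    features: Sequence[GenomicInterval],
    context: str | None = "CG",
    position_filter: PositionFilter | None = None,
) -> pd.DataFrame:
    """Feature x sample matrix of weighted methylation levels (NaN=undefined).

    Row order follows ``features``; the index holds feature names (or
    coordinates when unnamed)."""
    if not features:
        raise ValueError("features must be non-empty")
    index = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in features]
    data: dict[str, list[float]] = {}
    for sample in samples:
        agg = _RegionAggregator(sample, context, position_filter)
        col = []
        for iv in features:
            m, n, _, _ = agg.query(iv.chrom, iv.start, iv.end)
            col.append(m / n if n > 0 else float("nan"))
        data[sample.sample_id] = col
    return pd.DataFrame(data, index=index)


def write_bedgraph(
    sample: MethylomeSample,
    context: str | None,
    path: str | Path,
    position_filter: PositionFilter | None = None,
) -> None:
    """Write per-cytosine methylation levels as a bedGraph track.

    Cytosines with zero coverage (undefined level) are omitted."""
    f = sample.frame
    if context is not None:
        f = f[f["context"] == context]
    if position_filter is not None:
        f = position_filter.restrict(f)
    n = f["m"] + f["u"]
    f = f[n > 0]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{sample.sample_id}"\n')
        if len(f):
            level = f["m"] / (f["m"] + f["u"])
            out = pd.DataFrame(
                {
                    "chrom": f["chrom"],
                    "start": f["pos"] - 1,
                    "end": f["pos"],
                    "level": level.map(lambda x: f"{x:.6g}"),
                }
            ).sort_values(["chrom", "start"], kind="mergesort")
            out.to_csv(fh, sep="\t", header=False, index=False)


def pool_symmetric_cg(sample: MethylomeSample) -> MethylomeSample:
    """Optional CpG-dyad pooling: merge +/- strand CG counts onto the + strand
    position of each symmetric dyad. Off the default analysis path."""
    f = sample.frame
    cg = f[f["context"] == "CG"].copy()
    # the - strand cytosine of a dyad sits one base right of the + strand one
    key = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    cg["dyad"] = key
    pooled = (
        cg.groupby(["chrom", "dyad"], as_index=False)
        .agg(m=("m", "sum"), u=("u", "sum"))
        .rename(columns={"dyad": "pos"})
    )
    pooled["strand"] = "+"
    pooled["context"] = "CG"
    pooled["trinucleotide"] = "CGN"
    rest = f[f["context"] != "CG"]
    return MethylomeSample(sample.sample_id, pd.concat([pooled, rest], ignore_index=True))
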