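"""Cytosine report parsing, context assignment, coverage filtering and
region-level methylation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diatmeth as dm
from diatmeth.methylome import ReportParseError, pool_symmetric_cg

from conftest import make_sample

# ---------------------------------------------------------------------------
# report parsing
# ---------------------------------------------------------------------------


def _write_report(path, lines):
    path.write_text("".join(line + "\n" for line in lines))
    return path


def test_read_cytosine_report_roundtrip(tmp_path):
    lines = [
        "chr1\t10\t+\t5\t15\tCG\tCGA",
        "chr1\t11\t-\t3\t1\tCG\tCGT",
        "chr2\t5\t+\t0\t0\tCHH\tCAT",
    ]
    sample = dm.read_cytosine_report(_write_report(tmp_path / "r.tsv", lines), "S")
    assert len(sample) == 3
    recs = list(sample)
    assert recs[0].coverage == 20 and recs[0].level == pytest.approx(0.25)
    out = tmp_path / "w.tsv"
    dm.write_cytosine_report(sample, out)
    again = dm.read_cytosine_report(out, "S")
    pd.testing.assert_frame_equal(sample.frame, again.frame)


@pytest.mark.parametrize(
    "bad_line, match",
    [
        ("chr1\t10\t+\t-1\t3\tCG\tCGA", "negative"),
        ("chr1\t10\t+\t1\t3\tXX\tCGA", "context"),
        ("chr1\t10\t+\t1\t3\tCG", "7 tab-separated"),
        ("chr1\tten\t+\t1\t3\tCG\tCGA", "non-integer"),
    ],
)
def test_read_cytosine_report_errors_name_line(tmp_path, bad_line, match):
    lines = ["chr1\t1\t+\t1\t1\tCG\tCGA", bad_line]
    with pytest.raises(ReportParseError, match="2"):
        dm.read_cytosine_report(_write_report(tmp_path / "r.tsv", lines))
    with pytest.raises(ReportParseError, match=match):
        dm.read_cytosine_report(_write_report(tmp_path / "r.tsv", lines))


def test_duplicate_position_rejected(tmp_path):
    lines = ["chr1\t10\t+\t1\t1\tCG\tCGA"] * 2
    with pytest.raises(ReportParseError, match="duplicate"):
        dm.read_cytosine_report(_write_report(tmp_path / "r.tsv", lines))


# ---------------------------------------------------------------------------
# context assignment
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq, expected",
    [
        # (1-based pos, strand) -> context
        ("ACGT", {(2, "+"): "CG", (3, "-"): "CG"}),
        ("ACAGT", {(2, "+"): "CHG", (4, "-"): "CHG"}),
        ("ACATT", {(2, "+"): "CHH"}),
    ],
)
def test_assign_contexts_definitions(seq, expected):
    ctx = dm.assign_contexts({"c": seq})["c"]
    got = {(int(r.pos), r.strand): r.context for r in ctx.itertuples()}
    for key, value in expected.items():
        assert got[key] == value


def test_assign_contexts_contig_ends_default_chh():
    # C at the last base has no downstream bases at all
    ctx = dm.assign_contexts({"c": "AAC"})["c"]
    assert ctx.iloc[0].context == "CHH"
    # one downstream base that is not G: CHG/CHH undecidable -> CHH
    ctx = dm.assign_contexts({"c": "ACA"})["c"]
    got = {(int(r.pos), r.strand): r.context for r in ctx.itertuples()}
    assert got[(2, "+")] == "CHH"


def test_assign_contexts_rejects_bad_alphabet():
    with pytest.raises(ValueError, match="non-ACGTN"):
        dm.assign_contexts({"c": "ACXGT"})


def _context_oracle(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    out = {}
    n = len(seq)
    for i, b in enumerate(seq):
        if b == "C":
            n1 = seq[i + 1] if i + 1 < n else "N"
            n2 = seq[i + 2] if i + 2 < n else "N"
            out[(i + 1, "+")] = "CG" if n1 == "G" else ("CHG" if n2 == "G" else "CHH")
        if b == "G":
            n1 = comp[seq[i - 1]] if i >= 1 else "N"
            n2 = comp[seq[i - 2]] if i >= 2 else "N"
            out[(i + 1, "-")] = "CG" if n1 == "G" else ("CHG" if n2 == "G" else "CHH")
    return out


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
def test_assign_contexts_matches_independent_scan(seq):
    ctx = dm.assign_contexts({"c": seq})["c"]
    got = {(int(r.pos), r.strand): r.context for r in ctx.itertuples()}
    assert got == _context_oracle(seq)


def test_assign_contexts_on_random_10kb():
    rng = np.random.default_rng(3)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=10_000)])
    ctx = dm.assign_contexts({"c": seq})["c"]
    got = {(int(r.pos), r.strand): r.context for r in ctx.itertuples()}
    assert got == _context_oracle(seq)


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------


def _three_samples_at(covs, pos=10):
    return [
        make_sample([("chr1", pos, "+", c // 2, c - c // 2, "CG")], f"s{i}")
        for i, c in enumerate(covs)
    ]


def test_filter_requires_threshold_in_every_sample():
    kept = dm.filter_by_coverage(_three_samples_at([6, 6, 6]), 5)
    assert ("chr1", 10, "+") in kept
    dropped = dm.filter_by_coverage(_three_samples_at([6, 4, 6]), 5)
    assert len(dropped) == 0


def test_filter_min_cov_zero_is_identity():
    samples = _three_samples_at([0, 3, 9])
    assert len(dm.filter_by_coverage(samples, 0)) == 1


def test_filter_respects_context():
    s = make_sample(
        [("chr1", 10, "+", 3, 3, "CG"), ("chr1", 20, "+", 3, 3, "CHH")]
    )
    assert len(dm.filter_by_coverage([s], 5, "CG")) == 1
    assert len(dm.filter_by_coverage([s], 5, None)) == 2


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=40), st.integers(min_value=0, max_value=40))
def test_filter_monotone_in_min_cov(cov_a, cov_b):
    samples = _three_samples_at([cov_a, cov_b, max(cov_a, cov_b)])
    sizes = [len(dm.filter_by_coverage(samples, c)) for c in range(0, 45, 5)]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# region methylation
# ---------------------------------------------------------------------------


def test_region_methylation_examples():
    s = make_sample(
        [("chr1", 5, "+", 3, 1, "CG"), ("chr1", 8, "-", 1, 3, "CG")]
    )
    r = dm.region_methylation(s, dm.GenomicInterval("chr1", 0, 100))
    assert r.level == pytest.approx(0.5) and (r.m, r.n, r.n_sites) == (4, 8, 2)

    single = make_sample([("chr1", 5, "+", 8, 2, "CG")])
    assert dm.region_methylation(single, dm.GenomicInterval("chr1", 0, 10)).level == pytest.approx(0.8)

    empty = dm.region_methylation(s, dm.GenomicInterval("chr2", 0, 10))
    assert np.isnan(empty.level) and empty.n_sites == 0 and not empty.defined


def test_region_methylation_is_coverage_weighted_mean_of_site_levels():
    rng = np.random.default_rng(11)
    rows = []
    for pos in range(1, 60):
        n = int(rng.integers(1, 30))
        m = int(rng.integers(0, n + 1))
        rows.append(("chr1", pos, "+", m, n - m, "CG"))
    s = make_sample(rows)
    r = dm.region_methylation(s, dm.GenomicInterval("chr1", 0, 60))
    levels = np.array([m / (m + u) for _, _, _, m, u, _ in rows])
    weights = np.array([m + u for _, _, _, m, u, _ in rows])
    assert r.level == pytest.approx(np.average(levels, weights=weights), abs=1e-12)


def _brute_region(rows, interval, context="CG"):
    m = n = sites = 0
    for chrom, pos, strand, mm, uu, ctx in rows:
        if chrom == interval.chrom and interval.start < pos <= interval.end and ctx == context:
            m += mm
            n += mm + uu
            sites += 1
    return m, n, sites


def test_region_methylation_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(100):
        rows = []
        used = set()
        for _ in range(int(rng.integers(1, 80))):
            key = (f"chr{rng.integers(1, 3)}", int(rng.integers(1, 200)),
                   "+" if rng.integers(2) else "-")
            if key in used:
                continue
            used.add(key)
            n = int(rng.integers(0, 20))
            m = int(rng.integers(0, n + 1))
            ctx = ["CG", "CHG", "CHH"][int(rng.integers(3))]
            rows.append((*key, m, n - m, ctx))
        s = make_sample(rows)
        start = int(rng.integers(0, 150))
        iv = dm.GenomicInterval("chr1", start, start + int(rng.integers(1, 80)))
        got = dm.region_methylation(s, iv)
        m, n, sites = _brute_region(rows, iv)
        assert (got.m, got.n, got.n_sites) == (m, n, sites)
        if n:
            assert got.level == pytest.approx(m / n, abs=0)
        else:
            assert np.isnan(got.level)


def test_feature_methylation_matrix_shape_and_values(study, position_filter):
    tes = study.annotations.tes[:2]
    samples = [study.samples[s] for s in ("WT", "KO1", "KO2")]
    mat = dm.feature_methylation_matrix(samples, tes, "CG", position_filter)
    assert mat.shape == (2, 3)
    assert list(mat.columns) == ["WT", "KO1", "KO2"]


def test_methylated_island_and_background_levels_recovered(study, position_filter):
    """WT island TEs sit near the planted 0.80; knockouts near 0.80/4.5;
    background genes near 0.02 (binomial-SE bounds)."""
    cfg = study.config
    island_te = study.annotations.tes[0]  # islands come first
    samples = [study.samples[s] for s in ("WT", "KO1", "KO2")]
    mat = dm.feature_methylation_matrix(samples, [island_te], "CG", position_filter)
    depleted = cfg.island_cg_methylation / cfg.ko_depletion_factor
    assert mat.iloc[0]["WT"] == pytest.approx(cfg.island_cg_methylation, abs=0.02)
    assert mat.iloc[0]["KO1"] == pytest.approx(depleted, abs=0.02)
    assert mat.iloc[0]["KO2"] == pytest.approx(depleted, abs=0.02)
    gene = study.annotations.genes[0]
    gmat = dm.feature_methylation_matrix(samples, [gene], "CG", position_filter)
    assert gmat.iloc[0].max() < 0.06


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def test_write_bedgraph_converts_to_zero_based(tmp_path):
    s = make_sample([("chr1", 10, "+", 1, 1, "CG")])
    path = tmp_path / "t.bedgraph"
    dm.write_bedgraph(s, "CG", path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("track")
    assert lines[1].split("\t") == ["chr1", "9", "10", "0.5"]


def test_write_bedgraph_empty_track_has_header_only(tmp_path):
    s = make_sample([("chr1", 10, "+", 0, 0, "CG")])  # zero coverage -> omitted
    path = tmp_path / "t.bedgraph"
    dm.write_bedgraph(s, "CG", path)
    assert len(path.read_text().splitlines()) == 1


def test_bedgraph_levels_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    rows = []
    for pos in range(1, 40):
        n = int(rng.integers(1, 50))
        m = int(rng.integers(0, n + 1))
        rows.append(("chr1", pos, "+", m, n - m, "CG"))
    s = make_sample(rows)
    path = tmp_path / "t.bedgraph"
    dm.write_bedgraph(s, "CG", path)
    body = [line.split("\t") for line in path.read_text().splitlines()[1:]]
    for (chrom, start, end, level), (_, pos, _, m, u, _) in zip(body, rows):
        assert int(start) == pos - 1 and int(end) == pos
        assert float(level) == pytest.approx(m / (m + u), abs=1e-6)


def test_pool_symmetric_cg_merges_dyads():
    s = make_sample(
        [("chr1", 10, "+", 3, 1, "CG"), ("chr1", 11, "-", 2, 2, "CG")]
    )
    pooled = pool_symmetric_cg(s)
    assert len(pooled) == 1
    rec = next(iter(pooled))
    assert (rec.pos, rec.m, rec.u) == (10, 5, 3)
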