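"""Binned DMR calling: score test, aggregation, thresholds, consensus."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import diatmeth as dm
from diatmeth.dmr import DmrParams, score_test_arrays

from conftest import make_sample

# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------


def test_make_bins_tiles_with_partial_final_bin():
    bins = dm.make_bins({"c": 250}, 100)
    assert [(b.start, b.end) for b in bins] == [(0, 100), (100, 200), (200, 250)]
    assert [(b.start, b.end) for b in dm.make_bins({"c": 100}, 100)] == [(0, 100)]
    assert dm.make_bins({"c": 0}, 100) == []


def test_make_bins_rejects_bad_width():
    with pytest.raises(ValueError):
        dm.make_bins({"c": 100}, 0)


# ---------------------------------------------------------------------------
# score test
# ---------------------------------------------------------------------------


def test_score_test_equal_proportions_is_null():
    r = dm.score_test(10, 20, 10, 20)
    assert r.z == 0.0 and r.p == 1.0


def test_score_test_worked_example_matches_closed_form():
    """(30,40) vs (10,40): pooled 0.5, z = 0.5/sqrt(0.25*(1/40+1/40))."""
    r = dm.score_test(30, 40, 10, 40)
    expected_z = 0.5 / math.sqrt(0.25 * (1 / 40 + 1 / 40))
    assert r.z == pytest.approx(expected_z, abs=1e-10)
    assert r.z == pytest.approx(4.4721359549, abs=1e-9)
    assert r.p == pytest.approx(2 * norm.sf(expected_z), abs=1e-15)
    assert r.p == pytest.approx(7.744e-6, rel=1e-3)


def test_score_test_zero_variance_convention():
    assert dm.score_test(0, 40, 0, 40) == dm.ScoreTestResult(0.0, 1.0)
    assert dm.score_test(40, 40, 40, 40) == dm.ScoreTestResult(0.0, 1.0)


def test_score_test_untestable_marker_not_exception():
    r = dm.score_test(0, 0, 5, 10)
    assert not r.testable and math.isnan(r.z)


def test_score_test_rejects_invalid_counts():
    with pytest.raises(ValueError):
        dm.score_test(5, 4, 1, 10)
    with pytest.raises(ValueError):
        dm.score_test(-1, 4, 1, 10)


def test_score_test_antisymmetry_and_conventions_on_random_tuples():
    """Swapping samples flips z and preserves p, on 10^4 random count tuples;
    scalar and vectorized paths agree."""
    rng = np.random.default_rng(42)
    n1 = rng.integers(1, 200, size=10_000)
    n2 = rng.integers(1, 200, size=10_000)
    m1 = rng.binomial(n1, rng.uniform(0, 1, size=10_000))
    m2 = rng.binomial(n2, rng.uniform(0, 1, size=10_000))
    z_ab, p_ab = score_test_arrays(m1, n1, m2, n2)
    z_ba, p_ba = score_test_arrays(m2, n2, m1, n1)
    np.testing.assert_allclose(z_ab, -z_ba, atol=1e-12)
    np.testing.assert_allclose(p_ab, p_ba, atol=1e-12)
    # sign(z) = sign(p1 - p2)
    diff = m1 / n1 - m2 / n2
    assert np.all(np.sign(z_ab[diff != 0]) == np.sign(diff[diff != 0]))
    # spot-check scalar path against the vectorized one
    for i in rng.integers(0, 10_000, size=50):
        r = dm.score_test(int(m1[i]), int(n1[i]), int(m2[i]), int(n2[i]))
        assert r.z == pytest.approx(z_ab[i], abs=1e-12)
        assert r.p == pytest.approx(p_ab[i], abs=1e-12)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_aggregate_counts_example_and_empty_bin():
    ref = make_sample(
        [("c", 5, "+", 3, 1, "CG"), ("c", 8, "-", 1, 3, "CG")], "ref"
    )
    treat = make_sample(
        [("c", 5, "+", 0, 4, "CG"), ("c", 8, "-", 0, 4, "CG")], "treat"
    )
    bins = dm.make_bins({"c": 200}, 100)
    counts = dm.aggregate_counts(bins, ref, treat)
    assert (counts[0].m_ref, counts[0].n_ref) == (4, 8)
    assert (counts[0].m_treat, counts[0].n_treat) == (0, 8)
    assert counts[0].n_cytosines == 2 and counts[0].n_meth_ref == 2
    assert (counts[1].m_ref, counts[1].n_ref, counts[1].n_cytosines) == (0, 0, 0)


def test_aggregate_counts_matches_brute_force_on_random_fixture():
    rng = np.random.default_rng(9)
    for _ in range(100):
        rows_ref, rows_treat = [], []
        positions = rng.choice(np.arange(1, 300), size=60, replace=False)
        for pos in positions:
            for rows in (rows_ref, rows_treat):
                n = int(rng.integers(0, 20))
                m = int(rng.integers(0, n + 1))
                rows.append(("c", int(pos), "+", m, n - m, "CG"))
        ref = make_sample(rows_ref, "ref")
        treat = make_sample(rows_treat, "treat")
        width = int(rng.integers(20, 120))
        bins = dm.make_bins({"c": 300}, width)
        counts = dm.aggregate_counts(bins, ref, treat)
        for b, c in zip(bins, counts):
            mr = sum(m for _, p, _, m, _, _ in rows_ref if b.start < p <= b.end)
            nr = sum(m + u for _, p, _, m, u, _ in rows_ref if b.start < p <= b.end)
            mt = sum(m for _, p, _, m, _, _ in rows_treat if b.start < p <= b.end)
            nt = sum(m + u for _, p, _, m, u, _ in rows_treat if b.start < p <= b.end)
            assert (c.m_ref, c.n_ref, c.m_treat, c.n_treat) == (mr, nr, mt, nt)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def _pair_for_bin(m_ref, n_ref, m_treat, n_treat, n_sites=10):
    """Spread the requested totals over n_sites cytosines in bin [0,100)."""
    def rows(m, n):
        per_n, rem_n = divmod(n, n_sites)
        per_m, rem_m = divmod(m, n_sites)
        out = []
        for i in range(n_sites):
            ni = per_n + (1 if i < rem_n else 0)
            mi = per_m + (1 if i < rem_m else 0)
            out.append(("c", i + 1, "+", mi, ni - mi, "CG"))
        return out

    return make_sample(rows(m_ref, n_ref), "ref"), make_sample(rows(m_treat, n_treat), "treat")


def test_default_params_echo_study_design():
    p = DmrParams()
    assert (p.bin_width, p.context, p.min_cov, p.min_delta, p.max_p, p.min_ref_meth_cpg) == (
        100, "CG", 5, 0.20, 0.01, 2,
    )


def test_call_dmrs_detects_strong_loss():
    ref, treat = _pair_for_bin(80, 100, 10, 100)
    res = dm.call_dmrs(ref, treat, {"c": 100}, DmrParams(min_cov=0))
    assert len(res.hypo) == 1
    d = res.hypo[0]
    assert d.delta == pytest.approx(0.7)
    assert d.test.p < 0.01 and d.n_meth_ref >= 2


def test_hypo_requires_two_methylated_reference_cytosines():
    """Same totals, but all methylated reads on a single reference cytosine:
    the bin passes delta/p yet is not an hypoDMR."""
    rows_ref = [("c", 1, "+", 80, 0, "CG")] + [
        ("c", i, "+", 0, 10, "CG") for i in range(2, 4)
    ]
    rows_treat = [("c", 1, "+", 10, 70, "CG")] + [
        ("c", i, "+", 0, 10, "CG") for i in range(2, 4)
    ]
    ref, treat = make_sample(rows_ref, "ref"), make_sample(rows_treat, "treat")
    res = dm.call_dmrs(ref, treat, {"c": 100}, DmrParams(min_cov=0))
    assert len(res.hypo) == 0 and res.n_hypo_filtered == 1
    res2 = dm.call_dmrs(ref, treat, {"c": 100}, DmrParams(min_cov=0, min_ref_meth_cpg=1))
    assert len(res2.hypo) == 1


def test_call_dmrs_direction_and_sign():
    ref, treat = _pair_for_bin(10, 100, 80, 100)
    res = dm.call_dmrs(ref, treat, {"c": 100}, DmrParams(min_cov=0))
    assert len(res.hyper) == 1 and res.hyper[0].delta < 0


def test_call_dmrs_empty_filter_returns_empty_set():
    ref, treat = _pair_for_bin(8, 10, 1, 10)
    res = dm.call_dmrs(ref, treat, {"c": 100}, DmrParams(min_cov=1000))
    assert len(res) == 0


def test_thresholds_are_monotone(study, position_filter):
    """Raising min_delta or lowering max_p yields a subset of calls."""
    wt, ko = study.samples["WT"], study.samples["KO1"]
    gl = study.genome_lengths

    def keys(params):
        res = dm.call_dmrs(wt, ko, gl, params, position_filter)
        return {(d.interval.chrom, d.interval.start, d.direction) for d in res}

    base = keys(DmrParams())
    assert keys(DmrParams(min_delta=0.5)) <= base
    assert keys(DmrParams(max_p=0.0001)) <= base


def test_impossible_delta_yields_no_dmrs(study, position_filter):
    res = dm.call_dmrs(
        study.samples["WT"], study.samples["KO1"], study.genome_lengths,
        DmrParams(min_delta=1.01), position_filter,
    )
    assert len(res) == 0


# ---------------------------------------------------------------------------
# consensus + genome fraction
# ---------------------------------------------------------------------------


def _dmr_at(start, direction="hypo"):
    iv = dm.GenomicInterval("c", start, start + 100, feature_class="DMR")
    return dm.Dmr(iv, direction, 0.5, 0.8, 0.3, dm.ScoreTestResult(5.0, 1e-6), 5, 3)


def _dmr_set(starts, direction="hypo"):
    return dm.DmrSet([_dmr_at(s, direction) for s in starts], 100, {"c": 1000}, DmrParams())


def test_consensus_set_algebra():
    a = _dmr_set([0, 100, 200])
    b = _dmr_set([100, 200, 300])
    cons = dm.consensus_dmrs(a, b)
    assert {d.interval.start for d in cons.common} == {100, 200}
    assert cons.shared_a == pytest.approx(2 / 3)
    assert cons.shared_b == pytest.approx(2 / 3)
    assert [d.interval.start for d in cons.a_only] == [0]
    assert [d.interval.start for d in cons.b_only] == [300]


def test_consensus_identical_and_disjoint():
    a = _dmr_set([0, 100])
    same = dm.consensus_dmrs(a, a)
    assert same.shared_a == 1.0 and not same.a_only and not same.b_only
    assert {d.interval.start for d in same.common} == {0, 100}  # idempotent
    disjoint = dm.consensus_dmrs(_dmr_set([0]), _dmr_set([500]))
    assert disjoint.shared_a == 0.0 and not disjoint.common


def test_consensus_rejects_mismatched_grids():
    a = _dmr_set([0])
    b = dm.DmrSet([_dmr_at(0)], 50, {"c": 1000}, DmrParams())
    with pytest.raises(ValueError, match="grid"):
        dm.consensus_dmrs(a, b)


def test_genome_fraction_arithmetic():
    s = _dmr_set([i * 100 for i in range(10)])
    assert dm.genome_fraction(s, {"c": 1_000_000}) == pytest.approx(0.1)
    assert dm.genome_fraction(_dmr_set([]), {"c": 1000}) == 0.0
    full = _dmr_set([0, 100])
    assert dm.genome_fraction(full, {"c": 200}) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        dm.genome_fraction(s, {"c": 0})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 60), st.integers(1, 60), st.integers(0, 60), st.integers(1, 60))
def test_score_test_p_in_unit_interval(m1, n1, m2, n2):
    m1, m2 = min(m1, n1), min(m2, n2)
    r = dm.score_test(m1, n1, m2, n2)
    assert 0.0 <= r.p <= 1.0
    assert r.p == pytest.approx(2 * norm.sf(abs(r.z)), abs=1e-12)
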