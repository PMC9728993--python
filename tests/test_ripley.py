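"""Ripley's K estimator, Monte-Carlo null, empirical p-values, BH, and
the per-nucleus clustering test."""

import math

import numpy as np
import pytest

from ecspat import (
    RipleyConfig,
    bh_adjust,
    cluster_cohort,
    cluster_test,
    cohort_summary,
    empirical_pvalue,
    ripley_k,
    sample_null,
    simulate_csr_nucleus,
    simulate_thomas_nucleus,
)
from ecspat.ripley import ball_volume

from conftest import brute_force_k, make_fociset

V5 = ball_volume(5.0)  # ≈ 523.60 µm³


class TestRipleyK:
    def test_two_point_hand_evaluation(self):
        pts = [[0, 0, 0], [0.5, 0, 0]]
        k = ripley_k(pts, [0.4, 0.6], V5)
        assert k[0] == 0.0
        # one unordered pair -> 2 ordered pairs: K = V·2/n² = V/2
        assert k[1] == pytest.approx(V5 / 2, rel=1e-12)
        assert k[1] == pytest.approx(261.80, abs=0.01)

    def test_zero_below_minimum_pairwise_distance(self, rng):
        pts = rng.uniform(-4, 4, size=(20, 3))
        dmin = min(np.linalg.norm(pts[i] - pts[j])
                   for i in range(20) for j in range(i + 1, 20))
        assert np.all(ripley_k(pts, [dmin * 0.99], V5) == 0)

    def test_matches_brute_force_exactly(self, rng):
        radii = np.round(np.arange(1, 11) * 0.1, 10)
        for _ in range(25):
            n = int(rng.integers(2, 120))
            pts = rng.uniform(-3, 3, size=(n, 3))
            fast = ripley_k(pts, radii, V5)
            assert np.array_equal(fast, brute_force_k(pts, radii, V5))

    def test_monotone_in_radius(self, rng):
        pts = rng.uniform(-4, 4, size=(50, 3))
        k = ripley_k(pts, np.linspace(0.05, 2, 20), V5)
        assert np.all(np.diff(k) >= 0)

    def test_textbook_normalisation(self, rng):
        pts = rng.uniform(-2, 2, size=(10, 3))
        paper = ripley_k(pts, [1.0], V5, estimator="paper")
        textbook = ripley_k(pts, [1.0], V5, estimator="textbook")
        assert textbook[0] == pytest.approx(paper[0] * 10 / 9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ripley_k([[0, 0, 0]], [0.5], V5)
        with pytest.raises(ValueError):
            ripley_k([[0, 0, 0], [np.nan, 0, 0]], [0.5], V5)


class TestNullSample:
    def test_shape_and_determinism(self):
        cfg = RipleyConfig(n_null=100, seed=9)
        a = sample_null(25, cfg)
        b = sample_null(25, cfg)
        assert a.shape == (100, 10)
        assert np.array_equal(a, b)

    def test_rows_are_valid_k_curves(self):
        null = sample_null(25, RipleyConfig(n_null=100, seed=10))
        assert np.all(np.diff(null, axis=1) >= 0)
        assert np.all(null >= 0)


class TestEmpiricalPValue:
    def test_extreme_ranks(self):
        null = np.arange(100, dtype=float)
        top = empirical_pvalue(1000.0, null)
        assert top.p == 0.0 and top.resolution == 0.01
        assert empirical_pvalue(-5.0, null).p == 1.0

    def test_tie_handling_at_decision_boundary(self):
        # 20 null values: 13 below, 2 tied with the observation, 5 above;
        # the tied block spans p in (0.25, 0.35], so at alpha=0.3 the
        # verdict depends on tie-breaking
        null = np.array([0.0] * 13 + [5.0] * 2 + [9.0] * 5)
        opt = empirical_pvalue(5.0, null, "optimistic", alpha=0.3)
        con = empirical_pvalue(5.0, null, "conservative", alpha=0.3)
        assert opt.p == pytest.approx(5 / 20)
        assert con.p == pytest.approx(7 / 20)

    def test_ties_away_from_boundary_count_against(self):
        # same configuration but alpha=0.05: block does not straddle the
        # cut, the most-pessimistic rank applies
        null = np.array([0.0] * 13 + [5.0] * 2 + [9.0] * 5)
        opt = empirical_pvalue(5.0, null, "optimistic", alpha=0.05)
        assert opt.p == pytest.approx(7 / 20)

    def test_tied_at_zero_block_is_never_promoted(self):
        # observation 0 with 99% of the null at 0 has no clustering
        # signal at all; the optimistic rule must not assign a small p
        null = np.array([0.0] * 99 + [2.0])
        assert empirical_pvalue(0.0, null, "optimistic").p == 1.0

    def test_optimistic_never_exceeds_conservative(self, rng):
        for _ in range(50):
            null = rng.integers(0, 6, size=40).astype(float)
            obs = float(rng.integers(0, 6))
            for alpha in (0.05, 0.2, 0.5):
                o = empirical_pvalue(obs, null, "optimistic", alpha=alpha)
                c = empirical_pvalue(obs, null, "conservative", alpha=alpha)
                assert o.p <= c.p

    def test_randomized_policy_reproducible(self):
        null = np.array([0.0] * 70 + [5.0] * 20 + [9.0] * 10)
        a = empirical_pvalue(5.0, null, "randomized", alpha=0.2, tie_rng=123)
        b = empirical_pvalue(5.0, null, "randomized", alpha=0.2, tie_rng=123)
        assert a.p == b.p and a.randomized_significant == b.randomized_significant

    def test_empty_null_raises(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, [])


class TestBHAdjust:
    def test_hand_stepup_example(self):
        q, reject = bh_adjust([0.01, 0.02, 0.2], fdr=0.05)
        assert list(reject) == [True, True, False]
        assert q[0] == pytest.approx(0.03)
        assert q[2] == pytest.approx(0.2)

    def test_all_ones_no_rejections(self):
        q, reject = bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any() and np.all(q == 1.0)

    def test_single_p_below_level(self):
        _, reject = bh_adjust([0.04], fdr=0.05)
        assert reject[0]


class TestClusterTest:
    def test_min_foci_exclusive_boundary(self):
        cfg = RipleyConfig(n_null=100, seed=1, min_foci=20)
        at = cluster_test(simulate_csr_nucleus(20, seed=2), "EGFR", cfg)
        above = cluster_test(simulate_csr_nucleus(21, seed=2), "EGFR", cfg)
        assert at.excluded and "min_foci" in at.reason
        assert not above.excluded and len(above.table) == 10

    def test_csr_nucleus_rarely_significant(self):
        cfg = RipleyConfig(n_null=500, seed=3)
        res = cluster_test(simulate_csr_nucleus(40, seed=4), "EGFR", cfg)
        assert not res.any_significant()

    def test_thomas_nucleus_detected_at_small_radius(self):
        fs = simulate_thomas_nucleus(5, 8, 0.05, seed=5)
        res = cluster_test(fs, "EGFR", RipleyConfig(n_null=500, seed=6))
        assert res.any_significant(max_radius=0.2)

    def test_significance_requires_excess_over_null_median(self):
        fs = simulate_thomas_nucleus(5, 8, 0.05, seed=7)
        res = cluster_test(fs, "EGFR", RipleyConfig(n_null=500, seed=8))
        sig = res.table[res.table["significant"]]
        assert (sig["k_obs"] > sig["null_median"]).all()

    def test_detection_power_monotone_in_cluster_tightness(self):
        rates = []
        for sigma in (0.4, 0.2, 0.05):
            hits = 0
            for s in range(15):
                fs = simulate_thomas_nucleus(5, 8, sigma, seed=100 + s)
                r = cluster_test(fs, "EGFR", RipleyConfig(n_null=400, seed=200 + s))
                hits += (not r.excluded) and r.any_significant()
            rates.append(hits / 15)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.9


class TestCohort:
    def test_single_nucleus_summary_bookkeeping(self):
        fs = simulate_thomas_nucleus(5, 8, 0.05, seed=9)
        small = simulate_csr_nucleus(5, seed=10, nucleus_id="tiny")
        res = cluster_cohort([fs, small], "EGFR", RipleyConfig(n_null=300, seed=11))
        table = cohort_summary(res)
        assert (table["n_tested"] == 1).all()
        assert table.attrs["n_excluded"] == 1
        assert table.attrs["excluded_ids"] == ["tiny"]

    def test_all_excluded_raises(self):
        tiny = [simulate_csr_nucleus(3, seed=s) for s in range(2)]
        res = cluster_cohort(tiny, "EGFR", RipleyConfig(n_null=300, seed=12))
        with pytest.raises(ValueError):
            cohort_summary(res)

    def test_cohort_reproducible(self):
        cohort = [simulate_csr_nucleus(30, seed=s) for s in range(3)]
        cfg = RipleyConfig(n_null=200, seed=13)
        a = cluster_cohort(cohort, "EGFR", cfg)
        b = cluster_cohort(cohort, "EGFR", cfg)
        for x, y in zip(a, b):
            assert x.table.equals(y.table)
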