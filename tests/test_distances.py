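"""Shortest-distance analyses against hand geometry and O(n²) oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecspat import (
    LargeFociSet,
    cumulative_distance_distribution,
    filter_large_foci,
    foci_to_hub_distances,
    proximity_fraction,
    shortest_distances,
)
from ecspat.distances import DistanceSummary, round_percent, truncate_percent

from conftest import brute_force_nearest, make_fociset


class TestShortestDistances:
    def test_collinear_hand_geometry(self):
        fs = make_fociset([[0, 0, 0], [1, 0, 0], [3, 0, 0]])
        s = shortest_distances(fs, "EGFR", "EGFR")
        assert np.allclose(sorted(s.per_focus_shortest), [1, 1, 2])
        assert s.mean_shortest == pytest.approx(4 / 3)
        assert s.min_shortest == 1.0

    def test_coincident_foci_distance_zero(self):
        s = shortest_distances(make_fociset([[1, 1, 1], [1, 1, 1]]), "EGFR", "EGFR")
        assert s.min_shortest == 0.0

    def test_doublet_fixture_all_at_separation(self, rng):
        # pairs placed far apart: every per-focus shortest equals 0.2
        anchors = rng.uniform(-40, 40, size=(6, 3))
        coords = []
        for a in anchors:
            coords.extend([a, a + [0.2, 0, 0]])
        s = shortest_distances(make_fociset(coords, bounding_radius=100), "EGFR", "EGFR")
        assert np.allclose(s.per_focus_shortest, 0.2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(2, 200)
            fs = make_fociset(rng.uniform(-5, 5, size=(n, 3)))
            s = shortest_distances(fs, "EGFR", "EGFR")
            oracle = brute_force_nearest(fs.coords(), fs.coords(), same=True)
            assert np.allclose(np.sort(s.per_focus_shortest), np.sort(oracle))

    def test_cross_channel_directional(self, rng):
        coords = np.vstack([rng.uniform(-3, 3, size=(8, 3)), rng.uniform(-3, 3, size=(3, 3))])
        fs = make_fociset(coords, channel=["A"] * 8 + ["B"] * 3)
        ab = shortest_distances(fs, "A", "B")
        ba = shortest_distances(fs, "B", "A")
        assert ab.per_focus_shortest.size == 8 and ba.per_focus_shortest.size == 3
        oa = brute_force_nearest(fs.coords("A"), fs.coords("B"), same=False)
        assert np.allclose(ab.per_focus_shortest, oa)

    def test_too_few_foci_flagged_not_raised(self):
        s = shortest_distances(make_fociset([[0, 0, 0]]), "EGFR", "EGFR")
        assert s.empty and math.isnan(s.mean_shortest)

    def test_unknown_channel_raises(self):
        with pytest.raises(ValueError, match="unknown channel"):
            shortest_distances(make_fociset([[0, 0, 0], [1, 0, 0]]), "EGFR", "CDK4")

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(-2, 2, size=(40, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([1.0, -2.0, 0.5])
        a = shortest_distances(make_fociset(pts), "EGFR", "EGFR")
        b = shortest_distances(make_fociset(moved), "EGFR", "EGFR")
        assert np.allclose(np.sort(a.per_focus_shortest), np.sort(b.per_focus_shortest))


class TestProximityFraction:
    def test_printed_count_percentages(self):
        # 4 of 1011 source foci below threshold -> 0.39%; 4 of 518 -> 0.77%
        for total, expected in [(1011, 0.39), (518, 0.77)]:
            d = np.full(total, 1.0)
            d[:4] = 0.1
            s = DistanceSummary("n", ("A", "B"), d)
            count, tot, pct = proximity_fraction(s, 0.2)
            assert (count, tot, pct) == (4, total, expected)

    def test_strict_inequality_at_threshold(self):
        s = DistanceSummary("n", ("A", "A"), np.array([0.2, 0.3]))
        count, total, pct = proximity_fraction(s, 0.2)
        assert (count, total, pct) == (0, 2, 0.0)

    def test_empty_summary(self):
        count, total, pct = proximity_fraction(DistanceSummary("n", ("A", "A")), 0.2)
        assert (count, total) == (0, 0) and math.isnan(pct)

    @given(st.lists(st.floats(0, 2), min_size=1, max_size=50),
           st.floats(0.01, 2), st.floats(0.01, 2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, dists, t1, t2):
        s = DistanceSummary("n", ("A", "A"), np.array(dists))
        lo, hi = sorted([t1, t2])
        assert s.n_below(lo) <= s.n_below(hi)

    def test_cohort_percent_rounding(self):
        assert round_percent(2, 24) == 8.3
        assert round_percent(4, 24) == 16.7
        assert truncate_percent(4, 1011) == 0.39


class TestCumulativeDistribution:
    def test_single_distance_step(self):
        s = DistanceSummary("n", ("A", "A"), np.array([0.5]))
        cdf = cumulative_distance_distribution([s], grid=[0.4, 0.5, 0.6])
        assert list(cdf["cumulative_frequency"]) == [0.0, 1.0, 1.0]

    def test_doublet_jump(self):
        s = DistanceSummary("n", ("A", "A"), np.full(10, 0.2))
        cdf = cumulative_distance_distribution([s], grid=[0.19, 0.2])
        assert list(cdf["cumulative_frequency"]) == [0.0, 1.0]

    def test_monotone_and_ends_at_one(self, rng):
        sums = [DistanceSummary(f"n{i}", ("A", "A"), rng.uniform(0, 2, size=20))
                for i in range(5)]
        cdf = cumulative_distance_distribution(sums)
        v = cdf["cumulative_frequency"].to_numpy()
        assert np.all(np.diff(v) >= 0) and v[-1] == 1.0

    def test_empty_summaries_skipped_and_counted(self):
        good = DistanceSummary("a", ("A", "A"), np.array([0.5]))
        empty = DistanceSummary("b", ("A", "A"))
        cdf = cumulative_distance_distribution([good, empty])
        assert cdf.attrs["n_empty_summaries"] == 1

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            cumulative_distance_distribution([DistanceSummary("a", ("A", "A"))])


class TestLargeFoci:
    def test_diameter_filter_inclusive_boundary(self):
        out = filter_large_foci([(0, 0, 0, 0.3), (1, 0, 0, 0.5), (2, 0, 0, 0.8)])
        assert len(out) == 2 and out.table["diameter_um"].min() == 0.5

    def test_empty_and_all_subthreshold(self):
        assert len(filter_large_foci([])) == 0
        assert len(filter_large_foci([(0, 0, 0, 0.2)])) == 0

    def test_missing_diameter_raises(self):
        bad = pd.DataFrame({"x_um": [0], "y_um": [0], "z_um": [0],
                            "diameter_um": [np.nan]})
        with pytest.raises(ValueError):
            filter_large_foci(bad)


class TestHubDistances:
    def test_hand_example(self):
        foci = make_fociset([[0, 0, 0]])
        hubs = LargeFociSet("n", pd.DataFrame(
            {"x_um": [1, 0], "y_um": [0, 2], "z_um": [0, 0], "diameter_um": [0.6, 0.7]}))
        s = foci_to_hub_distances(foci, hubs)
        assert s.per_focus_shortest[0] == pytest.approx(1.0)

    def test_coincident_focus_and_hub(self):
        hubs = LargeFociSet("n", pd.DataFrame(
            {"x_um": [0.0], "y_um": [0.0], "z_um": [0.0], "diameter_um": [0.6]}))
        s = foci_to_hub_distances(make_fociset([[0, 0, 0]]), hubs)
        assert s.min_shortest == 0.0

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(-4, 4, size=(30, 3))
        hub_pts = rng.uniform(-4, 4, size=(4, 3))
        hubs = LargeFociSet("n", pd.DataFrame(
            {"x_um": hub_pts[:, 0], "y_um": hub_pts[:, 1], "z_um": hub_pts[:, 2],
             "diameter_um": np.full(4, 0.8)}))
        s = foci_to_hub_distances(make_fociset(pts), hubs)
        assert np.allclose(s.per_focus_shortest,
                           brute_force_nearest(pts, hub_pts, same=False))

    def test_no_hubs_flagged_empty(self):
        hubs = LargeFociSet("n", pd.DataFrame(columns=["x_um", "y_um", "z_um",
                                                       "diameter_um"]))
        assert foci_to_hub_distances(make_fociset([[0, 0, 0]]), hubs).empty
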