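import numpy as np
import pytest

from spatmetrics import (
    Landscape,
    PointPattern,
    occupancy_curve,
    oring_estimate,
    quadrat_counts,
    simulate_csr,
    taylor_curve,
    two_plot_cov,
    two_plot_pairs,
    two_plot_turnover,
)
from spatmetrics.metrics import MetricCurve


class TestQuadratCounts:
    def test_toy_grid_counts(self, toy_pattern):
        assert sorted(quadrat_counts(toy_pattern, 1.0)) == [0, 1, 1, 1]

    def test_empty_pattern_all_zero(self):
        pat = PointPattern(np.empty((0, 2)), Landscape(4.0, 4.0))
        counts = quadrat_counts(pat, 1.0)
        assert counts.size == 16 and not counts.any()

    def test_single_tile_is_total(self, toy_pattern):
        assert quadrat_counts(toy_pattern, 2.0).tolist() == [3]

    def test_partial_tiles_discarded(self, toy_pattern):
        # side 1.5 fits one tile only: counts points in [0,1.5)^2
        assert quadrat_counts(toy_pattern, 1.5).tolist() == [1]

    def test_oversized_side_rejected(self, toy_pattern):
        with pytest.raises(ValueError, match="exceeds"):
            quadrat_counts(toy_pattern, 3.0)

    def test_random_scheme_reproducible(self, csr_pattern):
        a = quadrat_counts(csr_pattern, 5.0, scheme="random", n_random=50, seed=3)
        b = quadrat_counts(csr_pattern, 5.0, scheme="random", n_random=50, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.size == 50


class TestTaylorAndOccupancy:
    def test_toy_mean_and_variance(self, toy_pattern):
        c = taylor_curve(toy_pattern, [1.0])
        assert c.mean[0] == pytest.approx(0.75)
        assert c.ordinate[0] == pytest.approx(0.25)  # unbiased, divisor 3
        assert c.support[0] == 4

    def test_toy_occupancy(self, toy_pattern):
        c = occupancy_curve(toy_pattern, [1.0])
        assert c.ordinate[0] == pytest.approx(0.75)

    def test_occupancy_saturates_when_all_quadrats_filled(self):
        coords = np.array([(x + 1.0, y + 1.0) for x in (0, 2) for y in (0, 2)])
        pat = PointPattern(coords, Landscape(4.0, 4.0))
        c = occupancy_curve(pat, [2.0])
        assert c.ordinate[0] == 1.0 and c.support[0] == 4

    def test_empty_pattern_zero_occupancy(self):
        pat = PointPattern(np.empty((0, 2)), Landscape(4.0, 4.0))
        c = occupancy_curve(pat, [1.0, 2.0])
        assert not c.ordinate.any()

    def test_undersupported_side_dropped_with_warning(self, toy_pattern):
        with pytest.warns(UserWarning, match="dropping"):
            c = taylor_curve(toy_pattern, [1.0, 2.0])  # side 2 -> single quadrat
        np.testing.assert_allclose(c.abscissa, [1.0])

    def test_csr_mean_count_equals_area_in_scaled_units(self):
        """At unit intensity the expected quadrat count is the quadrat area."""
        from spatmetrics import rescale_to_unit_intensity

        pat = simulate_csr(2000, Landscape(100.0, 100.0), seed=1)
        scaled, _ = rescale_to_unit_intensity(pat)
        c = taylor_curve(scaled, np.array([1.0, 2.0, 4.0]))
        np.testing.assert_allclose(c.mean, c.abscissa, rtol=0.05)


class TestOring:
    def test_two_point_buffer_hand_count(self):
        """Two interior points at distance 1: the bin holding d=1 gets
        2 / (2 * annulus_area * lambda), every other bin zero."""
        land = Landscape(10.0, 10.0)
        pat = PointPattern(np.array([(5.0, 4.5), (5.0, 5.5)]), land)
        edges = np.array([0.0, 0.5, 1.5, 2.0])
        c = oring_estimate(pat, edges, correction="buffer")
        lam = 2 / 100.0
        a_mid = np.pi * (1.5**2 - 0.5**2)
        assert c.ordinate[0] == 0.0
        assert c.ordinate[1] == pytest.approx(2 / (2 * a_mid * lam))
        assert c.ordinate[2] == 0.0

    def test_translation_csr_flat(self, csr_pattern):
        from spatmetrics import rescale_to_unit_intensity

        scaled, _ = rescale_to_unit_intensity(csr_pattern)
        c = oring_estimate(scaled, np.linspace(0, 4, 9))
        assert abs(c.ordinate.mean() - 1.0) < 0.08

    def test_buffer_neighbour_count_identity(self, csr_pattern):
        """sum_bins Omega_hat * annulus_area * lambda = mean neighbours within
        r_max per interior point -- exact for the buffer correction."""
        edges = np.linspace(0, 5, 11)
        c = oring_estimate(csr_pattern, edges, correction="buffer")
        areas = np.pi * np.diff(edges**2)
        lhs = float(np.sum(c.ordinate * areas) * csr_pattern.intensity)
        xy = csr_pattern.coords
        r_max = edges[-1]
        w, h = 50.0, 50.0
        interior = (
            (xy[:, 0] >= r_max) & (xy[:, 0] <= w - r_max)
            & (xy[:, 1] >= r_max) & (xy[:, 1] <= h - r_max)
        )
        d = np.hypot(*(xy[interior][:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        neigh = ((d < r_max) & (d > 0)).sum() / interior.sum()
        assert lhs == pytest.approx(neigh, rel=1e-9)

    def test_single_point_rejected(self):
        pat = PointPattern(np.array([(1.0, 1.0)]), Landscape(4.0, 4.0))
        with pytest.raises(ValueError, match="at least 2"):
            oring_estimate(pat, np.array([0.0, 1.0]))


class TestTwoPlotPairs:
    def test_toy_enumeration(self, toy_pattern):
        pairs = two_plot_pairs(toy_pattern, 1.0, [0.0])[0.0]
        # horizontal: (tile(0,0), tile(1,0)) = (1,1), (tile(0,1), tile(1,1)) = (0,1)
        # vertical:   (tile(0,0), tile(0,1)) = (1,0), (tile(1,0), tile(1,1)) = (1,1)
        assert sorted(map(tuple, pairs.tolist())) == [(0, 1), (1, 0), (1, 1), (1, 1)]

    def test_infeasible_gap_dropped(self, toy_pattern):
        with pytest.warns(UserWarning, match="no feasible"):
            out = two_plot_pairs(toy_pattern, 1.0, [0.0, 5.0])
        assert list(out) == [0.0]

    def test_only_zero_gap_fits_two_by_two(self, toy_pattern):
        with pytest.warns(UserWarning):
            out = two_plot_pairs(toy_pattern, 1.0, [0.0, 0.5])
        assert list(out) == [0.0]


class TestTwoPlotCov:
    def test_toy_value(self, toy_pattern):
        c = two_plot_cov(toy_pattern, 1.0, [0.0])
        # pairs {(1,1),(0,1),(1,0),(1,1)}, pooled mean 0.75, divisor 3
        assert c.ordinate[0] == pytest.approx(-1.0 / 12.0)
        assert c.plot_side == 1.0

    def test_translated_duplicate_gives_large_positive(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, (60, 2)) * [4.0, 20.0]
        shifted = base + [6.0, 0.0]  # side 4 + gap 2
        pat = PointPattern(np.vstack([base, shifted]), Landscape(20.0, 20.0))
        c = two_plot_cov(pat, 4.0, [0.0, 2.0])
        at2 = c.ordinate[c.abscissa == 2.0][0]
        assert at2 > 1.0
        assert at2 > c.ordinate[c.abscissa == 0.0][0]

    def test_csr_covariance_near_zero(self):
        pat = simulate_csr(1000, Landscape(100.0, 100.0), seed=5)
        c = two_plot_cov(pat, 10.0, [0.0, 10.0, 30.0])
        var = quadrat_counts(pat, 10.0).var(ddof=1)
        assert np.all(np.abs(c.ordinate) < 0.35 * var)


class TestTwoPlotTurnover:
    def test_toy_value(self, toy_pattern):
        c = two_plot_turnover(toy_pattern, 1.0, [0.0])
        # both occupied in 2/4 pairs; pooled occupancy 6/8
        assert c.ordinate[0] == pytest.approx((2 / 4) / (6 / 8))

    def test_fully_occupied_gives_one(self):
        coords = np.array([(x + 0.5, y + 0.5) for x in range(4) for y in range(4)])
        pat = PointPattern(coords, Landscape(4.0, 4.0))
        c = two_plot_turnover(pat, 1.0, [0.0, 1.0])
        np.testing.assert_allclose(c.ordinate, 1.0)

    def test_distant_plots_approach_occupancy(self):
        """For CSR, plots far apart are independent so T ~ Psi."""
        pat = simulate_csr(800, Landscape(200.0, 200.0), seed=6)
        t = two_plot_turnover(pat, 10.0, [100.0])
        psi = occupancy_curve(pat, [10.0]).ordinate[0]
        assert t.ordinate[0] == pytest.approx(psi, abs=0.08)

    def test_empty_pattern_errors(self):
        pat = PointPattern(np.empty((0, 2)), Landscape(4.0, 4.0))
        with pytest.raises(ValueError, match="turnover undefined"):
            two_plot_turnover(pat, 1.0, [0.0])


class TestMetricCurve:
    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            MetricCurve("nope", [1.0], [1.0], [1])

    def test_rejects_decreasing_abscissa(self):
        with pytest.raises(ValueError, match="increasing"):
            MetricCurve("oring", [2.0, 1.0], [1.0, 1.0], [1, 1])

    def test_rejects_out_of_range_occupancy(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            MetricCurve("occupancy", [1.0], [1.5], [1])

    def test_two_plot_requires_plot_side(self):
        with pytest.raises(ValueError, match="plot_side"):
            MetricCurve("turnover", [1.0], [0.5], [1])
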