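import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scotomap as sm
from scotomap.stats import (
    NormalizedHistogram,
    PairDeviation,
    bin_by_eccentricity,
    bold_modulation,
    deviation_rank,
    euclidean_distance,
    mixed_slope,
    normalized_hist,
    pair_deviation,
    quadrant_of,
    quadrant_summary,
    size_distribution_test,
)
from scotomap.timeseries import TimeSeriesSet


def model_at(x, y, sigma=1.0, ve=0.5):
    return sm.PRFModel(x0=x, y0=y, sigma=sigma, beta=1.0, baseline=0.0, ve=ve)


class TestBoldModulation:
    def test_constant_series_is_zero(self):
        assert bold_modulation(np.full((1, 50), 3.0))[0] == 0.0

    def test_sine_amplitude_over_sqrt2(self):
        t = np.linspace(0, 2 * np.pi * 100, 10000, endpoint=False)
        out = bold_modulation(TimeSeriesSet(2.0 * np.sin(t)[None, :], 1.5))
        assert out[0] == pytest.approx(2.0 / np.sqrt(2), rel=0.01)

    def test_homogeneous_in_gain(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 100))
        assert np.allclose(bold_modulation(5 * x), 5 * bold_modulation(x))


class TestEccentricityBinning:
    def test_single_populated_bin(self):
        models = [model_at(1.5, 0.0) for _ in range(10)]
        prof = bin_by_eccentricity(np.arange(10.0), models)
        assert prof.count[1] == 10
        assert prof.mean[1] == pytest.approx(4.5)
        assert np.isnan(prof.mean[0])

    def test_means_match_brute_force(self):
        rng = np.random.default_rng(1)
        ecc = rng.uniform(0, 7, 100)
        models = [model_at(e, 0.0) for e in ecc]
        prof = bin_by_eccentricity(ecc, models)
        for k in range(7):
            members = ecc[(ecc >= k) & (ecc < k + 1)]
            if members.size:
                assert prof.mean[k] == pytest.approx(members.mean())

    def test_boundary_goes_to_upper_bin(self):
        prof = bin_by_eccentricity(np.array([1.0]), [model_at(2.0, 0.0)])
        assert prof.count[2] == 1 and prof.count[1] == 0

    def test_bootstrap_interval_brackets_mean(self):
        models = [model_at(1.2, 0.0) for _ in range(50)]
        vals = np.random.default_rng(2).normal(5, 1, 50)
        prof = bin_by_eccentricity(vals, models)
        assert prof.ci_low[1] <= prof.mean[1] <= prof.ci_high[1]


class TestNormalizedHist:
    def test_mass_sums_to_one(self):
        models = [model_at(x, 0.5) for x in np.linspace(0.1, 6, 40)]
        h = normalized_hist(models, "eccentricity")
        assert h.mass.sum() == pytest.approx(1.0)

    def test_single_bin_concentration(self):
        models = [model_at(1.5, 0.0) for _ in range(7)]
        h = normalized_hist(models, "eccentricity")
        assert h.mass[1] == pytest.approx(1.0)

    def test_duplication_invariance(self):
        models = [model_at(x, 0.3) for x in (0.5, 2.5, 4.5)]
        h1 = normalized_hist(models, "size")
        h2 = normalized_hist(models * 2, "size")
        assert np.allclose(h1.mass, h2.mass)

    def test_zero_models_flagged(self):
        h = normalized_hist([], "polar")
        assert h.empty and np.all(h.mass == 0)

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError):
            normalized_hist([model_at(1, 1)], "volume")


class TestPairDeviation:
    def mk(self, mass, edges=None):
        mass = np.asarray(mass, float)
        edges = np.arange(len(mass) + 1.0) if edges is None else edges
        return NormalizedHistogram("size", edges, mass, 10)

    def test_identical_histograms_zero(self):
        h = self.mk([0.5, 0.5])
        assert pair_deviation(h, h).aggregate == 0.0

    def test_disjoint_histograms_aggregate_two(self):
        assert pair_deviation(self.mk([1.0, 0.0]), self.mk([0.0, 1.0])).aggregate == 2.0

    def test_hand_computed_case(self):
        d = pair_deviation(self.mk([0.5, 0.5]), self.mk([0.75, 0.25]))
        assert d.aggregate == pytest.approx(0.5)
        assert np.allclose(d.per_bin, [-0.25, 0.25])

    def test_edge_mismatch_rejected(self):
        with pytest.raises(ValueError, match="edges"):
            pair_deviation(self.mk([1.0]), self.mk([0.5, 0.5]))

    @given(
        st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
        st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
    )
    def test_metric_like(self, a, b):
        ha = self.mk(np.array(a) / sum(a))
        hb = self.mk(np.array(b) / sum(b))
        dab = pair_deviation(ha, hb).aggregate
        dba = pair_deviation(hb, ha).aggregate
        assert dab >= 0 and dab == pytest.approx(dba)
        assert pair_deviation(ha, ha).aggregate == 0.0


class TestDeviationRank:
    def mk_dev(self, agg):
        return PairDeviation(per_bin=np.array([agg]), edges=np.array([0.0, 1.0]))

    def test_smallest_pair_ranks_first(self):
        rr = deviation_rank(self.mk_dev(0.01), [self.mk_dev(v) for v in np.arange(1, 7) / 10])
        assert rr.rank == 1.0 and not rr.significant

    def test_largest_pair_is_significant(self):
        baseline = [self.mk_dev(v) for v in np.arange(1, 20) / 20]
        rr = deviation_rank(self.mk_dev(5.0), baseline)
        assert rr.rank == 20.0 and rr.percentile == 100.0 and rr.significant

    def test_midrank_on_ties(self):
        baseline = [self.mk_dev(0.5) for _ in range(6)]
        rr = deviation_rank(self.mk_dev(0.5), baseline)
        assert rr.rank == 1 + 0.5 * 6

    def test_small_baseline_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            deviation_rank(self.mk_dev(1.0), [self.mk_dev(0.1)] * 4)


class TestQuadrants:
    def test_sign_convention(self):
        assert list(quadrant_of([-1, 1, -1, 1], [1, 1, -1, -1])) == ["UL", "UR", "LL", "LR"]

    def test_meridians_assigned_by_polar_intervals(self):
        # each meridian belongs to the quadrant whose half-open polar interval
        # it closes: upper -> UR (theta = 0), left -> UL (pi/2), lower -> LL
        # (pi), right -> LR (3pi/2); the upper-left quadrant spans (0, pi/2]
        assert quadrant_of([0.0], [1.0])[0] == "UR"
        assert quadrant_of([-1.0], [0.0])[0] == "UL"
        assert quadrant_of([0.0], [-1.0])[0] == "LL"
        assert quadrant_of([1.0], [0.0])[0] == "LR"

    def test_symmetric_sheets_have_equal_sizes(self):
        models = [model_at(x, y, 1.3) for x, y in [(1, 1), (-1, 1), (1, -1), (-1, -1)]]
        qs = quadrant_summary(models)
        assert np.allclose(qs.table["mean_sigma"], 1.3)

    def test_empty_quadrants_flagged(self):
        qs = quadrant_summary([model_at(-1, 1)])
        assert set(qs.empty_quadrants) == {"UR", "LL", "LR"}

    def test_means_match_groupby(self):
        rng = np.random.default_rng(4)
        models = [
            model_at(x, y, s)
            for x, y, s in zip(
                rng.uniform(-5, 5, 60), rng.uniform(-5, 5, 60), rng.uniform(0.5, 3, 60)
            )
        ]
        mods = rng.uniform(0, 1, 60)
        qs = quadrant_summary(models, mods)
        quad = quadrant_of([m.x0 for m in models], [m.y0 for m in models])
        for q in sm.stats.QUADRANTS:
            sel = quad == q
            if sel.any():
                assert qs[q]["mean_modulation"] == pytest.approx(mods[sel].mean())
                assert qs[q]["mean_sigma"] == pytest.approx(
                    np.mean([m.sigma for m, s in zip(models, sel) if s])
                )


class TestEuclideanDistance:
    def test_three_four_five(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity_and_symmetry(self):
        assert euclidean_distance((1, 2), (1, 2)) == 0.0
        assert euclidean_distance((0, 1), (5, -2)) == euclidean_distance((5, -2), (0, 1))


class TestMixedSlope:
    def test_exact_line_single_subject(self):
        x = np.arange(10.0)
        res = mixed_slope(2 * x, x, np.zeros(10))
        assert res.method == "ols"
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mixed_slope(np.arange(4.0), np.ones(4), np.zeros(4))

    def test_null_slope_ci_coverage(self):
        """With y independent of x the 95% CI covers 0 in >= 90% of replicates."""
        rng = np.random.default_rng(5)
        cover = 0
        n_rep = 100
        for _ in range(n_rep):
            subj = np.repeat(np.arange(8), 4)
            x = rng.normal(size=32)
            y = rng.normal(size=32)
            lo, hi = mixed_slope(y, x, subj).slope_ci
            cover += lo <= 0 <= hi
        assert cover / n_rep >= 0.90

    def test_hierarchical_slope_recovery(self):
        rng = np.random.default_rng(6)
        subj = np.repeat(np.arange(12), 6)
        x = rng.normal(size=72)
        slopes = -0.3 + 0.1 * rng.normal(size=12)
        y = slopes[subj] * x + 0.1 * rng.normal(size=72)
        res = mixed_slope(y, x, subj)
        assert abs(res.slope - (-0.3)) < 2 * res.slope_se
        assert res.r2 < 0  # signed convention follows the slope

    def test_signed_r2_convention(self):
        x = np.arange(10.0)
        res = mixed_slope(-1.5 * x, x, np.zeros(10))
        assert res.r2 == pytest.approx(-1.0)


class TestSizeDistributionTest:
    def mk(self, sigmas):
        return [model_at(1, 1, s) for s in sigmas]

    def test_identical_groups_t_zero(self):
        byp = {0: self.mk([1, 2]), 1: self.mk([1, 2]), 2: self.mk([1, 2]), 3: self.mk([1, 2])}
        labels = {0: "g", 1: "g", 2: "c", 3: "c"}
        assert size_distribution_test(byp, labels).t == pytest.approx(0.0)

    def test_doubled_sigmas_shift_medians(self):
        byp = {i: self.mk([1.0, 2.0, 3.0]) for i in range(3)}
        byp.update({i + 3: self.mk([2.0, 4.0, 6.0]) for i in range(3)})
        labels = {i: ("c" if i < 3 else "g") for i in range(6)}
        res = size_distribution_test(byp, labels)
        assert res.group_medians["g"] == pytest.approx(2 * res.group_medians["c"])
        assert res.t < 0  # alphabetical group order: c minus g

    def test_matches_hand_computed_welch(self):
        from scipy.stats import ttest_ind

        a, b = [1.0, 1.2, 1.4], [1.1, 1.5, 1.9]
        byp = {i: self.mk([v]) for i, v in enumerate(a + b)}
        labels = {i: ("a" if i < 3 else "b") for i in range(6)}
        res = size_distribution_test(byp, labels)
        t, p = ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)

    def test_small_group_rejected(self):
        byp = {0: self.mk([1]), 1: self.mk([1]), 2: self.mk([1])}
        labels = {0: "a", 1: "a", 2: "b"}
        with pytest.raises(ValueError, match="fewer than 2"):
            size_distribution_test(byp, labels)
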