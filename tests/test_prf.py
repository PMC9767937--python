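import numpy as np
import pytest

import scotomap as sm
from scotomap.prf import (
    GridSpec,
    _candidate_predictions,
    _ve_matrix,
    dct_basis,
    polar_angle,
)
from scotomap.timeseries import TimeSeriesSet


class TestHRF:
    def test_peak_near_specified_delay(self, hrf):
        t = np.arange(0, hrf.length, 0.1)
        h = sm.HRFSpec().sample(0.1)
        assert abs(t[np.argmax(h)] - hrf.delay_peak) < 0.3

    def test_peak_normalized(self, hrf):
        assert np.max(np.abs(hrf.sample(1.5))) == pytest.approx(1.0)

    def test_invalid_delays_rejected(self):
        with pytest.raises(ValueError):
            sm.HRFSpec(delay_peak=-1)


class TestPreprocess:
    def test_dummy_frames_dropped(self):
        ts = TimeSeriesSet(np.random.default_rng(0).normal(100, 1, (3, 136)), 1.5)
        out = sm.preprocess(ts)
        assert out.n_frames == 128

    def test_constant_series_zeroed(self):
        ts = TimeSeriesSet(np.full((2, 20), 50.0), 1.5)
        out = sm.preprocess(ts, dummy=4)
        assert np.allclose(out.data, 0.0)

    def test_slow_drift_removed(self):
        """A 0.0005 Hz cosine, below the 0.001 Hz cutoff, is filtered out.

        Uses a run long enough (3000 s) that 0.0005 Hz is below the cutoff and
        representable in the cosine basis; the residual amplitude at the drift
        frequency must fall below 1% of the injected amplitude.
        """
        tr, n, amp, f = 1.5, 2000, 5.0, 0.0005
        i = np.arange(n)
        drift = amp * np.cos(2 * np.pi * f * (i + 0.5) * tr)
        ts = TimeSeriesSet(drift[None, :], tr)
        out = sm.preprocess(ts, dummy=0, psc=False)
        # amplitude of the residual at the drift frequency
        c = np.cos(2 * np.pi * f * (i + 0.5) * tr)
        resid_amp = abs(2.0 * (out.data[0] @ c) / n)
        assert resid_amp < 0.01 * amp

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="dummy"):
            sm.preprocess(TimeSeriesSet(np.zeros((1, 8)), 1.5), dummy=8)

    def test_dct_basis_always_contains_mean(self):
        b = dct_basis(128, 1.5, 0.001)
        assert b.shape == (128, 1)  # only the constant survives on a 192 s run
        b2 = dct_basis(2000, 1.5, 0.001)
        assert b2.shape[1] > 2


class TestPredictTimeseries:
    def test_zero_beta_gives_baseline(self, small_aperture, hrf):
        m = sm.PRFModel(x0=0, y0=0, sigma=1, beta=0.0, baseline=3.0, ve=0)
        out = sm.predict_timeseries(m, small_aperture, hrf)
        assert np.allclose(out, 3.0)

    def test_far_outside_prf_is_flat(self, small_aperture, hrf):
        far = sm.PRFModel(x0=30, y0=30, sigma=1, beta=1.0, baseline=0.0, ve=0)
        inside = sm.PRFModel(x0=0, y0=0, sigma=1, beta=1.0, baseline=0.0, ve=0)
        out_far = sm.predict_timeseries(far, small_aperture, hrf)
        out_in = sm.predict_timeseries(inside, small_aperture, hrf)
        assert np.ptp(out_far) < 1e-3 * np.ptp(out_in)

    def test_translation_invariance(self, hrf):
        """Shifting aperture and pRF center together leaves the drive unchanged."""
        rng = np.random.default_rng(5)
        frames = (rng.uniform(size=(10, 31, 31)) > 0.7).astype(np.float32)
        shift_px, shift_deg = 4, 2.0
        frames[:, :, -shift_px:] = 0  # keep the roll from wrapping content
        movie = sm.ApertureMovie(frames, 1.5, deg_per_pixel=0.5)
        shifted = sm.ApertureMovie(np.roll(frames, shift_px, axis=2), 1.5, 0.5)
        a = sm.predict_timeseries(
            sm.PRFModel(x0=-3, y0=1, sigma=1.2, beta=1, baseline=0, ve=0), movie, hrf
        )
        b = sm.predict_timeseries(
            sm.PRFModel(x0=-3 + shift_deg, y0=1, sigma=1.2, beta=1, baseline=0, ve=0),
            shifted,
            hrf,
        )
        # compare away from wrap-around effects: both pRFs sit well inside
        assert np.allclose(a, b, atol=1e-6)

    def test_requires_dummy_stripped(self, small_movie, hrf):
        m = sm.PRFModel(x0=0, y0=0, sigma=1, beta=1, baseline=0, ve=0)
        with pytest.raises(ValueError, match="dummy"):
            sm.predict_timeseries(m, small_movie, hrf)


class TestModelValidation:
    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            sm.PRFModel(x0=0, y0=0, sigma=0.0, beta=1, baseline=0, ve=0)

    def test_ecc_consistent_with_center(self):
        m = sm.PRFModel(x0=3, y0=4, sigma=1, beta=1, baseline=0, ve=0)
        assert m.ecc == pytest.approx(5.0, abs=1e-9)


class TestPolarConvention:
    def test_upper_meridian_is_zero(self):
        assert polar_angle(0.0, 1.0) == pytest.approx(0.0)

    def test_upper_left_in_first_quadrant_range(self):
        th = polar_angle(-1.0, 1.0)
        assert 0 < th <= np.pi / 2

    def test_counterclockwise_progression(self):
        # UL -> LL -> LR -> UR as theta increases
        assert polar_angle(-1, 1) < polar_angle(-1, -1) < polar_angle(1, -1) < polar_angle(1, 1)


class TestCoarseFit:
    def test_noiseless_on_grid_recovery_is_exact(self, small_aperture, hrf):
        truth = sm.PRFModel(x0=2.0, y0=-1.5, sigma=1.0, beta=1.3, baseline=0.2, ve=1)
        y = sm.predict_timeseries(truth, small_aperture, hrf)
        mapper = sm.GaussianPRFMapper(apertures=small_aperture, hrf=hrf, refine=False)
        mapper.fit(y[None, :])
        m = mapper.models_[0]
        assert (m.x0, m.y0, m.sigma) == (2.0, -1.5, 1.0)
        assert m.ve == pytest.approx(1.0, abs=1e-9)
        assert m.beta == pytest.approx(1.3, rel=1e-6)
        assert m.baseline == pytest.approx(0.2, abs=1e-6)

    def test_refinement_recovers_off_grid_truth(self, small_aperture, hrf):
        truth = sm.PRFModel(x0=1.37, y0=-0.83, sigma=0.9, beta=1, baseline=0, ve=1)
        y = sm.predict_timeseries(truth, small_aperture, hrf)
        fit = sm.fit_prf(y, small_aperture, hrf=hrf)
        assert np.hypot(fit.x0 - truth.x0, fit.y0 - truth.y0) < 0.05
        assert abs(fit.sigma - truth.sigma) < 0.05

    def test_refinement_never_degrades_ve(self, small_aperture, hrf, rng):
        truth = sm.PRFModel(x0=1.0, y0=1.0, sigma=1.0, beta=1, baseline=0, ve=1)
        y = sm.predict_timeseries(truth, small_aperture, hrf) + rng.normal(0, 0.5, 128)
        coarse = sm.GaussianPRFMapper(
            apertures=small_aperture, hrf=hrf, refine=False
        ).fit(y[None, :])
        refined = sm.GaussianPRFMapper(
            apertures=small_aperture, hrf=hrf, refine=True
        ).fit(y[None, :])
        assert refined.ve_[0] >= coarse.ve_[0]

    def test_duplicate_candidates_break_ties_deterministically(self, small_aperture, hrf):
        truth = sm.PRFModel(x0=1.0, y0=0.0, sigma=1.0, beta=1, baseline=0, ve=1)
        y = sm.predict_timeseries(truth, small_aperture, hrf)
        g1 = GridSpec(xs=np.array([1.0, 1.0, -1.0]), ys=np.array([0.0]), sigmas=(1.0, 1.0))
        g2 = GridSpec(xs=np.array([-1.0, 1.0, 1.0]), ys=np.array([0.0]), sigmas=(1.0, 1.0))
        f1 = sm.fit_prf(y, small_aperture, grid=g1, hrf=hrf, refine=False)
        f2 = sm.fit_prf(y, small_aperture, grid=g2, hrf=hrf, refine=False)
        assert (f1.x0, f1.y0, f1.sigma) == (f2.x0, f2.y0, f2.sigma)

    def test_zero_variance_series_flagged_degenerate(self, small_aperture, hrf):
        fit = sm.fit_prf(np.zeros(128), small_aperture, hrf=hrf)
        assert fit.degenerate and fit.ve == 0.0

    def test_pure_noise_rarely_passes_threshold(self, ff_aperture, hrf):
        """Noise-only series stay below the VE=0.15 responsiveness cut."""
        params, preds = _candidate_predictions(ff_aperture, GridSpec(), hrf)
        noise = np.random.default_rng(123).normal(size=(1000, 128))
        ve = _ve_matrix(preds, noise).max(axis=0)
        assert np.mean(ve < 0.15) >= 0.99


class TestThreshold:
    def make(self, ve=0.5, ecc=3.0):
        return sm.PRFModel(x0=ecc, y0=0, sigma=1, beta=1, baseline=0, ve=ve)

    def test_ve_boundary(self):
        kept = sm.threshold_models([self.make(ve=0.14), self.make(ve=0.15)])
        assert len(kept) == 1 and kept[0].ve == 0.15

    def test_ecc_boundary(self):
        kept = sm.threshold_models([self.make(ecc=7.5), self.make(ecc=7.0)])
        assert len(kept) == 1 and kept[0].ecc == pytest.approx(7.0)

    def test_empty_input(self):
        assert sm.threshold_models([]) == []

    def test_order_preserved(self):
        models = [self.make(ecc=e) for e in (1.0, 5.0, 2.0)]
        assert [m.x0 for m in sm.threshold_models(models)] == [1.0, 5.0, 2.0]


class TestMicroProbing:
    def test_weights_peak_near_true_center(self, small_aperture, hrf):
        truth = sm.PRFModel(x0=3.0, y0=-2.0, sigma=0.8, beta=1, baseline=0, ve=1)
        y = sm.predict_timeseries(truth, small_aperture, hrf)
        pm = sm.micro_probe(y, small_aperture, hrf=hrf)
        best = pm.probes[np.argmax(pm.weights[0])]
        assert np.hypot(best[0] - truth.x0, best[1] - truth.y0) <= 1.0
        assert np.hypot(*(pm.centers[0] - [truth.x0, truth.y0])) < 1.0

    def test_flat_series_flagged(self, small_aperture, hrf):
        pm = sm.micro_probe(np.zeros(128), small_aperture, hrf=hrf)
        assert pm.degenerate[0]
        assert np.all(pm.weights[0] == 0)
        assert np.isnan(pm.centers[0]).all()

    def test_symmetric_weights_centroid_at_center(self):
        from scotomap.prf import ProbeMap

        ax = np.arange(-2.0, 2.5, 1.0)
        xx, yy = np.meshgrid(ax, ax)
        probes = np.column_stack([xx.ravel(), yy.ravel()])
        w = np.exp(-(probes[:, 0] ** 2 + probes[:, 1] ** 2))[None, :]
        c = (w @ probes) / w.sum()
        assert np.allclose(c, 0.0, atol=1e-12)
        pm = ProbeMap(probes, 0.5, w, c, np.zeros(1), np.zeros(1, bool))
        assert pm.to_long_frame().shape[0] == len(probes)

    def test_empty_probe_set_rejected(self, small_aperture):
        prober = sm.MicroProber(apertures=small_aperture, spacing=100.0, extent=7.0)
        # a lone origin probe survives any spacing; shrink extent to force empty
        prober = sm.MicroProber(apertures=small_aperture, spacing=1.0, extent=-1.0)
        with pytest.raises(ValueError, match="empty probe set"):
            prober.probe_lattice()


class TestSklearnCompat:
    def test_get_set_params_round_trip(self, small_aperture):
        mapper = sm.GaussianPRFMapper(apertures=small_aperture, refine=False)
        params = mapper.get_params()
        assert params["refine"] is False
        mapper.set_params(refine=True)
        assert mapper.refine is True

    def test_clone(self, small_aperture):
        from sklearn.base import clone

        mapper = sm.GaussianPRFMapper(apertures=small_aperture, refine=False)
        c = clone(mapper)
        assert np.array_equal(c.apertures.frames, small_aperture.frames)
        assert c.refine is False
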