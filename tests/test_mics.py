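import math

import numpy as np
import pytest

from micskit.mics import (
    AMPLITUDE_GATE,
    CorrelationMap,
    MixtureFit,
    GaussianComponent,
    diffusion_from_lag_series,
    fit_mixture,
    mics_map,
    select_model,
    stics_correlate,
    summarize_component,
)
from micskit.preprocess import remove_time_average
from micskit.stack_io import Window
from micskit.synth_imaging import mics_acquisition

from conftest import make_stack


def direct_stics(deltas, means, lag, max_shift):
    """Quadruple-loop oracle for the lag correlation of a window stack."""
    T, h, w = deltas.shape
    out = np.zeros((2 * max_shift + 1, 2 * max_shift + 1))
    for psi in range(-max_shift, max_shift + 1):
        for xi in range(-max_shift, max_shift + 1):
            acc = 0.0
            for t in range(T - lag):
                s, n = 0.0, 0
                for y in range(h):
                    for x in range(w):
                        if 0 <= y + psi < h and 0 <= x + xi < w:
                            s += deltas[t, y, x] * deltas[t + lag, y + psi, x + xi]
                            n += 1
                acc += s / n / (means[t] * means[t + lag])
            out[psi + max_shift, xi + max_shift] = acc / (T - lag)
    return out


def gaussian_surface(XI, PSI, a1=0.0, sig=2.0, eps=0.0, a2=0.0, mu=(0, 0),
                     smaj=3.0, smin=1.0, theta=0.0):
    iso = a1 * np.exp(-(XI ** 2 + PSI ** 2) / (2 * sig ** 2))
    ct, st = math.cos(theta), math.sin(theta)
    u = (XI - mu[0]) * ct + (PSI - mu[1]) * st
    v = -(XI - mu[0]) * st + (PSI - mu[1]) * ct
    ani = a2 * np.exp(-0.5 * (u ** 2 / smaj ** 2 + v ** 2 / smin ** 2))
    return iso + ani + eps


@pytest.fixture
def grids():
    xi = np.arange(-8, 9)
    return np.meshgrid(xi, xi)


def surface_map(surf, lag=1):
    return CorrelationMap(surface=surf, lag=lag, lag_seconds=lag * 0.0496, n_pairs=500)


class TestSticsCorrelate:
    def test_static_stack_zero_everywhere(self, simple_meta):
        frames = np.repeat(np.random.default_rng(0).uniform(1, 5, (8, 8))[None], 12, axis=0)
        fluct = remove_time_average(make_stack(frames, simple_meta))
        for lag in (1, 3, 5):
            cm = stics_correlate(fluct, Window((0, 0), 8), lag, max_shift=3)
            np.testing.assert_allclose(cm.surface, 0.0, atol=1e-12)
            assert cm.n_pairs == 12 - lag

    def test_fft_matches_quadruple_loop_oracle(self, simple_meta, rng):
        frames = rng.uniform(1, 10, size=(12, 8, 8))
        fluct = remove_time_average(make_stack(frames, simple_meta))
        win = Window((0, 0), 8)
        means = frames.mean(axis=(1, 2))
        for lag in (1, 4):
            cm = stics_correlate(fluct, win, lag, max_shift=3)
            expected = direct_stics(fluct.deltas, means, lag, 3)
            np.testing.assert_allclose(cm.surface, expected, atol=1e-10)

    def test_lag_bounds_enforced(self, simple_meta, rng):
        fluct = remove_time_average(make_stack(rng.uniform(1, 2, (5, 8, 8)), simple_meta))
        with pytest.raises(ValueError):
            stics_correlate(fluct, Window((0, 0), 8), lag=5, max_shift=3)
        with pytest.raises(ValueError):
            stics_correlate(fluct, Window((0, 0), 8), lag=1, max_shift=4)


class TestSelectModel:
    def test_equal_sse_retains_isotropic(self):
        assert select_model(1.0, 1.0, 289) == 1.0

    def test_worse_full_fit_retains_isotropic(self):
        assert select_model(1.0, 1.1, 289) == 1.0

    def test_closed_form_value(self):
        """n ln(SSE ratio) with chi2(6): 289 ln 1.5 ~ 117.2, p far below any gate."""
        lam = 289 * math.log(1.5)
        assert lam == pytest.approx(117.2, abs=0.05)
        assert select_model(1.5, 1.0, 289, df_extra=6) < 1e-20

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_model(1.5, 1.0, 10)


class TestFitMixture:
    def test_isotropic_surface_recovered(self, grids, rng):
        XI, PSI = grids
        surf = gaussian_surface(XI, PSI, a1=0.01, sig=2.0) + rng.normal(0, 5e-5, XI.shape)
        fit = fit_mixture(surface_map(surf))
        assert fit.classification == "isotropic"
        iso = fit.isotropic
        assert iso.amplitude == pytest.approx(0.01, rel=0.05)
        assert iso.sigma_major == pytest.approx(2.0, rel=0.05)
        assert fit.r2 > 0.99

    def test_anisotropic_surface_recovered(self, grids, rng):
        XI, PSI = grids
        theta = math.radians(30)
        surf = gaussian_surface(XI, PSI, a1=0.008, sig=1.5, a2=0.006, mu=(1.5, -0.5),
                                smaj=3.0, smin=1.0, theta=theta)
        surf = surf + rng.normal(0, 2e-5, XI.shape)
        fit = fit_mixture(surface_map(surf))
        assert fit.classification == "isotropic+anisotropic"
        ani = fit.anisotropic
        dtheta = abs(ani.theta - theta) % math.pi
        assert min(dtheta, math.pi - dtheta) < math.radians(5)
        assert ani.sigma_major / ani.sigma_minor == pytest.approx(3.0, rel=0.1)
        assert ani.center[0] == pytest.approx(1.5, abs=0.2)

    def test_uniform_noise_classified_as_noise(self, grids, rng):
        XI, PSI = grids
        fit = fit_mixture(surface_map(rng.normal(0, 1e-3, XI.shape)))
        assert fit.r2 <= 0.1
        assert fit.classification == "noise"
        assert fit.components == []

    def test_stderr_from_hessian_available(self, grids, rng):
        XI, PSI = grids
        surf = gaussian_surface(XI, PSI, a1=0.01, sig=2.0) + rng.normal(0, 1e-4, XI.shape)
        fit = fit_mixture(surface_map(surf))
        assert np.isfinite(fit.stderr["a1"]) and fit.stderr["a1"] > 0
        assert np.isfinite(fit.stderr["sigma_iso"])


class TestSummarize:
    def iso_fit(self, sig=2.0, a1=0.01):
        comp = GaussianComponent(amplitude=a1, center=(0.0, 0.0), sigma_major=sig,
                                 sigma_minor=sig, theta=0.0, is_isotropic=True)
        return MixtureFit(components=[comp], epsilon=0.0, r2=0.9, lrt_p=0.5,
                          classification="isotropic", stderr={})

    def test_fwhm_conversion(self):
        meta = mics_acquisition()
        rec = summarize_component(self.iso_fit(sig=2.0), meta)
        assert rec["circle"]["fwhm_um"] == pytest.approx(0.4710, abs=1e-4)

    def test_isotropic_only_emits_circle_without_cross(self):
        rec = summarize_component(self.iso_fit(), mics_acquisition())
        assert "circle" in rec and "cross" not in rec

    def test_noise_fit_yields_empty_record(self):
        fit = MixtureFit(components=[], epsilon=0.0, r2=0.05, lrt_p=1.0,
                         classification="noise", stderr={})
        assert summarize_component(fit, mics_acquisition()) == {}

    def test_sub_gate_amplitude_never_reported(self, grids, rng):
        """An anisotropic term below the 1e-4 amplitude gate is dropped even
        when the LRT would admit it."""
        XI, PSI = grids
        surf = gaussian_surface(XI, PSI, a1=0.01, sig=2.0) + rng.normal(0, 5e-5, XI.shape)
        fit = fit_mixture(surface_map(surf))
        for comp in fit.components:
            assert comp.amplitude > AMPLITUDE_GATE


class TestDiffusionFromLagSeries:
    def make_series(self, sig2_of_tau, meta):
        fits = []
        for tau, s2 in sig2_of_tau:
            comp = GaussianComponent(amplitude=0.01, center=(0.0, 0.0),
                                     sigma_major=math.sqrt(s2), sigma_minor=math.sqrt(s2),
                                     theta=0.0, is_isotropic=True)
            fits.append(MixtureFit(components=[comp], epsilon=0.0, r2=0.9, lrt_p=0.5,
                                   classification="isotropic", stderr={}, lag=tau,
                                   lag_seconds=tau * meta.frame_interval))
        return fits

    def test_exact_inversion_of_generating_line(self):
        """sigma^2(tau) = 4 px^2 + 2 D tau with D = 0.05 um^2/s inverts exactly."""
        meta = mics_acquisition()
        D = 0.05
        pts = [(tau, 4.0 + 2 * D * tau * meta.frame_interval / meta.pixel_size ** 2)
               for tau in range(1, 11)]
        D_est, se = diffusion_from_lag_series(self.make_series(pts, meta), meta)
        assert D_est == pytest.approx(D, rel=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_requires_five_usable_lags(self):
        meta = mics_acquisition()
        fits = self.make_series([(1, 4.0), (2, 4.1)], meta)
        with pytest.raises(ValueError):
            diffusion_from_lag_series(fits, meta)


class TestMicsMap:
    def test_window_by_lag_grid_shape(self, rng):
        """A 64x32 strip with 32-px windows at step 16 yields 3 windows."""
        meta = mics_acquisition()
        frames = rng.poisson(50.0, size=(60, 32, 64)).astype(float)
        stack = make_stack(frames, meta)
        kmap = mics_map(stack, window_size=32, step=16, max_lag=5, max_shift=8)
        assert len(kmap.windows) == 3
        assert all(len(series) == 5 for series in kmap.grid)
        records = kmap.to_records()
        assert len(records) == 15
        assert {r["lag_frames"] for r in records} == {1, 2, 3, 4, 5}
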