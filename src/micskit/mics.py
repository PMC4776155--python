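"""Multimodal image correlation spectroscopy (mICS).

The spatiotemporal correlation of intensity fluctuations is computed over
pixel shifts (ξ, ψ) for a series of frame lags Δt, then each lag's surface
is fitted with a two-component Gaussian mixture: a centered isotropic
Gaussian (diffusion or binding) plus an offset, rotated anisotropic Gaussian
(confined/directed motion along a structure), on top of a spatially uniform
noise level ε. The anisotropic term is kept only when a one-sided
likelihood-ratio test rejects the purely isotropic model (p < 0.05); fits
with R² ≤ 0.1 are classified as noise; components are reported only when
their amplitude exceeds 10⁻⁴.

Sliding 32×32 windows with half-window overlap turn a 256×32 px strip
recording into a spatial map of per-lag motion phenotypes: lag-stable
isotropic amplitude indicates binding, lag-decaying amplitude with linearly
growing σ² indicates diffusion (the iMSD law σ²(τ) = σ₀² + 2Dτ per axis),
and a significant anisotropic component indicates confined motion whose
orientation θ tracks the underlying structure.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2, linregress

from micskit._corr import corr_from_ffts, padded_fft, pair_counts
from micskit.preprocess import FluctuationStack, bleach_correct, remove_time_average
from micskit.stack_io import AcquisitionMeta, ImageStack, Window, tile_windows

__all__ = [
    "CorrelationMap",
    "GaussianComponent",
    "MixtureFit",
    "KineticMap",
    "stics_correlate",
    "stics_correlate_multi",
    "fit_mixture",
    "select_model",
    "mics_map",
    "summarize_component",
    "diffusion_from_lag_series",
    "AMPLITUDE_GATE",
    "R2_NOISE_GATE",
    "LRT_ALPHA",
]

#: A fitted component is reported only if its amplitude exceeds this.
AMPLITUDE_GATE = 1e-4
#: Fits with R² at or below this are classified as structureless noise.
R2_NOISE_GATE = 0.1
#: One-sided LRT significance level for accepting the anisotropic term.
LRT_ALPHA = 0.05
#: Effective degrees of freedom of the likelihood-ratio test. The
#: anisotropic term adds 6 parameters (a₂, µ_ξ, µ_ψ, σ_major, σ_minor, θ),
#: but θ, the center and the widths are unidentified when a₂ = 0, which
#: inflates the null distribution of the statistic beyond χ²(6); Monte
#: Carlo calibration on isotropic surfaces with iid noise puts the null at
#: χ²(9) (empirical 5% size at the 0.05 gate).
LRT_DF_EXTRA = 9


@dataclasses.dataclass
class CorrelationMap:
    """Spatiotemporal correlation surface C(ξ, ψ; Δt) for one lag.

    ``surface`` is indexed (ψ, ξ), odd-sized and centered at ξ = ψ = 0.
    ``lag`` is in frames, ``lag_seconds`` in seconds; ``n_pairs`` is the
    number of frame pairs averaged (T − Δt).
    """

    surface: np.ndarray
    lag: int
    lag_seconds: float
    n_pairs: int

    def __post_init__(self) -> None:
        s = np.asarray(self.surface)
        if s.ndim != 2 or s.shape[0] % 2 == 0 or s.shape[1] % 2 == 0:
            raise ValueError("surface must be 2D with odd dimensions (centered)")

    @property
    def max_shift(self) -> int:
        return (self.surface.shape[1] - 1) // 2

    def shift_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (ξ, ψ) matching the surface layout."""
        my = (self.surface.shape[0] - 1) // 2
        mx = (self.surface.shape[1] - 1) // 2
        xi = np.arange(-mx, mx + 1)
        psi = np.arange(-my, my + 1)
        return np.meshgrid(xi, psi)


@dataclasses.dataclass
class GaussianComponent:
    """One fitted Gaussian component of the mixture.

    For the isotropic component the center is (0, 0), σ_major = σ_minor and
    θ = 0. θ is the major-axis orientation in radians, reported modulo π.
    """

    amplitude: float
    center: tuple[float, float]
    sigma_major: float
    sigma_minor: float
    theta: float
    is_isotropic: bool


@dataclasses.dataclass
class MixtureFit:
    """Result of fitting one correlation surface.

    ``classification`` is one of ``"noise"``, ``"isotropic"``,
    ``"isotropic+anisotropic"``. ``lrt_p`` is the p-value of the one-sided
    likelihood-ratio test for the anisotropic term; ``stderr`` holds
    per-parameter standard errors from the inverse Hessian of the SSE
    (NaN when the Hessian is singular).
    """

    components: list[GaussianComponent]
    epsilon: float
    r2: float
    lrt_p: float
    classification: str
    stderr: dict[str, float]
    lag: int = 0
    lag_seconds: float = 0.0
    converged: bool = True

    @property
    def isotropic(self) -> GaussianComponent | None:
        for c in self.components:
            if c.is_isotropic:
                return c
        return None

    @property
    def anisotropic(self) -> GaussianComponent | None:
        for c in self.components:
            if not c.is_isotropic:
                return c
        return None


@dataclasses.dataclass
class KineticMap:
    """Per-window, per-lag mixture fits across a cell."""

    grid: list[list[MixtureFit]]
    windows: list[Window]
    meta: AcquisitionMeta
    lags: list[int]

    def to_records(self) -> list[dict]:
        """Flatten to long-format records (one row per window × lag)."""
        rows = []
        for win, series in zip(self.windows, self.grid):
            for fit in series:
                iso, ani = fit.isotropic, fit.anisotropic
                rows.append({
                    "window_row": win.row,
                    "window_col": win.col,
                    "window_size": win.size,
                    "lag_frames": fit.lag,
                    "lag_s": fit.lag_seconds,
                    "classification": fit.classification,
                    "a1": iso.amplitude if iso else np.nan,
                    "sigma_iso": iso.sigma_major if iso else np.nan,
                    "a2": ani.amplitude if ani else np.nan,
                    "mu_x": ani.center[0] if ani else np.nan,
                    "mu_y": ani.center[1] if ani else np.nan,
                    "sigma_major": ani.sigma_major if ani else np.nan,
                    "sigma_minor": ani.sigma_minor if ani else np.nan,
                    "theta": ani.theta if ani else np.nan,
                    "epsilon": fit.epsilon,
                    "r2": fit.r2,
                    "lrt_p": fit.lrt_p,
                    **{f"stderr_{k}": v for k, v in fit.stderr.items()},
                })
        return rows


# ---------------------------------------------------------------------------
# spatiotemporal correlation


def stics_correlate_multi(fluct: FluctuationStack, window: Window,
                          lags: Sequence[int], max_shift: int) -> list[CorrelationMap]:
    """Spatiotemporal correlation of a window at several frame lags.

    For each lag Δt the correlation averages, over all T − Δt ordered frame
    pairs (t, t + Δt) and all in-bounds pixel pairs,

        C(ξ, ψ; Δt) = ⟨ δI(x, y, t) · δI(x+ξ, y+ψ, t+Δt) ⟩ / (⟨I⟩_t ⟨I⟩_{t+Δt})

    where ⟨I⟩_t is the raw window mean intensity of frame t. Shifts are
    non-periodic with per-shift pair-count normalization, cropped to
    |ξ|, |ψ| ≤ max_shift. The FFT of each window frame is computed once and
    reused for every lag.
    """
    T = fluct.n_frames
    lags = list(lags)
    if any(l < 1 for l in lags):
        raise ValueError("lags must be >= 1")
    if max(lags) >= T:
        raise ValueError(f"lag {max(lags)} >= number of frames {T}")
    if max_shift >= window.size / 2:
        raise ValueError(f"max_shift {max_shift} must be < window size/2 = {window.size / 2}")

    deltas = window.extract(fluct.deltas)
    means = _window_raw_means(fluct, window)
    if np.any(means <= 0):
        raise ValueError("raw window mean must be positive for normalization")
    # fold the per-frame normalization into the frames so FFT products sum
    normed = deltas / means[:, None, None]

    h = w = window.size
    ffts = [padded_fft(normed[t], max_shift, max_shift) for t in range(T)]
    counts = pair_counts(h, w, max_shift, max_shift)

    maps = []
    for lag in lags:
        facc = np.zeros_like(ffts[0])
        for t in range(T - lag):
            facc += np.conj(ffts[t]) * ffts[t + lag]
        acc = corr_from_ffts_accumulated(facc, (h, w), max_shift)
        surface = acc / counts / (T - lag)
        maps.append(CorrelationMap(
            surface=surface,
            lag=lag,
            lag_seconds=lag * fluct.source_meta.frame_interval,
            n_pairs=T - lag,
        ))
    return maps


def corr_from_ffts_accumulated(facc: np.ndarray, frame_shape: tuple[int, int],
                               max_shift: int) -> np.ndarray:
    """Inverse transform of an accumulated FFT cross-product (internal)."""
    from scipy.fft import irfft2, next_fast_len

    shape = (next_fast_len(frame_shape[0] + max_shift),
             next_fast_len(frame_shape[1] + max_shift))
    full = irfft2(facc, s=shape)
    idx = np.arange(-max_shift, max_shift + 1)
    return full[np.ix_(idx % shape[0], idx % shape[1])]


def _window_raw_means(fluct: FluctuationStack, window: Window) -> np.ndarray:
    """Raw (pre-subtraction) window mean intensity per frame."""
    delta_means = window.extract(fluct.deltas).mean(axis=(1, 2))
    if fluct.time_average is not None:
        return delta_means + fluct.time_average[window.slices()].mean()
    # fall back to the global per-frame mean when the time-average image
    # was not retained (moving-average high-pass path)
    return delta_means + fluct.mean_intensity


def stics_correlate(fluct: FluctuationStack, window: Window, lag: int,
                    max_shift: int) -> CorrelationMap:
    """Spatiotemporal correlation of a window at one frame lag."""
    return stics_correlate_multi(fluct, window, [lag], max_shift)[0]


# ---------------------------------------------------------------------------
# mixture model fitting


def _iso_surface(XI, PSI, a1, sigma, eps):
    return a1 * np.exp(-(XI ** 2 + PSI ** 2) / (2.0 * sigma ** 2)) + eps


def _aniso_surface(XI, PSI, a2, mux, muy, smaj, smin, theta):
    ct, st = np.cos(theta), np.sin(theta)
    u = (XI - mux) * ct + (PSI - muy) * st      # along the major axis
    v = -(XI - mux) * st + (PSI - muy) * ct     # along the minor axis
    return a2 * np.exp(-0.5 * (u ** 2 / smaj ** 2 + v ** 2 / smin ** 2))


def _moment_seed(XI, PSI, values):
    """Center and spread of the positive part of a surface."""
    w = np.clip(values, 0.0, None)
    total = w.sum()
    if total <= 0:
        return 0.0, 0.0, 1.5, 1.5, 0.0
    mx = float((w * XI).sum() / total)
    my = float((w * PSI).sum() / total)
    cxx = float((w * (XI - mx) ** 2).sum() / total)
    cyy = float((w * (PSI - my) ** 2).sum() / total)
    cxy = float((w * (XI - mx) * (PSI - my)).sum() / total)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    smaj = math.sqrt(max(evals[1], 0.25))
    smin = math.sqrt(max(evals[0], 0.25))
    theta = math.atan2(evecs[1, 1], evecs[0, 1]) % math.pi
    return mx, my, smaj, smin, theta


def select_model(sse_iso: float, sse_full: float, n_points: int,
                 df_extra: int = LRT_DF_EXTRA) -> float:
    """One-sided likelihood-ratio p-value for adding the anisotropic term.

    Under Gaussian residuals the LRT statistic for nested least-squares fits
    is Λ = n · ln(SSE_iso / SSE_full); p is the upper χ²(df_extra) tail.
    The full fit is seeded at the isotropic optimum so SSE_full ≤ SSE_iso;
    if numerical fitting nevertheless worsens the SSE, p = 1 and the
    isotropic model is retained.
    """
    if n_points <= df_extra + 3:
        raise ValueError("too few points for the likelihood-ratio test")
    if sse_full <= 0 or sse_iso <= 0 or sse_full > sse_iso:
        return 1.0
    lam = n_points * math.log(sse_iso / sse_full)
    return float(chi2.sf(lam, df_extra))


def fit_mixture(corr: CorrelationMap, df_extra: int = LRT_DF_EXTRA) -> MixtureFit:
    """Fit the isotropic + anisotropic Gaussian mixture to one lag surface.

    Fitting proceeds in two stages: a purely isotropic fit
    (a₁, σ_iso, ε; seeded from the second moments of the positive part of
    the surface), then the full model seeded at the isotropic optimum plus a
    principal-axis decomposition of the residual. Model selection and
    classification apply, in order: the R² noise gate, the likelihood-ratio
    test, and the amplitude gate.
    """
    surface = np.asarray(corr.surface, dtype=np.float64)
    if not np.all(np.isfinite(surface)):
        raise ValueError("correlation surface contains non-finite values")
    XI, PSI = corr.shift_grids()
    xi, psi, y = XI.ravel(), PSI.ravel(), surface.ravel()
    n = y.size
    ms = corr.max_shift

    # --- stage 1: isotropic model
    eps0 = float(np.median(y))
    a10 = float(y.max() - eps0)
    _, _, smaj0, smin0, _ = _moment_seed(xi, psi, y - eps0)
    sig0 = float(np.clip(math.sqrt(smaj0 * smin0), 0.5, ms))

    def res_iso(p):
        return _iso_surface(xi, psi, p[0], p[1], p[2]) - y

    # widths are bounded below by half a pixel (sub-pixel correlation
    # structure cannot exist in pixel-sampled data and only threads noise
    # points) and above by 2× the fitted shift range (a component much wider
    # than the crop is indistinguishable from the uniform background ε)
    iso_sol = least_squares(res_iso, x0=[a10, sig0, eps0],
                            bounds=([-np.inf, 0.5, -np.inf], [np.inf, 2.0 * ms, np.inf]),
                            method="trf", xtol=1e-12, ftol=1e-12)
    sse_iso = float(np.sum(iso_sol.fun ** 2))
    a1, sig_iso, eps_iso = iso_sol.x

    # --- stage 2: full model, seeded at the isotropic optimum
    resid = y - _iso_surface(xi, psi, a1, sig_iso, eps_iso)
    mx0, my0, smaj0, smin0, th0 = _moment_seed(xi, psi, resid)
    a20 = float(np.clip(resid.max(), 1e-6, None))

    def res_full(p):
        a1f, sigf, epsf, a2f, mxf, myf, smajf, sminf, thf = p
        return (_iso_surface(xi, psi, a1f, sigf, epsf)
                + _aniso_surface(xi, psi, a2f, mxf, myf, smajf, sminf, thf) - y)

    lb = [-np.inf, 0.5, -np.inf, -np.inf, -ms, -ms, 0.5, 0.5, -np.inf]
    ub = [np.inf, 2.0 * ms, np.inf, np.inf, ms, ms, ms, ms, np.inf]
    x0 = [a1, sig_iso, eps_iso, a20,
          float(np.clip(mx0, -ms, ms)), float(np.clip(my0, -ms, ms)),
          float(np.clip(smaj0, 0.5, ms)), float(np.clip(smin0, 0.5, ms)), th0]
    converged = True
    try:
        full_sol = least_squares(res_full, x0=x0, bounds=(lb, ub),
                                 method="trf", xtol=1e-12, ftol=1e-12)
        sse_full = float(np.sum(full_sol.fun ** 2))
    except Exception:
        full_sol = None
        sse_full = np.inf
        converged = False

    p_value = select_model(sse_iso, sse_full, n, df_extra) if np.isfinite(sse_full) else 1.0
    use_aniso = p_value < LRT_ALPHA and full_sol is not None

    if use_aniso:
        a1, sig_iso, eps, a2, mux, muy, smaj, smin, theta = full_sol.x
        if smin > smaj:  # canonicalize: major axis is the longer one
            smaj, smin = smin, smaj
            theta += math.pi / 2.0
        theta = theta % math.pi
        # a second component that is centered and circular carries no
        # anisotropy information (it duplicates the isotropic component's
        # symmetry, occasionally swapping roles with it): retain the
        # isotropic model in that case
        if math.hypot(mux, muy) <= 0.5 and smaj / smin < 1.2:
            use_aniso = False
            p_value = 1.0

    if use_aniso:
        sse_sel, sol_sel = sse_full, full_sol
        names = ("a1", "sigma_iso", "epsilon", "a2", "mu_x", "mu_y",
                 "sigma_major", "sigma_minor", "theta")
    else:
        a1, sig_iso, eps = iso_sol.x  # restore: full-fit values may be stale
        a2 = mux = muy = smaj = smin = theta = np.nan
        sse_sel, sol_sel = sse_iso, iso_sol
        names = ("a1", "sigma_iso", "epsilon")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse_sel / ss_tot if ss_tot > 0 else 0.0

    # stderr from the inverse Hessian of the SSE (H ≈ 2 JᵀJ at the optimum)
    stderr = {k: float("nan") for k in names}
    dof = n - len(names)
    if dof > 0:
        try:
            cov = np.linalg.inv(sol_sel.jac.T @ sol_sel.jac) * (sse_sel / dof)
            for i, k in enumerate(names):
                stderr[k] = float(np.sqrt(max(cov[i, i], 0.0)))
        except np.linalg.LinAlgError:
            pass

    components: list[GaussianComponent] = []
    if r2 <= R2_NOISE_GATE:
        classification = "noise"
    else:
        if a1 > AMPLITUDE_GATE:
            components.append(GaussianComponent(
                amplitude=float(a1), center=(0.0, 0.0),
                sigma_major=float(sig_iso), sigma_minor=float(sig_iso),
                theta=0.0, is_isotropic=True))
        if use_aniso and a2 > AMPLITUDE_GATE:
            components.append(GaussianComponent(
                amplitude=float(a2), center=(float(mux), float(muy)),
                sigma_major=float(smaj), sigma_minor=float(smin),
                theta=float(theta), is_isotropic=False))
        classification = ("isotropic+anisotropic"
                          if any(not c.is_isotropic for c in components)
                          else "isotropic")

    return MixtureFit(components=components, epsilon=float(eps), r2=float(r2),
                      lrt_p=float(p_value), classification=classification,
                      stderr=stderr, lag=corr.lag, lag_seconds=corr.lag_seconds,
                      converged=converged)


# ---------------------------------------------------------------------------
# windowed kinetic mapping and derived quantities


def mics_map(stack: ImageStack | FluctuationStack, window_size: int = 32,
             step: int = 16, max_lag: int = 20, max_shift: int = 8,
             preprocess: bool = True) -> KineticMap:
    """Sliding-window mICS analysis of a full stack.

    When given a raw :class:`ImageStack` (and ``preprocess`` is true) the
    stack is bleach-corrected and its time average removed first; a
    :class:`FluctuationStack` is used as-is. Returns one
    :class:`MixtureFit` per window per lag τ = 1..max_lag.
    """
    if isinstance(stack, ImageStack):
        if preprocess:
            fluct = remove_time_average(bleach_correct(stack))
        else:
            fluct = remove_time_average(stack)
        meta = stack.meta
    else:
        fluct = stack
        meta = fluct.source_meta
    h, w = fluct.deltas.shape[1:]
    if window_size > min(h, w):
        raise ValueError(f"window size {window_size} exceeds frame dims ({h}, {w})")
    windows = [Window(origin=(r, c), size=window_size)
               for r in range(0, h - window_size + 1, step)
               for c in range(0, w - window_size + 1, step)]
    lags = list(range(1, max_lag + 1))
    grid: list[list[MixtureFit]] = []
    for win in windows:
        maps = stics_correlate_multi(fluct, win, lags, max_shift)
        grid.append([fit_mixture(m) for m in maps])
    return KineticMap(grid=grid, windows=windows, meta=meta, lags=lags)


def summarize_component(fit: MixtureFit, meta: AcquisitionMeta) -> dict:
    """Display record for one fit: FWHM circle (isotropic) and cross (anisotropic).

    FWHM = 2·sqrt(2·ln 2)·σ, converted to µm via the pixel size. The cross
    axes run along θ and θ + π/2; weights are relative amplitudes. Returns
    an empty dict for noise classifications.
    """
    if fit.classification == "noise":
        return {}
    fwhm_factor = 2.0 * math.sqrt(2.0 * math.log(2.0))
    record: dict = {}
    total_amp = sum(abs(c.amplitude) for c in fit.components) or 1.0
    iso = fit.isotropic
    if iso is not None:
        record["circle"] = {
            "fwhm_um": fwhm_factor * iso.sigma_major * meta.pixel_size,
            "weight": abs(iso.amplitude) / total_amp,
        }
    ani = fit.anisotropic
    if ani is not None:
        record["cross"] = {
            "center_um": (ani.center[0] * meta.pixel_size,
                          ani.center[1] * meta.pixel_size),
            "fwhm_major_um": fwhm_factor * ani.sigma_major * meta.pixel_size,
            "fwhm_minor_um": fwhm_factor * ani.sigma_minor * meta.pixel_size,
            "theta": ani.theta,
            "weight": abs(ani.amplitude) / total_amp,
        }
    return record


def diffusion_from_lag_series(fits: Sequence[MixtureFit],
                              meta: AcquisitionMeta) -> tuple[float, float]:
    """Diffusion coefficient from the growth of the isotropic variance.

    Under free diffusion the correlation peak's per-axis variance grows as
    σ²(τ) = σ₀² + 2Dτ. A line is fitted to σ_iso²·pixel_size² versus
    τ·frame_interval over every lag whose fit has an isotropic component;
    the slope equals 2D. Returns (D, stderr_D) in µm²/s.
    """
    taus, sig2 = [], []
    for fit in fits:
        iso = fit.isotropic
        if iso is not None and fit.classification != "noise":
            taus.append(fit.lag_seconds if fit.lag_seconds > 0
                        else fit.lag * meta.frame_interval)
            sig2.append((iso.sigma_major * meta.pixel_size) ** 2)
    if len(taus) < 5:
        raise ValueError(f"need >= 5 lags with an isotropic component, got {len(taus)}")
    reg = linregress(np.asarray(taus), np.asarray(sig2))
    return reg.slope / 2.0, reg.stderr / 2.0
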