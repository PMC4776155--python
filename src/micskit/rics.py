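"""Raster image correlation spectroscopy (RICS).

RICS exploits the timing structure of raster scanning: adjacent pixels along
the fast axis are only microseconds apart (pixel dwell τ_p), adjacent lines
milliseconds apart (line time τ_l). A molecule diffusing during the scan
therefore broadens the spatial autocorrelation of each frame by an amount
set by its diffusion coefficient D, and fitting the raster-scan diffusion
model to the frame-averaged correlation recovers D.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from micskit._corr import cross_corr_sum, pair_counts
from micskit.preprocess import moving_average_highpass
from micskit.stack_io import AcquisitionMeta, ImageStack, Window

__all__ = [
    "RICSCorrelation",
    "RICSFit",
    "GAMMA_3D_GAUSSIAN",
    "spatial_autocorrelation",
    "rics_preprocess",
    "rics_average",
    "rics_model",
    "fit_rics",
]

#: Shape factor γ for a 3D Gaussian illumination volume, 1/(2·sqrt(2)).
GAMMA_3D_GAUSSIAN = 0.3536


@dataclasses.dataclass
class RICSCorrelation:
    """Frame-averaged spatial autocorrelation surface G(ξ, ψ).

    ``surface`` is indexed (ψ, ξ) and centered: shape
    (2*max_row_shift+1, 2*max_col_shift+1) with (0, 0) in the middle.
    """

    surface: np.ndarray
    n_frames_averaged: int
    meta: AcquisitionMeta

    @property
    def max_col_shift(self) -> int:
        return (self.surface.shape[1] - 1) // 2

    @property
    def max_row_shift(self) -> int:
        return (self.surface.shape[0] - 1) // 2


@dataclasses.dataclass
class RICSFit:
    """Fitted raster-scan diffusion model parameters.

    D in µm²/s; N is the mean number of particles in the focal volume;
    b a constant correlation offset; gamma the fixed illumination shape
    factor. ``stderr`` maps parameter name to its standard error (NaN when
    the covariance is singular).
    """

    D: float
    N: float
    b: float
    gamma: float
    fit_r2: float
    stderr: dict[str, float]
    sse: float
    n_points: int
    converged: bool


def spatial_autocorrelation(frame: np.ndarray,
                            max_col_shift: int | None = None,
                            max_row_shift: int | None = None) -> np.ndarray:
    """Intensity-normalized spatial autocorrelation of one frame.

    G(ξ, ψ) = ⟨I(x, y)·I(x+ξ, y+ψ)⟩ / ⟨I⟩² − 1, with the average taken over
    all in-bounds pixel pairs (zero-padded, non-periodic). G(0, 0) equals the
    frame's variance/mean².
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    m = frame.mean()
    if m == 0:
        raise ValueError("frame mean is zero; normalized correlation undefined")
    h, w = frame.shape
    if max_col_shift is None:
        max_col_shift = w - 1
    if max_row_shift is None:
        max_row_shift = h - 1
    sums = cross_corr_sum(frame, frame, max_row_shift, max_col_shift)
    counts = pair_counts(h, w, max_row_shift, max_col_shift)
    return sums / counts / (m * m) - 1.0


def rics_preprocess(stack: ImageStack, ma_window: int = 10) -> ImageStack:
    """Temporal high-pass for RICS: subtract a moving average, re-add the mean.

    The per-pixel 10-frame moving average removes slow motion (cell
    movement); the stack's overall mean intensity is added back so the
    normalized correlation remains defined.
    """
    fluct = moving_average_highpass(stack, window=ma_window)
    offset = float(stack.frames.mean())
    frames = np.clip(fluct.deltas + offset, 0.0, None)
    return ImageStack(frames=frames, meta=stack.meta, channel_label=stack.channel_label)


def rics_average(stack: ImageStack, window: Window | None = None,
                 max_col_shift: int = 16, max_row_shift: int = 8) -> RICSCorrelation:
    """Average the per-frame spatial autocorrelation across all frames.

    ``stack`` should already be high-pass filtered (see
    :func:`rics_preprocess`). If ``window`` is given, only that region is
    correlated.
    """
    frames = window.extract(stack.frames) if window is not None else stack.frames
    h, w = frames.shape[1:]
    max_col_shift = min(max_col_shift, w - 1)
    max_row_shift = min(max_row_shift, h - 1)
    acc = np.zeros((2 * max_row_shift + 1, 2 * max_col_shift + 1))
    for t in range(frames.shape[0]):
        acc += spatial_autocorrelation(frames[t], max_col_shift, max_row_shift)
    acc /= frames.shape[0]
    return RICSCorrelation(surface=acc, n_frames_averaged=frames.shape[0], meta=stack.meta)


def rics_model(xi: np.ndarray, psi: np.ndarray, D: float, N: float, b: float,
               meta: AcquisitionMeta, gamma: float = GAMMA_3D_GAUSSIAN) -> np.ndarray:
    """Raster-scan 2D diffusion model G_RICS(ξ, ψ) = S(ξ, ψ)·G(ξ, ψ) + b.

    G carries the molecular dynamics (3D Gaussian focal volume, diffusion
    during the pixel/line delays); S carries the scanning optics (the beam
    displacement between correlated pixels). |ξ|, |ψ| keep the model
    symmetric, matching the symmetrized non-periodic correlation.
    """
    tau = meta.pixel_dwell * np.abs(xi) + meta.line_time * np.abs(psi)
    w0sq = meta.beam_waist ** 2
    wzsq = meta.axial_waist ** 2
    denom = 1.0 + 4.0 * D * tau / w0sq
    denom_z = 1.0 + 4.0 * D * tau / wzsq
    G = (gamma / N) / denom / np.sqrt(denom_z)
    dr2 = (xi * meta.pixel_size) ** 2 + (psi * meta.pixel_size) ** 2
    S = np.exp(-dr2 / w0sq / denom)
    return S * G + b


def _ma_filter_weights(ma_window: int) -> np.ndarray:
    """Frame-lag weights induced by the moving-average high-pass.

    Subtracting the centered moving average is a linear temporal filter
    g = δ₀ − 1/W over the W-frame span; the measured correlation at frame
    lag 0 is the filter-kernel autocorrelation Σ_k β_k applied to the true
    correlation at frame lags k. Returns weights α_k for k = 0..span−1
    (α_0 = β_0, α_k = β_k + β_{−k}, using time symmetry of diffusion).
    """
    half = ma_window // 2
    span = 2 * half + 1
    g = np.full(span, -1.0 / span)
    g[half] += 1.0
    beta = np.correlate(g, g, mode="full")  # lags -(span-1)..(span-1)
    mid = span - 1
    alpha = np.empty(span)
    alpha[0] = beta[mid]
    for k in range(1, span):
        alpha[k] = beta[mid + k] + beta[mid - k]
    return alpha


def rics_model_filtered(xi: np.ndarray, psi: np.ndarray, D: float, N: float,
                        b: float, meta: AcquisitionMeta,
                        gamma: float = GAMMA_3D_GAUSSIAN,
                        ma_window: int | None = 10) -> np.ndarray:
    """RICS model including the moving-average high-pass transfer.

    At slow D consecutive frames remain spatially correlated, so the
    high-pass subtraction removes a wide, lag-mixed component from the
    measured correlation; ignoring it biases D low. This evaluates the
    model correlation at effective delays τ + k·frame_interval and combines
    them with the filter weights from :func:`_ma_filter_weights`. With
    ``ma_window=None`` this reduces to :func:`rics_model`.
    """
    if ma_window is None:
        return rics_model(xi, psi, D, N, b, meta, gamma)
    alpha = _ma_filter_weights(ma_window)
    tau0 = meta.pixel_dwell * np.abs(xi) + meta.line_time * np.abs(psi)
    w0sq = meta.beam_waist ** 2
    wzsq = meta.axial_waist ** 2
    dr2 = (xi * meta.pixel_size) ** 2 + (psi * meta.pixel_size) ** 2
    out = np.zeros_like(tau0, dtype=np.float64)
    for k, a_k in enumerate(alpha):
        tau = tau0 + k * meta.frame_interval
        denom = 1.0 + 4.0 * D * tau / w0sq
        denom_z = 1.0 + 4.0 * D * tau / wzsq
        out += a_k * (gamma / N) / denom / np.sqrt(denom_z) * np.exp(-dr2 / w0sq / denom)
    return out + b


def _fit_region(corr: RICSCorrelation, fit_col_shift: int, fit_row_shift: int):
    cx, cy = corr.max_col_shift, corr.max_row_shift
    fit_col_shift = min(fit_col_shift, cx)
    fit_row_shift = min(fit_row_shift, cy)
    xi = np.arange(-fit_col_shift, fit_col_shift + 1)
    psi = np.arange(-fit_row_shift, fit_row_shift + 1)
    XI, PSI = np.meshgrid(xi, psi)
    sub = corr.surface[cy - fit_row_shift:cy + fit_row_shift + 1,
                       cx - fit_col_shift:cx + fit_col_shift + 1]
    mask = ~((XI == 0) & (PSI == 0))  # exclude the shot-noise spike at (0,0)
    return XI[mask].ravel(), PSI[mask].ravel(), sub[mask].ravel()


def fit_rics(corr: RICSCorrelation, gamma: float = GAMMA_3D_GAUSSIAN,
             omega0: float | None = None, omega_z: float | None = None,
             fit_col_shift: int = 16, fit_row_shift: int = 8,
             ma_window: int | None = 10) -> RICSFit:
    """Fit the raster-scan diffusion model to a correlation surface.

    Free parameters are D, N and the offset b; γ, ω₀ and ω_z are instrument
    constants (they are not identifiable jointly with D and N from a single
    surface). Multi-start in D avoids the local minima of the scanning term.
    ``ma_window`` must match the moving-average span used in preprocessing
    so the model accounts for the high-pass transfer (see
    :func:`rics_model_filtered`); pass None if the stack was not filtered.
    """
    meta = corr.meta
    if omega0 is not None or omega_z is not None:
        meta = dataclasses.replace(
            meta,
            beam_waist=omega0 if omega0 is not None else meta.beam_waist,
            axial_waist=omega_z if omega_z is not None else meta.axial_waist,
        )
    xi, psi, g = _fit_region(corr, fit_col_shift, fit_row_shift)
    n_points = g.size

    cy, cx = corr.max_row_shift, corr.max_col_shift
    g10 = corr.surface[cy, cx + 1] if corr.max_col_shift >= 1 else corr.surface[cy, cx]
    n0 = gamma / g10 if g10 > 0 else 1.0
    n0 = float(np.clip(n0, 1e-3, 1e6))
    b0 = float(np.min(g))

    def residuals(p):
        D, N, b = p
        return rics_model_filtered(xi, psi, D, N, b, meta, gamma, ma_window) - g

    best = None
    for d0 in (0.1, 1.0, 10.0, 100.0):
        try:
            sol = least_squares(
                residuals, x0=[d0, n0, b0],
                bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                method="trf", xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0] - 1e-15 * abs(best[0]) or (
                np.isclose(sse, best[0], rtol=1e-9) and sol.x[0] < best[1].x[0]):
            best = (sse, sol)
    if best is None:
        raise RuntimeError("RICS fit failed to converge from all starting points")
    sse, sol = best
    D, N, b = sol.x

    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else np.nan

    stderr = {k: float("nan") for k in ("D", "N", "b")}
    dof = n_points - 3
    if dof > 0:
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.inv(JTJ) * (sse / dof)
            for i, k in enumerate(("D", "N", "b")):
                stderr[k] = float(np.sqrt(max(cov[i, i], 0.0)))
        except np.linalg.LinAlgError:
            pass

    return RICSFit(D=float(D), N=float(N), b=float(b), gamma=gamma,
                   fit_r2=float(r2), stderr=stderr, sse=sse,
                   n_points=n_points, converged=bool(sol.success))
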