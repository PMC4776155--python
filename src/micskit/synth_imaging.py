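"""Synthetic raster-scanned confocal image stacks with ground-truth motion.

Point emitters move in a 2D plane according to one of five motion modes
(free diffusion, stable binding, diffusion confined by an oscillating
boundary, a rigid oscillating filament of emitters, or directed transport)
and are imaged through a Gaussian excitation profile with Poisson photon
noise and optional Gaussian read noise. Two renderers are provided:

* :func:`render_raster` honors the raster-scan timing — every scan line is
  sampled at its own acquisition time, so emitters move *during* the frame.
  This is what makes the RICS correlation shape sensitive to fast diffusion.
* :func:`render_frames` samples a whole frame at its start time — a fast
  approximation valid when motion per frame is small compared with the PSF,
  as in mICS-scale recordings of slow motion.

Emitters live on a field extending a margin of 6·ω₀ beyond each frame edge,
with periodic re-entry, so the emitter density in view stays stationary.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from micskit.stack_io import AcquisitionMeta, ImageStack

__all__ = [
    "MotionModel",
    "SceneConfig",
    "simulate_trajectories",
    "frame_times",
    "line_times",
    "render_raster",
    "render_frames",
    "rics_acquisition",
    "mics_acquisition",
    "standard_rics_scene",
    "standard_mics_scene",
]

MODES = ("diffusion", "bound", "confined_oscillating", "filament_oscillating", "directed")


@dataclasses.dataclass
class MotionModel:
    """Parameters of one motion mode.

    Only the parameters of the active ``mode`` are used: ``D`` (µm²/s) for
    diffusion/confined/directed; ``velocity`` (µm/s, (vx, vy)) for directed;
    ``box_half_width``, ``osc_amplitude`` and ``osc_period`` (µm, µm, s) for
    the oscillating confinement box; ``filament_orientation`` (radians),
    ``filament_length`` (µm) plus the oscillation parameters for the
    oscillating filament.

    For the bound mode, ``residence_time`` (s) sets an exponential dwell
    after which an emitter relocates to a new uniform random site (slow
    binding-site exchange). ``None`` means emitters are static for the whole
    acquisition; note that fully static structure is removed exactly by
    time-average subtraction and contributes nothing to correlations — a
    lag-stable binding plateau requires a finite residence time, long
    compared with the longest analysis lag.
    """

    mode: str
    D: float = 0.0
    velocity: tuple[float, float] = (0.0, 0.0)
    box_half_width: float = 0.5
    osc_amplitude: float = 0.2
    osc_period: float = 2.0
    filament_orientation: float = 0.0
    filament_length: float = 2.0
    residence_time: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown motion mode {self.mode!r}; choose from {MODES}")
        if self.mode in ("diffusion", "confined_oscillating") and self.D <= 0:
            raise ValueError(f"mode {self.mode!r} requires D > 0")
        if self.mode in ("confined_oscillating", "filament_oscillating"):
            if self.osc_period <= 0 or self.osc_amplitude < 0:
                raise ValueError("oscillation period must be > 0 and amplitude >= 0")


@dataclasses.dataclass
class SceneConfig:
    """Scene geometry, emitter brightness, noise and the random seed.

    ``brightness`` is the expected photon count per emitter per pixel dwell
    at the PSF peak; with Poisson noise the single-emitter peak SNR is
    therefore √brightness. ``psf_waist`` defaults to the metadata beam
    waist. The seed fixes both trajectories and every noise stream.
    """

    n_particles: int
    brightness: float
    frame_geometry: AcquisitionMeta
    height: int
    width: int
    n_frames: int
    psf_waist: float | None = None
    poisson: bool = True
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.brightness <= 0:
            raise ValueError("n_particles and brightness must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        self.frame_geometry.validate_frame_shape(self.height, self.width)

    @property
    def waist(self) -> float:
        return self.psf_waist if self.psf_waist is not None else self.frame_geometry.beam_waist

    def field_bounds(self) -> tuple[float, float, float, float]:
        """(x_lo, x_hi, y_lo, y_hi) of the emitter field in µm."""
        m = 6.0 * self.waist
        px = self.frame_geometry.pixel_size
        return (-m, (self.width - 1) * px + m, -m, (self.height - 1) * px + m)


def frame_times(config: SceneConfig) -> np.ndarray:
    """Acquisition start time of every frame."""
    return np.arange(config.n_frames) * config.frame_geometry.frame_interval


def line_times(config: SceneConfig) -> np.ndarray:
    """Acquisition time of every scan line, shape (n_frames * height,).

    t(frame, row) = frame·frame_interval + row·τ_l. Within one line, pixel
    displacements over a single dwell time are far below the PSF scale for
    any realistic D, so per-line sampling is the raster time base.
    """
    meta = config.frame_geometry
    f = np.arange(config.n_frames) * meta.frame_interval
    r = np.arange(config.height) * meta.line_time
    return (f[:, None] + r[None, :]).ravel()


def rics_acquisition(beam_waist: float = 0.25, axial_waist: float = 0.75) -> AcquisitionMeta:
    """Standard fast raster geometry: 128×128 px, 80 nm/px, 6.3 µs dwell.

    The line period includes a 20% flyback allowance; frames are acquired
    continuously (frame interval = 128 line periods).
    """
    line = 1.2 * 128 * 6.3e-6
    return AcquisitionMeta(pixel_size=0.08, pixel_dwell=6.3e-6, line_time=line,
                           frame_interval=128 * line, beam_waist=beam_waist,
                           axial_waist=axial_waist)


def mics_acquisition(beam_waist: float = 0.25, axial_waist: float = 0.75) -> AcquisitionMeta:
    """Standard strip geometry for lag analysis: 256×32 px, 100 nm/px,
    1.27 µs dwell, 49.6 ms per frame acquired continuously."""
    return AcquisitionMeta(pixel_size=0.1, pixel_dwell=1.27e-6,
                           line_time=49.6e-3 / 32, frame_interval=49.6e-3,
                           beam_waist=beam_waist, axial_waist=axial_waist)


def standard_rics_scene(model: MotionModel, seed: int, n_frames: int = 100,
                        n_particles: int = 60, brightness: float = 25.0) -> ImageStack:
    """Raster-rendered 128×128 stack at the standard fast-scan geometry.

    Defaults give a sparse emitter field (strong fluctuations, as in
    fluctuation spectroscopy) with single-emitter peak SNR ≈ 5.
    """
    cfg = SceneConfig(n_particles=n_particles, brightness=brightness,
                      frame_geometry=rics_acquisition(), height=128, width=128,
                      n_frames=n_frames, seed=seed)
    traj = simulate_trajectories(model, cfg, line_times(cfg))
    return render_raster(traj, cfg)


def standard_mics_scene(model: MotionModel, seed: int, n_frames: int = 1000,
                        n_particles: int = 900, brightness: float = 25.0) -> ImageStack:
    """Frame-rendered 256×32 strip stack at the standard lag geometry.

    Defaults give ≈ 5 emitters/µm² and single-emitter peak SNR ≈ 5; motion
    per 49.6 ms frame is small against the PSF for the slow modes this
    geometry targets, so snapshot rendering is adequate.
    """
    cfg = SceneConfig(n_particles=n_particles, brightness=brightness,
                      frame_geometry=mics_acquisition(), height=32, width=256,
                      n_frames=n_frames, seed=seed)
    traj = simulate_trajectories(model, cfg)
    return render_frames(traj, cfg)


def _wrap(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + np.mod(pos - lo, hi - lo)


def _reflect(pos: np.ndarray, lo, hi):
    """Fold positions into [lo, hi] by specular reflection (vectorized)."""
    span = hi - lo
    y = np.mod(pos - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def simulate_trajectories(model: MotionModel, config: SceneConfig,
                          times: np.ndarray | None = None) -> np.ndarray:
    """Emitter positions at the given sample times.

    Returns an array of shape (n_times, n_particles, 2) of (x, y) positions
    in µm. Diffusive steps between consecutive sample times are Gaussian
    with per-axis variance 2·D·Δt; bound emitters are static; confined
    emitters diffuse inside a reflecting box whose +x wall oscillates as
    x₀ + A·sin(2πt/P); the oscillating filament is a rigid line of static
    emitters translated sinusoidally perpendicular to its axis; directed
    motion adds a v·Δt drift. Unconfined modes wrap periodically on the
    margin-extended field.
    """
    if times is None:
        times = frame_times(config)
    times = np.asarray(times, dtype=np.float64)
    rng = np.random.default_rng([config.seed, 0xA11CE])
    n_t, n_p = times.size, config.n_particles
    x_lo, x_hi, y_lo, y_hi = config.field_bounds()
    px = config.frame_geometry.pixel_size
    cx = (config.width - 1) * px / 2.0
    cy = (config.height - 1) * px / 2.0

    if model.mode == "filament_oscillating":
        s = np.linspace(-model.filament_length / 2.0, model.filament_length / 2.0, n_p)
        th = model.filament_orientation
        base = np.stack([cx + s * math.cos(th), cy + s * math.sin(th)], axis=1)
        phase = model.osc_amplitude * np.sin(2.0 * math.pi * times / model.osc_period)
        perp = np.array([-math.sin(th), math.cos(th)])
        return base[None, :, :] + phase[:, None, None] * perp[None, None, :]

    if model.mode == "bound":
        start = np.column_stack([rng.uniform(x_lo, x_hi, n_p),
                                 rng.uniform(y_lo, y_hi, n_p)])
        if model.residence_time is None:
            return np.broadcast_to(start, (n_t, n_p, 2)).copy()
        pos = np.empty((n_t, n_p, 2))
        pos[0] = start
        cur = start.copy()
        next_hop = times[0] + rng.exponential(model.residence_time, n_p)
        for i in range(1, n_t):
            hop = times[i] >= next_hop
            k = int(hop.sum())
            if k:
                cur[hop, 0] = rng.uniform(x_lo, x_hi, k)
                cur[hop, 1] = rng.uniform(y_lo, y_hi, k)
                next_hop[hop] = times[i] + rng.exponential(model.residence_time, k)
            pos[i] = cur
        return pos

    if model.mode == "confined_oscillating":
        hw = model.box_half_width
        centers = np.column_stack([
            rng.uniform(x_lo + hw + model.osc_amplitude, x_hi - hw - model.osc_amplitude, n_p),
            rng.uniform(y_lo + hw, y_hi - hw, n_p),
        ])
        pos = np.empty((n_t, n_p, 2))
        cur = centers + rng.uniform(-hw, hw, (n_p, 2)) * 0.5
        dts = np.diff(times, prepend=times[0])
        for i, t in enumerate(times):
            if i > 0:
                cur = cur + rng.normal(0.0, math.sqrt(2.0 * model.D * dts[i]), (n_p, 2))
            wall_hi_x = centers[:, 0] + hw + model.osc_amplitude * math.sin(
                2.0 * math.pi * t / model.osc_period)
            cur[:, 0] = _reflect(cur[:, 0], centers[:, 0] - hw, wall_hi_x)
            cur[:, 1] = _reflect(cur[:, 1], centers[:, 1] - hw, centers[:, 1] + hw)
            pos[i] = cur
        return pos

    # diffusion / directed on the periodic margin-extended field
    start = np.column_stack([rng.uniform(x_lo, x_hi, n_p),
                             rng.uniform(y_lo, y_hi, n_p)])
    dts = np.diff(times)
    steps = np.zeros((n_t, n_p, 2))
    if model.D > 0:
        steps[1:] = rng.normal(0.0, 1.0, (n_t - 1, n_p, 2)) * np.sqrt(
            2.0 * model.D * dts)[:, None, None]
    if model.mode == "directed":
        v = np.asarray(model.velocity, dtype=np.float64)
        steps[1:] += v[None, None, :] * dts[:, None, None]
    pos = start[None, :, :] + np.cumsum(steps, axis=0)
    pos[..., 0] = _wrap(pos[..., 0], x_lo, x_hi)
    pos[..., 1] = _wrap(pos[..., 1], y_lo, y_hi)
    return pos


def _apply_noise(stack: np.ndarray, config: SceneConfig) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 0x0F0F0])
    out = stack
    if config.poisson:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float64)
    if config.gaussian_sd > 0:
        out = out + rng.normal(0.0, config.gaussian_sd, out.shape)
    return np.clip(out, 0.0, None)


def render_raster(trajectories: np.ndarray, config: SceneConfig) -> ImageStack:
    """Render frames with per-line raster timing.

    ``trajectories`` must be sampled at :func:`line_times` (shape
    (n_frames*height, n_particles, 2)). Pixel (row, col) of frame f reads
    the emitter configuration at t = f·frame_interval + row·τ_l; the pixel
    value is Σ_p brightness·exp(−2·d²/ω₀²) with d the distance from the
    pixel center, then photon/read noise.
    """
    meta = config.frame_geometry
    n_f, H, W = config.n_frames, config.height, config.width
    if trajectories.shape[0] != n_f * H:
        raise ValueError(
            f"raster rendering needs line-time sampling: expected {n_f * H} "
            f"time samples, got {trajectories.shape[0]}")
    pos = trajectories.reshape(n_f, H, config.n_particles, 2)
    px = meta.pixel_size
    w2 = config.waist ** 2
    xs = np.arange(W) * px
    stack = np.empty((n_f, H, W))
    for r in range(H):
        y_r = r * px
        p_r = pos[:, r]                                   # (n_f, n_p, 2)
        wy = config.brightness * np.exp(-2.0 * (p_r[..., 1] - y_r) ** 2 / w2)
        ex = np.exp(-2.0 * (xs[None, None, :] - p_r[..., 0][:, :, None]) ** 2 / w2)
        stack[:, r, :] = np.matmul(wy[:, None, :], ex)[:, 0, :]
    stack = _apply_noise(stack, config)
    return ImageStack(frames=stack, meta=meta, channel_label="synthetic")


def render_frames(trajectories: np.ndarray, config: SceneConfig,
                  chunk: int = 100) -> ImageStack:
    """Render frames as instantaneous snapshots at each frame start time.

    ``trajectories`` must be sampled at :func:`frame_times` (shape
    (n_frames, n_particles, 2)). The Gaussian PSF factorizes along x and y,
    so each frame is a sum of per-emitter outer products.
    """
    meta = config.frame_geometry
    n_f, H, W = config.n_frames, config.height, config.width
    if trajectories.shape[0] != n_f:
        raise ValueError(
            f"frame rendering needs frame-time sampling: expected {n_f} "
            f"time samples, got {trajectories.shape[0]}")
    px = meta.pixel_size
    w2 = config.waist ** 2
    xs = np.arange(W) * px
    ys = np.arange(H) * px
    stack = np.empty((n_f, H, W))
    for f0 in range(0, n_f, chunk):
        f1 = min(f0 + chunk, n_f)
        p = trajectories[f0:f1]                          # (c, n_p, 2)
        ex = np.exp(-2.0 * (xs[None, None, :] - p[..., 0][:, :, None]) ** 2 / w2)
        ey = np.exp(-2.0 * (ys[None, None, :] - p[..., 1][:, :, None]) ** 2 / w2)
        stack[f0:f1] = config.brightness * np.matmul(ey.transpose(0, 2, 1), ex)
    stack = _apply_noise(stack, config)
    return ImageStack(frames=stack, meta=meta, channel_label="synthetic")
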