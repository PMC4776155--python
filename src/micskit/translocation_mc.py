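"""1D Monte Carlo simulation of receptor cytoplasm→nucleus translocation.

A population of particles starts uniformly distributed on the 1D interval
[0, L] between the nuclear envelope (x = 0) and the cell membrane (x = L).
At every time step each particle independently chooses one of three modes:
diffusion (Gaussian step, per-axis variance 2·D·dt), standing still (binding
or an idle motor), or directed dynein transport toward the nucleus (step
magnitude drawn from Normal(v·dt, v·dt/2), truncated at 0 to keep transport
unidirectional). The membrane reflects; a particle reaching the nuclear
envelope is absorbed with probability equal to the nuclear permeability
p(t) — the nucleus is a one-way sink — and otherwise reflected back.
Permeability is either constant or increases linearly in time,
p(t) = min(1, p₀ + k·t).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "TranslocationConfig",
    "TranslocationResult",
    "step_particle",
    "run_translocation",
    "concavity_metric",
    "ABSORBED",
]

#: Sentinel returned by :func:`step_particle` on nuclear absorption.
ABSORBED = object()


@dataclasses.dataclass
class TranslocationConfig:
    """Simulation parameters.

    ``mode_probs`` = (p_diffusion, p_still, p_transport), summing to 1.
    ``permeability`` is the constant absorption probability p₀ at the
    nuclear envelope; a nonzero ``permeability_slope`` k makes it the linear
    schedule p(t) = min(1, p₀ + k·t). Defaults: a 50 µm cytoplasm, 500
    particles, 1 s steps for 1800 s. The mode probabilities below are
    placeholders, not measured values.
    """

    length: float = 50.0
    n_particles: int = 500
    dt: float = 1.0
    t_max: float = 1800.0
    mode_probs: tuple[float, float, float] = (0.5, 0.4, 0.1)
    D: float = 9.2
    dynein_velocity: float = 1.0
    permeability: float = 0.1
    permeability_slope: float = 0.0
    kymo_bins: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.mode_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or np.any(p > 1) or not np.isclose(p.sum(), 1.0):
            raise ValueError("mode_probs must be three probabilities in [0,1] summing to 1")
        if self.length <= 0 or self.dt <= 0 or self.t_max <= 0:
            raise ValueError("length, dt and t_max must be positive")
        if not (0.0 <= self.permeability <= 1.0):
            raise ValueError("permeability must be in [0, 1]")
        if self.permeability_slope < 0:
            raise ValueError("permeability_slope must be >= 0")

    def permeability_at(self, t: float) -> float:
        return min(1.0, self.permeability + self.permeability_slope * t)


@dataclasses.dataclass
class TranslocationResult:
    """Time series produced by :func:`run_translocation`.

    ``positions`` is (n_steps+1, n_particles) with NaN after absorption;
    ``nuclear_count`` the cumulative absorbed count per step;
    ``cyto_fraction`` = 1 − nuclear_count/n_particles; ``kymograph`` the
    binned histogram of surviving cytoplasmic positions over time,
    shape (kymo_bins, n_steps+1).
    """

    times: np.ndarray
    positions: np.ndarray
    nuclear_count: np.ndarray
    cyto_fraction: np.ndarray
    kymograph: np.ndarray
    absorption_times: np.ndarray
    config: TranslocationConfig


def _draw_step(mode: np.ndarray, config: TranslocationConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Displacement for each particle given its mode (vectorized)."""
    n = mode.size
    dx = np.zeros(n)
    diff = mode == 0
    trans = mode == 2
    if diff.any():
        dx[diff] = rng.normal(0.0, np.sqrt(2.0 * config.D * config.dt), diff.sum())
    if trans.any():
        v = config.dynein_velocity * config.dt
        mag = rng.normal(v, v / 2.0, trans.sum())
        dx[trans] = -np.clip(mag, 0.0, None)  # unidirectional, toward the nucleus
    return dx


def step_particle(x: float, t: float, config: TranslocationConfig,
                  rng: np.random.Generator):
    """Advance one particle by one time step.

    Returns the new position, or :data:`ABSORBED` if the particle crossed
    the nuclear envelope and the permeability draw admitted it.
    """
    if not (0.0 <= x <= config.length):
        raise ValueError(f"position {x} outside [0, {config.length}]")
    mode = rng.choice(3, p=config.mode_probs)
    dx = _draw_step(np.array([mode]), config, rng)[0]
    new = x + dx
    if new > config.length:
        new = 2.0 * config.length - new
        new = min(new, config.length)
    if new <= 0.0:
        if rng.random() < config.permeability_at(t):
            return ABSORBED
        new = min(abs(new), config.length)
    return new


def run_translocation(config: TranslocationConfig) -> TranslocationResult:
    """Run the full population simulation.

    Particles start uniform on [0, L] and are stepped for t_max/dt steps;
    per-step positions, cumulative nuclear uptake, the cytoplasmic fraction
    and a binned position kymograph are recorded.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_particles
    n_steps = int(round(config.t_max / config.dt))
    x = rng.uniform(0.0, config.length, n)
    alive = np.ones(n, dtype=bool)
    absorption_times = np.full(n, np.nan)

    times = np.arange(n_steps + 1) * config.dt
    positions = np.full((n_steps + 1, n), np.nan)
    positions[0] = x
    nuclear_count = np.zeros(n_steps + 1, dtype=int)
    edges = np.linspace(0.0, config.length, config.kymo_bins + 1)
    kymo = np.zeros((config.kymo_bins, n_steps + 1))
    kymo[:, 0], _ = np.histogram(x, bins=edges)

    for i in range(1, n_steps + 1):
        t = times[i]
        idx = np.flatnonzero(alive)
        if idx.size:
            mode = rng.choice(3, size=idx.size, p=config.mode_probs)
            dx = _draw_step(mode, config, rng)
            new = x[idx] + dx
            # membrane reflection
            over = new > config.length
            new[over] = np.minimum(2.0 * config.length - new[over], config.length)
            # nuclear envelope: absorb with probability p(t), else reflect
            at_env = new <= 0.0
            if at_env.any():
                admit = rng.random(at_env.sum()) < config.permeability_at(t)
                env_idx = idx[at_env]
                absorbed = env_idx[admit]
                alive[absorbed] = False
                absorption_times[absorbed] = t
                reflected = np.abs(new[at_env][~admit])
                new[at_env] = 0.0
                x[env_idx[~admit]] = np.minimum(reflected, config.length)
                keep = idx[~at_env]
                x[keep] = new[~at_env]
            else:
                x[idx] = new
        positions[i, alive] = x[alive]
        nuclear_count[i] = n - alive.sum()
        kymo[:, i], _ = np.histogram(x[alive], bins=edges)

    cyto_fraction = 1.0 - nuclear_count / n
    return TranslocationResult(times=times, positions=positions,
                               nuclear_count=nuclear_count,
                               cyto_fraction=cyto_fraction, kymograph=kymo,
                               absorption_times=absorption_times, config=config)


def concavity_metric(cyto_fraction: np.ndarray, times: np.ndarray | None = None) -> float:
    """Early/late depletion-slope ratio of a cytoplasmic-fraction series.

    The depletion interval is the full recorded series. The metric is the
    mean depletion rate over its first quartile divided by the mean rate
    over its last quartile; > 1 means early-rapid (convex, constant
    permeability phenotype), < 1 means delayed depletion (linearly
    increasing permeability phenotype). Requires at least 10 samples and at
    least 20% total depletion.
    """
    y = np.asarray(cyto_fraction, dtype=float)
    if y.size < 10:
        raise ValueError("series too short (need >= 10 samples)")
    total = y[0] - y[-1]
    if total < 0.2 * y[0]:
        raise ValueError("insufficient depletion (< 20%) for a concavity estimate")
    if times is None:
        times = np.arange(y.size, dtype=float)
    q = y.size // 4
    early = (y[0] - y[q]) / (times[q] - times[0])
    late = (y[-1 - q] - y[-1]) / (times[-1] - times[-1 - q])
    if late <= 0:
        return np.inf if early > 0 else 1.0
    return float(early / late)
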