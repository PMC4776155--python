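"""Pixel-shift Pearson colocalization and kymograph extraction.

The shifted-Pearson analysis quantifies colocalization of two channels by
computing Pearson's r between one channel and the other displaced by a few
pixels; a channel against itself peaks at r_p = 1 at zero shift, while two
unrelated structures stay near zero for every shift. The kymograph turns a
time-lapse stack into a position-versus-time intensity matrix along a path
(e.g. nucleus edge to cell edge).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr

from micskit.stack_io import ImageStack

__all__ = ["ShiftCorrelation", "Kymograph", "pearson_shift", "extract_kymograph"]


@dataclasses.dataclass
class ShiftCorrelation:
    """Pearson r over a grid of (x, y) pixel shifts.

    ``r_grid[iy, ix]`` is r_p with channel G displaced by
    (``shifts_x[ix]``, ``shifts_y[iy]``) relative to channel R, computed
    over the overlapping pixels only. ``r_x``/``r_y`` are the axis profiles
    at zero shift of the other axis. NaN marks undefined values
    (zero-variance overlap).
    """

    r_grid: np.ndarray
    shifts_x: np.ndarray
    shifts_y: np.ndarray
    channels: tuple[str, str] = ("R", "G")

    @property
    def r_x(self) -> np.ndarray:
        iy0 = int(np.where(self.shifts_y == 0)[0][0])
        return self.r_grid[iy0, :]

    @property
    def r_y(self) -> np.ndarray:
        ix0 = int(np.where(self.shifts_x == 0)[0][0])
        return self.r_grid[:, ix0]


@dataclasses.dataclass
class Kymograph:
    """Intensity over (position along path, time): one column per frame."""

    matrix: np.ndarray
    path: np.ndarray
    spacing: float  # µm between consecutive samples


def _overlap(a: np.ndarray, b: np.ndarray, dx: int, dy: int):
    """Paired pixels of a and b with b shifted by (dx, dy); overlap only."""
    h, w = a.shape
    ax0, ax1 = max(0, -dx), min(w, w - dx)
    ay0, ay1 = max(0, -dy), min(h, h - dy)
    sub_a = a[ay0:ay1, ax0:ax1]
    sub_b = b[ay0 + dy:ay1 + dy, ax0 + dx:ax1 + dx]
    return sub_a.ravel(), sub_b.ravel()


def pearson_shift(chan_r: np.ndarray, chan_g: np.ndarray,
                  shifts: range | np.ndarray = range(-4, 5),
                  channels: tuple[str, str] = ("R", "G")) -> ShiftCorrelation:
    """Pearson correlation of two channels over a grid of pixel shifts.

    For each shift (dx, dy) in ``shifts`` × ``shifts``, Pearson's r is
    computed over the pixels where the shifted images overlap (shifted-out
    pixels are excluded, not zero-padded, so r is unbiased by padding).
    Overlaps with zero variance in either channel yield NaN.
    """
    chan_r = np.asarray(chan_r, dtype=np.float64)
    chan_g = np.asarray(chan_g, dtype=np.float64)
    if chan_r.shape != chan_g.shape:
        raise ValueError("channels must have equal shapes")
    shifts = np.asarray(list(shifts), dtype=int)
    grid = np.full((shifts.size, shifts.size), np.nan)
    for iy, dy in enumerate(shifts):
        for ix, dx in enumerate(shifts):
            va, vb = _overlap(chan_r, chan_g, int(dx), int(dy))
            if va.size < 2 or va.std() == 0 or vb.std() == 0:
                continue
            if np.array_equal(va, vb):  # identical data: r = 1 by definition
                grid[iy, ix] = 1.0
            else:
                grid[iy, ix] = float(np.clip(pearsonr(va, vb).statistic, -1.0, 1.0))
    return ShiftCorrelation(r_grid=grid, shifts_x=shifts, shifts_y=shifts,
                            channels=channels)


def extract_kymograph(stack: ImageStack, path: np.ndarray,
                      n_samples: int) -> Kymograph:
    """Sample intensity along a polyline for every frame.

    ``path`` is an (n_vertices, 2) array of (row, col) pixel coordinates.
    Each frame is sampled by bilinear interpolation at ``n_samples`` points
    equally spaced in arc length from the first vertex to the last; columns
    of the returned matrix are frames.
    """
    path = np.asarray(path, dtype=np.float64)
    if path.ndim != 2 or path.shape[1] != 2 or path.shape[0] < 2:
        raise ValueError("path must be an (n_vertices >= 2, 2) array of (row, col)")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    h, w = stack.height, stack.width
    if (path[:, 0].min() < 0 or path[:, 0].max() > h - 1
            or path[:, 1].min() < 0 or path[:, 1].max() > w - 1):
        raise ValueError("path exits frame bounds")

    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.linspace(0.0, arclen[-1], n_samples)
    rows = np.interp(targets, arclen, path[:, 0])
    cols = np.interp(targets, arclen, path[:, 1])

    matrix = np.empty((n_samples, stack.n_frames))
    for t in range(stack.n_frames):
        matrix[:, t] = map_coordinates(stack.frames[t], [rows, cols],
                                       order=1, mode="nearest")
    spacing = (arclen[-1] / (n_samples - 1)) * stack.meta.pixel_size
    return Kymograph(matrix=matrix, path=path, spacing=spacing)
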