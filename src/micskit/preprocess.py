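"""Photobleaching correction and immobile-structure removal.

Correlation analyses operate on intensity *fluctuations*. Two static
contaminations must be removed first: a slow global intensity decay from
photobleaching, and the immobile structure of the cell itself. For mICS the
pipeline is bleach correction followed by subtraction of the time-averaged
image; for RICS a 10-frame moving-average subtraction removes slow motion
(e.g. cell movement) while keeping the microsecond/millisecond fluctuations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from micskit.stack_io import AcquisitionMeta, ImageStack

__all__ = [
    "FluctuationStack",
    "bleach_correct",
    "remove_time_average",
    "moving_average_highpass",
]


@dataclasses.dataclass
class FluctuationStack:
    """Zero-time-mean intensity fluctuations δI(x, y, t).

    ``deltas`` has the same (time, row, col) shape as the source stack;
    ``mean_intensity`` is the per-frame spatial mean f(t_i) of the *source*
    frames, kept for correlation normalization.
    """

    deltas: np.ndarray
    source_meta: AcquisitionMeta
    mean_intensity: np.ndarray
    time_average: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.deltas.shape[0]


def bleach_correct(stack: ImageStack) -> ImageStack:
    """Correct a time-lapse stack for photobleaching (Ries-style rule).

    Each frame is rescaled so that both the spatial mean and the spatial
    variance of the image stay at their initial values::

        I'(x, y, t) = I(x, y, t) / sqrt(f(t)/f(0)) + f(0) * (1 - sqrt(f(t)/f(0)))

    where f(t) is the spatial mean of frame t. The 1/sqrt scaling restores
    the variance of shot-noise-limited signal; the additive term restores
    the mean exactly.
    """
    f = stack.frame_means()
    if np.any(f <= 0):
        raise ValueError("bleach_correct requires strictly positive frame means")
    ratio = np.sqrt(f / f[0])
    corrected = stack.frames / ratio[:, None, None] + (f[0] * (1.0 - ratio))[:, None, None]
    # Tiny negative excursions can appear in dark pixels after the additive
    # shift when the stack brightens; clip to keep the non-negativity contract.
    corrected = np.clip(corrected, 0.0, None)
    return ImageStack(frames=corrected, meta=stack.meta, channel_label=stack.channel_label)


def remove_time_average(stack: ImageStack) -> FluctuationStack:
    """Subtract the time-averaged image to remove the immobile fraction.

    Output deltas have zero per-pixel time mean; only moving or fluctuating
    emitters contribute to subsequent correlations.
    """
    mean_img = stack.frames.mean(axis=0)
    deltas = stack.frames - mean_img[None, :, :]
    return FluctuationStack(
        deltas=deltas,
        source_meta=stack.meta,
        mean_intensity=stack.frame_means(),
        time_average=mean_img,
    )


def moving_average_highpass(stack: ImageStack, window: int = 10) -> FluctuationStack:
    """Subtract a centered per-pixel moving average (temporal high-pass).

    Removes slow intensity drift such as whole-cell movement while keeping
    frame-to-frame fluctuations. An even ``window`` is widened to the next
    odd span so the average is exactly centered (a centered average of a
    linear ramp reproduces the ramp at interior frames); at the stack edges
    the averaging window shrinks symmetrically.
    """
    T = stack.n_frames
    if T <= window:
        raise ValueError(f"stack length {T} must exceed moving-average window {window}")
    half = window // 2
    csum = np.cumsum(stack.frames, axis=0, dtype=np.float64)
    csum = np.concatenate([np.zeros((1,) + csum.shape[1:]), csum], axis=0)
    deltas = np.empty_like(stack.frames, dtype=np.float64)
    for t in range(T):
        # symmetric shrink: use the largest centered half-width that fits
        h = min(half, t, T - 1 - t)
        lo, hi = t - h, t + h + 1
        local_mean = (csum[hi] - csum[lo]) / (hi - lo)
        deltas[t] = stack.frames[t] - local_mean
    return FluctuationStack(
        deltas=deltas,
        source_meta=stack.meta,
        mean_intensity=stack.frame_means(),
    )
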