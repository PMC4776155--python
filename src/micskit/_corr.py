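"""Non-periodic (zero-padded) FFT correlation primitives.

Frames here are small (32–256 px), so circular wrap bias from plain FFT
correlation would be material; all correlations are computed with zero
padding and normalized by the per-shift count of in-bounds pixel pairs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pair_counts", "cross_corr_sum", "padded_fft", "corr_from_ffts"]


def pair_counts(height: int, width: int, max_row_shift: int, max_col_shift: int) -> np.ndarray:
    """Number of in-bounds pixel pairs at each shift (ψ, ξ).

    Returns an array of shape (2*max_row_shift+1, 2*max_col_shift+1) with
    entry (ψ, ξ) = (height - |ψ|) * (width - |ξ|).
    """
    psi = np.arange(-max_row_shift, max_row_shift + 1)
    xi = np.arange(-max_col_shift, max_col_shift + 1)
    return np.outer(height - np.abs(psi), width - np.abs(xi)).astype(np.float64)


def _fft_shape(height: int, width: int, max_row_shift: int, max_col_shift: int) -> tuple[int, int]:
    from scipy.fft import next_fast_len

    return (next_fast_len(height + max_row_shift),
            next_fast_len(width + max_col_shift))


def padded_fft(frame: np.ndarray, max_row_shift: int, max_col_shift: int) -> np.ndarray:
    """2D FFT of a zero-padded frame, sized so shifts up to max do not wrap."""
    from scipy.fft import rfft2

    shape = _fft_shape(frame.shape[0], frame.shape[1], max_row_shift, max_col_shift)
    return rfft2(frame, s=shape)


def corr_from_ffts(fa: np.ndarray, fb: np.ndarray, frame_shape: tuple[int, int],
                   max_row_shift: int, max_col_shift: int) -> np.ndarray:
    """Cross-correlation sums S(ψ, ξ) = Σ_{x,y} A(y, x) · B(y+ψ, x+ξ).

    ``fa``/``fb`` are padded FFTs from :func:`padded_fft` of frames A and B.
    Returns the (2*max_row_shift+1, 2*max_col_shift+1) array of raw pair
    sums, centered at shift (0, 0).
    """
    from scipy.fft import irfft2

    shape = _fft_shape(frame_shape[0], frame_shape[1], max_row_shift, max_col_shift)
    full = irfft2(np.conj(fa) * fb, s=shape)
    # index δ for δ >= 0, index P+δ for δ < 0
    rows = np.arange(-max_row_shift, max_row_shift + 1) % shape[0]
    cols = np.arange(-max_col_shift, max_col_shift + 1) % shape[1]
    return full[np.ix_(rows, cols)]


def cross_corr_sum(a: np.ndarray, b: np.ndarray,
                   max_row_shift: int, max_col_shift: int) -> np.ndarray:
    """Zero-padded cross-correlation sums between two equal-shape frames."""
    if a.shape != b.shape:
        raise ValueError("frames must have equal shapes")
    fa = padded_fft(a, max_row_shift, max_col_shift)
    fb = padded_fft(b, max_row_shift, max_col_shift)
    return corr_from_ffts(fa, fb, a.shape, max_row_shift, max_col_shift)
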