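"""Preprocessing applied before any thresholding.

Two corrections, run in this order:

1. :func:`subtract_background` — a histogram-based background subtractor:
   the background at each pixel is the *mode* of the intensity histogram
   inside a square sliding window centred on the pixel (the window is
   clipped at the frame border), and is subtracted with clipping at zero.
2. :func:`correct_bleach` — photobleaching compensation: per-frame mean
   intensities are fit to a mono-exponential ``a * exp(-b * t)`` (least
   squares on log-means, ``t`` in frame indices) and every frame is scaled
   by ``fit(0) / fit(t)`` so the corrected means are flat in time.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import TimeLapse

__all__ = ["subtract_background", "correct_bleach", "fit_bleach", "windowed_mode"]

#: Quantization levels used when a frame has more distinct rounded
#: intensities than this (256 mirrors the 8-bit histogram convention).
MAX_HISTOGRAM_LEVELS = 256


def windowed_mode(frame: np.ndarray, window_radius: int) -> np.ndarray:
    """Per-pixel histogram mode within a clipped square sliding window.

    The frame is quantized to integers by rounding; when more than
    :data:`MAX_HISTOGRAM_LEVELS` distinct rounded values occur, the range
    is re-binned to that many equal-width levels (bin centres are
    reported).  Ties between equally frequent values resolve to the
    smallest value, which keeps the subtraction conservative.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    side = 2 * window_radius + 1
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    if side > max(h, w):
        raise ValueError(f"window side {side} larger than frame {frame.shape}")

    q = np.rint(frame)
    values = np.unique(q)
    if values.size > MAX_HISTOGRAM_LEVELS:
        lo, hi = frame.min(), frame.max()
        width = (hi - lo) / MAX_HISTOGRAM_LEVELS
        idx = np.clip(((frame - lo) / width).astype(np.int64), 0, MAX_HISTOGRAM_LEVELS - 1)
        values = lo + (np.arange(MAX_HISTOGRAM_LEVELS) + 0.5) * width
        q = values[idx]

    best_count = np.full(frame.shape, -1, dtype=np.int64)
    mode = np.zeros_like(frame)
    area = float(side * side)
    for v in values:  # increasing order; strict '>' gives smallest-value ties
        ind = (q == v).astype(np.float64)
        # uniform_filter with zero padding -> mean over the full window with
        # out-of-frame pixels contributing 0, i.e. an exact clipped-window
        # count after multiplying back by the window area.
        count = np.rint(ndimage.uniform_filter(ind, size=side, mode="constant", cval=0.0) * area).astype(np.int64)
        better = count > best_count
        mode[better] = v
        best_count[better] = count[better]
    return mode


def subtract_background(stack: TimeLapse, window_radius: int = 32) -> TimeLapse:
    """Subtract a per-pixel sliding-window histogram-mode background.

    Results are clipped at zero; frame count and dimensions are preserved.
    """
    corrected = np.empty_like(stack.frames)
    for t, frame in enumerate(stack.frames):
        corrected[t] = np.clip(frame - windowed_mode(frame, window_radius), 0.0, None)
    return stack.with_frames(corrected)


def fit_bleach(stack: TimeLapse) -> tuple[float, float]:
    """Fit ``mean_t = a * exp(-b * t)`` to the per-frame mean intensities.

    Returns ``(a, b)``; ``t`` counts frames from 0.  Least squares on the
    log-means, so all frame means must be positive.
    """
    means = stack.frames.mean(axis=(1, 2))
    if stack.n_frames < 3:
        raise ValueError("bleach fit needs at least 3 frames")
    if np.any(means <= 0):
        raise ValueError("bleach fit requires positive frame means")
    t = np.arange(stack.n_frames, dtype=np.float64)
    slope, intercept = np.polyfit(t, np.log(means), 1)
    return float(np.exp(intercept)), float(-slope)


def correct_bleach(stack: TimeLapse) -> TimeLapse:
    """Undo exponential photobleaching by rescaling each frame.

    Frame ``t`` is multiplied by ``exp(b * t)`` where ``b`` is the fitted
    decay rate, i.e. by the ratio of the fitted mean at ``t = 0`` to the
    fitted mean at ``t``.  On a noiseless exponential decay the corrected
    means are exactly constant and refitting returns ``b = 0``; the
    operation is therefore idempotent up to floating-point tolerance.

    A failed fit (non-finite parameters) leaves the stack unchanged with a
    warning rather than aborting an analysis run.
    """
    try:
        a, b = fit_bleach(stack)
    except ValueError:
        raise
    if not (np.isfinite(a) and np.isfinite(b)):
        warnings.warn("bleach fit did not converge; returning stack unchanged")
        return stack.with_frames(stack.frames.copy())
    t = np.arange(stack.n_frames, dtype=np.float64)
    scale = np.exp(b * t)
    return stack.with_frames(stack.frames * scale[:, None, None])
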