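"""Independent brute-force reference implementations used as test oracles.

Deliberately written as straightforward per-pixel loops, independent of
the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np


def windowed_mode_bruteforce(frame: np.ndarray, radius: int) -> np.ndarray:
    """Mode of rounded intensities in a border-clipped square window.

    Ties resolve to the smallest value (matching the implementation's
    documented tie rule).
    """
    frame = np.asarray(frame, dtype=np.float64)
    q = np.rint(frame)
    h, w = frame.shape
    out = np.zeros_like(frame)
    for y in range(h):
        for x in range(w):
            y0, y1 = max(0, y - radius), min(h, y + radius + 1)
            x0, x1 = max(0, x - radius), min(w, x + radius + 1)
            window = q[y0:y1, x0:x1].ravel()
            values, counts = np.unique(window, return_counts=True)
            out[y, x] = values[np.argmax(counts)]  # first max = smallest value
    return out


def otsu_scores(frame: np.ndarray, nbins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Between-class variance of every histogram split, by direct sums.

    Returns ``(scores, centers)`` where ``scores[i]`` is
    ``w0*w1*(mu0-mu1)^2`` for the split class0 = bins 0..i (``-1`` for
    degenerate splits) and ``centers`` the bin centres of an nbins
    histogram over the frame's min-max range.
    """
    frame = np.asarray(frame, dtype=np.float64).ravel()
    hist, edges = np.histogram(frame, bins=nbins, range=(frame.min(), frame.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    scores = np.full(nbins - 1, -1.0)
    for i in range(nbins - 1):
        w0 = hist[: i + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (hist[i + 1 :] * centers[i + 1 :]).sum() / w1
        scores[i] = w0 * w1 * (mu0 - mu1) ** 2
    return scores, centers


def otsu_exhaustive(frame: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold by exhaustive search (first maximum on ties)."""
    scores, centers = otsu_scores(frame, nbins)
    return float(centers[int(np.argmax(scores))])


def local_mean_mask_bruteforce(
    frame: np.ndarray, radius: int, strictly_greater: bool = True
) -> np.ndarray:
    """Pixel-vs-local-mean comparison with mirror padding, per-pixel loop."""
    frame = np.asarray(frame, dtype=np.float64)
    padded = np.pad(frame, radius, mode="reflect")
    h, w = frame.shape
    out = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            window = padded[y : y + 2 * radius + 1, x : x + 2 * radius + 1]
            mean = window.sum() / window.size
            out[y, x] = frame[y, x] > mean if strictly_greater else frame[y, x] >= mean
    return out


def _neighbors(mask: np.ndarray, y: int, x: int) -> int:
    h, w = mask.shape
    n = 0
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                n += 1
    return n


def count_dilate_once(mask: np.ndarray, count: int) -> np.ndarray:
    """One count-threshold dilation step; outside the frame is background."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if not mask[y, x] and _neighbors(mask, y, x) >= count:
                out[y, x] = True
    return out


def count_erode_once(mask: np.ndarray, count: int) -> np.ndarray:
    """One count-threshold erosion step; outside the frame is background."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x] and (8 - _neighbors(mask, y, x)) >= count:
                out[y, x] = False
    return out


def ellipse_axes_from_moments(mask: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths of the moment-equivalent ellipse.

    Second central moments of the pixel-coordinate distribution; the
    equivalent ellipse has axis lengths 4*sqrt(eigenvalue) of the
    (normalized-moment) covariance matrix.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    n = ys.size
    cy, cx = ys.mean(), xs.mean()
    mu20 = ((ys - cy) ** 2).sum() / n
    mu02 = ((xs - cx) ** 2).sum() / n
    mu11 = ((ys - cy) * (xs - cx)).sum() / n
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    return 4.0 * np.sqrt(lam1), 4.0 * np.sqrt(max(lam2, 0.0))
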