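"""Decomposition of inner-membrane motion into shell (IBM) and cristae (CM) parts.

The IMM-structure mask changes between consecutive frames for two reasons:
the whole organelle moves or changes shape (inner boundary membrane, IBM),
and the internal cristae texture rearranges (cristae membrane, CM).  The
pipeline separates the two:

1. :func:`shell_mask` closes and hole-fills the IMM-structure mask into a
   solid per-frame organelle shell.
2. :func:`frame_changes` takes the symmetric difference (XOR) of
   consecutive frames — for 0/255 mask arithmetic the absolute frame
   difference is exactly the XOR, capturing appearing and disappearing
   pixels alike.
3. :func:`decompose_cm` removes the shell changes from the overall
   structure changes, leaving the cristae-only changes.
4. :func:`kinetics_trace` normalizes the change areas by the Otsu
   (whole-mitochondria) area to a moving-area fraction per frame pair, and
   averages over the time-lapse.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import binmorph
from .core import BinaryStack, require_same_geometry

__all__ = [
    "MorphologyConfig",
    "Normalization",
    "KineticsTrace",
    "shell_mask",
    "frame_changes",
    "decompose_cm",
    "kinetics_trace",
]


@dataclass(frozen=True)
class MorphologyConfig:
    """Closing parameters for the shell construction (ImageJ semantics)."""

    close_iterations: int = 2
    close_count: int = 2
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.close_iterations < 0:
            raise ValueError("close_iterations must be >= 0")
        if not 1 <= self.close_count <= 8:
            raise ValueError("close_count must be in 1..8")


class Normalization(enum.Enum):
    """Which Otsu area normalizes the change count of a frame pair."""

    EARLIER_FRAME = "earlier"
    MEAN_OF_PAIR = "mean_of_pair"


@dataclass(frozen=True)
class KineticsTrace:
    """Per-frame-pair moving-area fractions and their time-lapse means.

    Fractions are in [0, 1]: change-pixel count divided by the Otsu
    mitochondrial area of the pair.  Pairs whose denominator was zero are
    recorded as NaN and excluded from the means.
    """

    cm_fraction_per_pair: np.ndarray
    ibm_fraction_per_pair: np.ndarray
    denominator_area_per_pair: np.ndarray
    pair_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        cm = np.asarray(self.cm_fraction_per_pair, dtype=np.float64)
        ibm = np.asarray(self.ibm_fraction_per_pair, dtype=np.float64)
        den = np.asarray(self.denominator_area_per_pair, dtype=np.float64)
        if not (cm.shape == ibm.shape == den.shape):
            raise ValueError("per-pair arrays must share length")
        idx = self.pair_indices
        idx = np.arange(cm.size) if idx is None else np.asarray(idx, dtype=np.int64)
        object.__setattr__(self, "cm_fraction_per_pair", cm)
        object.__setattr__(self, "ibm_fraction_per_pair", ibm)
        object.__setattr__(self, "denominator_area_per_pair", den)
        object.__setattr__(self, "pair_indices", idx)

    @property
    def n_pairs(self) -> int:
        return self.cm_fraction_per_pair.size

    @property
    def cm_mean(self) -> float:
        return float(np.nanmean(self.cm_fraction_per_pair)) if self._any_valid() else float("nan")

    @property
    def ibm_mean(self) -> float:
        return float(np.nanmean(self.ibm_fraction_per_pair)) if self._any_valid() else float("nan")

    def _any_valid(self) -> bool:
        return bool(np.any(~np.isnan(self.cm_fraction_per_pair)))


def shell_mask(imm: BinaryStack, config: MorphologyConfig = MorphologyConfig()) -> BinaryStack:
    """Close and hole-fill the IMM-structure mask into the organelle shell.

    Dilation repeated ``close_iterations`` times followed by the same
    number of erosions (count-threshold semantics, see
    :mod:`cristadyn.binmorph`), then flood-fill of enclosed background.
    The result approximates the inner boundary membrane outline: solid,
    with no enclosed holes.
    """
    masks = np.empty(imm.masks.shape, dtype=bool)
    for t, frame in enumerate(imm.masks):
        closed = binmorph.count_close(frame, config.close_iterations, config.close_count)
        masks[t] = binmorph.fill_holes(closed) if config.fill_holes else closed
    return BinaryStack(masks=masks, source=f"shell[{imm.source}]")


def frame_changes(masks: BinaryStack) -> BinaryStack:
    """Symmetric difference of consecutive frames (n-1 change masks)."""
    if masks.n_frames < 2:
        raise ValueError("frame_changes needs at least 2 frames")
    return BinaryStack(
        masks=masks.masks[1:] ^ masks.masks[:-1],
        source=f"changes[{masks.source}]",
    )


def decompose_cm(imm_changes: BinaryStack, ibm_changes: BinaryStack) -> BinaryStack:
    """Cristae-only changes: structure changes minus shell changes.

    Set difference per frame pair — never negative, disjoint from the
    shell changes, and together with ``imm_changes & ibm_changes`` it
    reconstructs ``imm_changes`` exactly.
    """
    require_same_geometry(imm_changes, ibm_changes, "change stacks")
    return BinaryStack(
        masks=imm_changes.masks & ~ibm_changes.masks,
        source=f"cm[{imm_changes.source} - {ibm_changes.source}]",
    )


def kinetics_trace(
    cm_changes: BinaryStack,
    ibm_changes: BinaryStack,
    otsu: BinaryStack,
    normalization: Normalization = Normalization.EARLIER_FRAME,
) -> KineticsTrace:
    """Normalize change areas to moving-area fractions per frame pair.

    For pair ``k`` (frames ``k`` and ``k+1``) the denominator is the Otsu
    mitochondrial pixel count of frame ``k`` (or the pair mean, per
    ``normalization``).  Pairs with a zero denominator are reported as NaN
    with a warning and excluded from the means.
    """
    require_same_geometry(cm_changes, ibm_changes, "change stacks")
    if otsu.n_frames != cm_changes.n_frames + 1:
        raise ValueError(
            f"otsu must have one more frame than the change stacks "
            f"({otsu.n_frames} vs {cm_changes.n_frames})"
        )
    areas = otsu.area_per_frame().astype(np.float64)
    if normalization is Normalization.EARLIER_FRAME:
        denom = areas[:-1]
    else:
        denom = 0.5 * (areas[:-1] + areas[1:])
    cm_counts = cm_changes.masks.sum(axis=(1, 2)).astype(np.float64)
    ibm_counts = ibm_changes.masks.sum(axis=(1, 2)).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        cm_frac = np.where(denom > 0, cm_counts / denom, np.nan)
        ibm_frac = np.where(denom > 0, ibm_counts / denom, np.nan)
    n_empty = int(np.sum(denom == 0))
    if n_empty:
        warnings.warn(f"{n_empty} frame pair(s) with empty Otsu mask excluded from means")
    return KineticsTrace(
        cm_fraction_per_pair=cm_frac,
        ibm_fraction_per_pair=ibm_frac,
        denominator_area_per_pair=denom,
    )
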