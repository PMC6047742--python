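"""Cristae kinetics as a function of ER–mitochondria contact-site proximity.

Contact sites (mitochondria-associated membranes, MAMs) are defined
operationally as the framewise overlap of the Otsu-thresholded ER and
mitochondria masks.  The overlap is then enlarged by stepwise
count-threshold dilation (default 5, 10 and 20 iterations, count = 3),
giving nested proximity bands of increasing reach; restricting both the
cristae-change masks and the normalization area to a band yields the
cristae kinetics at that distance from the ER.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import binmorph
from .core import BinaryStack, DualChannelSequence, require_same_geometry
from .kinetics import KineticsTrace, Normalization

__all__ = [
    "MamBandSet",
    "align_er_frames",
    "expand_er_stack",
    "mam_core",
    "dilate_bands",
    "band_kinetics",
    "within_block_pairs",
]

DEFAULT_BAND_LEVELS = (5, 10, 20)
DEFAULT_DILATION_COUNT = 3


@dataclass(frozen=True)
class MamBandSet:
    """MAM core mask plus nested dilation bands, per mitochondrial frame.

    ``bands[L]`` is the core dilated ``L`` times; nesting
    ``core ⊆ bands[L1] ⊆ bands[L2]`` for ``L1 < L2`` holds by
    construction because count-threshold dilation only adds pixels.
    """

    core: BinaryStack
    bands: Mapping[int, BinaryStack]
    dilation_count: int = DEFAULT_DILATION_COUNT

    def __post_init__(self) -> None:
        levels = self.levels
        if list(levels) != sorted(set(levels)) or any(l <= 0 for l in levels):
            raise ValueError("band levels must be strictly increasing positive integers")
        for level, stack in self.bands.items():
            require_same_geometry(self.core, stack, f"core and band({level})")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(self.bands.keys())

    def check_nesting(self) -> bool:
        """True iff core ⊆ band(L1) ⊆ band(L2) ⊆ ... on every frame."""
        prev = self.core.masks
        for level in self.levels:
            cur = self.bands[level].masks
            if not np.all(prev <= cur):
                return False
            prev = cur
        return True


def align_er_frames(seq: DualChannelSequence) -> np.ndarray:
    """Index of the ER frame annotating each MTG frame.

    The acquisition interleaves one ER frame before every block of
    ``mito_block_len`` MTG frames, so MTG frame ``k`` maps to ER frame
    ``k // mito_block_len`` — the most recent preceding ER exposure.  The
    mapping is total by the sequence invariant.
    """
    block = seq.pattern.mito_block_len
    idx = np.arange(seq.mito.n_frames) // block
    if idx[-1] >= seq.er.n_frames:
        raise ValueError("MTG frames extend beyond the last ER frame's block")
    return idx


def expand_er_stack(er_masks: BinaryStack, assignment: np.ndarray) -> BinaryStack:
    """Repeat each ER mask over the MTG frames assigned to it."""
    if assignment.min() < 0 or assignment.max() >= er_masks.n_frames:
        raise ValueError("assignment indexes outside the ER stack")
    return BinaryStack(masks=er_masks.masks[assignment], source=f"expanded[{er_masks.source}]")


def mam_core(er_mask: BinaryStack, mito_mask: BinaryStack) -> BinaryStack:
    """Framewise overlap of the thresholded ER and mitochondria masks."""
    require_same_geometry(er_mask, mito_mask, "ER and mito masks")
    return BinaryStack(masks=er_mask.masks & mito_mask.masks, source="mam_core")


def dilate_bands(
    core: BinaryStack,
    levels: Sequence[int] = DEFAULT_BAND_LEVELS,
    count: int = DEFAULT_DILATION_COUNT,
) -> MamBandSet:
    """Enlarge the MAM core by stepwise count-threshold dilation.

    ``band(L)`` is the core dilated ``L`` times (8-neighborhood, a
    background pixel joins when >= ``count`` neighbors are foreground).
    Dilation is resumed incrementally between levels, so larger levels
    strictly contain smaller ones.
    """
    levels = tuple(levels)
    if list(levels) != sorted(set(levels)) or any(l <= 0 for l in levels):
        raise ValueError("levels must be strictly increasing positive integers")
    bands: dict[int, BinaryStack] = {}
    current = core.masks
    done = 0
    for level in levels:
        step = level - done
        dilated = np.empty_like(current)
        for t, frame in enumerate(current):
            dilated[t] = binmorph.count_dilate(frame, iterations=step, count=count)
        current = dilated
        done = level
        bands[level] = BinaryStack(masks=current, source=f"mam_band({level})")
    return MamBandSet(core=core, bands=bands, dilation_count=count)


def within_block_pairs(n_mito_frames: int, mito_block_len: int) -> np.ndarray:
    """Frame-pair indices (k, k+1) that do not straddle an ER block boundary.

    Pairs across blocks would mix frames annotated by different ER
    exposures and are excluded from band kinetics.
    """
    k = np.arange(n_mito_frames - 1)
    return k[(k // mito_block_len) == ((k + 1) // mito_block_len)]


def band_kinetics(
    cm_changes: BinaryStack,
    ibm_changes: BinaryStack,
    otsu_mito: BinaryStack,
    bands: MamBandSet,
    pair_indices: np.ndarray | None = None,
    normalization: Normalization = Normalization.EARLIER_FRAME,
) -> dict[int, KineticsTrace]:
    """Cristae kinetics restricted to each proximity band.

    For band level ``L`` and frame pair ``k``::

        fraction = |cm_changes_k ∩ band_L(k)| / |otsu_k ∩ band_L(k)|

    with the band and Otsu mask taken from the earlier frame of the pair
    (or averaged over the pair, per ``normalization``).  Pairs with an
    empty in-band Otsu area are NaN and excluded from the level mean; a
    level empty at all pairs is reported with every pair NaN.
    """
    require_same_geometry(cm_changes, ibm_changes, "change stacks")
    if otsu_mito.n_frames != cm_changes.n_frames + 1:
        raise ValueError("otsu_mito must have one more frame than the change stacks")
    if pair_indices is None:
        pair_indices = np.arange(cm_changes.n_frames)
    pair_indices = np.asarray(pair_indices, dtype=np.int64)

    out: dict[int, KineticsTrace] = {}
    for level in bands.levels:
        band = bands.bands[level].masks
        cm_frac = np.full(pair_indices.size, np.nan)
        ibm_frac = np.full(pair_indices.size, np.nan)
        denom = np.zeros(pair_indices.size)
        for i, k in enumerate(pair_indices):
            area_k = float(np.sum(otsu_mito.masks[k] & band[k]))
            if normalization is Normalization.MEAN_OF_PAIR:
                area_next = float(np.sum(otsu_mito.masks[k + 1] & band[k + 1]))
                area_k = 0.5 * (area_k + area_next)
            denom[i] = area_k
            if area_k > 0:
                cm_frac[i] = np.sum(cm_changes.masks[k] & band[k]) / area_k
                ibm_frac[i] = np.sum(ibm_changes.masks[k] & band[k]) / area_k
        if np.all(np.isnan(cm_frac)):
            warnings.warn(f"band({level}): empty at all frame pairs; level undefined")
        out[level] = KineticsTrace(
            cm_fraction_per_pair=cm_frac,
            ibm_fraction_per_pair=ibm_frac,
            denominator_area_per_pair=denom,
            pair_indices=pair_indices,
        )
    return out
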