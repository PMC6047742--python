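"""Core data containers for SIM time-lapse analysis.

A :class:`TimeLapse` wraps an ordered stack of 2-D intensity frames with
acquisition metadata (frame interval, pixel size, channel).  A
:class:`BinaryStack` holds per-frame boolean masks aligned to a time-lapse.
A :class:`DualChannelSequence` pairs an interleaved ER-marker acquisition
with the mitochondrial (MitoTracker Green, MTG) frames it annotates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "Channel",
    "TimeLapse",
    "BinaryStack",
    "AcquisitionPattern",
    "DualChannelSequence",
]


class Channel(enum.Enum):
    """Fluorescence channel role."""

    MITO = "mito"
    ER = "er"


def _as_frame_array(frames: object) -> np.ndarray:
    arr = np.asarray(frames, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"frames must form a (t, y, x) stack, got ndim={arr.ndim}")
    if arr.shape[0] < 1:
        raise ValueError("a time-lapse needs at least one frame")
    if not np.all(np.isfinite(arr)):
        raise ValueError("frame intensities must be finite")
    if arr.min() < 0:
        raise ValueError("frame intensities must be non-negative")
    return arr


@dataclass(frozen=True)
class TimeLapse:
    """Ordered stack of 2-D non-negative intensity frames.

    Parameters
    ----------
    frames
        Array-like of shape ``(t, y, x)`` (a single 2-D frame is promoted
        to a 1-frame stack).  Stored as float64 regardless of source bit
        depth.
    frame_interval_s
        Time between consecutive frames in seconds (1.0 for 1 Hz
        acquisitions).
    pixel_size_nm
        Physical pixel size in nanometres, if known.
    channel
        Which marker the stack records.
    """

    frames: np.ndarray
    frame_interval_s: float = 1.0
    pixel_size_nm: float | None = None
    channel: Channel = Channel.MITO

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", _as_frame_array(self.frames))
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def with_frames(self, frames: np.ndarray) -> "TimeLapse":
        """Return a copy carrying the same metadata but new frame data."""
        return replace(self, frames=frames)


@dataclass(frozen=True)
class BinaryStack:
    """Per-frame boolean masks aligned to a :class:`TimeLapse`.

    ``source`` is a free-form provenance tag recording which operation
    produced the masks (e.g. ``"otsu"``, ``"local_mean(r=2)"``).
    """

    masks: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.masks)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise ValueError(f"masks must form a (t, y, x) stack, got ndim={arr.ndim}")
        object.__setattr__(self, "masks", arr.astype(bool))

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.masks)

    def area_per_frame(self) -> np.ndarray:
        """Foreground pixel count of every frame."""
        return self.masks.sum(axis=(1, 2))

    def matches(self, other: "BinaryStack | TimeLapse") -> bool:
        return (
            self.n_frames == other.n_frames and self.frame_shape == other.frame_shape
        )


@dataclass(frozen=True)
class AcquisitionPattern:
    """Interleaving descriptor for dual-channel runs.

    The reference acquisition records, at 1 Hz, blocks of one ER frame
    followed by ``mito_block_len`` MTG frames, repeated ``repeats`` times.
    """

    er_block_len: int = 1
    mito_block_len: int = 10
    repeats: int = 3

    def __post_init__(self) -> None:
        if self.er_block_len != 1:
            raise ValueError("only single-ER-frame blocks are supported")
        if self.mito_block_len < 1 or self.repeats < 1:
            raise ValueError("block length and repeats must be >= 1")


@dataclass(frozen=True)
class DualChannelSequence:
    """Interleaved ER + mitochondria acquisition.

    Every MTG frame must be attributable to the most recent preceding ER
    frame; the pattern requires ``er.n_frames * mito_block_len >=
    mito.n_frames`` so that the block mapping is total.
    """

    er: TimeLapse
    mito: TimeLapse
    pattern: AcquisitionPattern = field(default_factory=AcquisitionPattern)

    def __post_init__(self) -> None:
        if self.er.channel is not Channel.ER:
            raise ValueError("er stack must carry channel=Channel.ER")
        if self.mito.channel is not Channel.MITO:
            raise ValueError("mito stack must carry channel=Channel.MITO")
        if self.er.frame_shape != self.mito.frame_shape:
            raise ValueError("ER and mito frames must share dimensions")
        if self.er.n_frames * self.pattern.mito_block_len < self.mito.n_frames:
            raise ValueError(
                "too few ER frames: every MTG frame needs a preceding ER frame "
                f"({self.er.n_frames} ER x block {self.pattern.mito_block_len} "
                f"< {self.mito.n_frames} MTG)"
            )


def require_same_geometry(a: BinaryStack, b: BinaryStack, what: str = "stacks") -> None:
    """Raise ``ValueError`` unless two binary stacks are frame-aligned."""
    if a.n_frames != b.n_frames or a.frame_shape != b.frame_shape:
        raise ValueError(
            f"{what} must share frame count and dimensions: "
            f"{a.n_frames}x{a.frame_shape} vs {b.n_frames}x{b.frame_shape}"
        )
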