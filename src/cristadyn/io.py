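"""TIFF / OME-TIFF reading and writing for time-lapses and masks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .core import BinaryStack, Channel, TimeLapse

__all__ = ["load_timelapse", "save_timelapse", "save_binary_stack", "load_binary_stack"]


def load_timelapse(
    path: str | Path,
    channel: Channel = Channel.MITO,
    frame_interval_s: float = 1.0,
    pixel_size_nm: float | None = None,
) -> TimeLapse:
    """Read a single- or multi-page grayscale TIFF as a :class:`TimeLapse`.

    Pages are taken in storage order.  Pixel size and frame interval are
    read from ImageJ/OME metadata when present, otherwise the provided
    defaults are used.

    Raises
    ------
    ValueError
        If the file has no pages, pages of differing size, or non-2-D pages.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        if not pages:
            raise ValueError(f"{path}: TIFF contains no pages")
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"{path}: TIFF pages differ in size: {sorted(shapes)}")
        if pages[0].ndim != 2:
            raise ValueError(f"{path}: expected 2-D grayscale pages, got {pages[0].shape}")
        meta = tif.imagej_metadata or {}
        if "finterval" in meta:
            frame_interval_s = float(meta["finterval"])
        # ImageJ stores pixel size via x-resolution (pixels per unit)
        try:
            res = tif.pages[0].tags["XResolution"].value
            unit = meta.get("unit", "")
            if unit in ("micron", "um", "µm") and res[0]:
                pixel_size_nm = 1000.0 * res[1] / res[0]
        except (KeyError, ZeroDivisionError):
            pass
    frames = np.stack(pages).astype(np.float64)
    return TimeLapse(
        frames=frames,
        frame_interval_s=frame_interval_s,
        pixel_size_nm=pixel_size_nm,
        channel=channel,
    )


def save_timelapse(stack: TimeLapse, path: str | Path) -> None:
    """Write a time-lapse as a multi-page 32-bit float TIFF.

    Frame interval and pixel size are stored as ImageJ-style metadata so
    that a round trip through :func:`load_timelapse` preserves them.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta: dict = {"finterval": stack.frame_interval_s, "axes": "TYX"}
    kwargs: dict = {"imagej": True, "metadata": meta}
    if stack.pixel_size_nm is not None:
        px_um = stack.pixel_size_nm / 1000.0
        kwargs["resolution"] = (1.0 / px_um, 1.0 / px_um)
        meta["unit"] = "um"
    tifffile.imwrite(path, stack.frames.astype(np.float32), **kwargs)


def save_binary_stack(stack: BinaryStack, path: str | Path) -> None:
    """Write masks as an 8-bit TIFF stack with foreground = 255."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (stack.masks.astype(np.uint8) * 255), imagej=True)


def load_binary_stack(path: str | Path, source: str = "") -> BinaryStack:
    """Read an 8-bit 0/255 mask TIFF back into a :class:`BinaryStack`."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return BinaryStack(masks=arr > 0, source=source or str(path))
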