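"""Synthetic two-channel SIM-like scenes with ground-truth motion.

The generator renders elongated mitochondria with an internal periodic
striation texture (emulating cristae at the ~120-130 nm resolution of a
reconstructed SIM acquisition) plus a branched ER tubule network in a
second channel, and records the ground truth needed to verify every
pipeline stage:

* **Texture motion** — the striation phase field is tiled into small
  rectangular cells (one stripe period wide); between consecutive frames
  each cell flips its phase (bright and dark stripes swap) with a
  probability scaled so the expected fraction of shell pixels changing
  class per frame pair equals ``texture_motion_fraction`` exactly.
  Striations occupy the organelle interior; the outermost ~3-px rim
  renders uniformly bright (the membrane-dense inner-boundary zone), so
  texture motion never perturbs the organelle outline.  The stripe field
  lives in the *laboratory* frame, which makes texture motion
  controllable independently of shell motion.
* **Shell motion** — whole organelles drift rigidly by
  ``shell_drift_px_per_frame`` (rounded to integer offsets per frame)
  while the lab-frame texture stays put, so a drifting scene changes the
  shell outline without any internal texture change.
* **ER proximity** — cells whose centre lies within ``mam_radius_px`` of
  the ER network flip at ``mam_slowdown`` times the base probability,
  emulating contact-site-dependent deceleration of cristae dynamics.
* **Photobleaching and noise** — the fluorescent signal decays as
  ``exp(-bleach_rate * t)`` (the camera background offset does not) and
  additive Gaussian read noise is applied last; truth is recorded before
  noise.

The dual-channel acquisition interleaves one ER frame before every block
of ``mito_block_len`` mitochondrial frames (the 3 x (1 ER + 10 MTG) @ 1 Hz
pattern); single-channel analyses simply ignore the ER stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AcquisitionPattern, BinaryStack, Channel, DualChannelSequence, TimeLapse

__all__ = ["SceneConfig", "SceneTruth", "SimulatedScene", "generate_scene"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene; all lengths in pixels.

    Defaults follow the reference acquisition (30 frames at 1 Hz,
    512-px reconstructed SIM field).  At 62 nm pixels the 0.85-px blur
    gives the ~2-px (~125 nm) FWHM of the reconstruction and the 4-px
    stripe period a ~250 nm cristae spacing, the scale the instrument
    resolves; ``mam_radius_px`` = 4 px (~250 nm) is the reach of the
    contact-site Ca2+ microdomain that decelerates cristae motion.
    ``n_mitochondria`` scales with the field (a 256-px scene holds ~5
    organelles at a realistic ~15-20% area fill).
    """

    frame_count: int = 30
    size: int = 512
    n_mitochondria: int = 12
    stripe_period_px: int = 4
    texture_motion_fraction: float = 0.07
    shell_drift_px_per_frame: float = 0.0
    er_fraction: float = 0.025
    mam_slowdown: float = 1.0
    mam_radius_px: float = 4.0
    bleach_rate: float = 0.01
    noise_sigma: float = 1.0
    background_offset: float = 10.0
    base_intensity: float = 100.0
    stripe_contrast: float = 100.0
    er_intensity: float = 150.0
    blur_sigma_px: float = 0.85
    cell_height_px: int = 6
    mito_block_len: int = 10
    pixel_size_nm: float = 62.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 1 or self.size < 32:
            raise ValueError("need frame_count >= 1 and size >= 32")
        if not 0 <= self.texture_motion_fraction <= 1:
            raise ValueError("texture_motion_fraction must be in [0, 1]")
        if not 0 <= self.mam_slowdown <= 1:
            raise ValueError("mam_slowdown must be in [0, 1]")
        if not 0 <= self.er_fraction < 1:
            raise ValueError("er_fraction must be in [0, 1)")
        if self.stripe_period_px < 2 or self.stripe_period_px % 2:
            raise ValueError("stripe_period_px must be an even integer >= 2")
        if self.n_mitochondria < 1 or self.size / self.n_mitochondria < 24:
            raise ValueError("n_mitochondria too large for the field size")


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth recorded before noise was applied."""

    shell_masks: BinaryStack
    texture_change_masks: BinaryStack  # one per consecutive mito frame pair
    true_cm_fraction: np.ndarray  # per pair: |change| / |shell of earlier frame|
    er_mask: np.ndarray  # static ER tubule network
    mam_core_truth: BinaryStack  # ER network ∩ shell, per mito frame
    slow_region: np.ndarray  # pixels within mam_radius_px of the ER network


@dataclass(frozen=True)
class SimulatedScene:
    mito: TimeLapse
    er: TimeLapse
    truth: SceneTruth
    config: SceneConfig

    def as_dual_channel(self) -> DualChannelSequence:
        pattern = AcquisitionPattern(
            mito_block_len=self.config.mito_block_len,
            repeats=self.er.n_frames,
        )
        return DualChannelSequence(er=self.er, mito=self.mito, pattern=pattern)


def _capsule_mask(size: int, cx: float, cy: float, length: float, width: float) -> np.ndarray:
    """Horizontal capsule (rounded-end rod) rasterized on the pixel grid."""
    y, x = np.mgrid[0:size, 0:size]
    dx = np.maximum(np.abs(x - cx) - length / 2.0, 0.0)
    dy = y - cy
    return dx * dx + dy * dy <= (width / 2.0) ** 2


def _er_network(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Branched tubule network: persistent random-walk strands, 3 px wide."""
    size = config.size
    mask = np.zeros((size, size), dtype=bool)
    target = config.er_fraction * size * size
    if target <= 0:
        return mask
    n_steps = int(size * 1.8)
    for _ in range(200):
        if mask.sum() >= target:
            break
        pos = rng.uniform(0, size, 2)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.25)
            pos = pos + np.array([np.cos(angle), np.sin(angle)])
            iy, ix = int(round(pos[1])) % size, int(round(pos[0])) % size
            mask[iy, ix] = True
    # dilate the 1-px skeleton to ~3-px tubule width
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def generate_scene(config: SceneConfig) -> SimulatedScene:
    """Render a seeded scene and its ground truth.

    Identical configs (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    size, T = config.size, config.frame_count
    half = config.stripe_period_px // 2
    cell_w = config.stripe_period_px
    cell_h = config.cell_height_px

    # --- geometry: horizontal capsules in evenly spaced strips ------------
    # Drift is along the long axis (coherent, stage-drift-like): the long
    # straight rims then translate along themselves, so a pure-drift scene
    # changes the lab-frame image only at the capsule end caps and the
    # shell outline, not in the striated interior.
    strip = size / config.n_mitochondria
    total_drift = config.shell_drift_px_per_frame * (T - 1)
    geoms = []
    for i in range(config.n_mitochondria):
        length = rng.uniform(0.4, 0.55) * size
        width = rng.uniform(18.0, 24.0)
        cx = rng.uniform(0.3, 0.7) * size - total_drift / 2.0
        cy = (i + 0.5) * strip + rng.uniform(-0.1, 0.1) * strip
        geoms.append((cx, cy, length, width))

    offsets = np.rint(config.shell_drift_px_per_frame * np.arange(T)).astype(int)
    shells = np.zeros((T, size, size), dtype=bool)
    for t in range(T):
        for cx, cy, length, width in geoms:
            shells[t] |= _capsule_mask(size, cx + offsets[t], cy, length, width)

    # --- ER network and the contact-site slow region ----------------------
    er_mask = _er_network(config, rng)
    if er_mask.any():
        dist = ndimage.distance_transform_edt(~er_mask)
        slow_region = dist <= config.mam_radius_px
    else:
        slow_region = np.zeros((size, size), dtype=bool)

    # --- lab-frame stripe field and per-cell phase-flip states ------------
    xs = np.arange(size)
    base_stripe = ((xs // half) % 2 == 0)  # columns: bright / dark
    base_stripe = np.broadcast_to(base_stripe, (size, size))
    n_cells_y = -(-size // cell_h)  # ceil
    n_cells_x = -(-size // cell_w)
    cy_grid, cx_grid = np.mgrid[0:n_cells_y, 0:n_cells_x]
    centers_y = np.clip(cy_grid * cell_h + cell_h // 2, 0, size - 1)
    centers_x = np.clip(cx_grid * cell_w + cell_w // 2, 0, size - 1)
    cell_slow = slow_region[centers_y, centers_x]

    state = np.zeros((n_cells_y, n_cells_x), dtype=bool)  # cumulative phase flips
    cell_of_y = np.arange(size) // cell_h
    cell_of_x = np.arange(size) // cell_w

    def expand(cells: np.ndarray) -> np.ndarray:
        return cells[np.ix_(cell_of_y, cell_of_x)]

    # Striations occupy the organelle *interior* (shell eroded by 3 px);
    # the outermost rim band renders uniformly bright, emulating the
    # membrane-dense inner-boundary zone.  Texture flips therefore never
    # touch the rim, so a flip cannot perturb the derived shell outline.
    # The flip probability is scaled by the shell-to-striated area ratio so
    # the expected moved-pixel fraction per frame pair equals
    # texture_motion_fraction of the shell area exactly.
    rim_structure = np.ones((3, 3), dtype=bool)
    interiors = np.empty_like(shells)
    for t in range(T):
        interiors[t] = ndimage.binary_erosion(shells[t], structure=rim_structure, iterations=3)

    mito_pre = np.empty((T, size, size), dtype=np.float64)
    change_masks = np.zeros((max(T - 1, 1), size, size), dtype=bool)

    mito_times = _mito_times(config)
    for t in range(T):
        if t > 0:
            draws = rng.random((n_cells_y, n_cells_x))
            striated_pair = interiors[t - 1] & interiors[t]
            area_striated = int(striated_pair.sum())
            shell_area_t = int(shells[t - 1].sum())
            if area_striated > 0:
                p_base = min(1.0, config.texture_motion_fraction * shell_area_t / area_striated)
            else:
                p_base = 0.0
            p_map = np.where(cell_slow, p_base * config.mam_slowdown, p_base)
            flips = draws < p_map
            state = state ^ flips
            change_masks[t - 1] = expand(flips) & striated_pair
        tex = base_stripe ^ expand(state)
        bright = tex | (shells[t] & ~interiors[t])
        signal = (config.base_intensity + config.stripe_contrast * bright) * shells[t]
        signal = ndimage.gaussian_filter(signal, config.blur_sigma_px)
        mito_pre[t] = config.background_offset + signal * np.exp(-config.bleach_rate * mito_times[t])

    shell_area = shells.reshape(T, -1).sum(axis=1).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        true_cm = np.where(
            shell_area[:-1] > 0,
            change_masks.reshape(max(T - 1, 1), -1).sum(axis=1)[: T - 1] / shell_area[:-1],
            np.nan,
        ) if T > 1 else np.zeros(0)

    # --- ER channel: one frame per mito block -----------------------------
    n_er = -(-T // config.mito_block_len)
    er_times = np.arange(n_er) * (config.mito_block_len + 1.0)
    er_pre = np.empty((n_er, size, size), dtype=np.float64)
    er_signal = ndimage.gaussian_filter(config.er_intensity * er_mask.astype(np.float64), config.blur_sigma_px)
    for b in range(n_er):
        er_pre[b] = config.background_offset + er_signal * np.exp(-config.bleach_rate * er_times[b])

    # --- noise last (truth already recorded) ------------------------------
    # A reconstructed SIM image has noise band-limited at roughly the PSF
    # scale, not per-pixel white noise: render white noise filtered by the
    # same blur kernel, rescaled so its standard deviation is noise_sigma.
    mito_frames = mito_pre
    er_frames = er_pre
    if config.noise_sigma > 0:
        gain = config.noise_sigma * 2.0 * config.blur_sigma_px * np.sqrt(np.pi)
        mito_frames = mito_pre + gain * ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, mito_pre.shape), (0, config.blur_sigma_px, config.blur_sigma_px)
        )
        er_frames = er_pre + gain * ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, er_pre.shape), (0, config.blur_sigma_px, config.blur_sigma_px)
        )
    mito_frames = np.clip(mito_frames, 0.0, None)
    er_frames = np.clip(er_frames, 0.0, None)

    truth = SceneTruth(
        shell_masks=BinaryStack(masks=shells, source="truth_shell"),
        texture_change_masks=BinaryStack(masks=change_masks[: max(T - 1, 0)], source="truth_changes")
        if T > 1
        else BinaryStack(masks=np.zeros((1, size, size), dtype=bool), source="truth_changes"),
        true_cm_fraction=np.asarray(true_cm, dtype=np.float64),
        er_mask=er_mask,
        mam_core_truth=BinaryStack(masks=shells & er_mask[None, :, :], source="truth_mam_core"),
        slow_region=slow_region,
    )
    mito = TimeLapse(
        frames=mito_frames,
        frame_interval_s=1.0,
        pixel_size_nm=config.pixel_size_nm,
        channel=Channel.MITO,
    )
    er = TimeLapse(
        frames=er_frames,
        frame_interval_s=1.0,
        pixel_size_nm=config.pixel_size_nm,
        channel=Channel.ER,
    )
    return SimulatedScene(mito=mito, er=er, truth=truth, config=config)


def _mito_times(config: SceneConfig) -> np.ndarray:
    """Acquisition time (s) of each mito frame in the interleaved pattern.

    Each block of ``mito_block_len`` MTG frames is preceded by one ER
    exposure, so block boundaries add one extra second at 1 Hz.
    """
    k = np.arange(config.frame_count)
    return (k // config.mito_block_len) * (config.mito_block_len + 1.0) + (k % config.mito_block_len) + 1.0
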