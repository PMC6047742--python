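import numpy as np
import pytest

from cristadyn import (
    AcquisitionPattern,
    BinaryStack,
    Channel,
    DualChannelSequence,
    TimeLapse,
    align_er_frames,
    band_kinetics,
    dilate_bands,
    mam_core,
)
from cristadyn.mam import expand_er_stack, within_block_pairs


def _seq(n_er, n_mito, block=10):
    er = TimeLapse(frames=np.zeros((n_er, 8, 8)), channel=Channel.ER)
    mito = TimeLapse(frames=np.zeros((n_mito, 8, 8)), channel=Channel.MITO)
    return DualChannelSequence(
        er=er, mito=mito, pattern=AcquisitionPattern(mito_block_len=block, repeats=n_er)
    )


class TestErFrameAlignment:
    def test_three_blocks_of_ten(self):
        idx = align_er_frames(_seq(3, 30))
        assert idx.tolist() == [0] * 10 + [1] * 10 + [2] * 10

    def test_single_block(self):
        assert align_er_frames(_seq(1, 10)).tolist() == [0] * 10

    def test_truncated_run(self):
        assert align_er_frames(_seq(2, 15)).tolist() == [0] * 10 + [1] * 5

    def test_expand_repeats_masks(self, rng):
        er_masks = BinaryStack(masks=rng.random((3, 8, 8)) < 0.5)
        expanded = expand_er_stack(er_masks, align_er_frames(_seq(3, 30)))
        assert expanded.n_frames == 30
        np.testing.assert_array_equal(expanded.masks[17], er_masks.masks[1])

    def test_within_block_pairs_skip_boundaries(self):
        pairs = within_block_pairs(30, 10)
        assert 9 not in pairs and 19 not in pairs
        assert len(pairs) == 27


class TestMamCore:
    def test_disjoint_masks_empty(self):
        er = BinaryStack(masks=np.eye(6, dtype=bool)[None])
        mito = BinaryStack(masks=~np.eye(6, dtype=bool)[None])
        assert not mam_core(er, mito).masks.any()

    def test_er_superset_returns_mito(self, rng):
        mito = BinaryStack(masks=rng.random((2, 8, 8)) < 0.4)
        er = BinaryStack(masks=np.ones((2, 8, 8), dtype=bool))
        np.testing.assert_array_equal(mam_core(er, mito).masks, mito.masks)

    def test_elementwise_and(self, rng):
        a = rng.random((2, 10, 10)) < 0.5
        b = rng.random((2, 10, 10)) < 0.5
        core = mam_core(BinaryStack(masks=a), BinaryStack(masks=b)).masks
        np.testing.assert_array_equal(core, a & b)


class TestDilateBands:
    def test_empty_core_gives_empty_bands(self):
        core = BinaryStack(masks=np.zeros((2, 12, 12), dtype=bool))
        bands = dilate_bands(core)
        assert not any(b.masks.any() for b in bands.bands.values())

    def test_isolated_pixel_never_grows_at_count_3(self):
        masks = np.zeros((1, 11, 11), dtype=bool)
        masks[0, 5, 5] = True
        bands = dilate_bands(BinaryStack(masks=masks), levels=(5, 10, 20), count=3)
        for level in (5, 10, 20):
            np.testing.assert_array_equal(bands.bands[level].masks, masks)

    def test_square_grows_on_edges_not_corners(self):
        from oracles import count_dilate_once

        masks = np.zeros((1, 13, 13), dtype=bool)
        masks[0, 4:9, 4:9] = True
        bands = dilate_bands(BinaryStack(masks=masks), levels=(1,), count=3)
        np.testing.assert_array_equal(bands.bands[1].masks[0], count_dilate_once(masks[0], 3))
        assert bands.bands[1].masks[0, 3, 6]  # edge midpoint grew
        assert not bands.bands[1].masks[0, 3, 3]  # diagonal corner did not

    def test_nesting_invariant_on_random_cores(self, rng):
        core = BinaryStack(masks=rng.random((3, 24, 24)) < 0.1)
        bands = dilate_bands(core, levels=(2, 5, 9), count=3)
        assert bands.check_nesting()
        areas = [bands.bands[l].area_per_frame() for l in (2, 5, 9)]
        assert np.all(areas[0] <= areas[1]) and np.all(areas[1] <= areas[2])

    def test_invalid_levels_rejected(self):
        core = BinaryStack(masks=np.zeros((1, 8, 8), dtype=bool))
        with pytest.raises(ValueError):
            dilate_bands(core, levels=(5, 5, 10))
        with pytest.raises(ValueError):
            dilate_bands(core, levels=(10, 5))


class TestBandKinetics:
    def _random_inputs(self, rng, n=4, size=16):
        cm = BinaryStack(masks=rng.random((n - 1, size, size)) < 0.1)
        ibm = BinaryStack(masks=rng.random((n - 1, size, size)) < 0.05)
        otsu = BinaryStack(masks=rng.random((n, size, size)) < 0.6)
        return cm, ibm, otsu

    def test_full_frame_band_equals_whole_kinetics(self, rng):
        from cristadyn import kinetics_trace

        cm, ibm, otsu = self._random_inputs(rng)
        full = BinaryStack(masks=np.ones(otsu.masks.shape, dtype=bool))
        from cristadyn.mam import MamBandSet

        bands = MamBandSet(core=full, bands={1: full})
        per_level = band_kinetics(cm, ibm, otsu, bands)
        whole = kinetics_trace(cm, ibm, otsu)
        np.testing.assert_allclose(
            per_level[1].cm_fraction_per_pair, whole.cm_fraction_per_pair
        )

    def test_disjoint_band_gives_zero_fraction(self, rng):
        cm, ibm, otsu = self._random_inputs(rng)
        half = np.zeros(otsu.masks.shape, dtype=bool)
        half[:, :, :8] = True
        cm_right = BinaryStack(masks=cm.masks & ~half[:-1])
        from cristadyn.mam import MamBandSet

        bands = MamBandSet(core=BinaryStack(masks=half), bands={1: BinaryStack(masks=half)})
        per_level = band_kinetics(cm_right, ibm, otsu, bands)
        assert np.nansum(per_level[1].cm_fraction_per_pair) == 0.0

    def test_band_empty_everywhere_warns_and_is_nan(self, rng):
        cm, ibm, otsu = self._random_inputs(rng)
        empty = BinaryStack(masks=np.zeros(otsu.masks.shape, dtype=bool))
        from cristadyn.mam import MamBandSet

        bands = MamBandSet(core=empty, bands={1: empty})
        with pytest.warns(UserWarning, match="empty"):
            per_level = band_kinetics(cm, ibm, otsu, bands)
        assert np.all(np.isnan(per_level[1].cm_fraction_per_pair))

    def test_pair_restriction(self, rng):
        cm, ibm, otsu = self._random_inputs(rng, n=5)
        full = BinaryStack(masks=np.ones(otsu.masks.shape, dtype=bool))
        from cristadyn.mam import MamBandSet

        bands = MamBandSet(core=full, bands={1: full})
        per_level = band_kinetics(cm, ibm, otsu, bands, pair_indices=np.array([0, 2]))
        assert per_level[1].n_pairs == 2
        assert per_level[1].pair_indices.tolist() == [0, 2]
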