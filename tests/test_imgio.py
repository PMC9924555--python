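"""Patch slicing/stitching bookkeeping and mask I/O round trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihcsubtype import imgio
from ihcsubtype.types import (
    Biomarker,
    ClassMask,
    ClassSet,
    DimensionError,
    FormatError,
    SlideImage,
)


def _slide(h, w, value=200):
    return SlideImage(
        pixels=np.full((h, w, 3), value, dtype=np.uint8),
        patient_id="P01",
        biomarker=Biomarker.ER,
        slide_id="s",
    )


class TestSlicePatches:
    @pytest.mark.parametrize(
        "shape,patch,expected",
        [
            ((1440, 1920), 480, 12),  # nominal full slide -> 3x4 grid
            ((480, 480), 480, 1),
            ((1440, 960), 480, 6),
            ((500, 999), 480, 2),  # remainders discarded
        ],
    )
    def test_patch_counts(self, shape, patch, expected):
        patches, grid = imgio.slice_patches(_slide(*shape), patch, patch // 2)
        assert len(patches) == expected
        assert grid.n_patches == expected
        assert grid.rows == shape[0] // patch and grid.cols == shape[1] // patch

    def test_patches_are_model_sized(self):
        patches, _ = imgio.slice_patches(_slide(960, 960), 480, 240)
        assert all(p.shape == (240, 240, 3) for p in patches)

    def test_oversized_patch_rejected(self):
        with pytest.raises(DimensionError):
            imgio.slice_patches(_slide(400, 600), 480, 240)

    @settings(max_examples=30, deadline=None)
    @given(
        h=st.integers(8, 60),
        w=st.integers(8, 60),
        patch=st.integers(4, 8),
    )
    def test_count_matches_brute_force_tiling(self, h, w, patch):
        """Patch count equals the number of full tiles found by enumeration."""
        brute = sum(
            1
            for r in range(0, h - patch + 1, patch)
            for c in range(0, w - patch + 1, patch)
        )
        patches, grid = imgio.slice_patches(_slide(h, w), patch, patch)
        assert len(patches) == brute == grid.n_patches


class TestSliceMask:
    def test_constant_mask_stays_constant(self):
        mask = ClassMask(np.full((960, 960), 2, dtype=np.int64), ClassSet.ERPR_4CLASS)
        patches, _ = imgio.slice_mask(mask, 480, 240)
        assert all((p.labels == 2).all() for p in patches)

    def test_single_pixel_stays_local(self):
        labels = np.zeros((960, 960), dtype=np.int64)
        labels[0, 0] = 3
        patches, _ = imgio.slice_mask(
            ClassMask(labels, ClassSet.ERPR_4CLASS), 480, 480
        )
        assert (patches[0].labels != 0).sum() == 1
        assert all((p.labels == 0).all() for p in patches[1:])

    def test_downscale_never_invents_labels(self):
        """Nearest-neighbour resize keeps the label set closed."""
        rng = np.random.default_rng(0)
        labels = rng.choice([0, 3], size=(480, 480)).astype(np.int64)
        patches, _ = imgio.slice_mask(
            ClassMask(labels, ClassSet.ERPR_4CLASS), 480, 240
        )
        assert set(np.unique(patches[0].labels)) <= {0, 3}


class TestStitchMasks:
    def test_round_trip_identity_without_resize(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, size=(960, 1440)).astype(np.int64)
        mask = ClassMask(labels, ClassSet.ERPR_4CLASS)
        patches, grid = imgio.slice_mask(mask, 480, 480)
        stitched = imgio.stitch_masks(patches, grid)
        assert np.array_equal(stitched.labels, labels)

    def test_zero_patches_stitch_to_zero_slide(self):
        grid = imgio.PatchGrid(4, 3, 480, 240, (1920, 1440))
        patches = [
            ClassMask(np.zeros((240, 240), dtype=np.int64), ClassSet.ERPR_4CLASS)
            for _ in range(12)
        ]
        out = imgio.stitch_masks(patches, grid)
        assert out.shape == (1920, 1440)
        assert not out.labels.any()

    def test_distinct_patch_labels_fill_their_blocks(self):
        grid = imgio.PatchGrid(2, 2, 480, 240, (960, 960))
        patches = [
            ClassMask(np.full((240, 240), v, dtype=np.int64), ClassSet.ERPR_4CLASS)
            for v in (0, 1, 2, 3)
        ]
        out = imgio.stitch_masks(patches, grid)
        for idx, v in enumerate((0, 1, 2, 3)):
            r, c = divmod(idx, 2)
            block = out.labels[r * 480 : (r + 1) * 480, c * 480 : (c + 1) * 480]
            assert (block == v).all()

    def test_patch_count_mismatch_rejected(self):
        grid = imgio.PatchGrid(2, 2, 480, 240, (960, 960))
        patches = [
            ClassMask(np.zeros((240, 240), dtype=np.int64), ClassSet.ERPR_4CLASS)
        ] * 3
        with pytest.raises(DimensionError):
            imgio.stitch_masks(patches, grid)


class TestFileIO:
    def test_mask_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        mask = ClassMask(
            rng.integers(0, 3, size=(64, 80)).astype(np.int64), ClassSet.KI67_3CLASS
        )
        path = tmp_path / "mask.png"
        imgio.save_mask(mask, path)
        loaded = imgio.load_mask(path)
        assert loaded.class_set is ClassSet.KI67_3CLASS
        assert np.array_equal(loaded.labels, mask.labels)

    def test_slide_round_trip_and_dimension_mapping(self, tmp_path):
        rng = np.random.default_rng(3)
        pixels = rng.integers(0, 256, size=(144, 192, 3)).astype(np.uint8)
        image = SlideImage(pixels, "P01", Biomarker.KI67, "s1")
        path = tmp_path / "slide.png"
        imgio.save_slide(image, path)
        loaded = imgio.load_slide(path, "P01", Biomarker.KI67)
        assert loaded.shape == (144, 192)
        assert np.array_equal(loaded.pixels, pixels)

    def test_grayscale_slide_rejected(self, tmp_path):
        from PIL import Image

        path = tmp_path / "gray.png"
        Image.fromarray(np.zeros((32, 32), dtype=np.uint8), mode="L").save(path)
        with pytest.raises(FormatError):
            imgio.load_slide(path)
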