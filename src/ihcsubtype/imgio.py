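"""Slide/mask I/O, non-overlapping patch extraction, and mask stitching.

Slides are processed as tilings of non-overlapping ``patch_size`` squares
(default 480 px at 40x magnification) which are resized to the network input
size (default 240 px). Images are resized bilinearly; masks always use
nearest-neighbour resampling so no interpolated labels appear. Any remainder
strip narrower than ``patch_size`` at the right/bottom border is discarded
(the nominal 1920x1440 slide tiles exactly into a 3x4 grid of 12 patches).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    Biomarker,
    ClassMask,
    ClassSet,
    DimensionError,
    FormatError,
    PatchGrid,
    SlideImage,
    ValidationError,
)

MANIFEST_COLUMNS = ["slide_path", "mask_path", "patient_id", "biomarker"]

# Display palette for indexed mask PNGs; pixel value == class label.
_MASK_PALETTE = [
    (0, 0, 0),
    (80, 60, 160),
    (220, 170, 110),
    (150, 80, 30),
]


def _grid_for(shape: tuple[int, int], patch_size: int, model_size: int) -> PatchGrid:
    h, w = shape
    if patch_size < 1:
        raise DimensionError("patch_size must be positive")
    if patch_size > h or patch_size > w:
        raise DimensionError(
            f"patch_size {patch_size} exceeds image dimensions {h}x{w}"
        )
    if model_size > patch_size:
        raise DimensionError("model_size must not exceed patch_size")
    return PatchGrid(
        rows=h // patch_size,
        cols=w // patch_size,
        patch_size=patch_size,
        model_size=model_size,
        origin_shape=(h, w),
    )


def _resize_image(pixels: np.ndarray, size: int) -> np.ndarray:
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels
    im = Image.fromarray(pixels)
    return np.asarray(im.resize((size, size), Image.BILINEAR))


def _resize_labels(labels: np.ndarray, size: int) -> np.ndarray:
    if labels.shape[0] == size and labels.shape[1] == size:
        return labels
    im = Image.fromarray(labels.astype(np.uint8))
    return np.asarray(im.resize((size, size), Image.NEAREST)).astype(labels.dtype)


def slice_patches(
    image: SlideImage, patch_size: int = 480, model_size: int = 240
) -> tuple[list[np.ndarray], PatchGrid]:
    """Tile a slide into row-major non-overlapping patches resized for the model.

    Returns ``rows*cols`` arrays of shape ``(model_size, model_size, 3)`` and
    the :class:`PatchGrid` needed to stitch predictions back together.
    """
    grid = _grid_for(image.shape, patch_size, model_size)
    patches = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            tile = image.pixels[
                r * patch_size : (r + 1) * patch_size,
                c * patch_size : (c + 1) * patch_size,
            ]
            patches.append(_resize_image(tile, model_size))
    return patches, grid


def slice_mask(
    mask: ClassMask, patch_size: int = 480, model_size: int = 240
) -> tuple[list[ClassMask], PatchGrid]:
    """Tile a class mask congruently with :func:`slice_patches`.

    Nearest-neighbour resizing guarantees the label set never grows.
    """
    grid = _grid_for(mask.shape, patch_size, model_size)
    patches = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            tile = mask.labels[
                r * patch_size : (r + 1) * patch_size,
                c * patch_size : (c + 1) * patch_size,
            ]
            patches.append(ClassMask(_resize_labels(tile, model_size), mask.class_set))
    return patches, grid


def stitch_masks(patch_masks: list[ClassMask], grid: PatchGrid) -> ClassMask:
    """Reassemble per-patch prediction masks into a full-slide mask.

    Each patch is upscaled (nearest neighbour) from ``model_size`` back to
    ``patch_size`` and placed at its row-major grid cell; the output covers
    ``(rows*patch_size, cols*patch_size)`` — any border remainder discarded at
    slicing time stays discarded.
    """
    if len(patch_masks) != grid.n_patches:
        raise DimensionError(
            f"expected {grid.n_patches} patches for grid, got {len(patch_masks)}"
        )
    class_set = patch_masks[0].class_set
    out = np.zeros(
        (grid.rows * grid.patch_size, grid.cols * grid.patch_size),
        dtype=patch_masks[0].labels.dtype,
    )
    for idx, patch in enumerate(patch_masks):
        if patch.class_set is not class_set:
            raise ValidationError("patch masks mix class sets")
        if patch.shape != (grid.model_size, grid.model_size):
            raise DimensionError(
                f"patch {idx} has shape {patch.shape}, expected "
                f"({grid.model_size}, {grid.model_size})"
            )
        r, c = divmod(idx, grid.cols)
        out[
            r * grid.patch_size : (r + 1) * grid.patch_size,
            c * grid.patch_size : (c + 1) * grid.patch_size,
        ] = _resize_labels(patch.labels, grid.patch_size)
    return ClassMask(out, class_set)


def load_slide(
    path: str | Path,
    patient_id: str = "",
    biomarker: Biomarker | str = Biomarker.ER,
    slide_id: str | None = None,
) -> SlideImage:
    """Read an RGB PNG/TIFF slide; non-RGB files are rejected."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "RGB":
            raise FormatError(f"{path} is {im.mode}, expected an RGB image")
        pixels = np.asarray(im)
    return SlideImage(
        pixels=pixels,
        patient_id=patient_id,
        biomarker=Biomarker(biomarker),
        slide_id=slide_id if slide_id is not None else path.stem,
    )


def save_slide(image: SlideImage, path: str | Path) -> None:
    Image.fromarray(image.pixels).save(Path(path))


def save_mask(mask: ClassMask, path: str | Path) -> None:
    """Persist a mask as a single-channel indexed PNG (pixel value == label)
    with a JSON sidecar mapping labels to class names."""
    path = Path(path)
    im = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    palette: list[int] = []
    for i in range(256):
        rgb = _MASK_PALETTE[i] if i < len(_MASK_PALETTE) else (i, i, i)
        palette.extend(rgb)
    im.putpalette(palette)
    im.save(path)
    sidecar = {
        "class_set": mask.class_set.name,
        "classes": {str(i): n for i, n in enumerate(mask.class_set.class_names)},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_mask(path: str | Path, class_set: ClassSet | None = None) -> ClassMask:
    """Load an indexed-PNG mask; the class set comes from the JSON sidecar
    unless given explicitly."""
    path = Path(path)
    if class_set is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"no class-set sidecar for {path}")
        class_set = ClassSet[json.loads(sidecar.read_text())["class_set"]]
    with Image.open(path) as im:
        if im.mode not in ("P", "L"):
            raise FormatError(f"{path} is {im.mode}, expected indexed/grayscale mask")
        labels = np.asarray(im).astype(np.int64)
    return ClassMask(labels, class_set)


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValidationError(f"manifest missing columns {missing}")
    rows.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns {missing}")
    return df
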