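"""Mask cleanup and instance splitting of touching nuclei.

Segmentation masks are cleaned per foreground class with binary opening then
closing (disk structuring elements) and a minimum-object-size filter, after
which touching nuclei are split with a marker-controlled watershed on the
Euclidean distance transform: markers are the local maxima of the distance
map separated by at least ``min_peak_distance`` (default: the generator's
minimum nucleus radius). The HER2 membrane class is cleaned but never
watershed-split — membranes are rings, not countable blobs — so instance
splitting applies to nucleus-like classes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, opening
from skimage.segmentation import watershed

from .types import ClassMask, ClassSet, InstanceLabels, ValidationError


@dataclass
class PostprocConfig:
    min_object_px: int = 30
    opening_radius: int = 1
    closing_radius: int = 1
    min_peak_distance: int = 8

    def __post_init__(self) -> None:
        if self.opening_radius < 0 or self.closing_radius < 0:
            raise ValidationError("morphology radii must be non-negative")
        if self.min_object_px < 0:
            raise ValidationError("min_object_px must be non-negative")


def splittable_classes(class_set: ClassSet) -> tuple[int, ...]:
    """Foreground classes that undergo watershed splitting (nuclei only)."""
    if class_set is ClassSet.HER2_3CLASS:
        return (1,)  # membrane class 2 is cleaned but not split
    return class_set.foreground_classes


def clean_mask(
    mask: ClassMask,
    min_object_px: int = 30,
    opening_radius: int = 1,
    closing_radius: int = 1,
) -> ClassMask:
    """Open, close, and size-filter each foreground class of a mask.

    Classes are processed independently and painted back in ascending label
    order; background is whatever no class claims.
    """
    if opening_radius < 0 or closing_radius < 0:
        raise ValidationError("morphology radii must be non-negative")
    out = np.zeros_like(mask.labels)
    for class_id in mask.class_set.foreground_classes:
        binary = mask.labels == class_id
        if not binary.any():
            continue
        if opening_radius > 0:
            binary = opening(binary, disk(opening_radius))
        if closing_radius > 0:
            binary = closing(binary, disk(closing_radius))
        if min_object_px > 0:
            components = cc_label(binary, connectivity=2)
            sizes = np.bincount(components.ravel())
            too_small = np.flatnonzero(sizes < min_object_px)
            binary = binary & ~np.isin(components, too_small[too_small > 0])
        out[binary] = class_id
    return ClassMask(out, mask.class_set)


def split_instances(
    mask: ClassMask,
    min_peak_distance: int = 8,
    classes: tuple[int, ...] | None = None,
) -> InstanceLabels:
    """Split each nucleus class into instances with a distance-transform
    watershed.

    Returns contiguous instance ids (1..K) across classes together with an
    id -> class map. Components that the peak detector leaves markerless
    (small or flat) still become single instances, so the instance pixels
    always partition the splittable foreground.
    """
    if classes is None:
        classes = splittable_classes(mask.class_set)
    labels = np.zeros(mask.shape, dtype=np.int32)
    instance_class: dict[int, int] = {}
    next_id = 1
    for class_id in classes:
        binary = mask.labels == class_id
        if not binary.any():
            continue
        distance = ndi.distance_transform_edt(binary)
        peaks = peak_local_max(
            distance,
            min_distance=max(1, min_peak_distance),
            labels=binary,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (y, x) in enumerate(peaks, start=1):
            markers[y, x] = i
        if markers.any():
            ws = watershed(-distance, markers, mask=binary)
        else:
            ws = np.zeros(mask.shape, dtype=np.int32)
        # rescue components that received no marker
        orphan = binary & (ws == 0)
        if orphan.any():
            extra = cc_label(orphan, connectivity=2)
            extra[extra > 0] += ws.max()
            ws = ws + extra
        for ws_id in np.unique(ws):
            if ws_id == 0:
                continue
            labels[ws == ws_id] = next_id
            instance_class[next_id] = class_id
            next_id += 1
    return InstanceLabels(labels=labels, instance_class=instance_class)


def count_objects(instances: InstanceLabels) -> dict[int, int]:
    """Number of instances per class."""
    counts: dict[int, int] = {}
    for class_id in instances.instance_class.values():
        counts[class_id] = counts.get(class_id, 0) + 1
    return counts


def process_mask(
    mask: ClassMask, config: PostprocConfig | None = None
) -> tuple[ClassMask, InstanceLabels, dict[int, int]]:
    """clean -> split -> count in one call."""
    config = config or PostprocConfig()
    cleaned = clean_mask(
        mask,
        min_object_px=config.min_object_px,
        opening_radius=config.opening_radius,
        closing_radius=config.closing_radius,
    )
    instances = split_instances(cleaned, min_peak_distance=config.min_peak_distance)
    return cleaned, instances, count_objects(instances)
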