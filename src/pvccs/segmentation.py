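"""Lesion detection and distance-transform-based region construction.

Calcified lesions are detected as 26-connected components of voxels at or
above the clinical 130 HU threshold (the *initial* segmentation). Around each
lesion, two further regions are built:

* an *extended* segmentation: voxels above 90 HU that are 26-connected to the
  initial segmentation, kept only within ``d1`` mm of its boundary, where
  ``d1`` is the largest interior distance of the initial segmentation (its
  "radius"); voxels in this band may partially contain calcium without
  reaching 130 HU;
* a *background* shell: non-calcification voxels within ``d2`` mm of the
  calcification boundary, where ``d2`` is the largest interior distance of
  the full calcification volume (initial plus extension). The background
  feeds the per-lesion intensity-mixture fit.

All distances are Euclidean voxel-center-to-voxel-center distances in mm,
weighted by the (anisotropic) voxel spacing. ``d2 >= d1`` is not guaranteed
and not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "LesionSegmentation",
    "detect_lesions",
    "anisotropic_distance_map",
    "extend_lesion",
    "define_background",
    "segment_lesions",
]

#: 26-connectivity structuring element (faces, edges and corners all connect).
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)

_DIST_EPS = 1e-9  # tolerance for <= comparisons on float distances


@dataclass
class LesionSegmentation:
    """Per-lesion voxel regions and the two characteristic distances (mm)."""

    label_id: int
    initial_mask: np.ndarray
    extended_mask: np.ndarray
    background_mask: np.ndarray
    d1_mm: float
    d2_mm: float

    @property
    def calcification_mask(self) -> np.ndarray:
        """Initial plus refined-extended segmentation."""
        return self.initial_mask | self.extended_mask


def detect_lesions(
    volume: CTVolume, detection_threshold_hu: float = 130.0, min_voxels: int = 1
) -> list[np.ndarray]:
    """Detect lesions as 26-connected components of ``HU >= threshold``.

    Returns one boolean mask per component, sorted by voxel count
    descending; components smaller than ``min_voxels`` are dropped. An empty
    list is returned when nothing exceeds the threshold.
    """
    binary = volume.intensities >= detection_threshold_hu
    labels, n = ndimage.label(binary, structure=STRUCTURE_26)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(-counts, kind="stable")
    return [labels == lab + 1 for lab in order if counts[lab] >= min_voxels]


def anisotropic_distance_map(
    mask: np.ndarray, spacing_mm: tuple[float, float, float], direction: str = "interior"
) -> np.ndarray:
    """Euclidean distance transform in mm, corrected for voxel anisotropy.

    ``interior``: for each mask voxel, the distance from its center to the
    nearest non-mask voxel center (zero outside the mask). ``exterior``: for
    each non-mask voxel, the distance to the nearest mask voxel center (zero
    inside the mask, infinite everywhere for an empty mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if direction == "interior":
        if not mask.any():
            raise ValueError("interior distance map of an empty mask is undefined")
        if mask.all():
            raise ValueError("interior distance map needs at least one outside voxel")
        return ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    if direction == "exterior":
        if not mask.any():
            return np.full(mask.shape, np.inf)
        return ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    raise ValueError(f"direction must be 'interior' or 'exterior', got {direction!r}")


def extend_lesion(
    volume: CTVolume, initial_mask: np.ndarray, extension_threshold_hu: float = 90.0
) -> tuple[np.ndarray, float]:
    """Refined extended segmentation of one lesion and its ``d1`` (mm).

    Candidates are voxels strictly above the extension threshold that are
    26-connected to the initial mask (grown through other candidates) and not
    part of it; candidates farther than ``d1`` from the initial boundary are
    discarded, which keeps streaks and noise chains from inflating the lesion.
    """
    initial_mask = np.asarray(initial_mask, dtype=bool)
    d1 = float(anisotropic_distance_map(initial_mask, volume.spacing_mm, "interior").max())
    region = (volume.intensities > extension_threshold_hu) | initial_mask
    labels, _ = ndimage.label(region, structure=STRUCTURE_26)
    seed_labels = np.unique(labels[initial_mask])
    connected = np.isin(labels, seed_labels[seed_labels > 0])
    candidates = connected & ~initial_mask
    exterior = anisotropic_distance_map(initial_mask, volume.spacing_mm, "exterior")
    extended = candidates & (exterior <= d1 + _DIST_EPS)
    return extended, d1


def define_background(
    volume: CTVolume,
    calcification_mask: np.ndarray,
    other_lesion_masks: tuple[np.ndarray, ...] = (),
) -> tuple[np.ndarray, float]:
    """Background shell of one lesion and its ``d2`` (mm).

    The shell contains every non-calcification voxel within ``d2`` mm of the
    calcification, excluding voxels that belong to any *other* lesion's
    calcification mask so that neighbouring calcium cannot contaminate the
    background intensity distribution. The shell is implicitly clipped to
    the volume bounds.
    """
    calcification_mask = np.asarray(calcification_mask, dtype=bool)
    d2 = float(
        anisotropic_distance_map(calcification_mask, volume.spacing_mm, "interior").max()
    )
    exterior = anisotropic_distance_map(calcification_mask, volume.spacing_mm, "exterior")
    background = ~calcification_mask & (exterior <= d2 + _DIST_EPS)
    for other in other_lesion_masks:
        background &= ~np.asarray(other, dtype=bool)
    return background, d2


def segment_lesions(
    volume: CTVolume,
    detection_threshold_hu: float = 130.0,
    extension_threshold_hu: float = 90.0,
    min_voxels: int = 1,
) -> list[LesionSegmentation]:
    """Full per-lesion segmentation of a volume: detect, extend, background.

    Backgrounds are built after all calcification masks are known so that
    each lesion's background can exclude every other lesion's calcium.
    """
    initial_masks = detect_lesions(volume, detection_threshold_hu, min_voxels)
    extended: list[tuple[np.ndarray, float]] = [
        extend_lesion(volume, m, extension_threshold_hu) for m in initial_masks
    ]
    calc_masks = [init | ext for init, (ext, _) in zip(initial_masks, extended)]
    lesions = []
    for i, (init, (ext, d1)) in enumerate(zip(initial_masks, extended)):
        others = tuple(c for j, c in enumerate(calc_masks) if j != i)
        background, d2 = define_background(volume, calc_masks[i], others)
        lesions.append(
            LesionSegmentation(
                label_id=i + 1,
                initial_mask=init,
                extended_mask=ext,
                background_mask=background,
                d1_mm=d1,
                d2_mm=d2,
            )
        )
    return lesions
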