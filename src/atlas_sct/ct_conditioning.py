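"""CT conditioning: air removal, tissue clustering, bone suppression, and
standardization into the water-MR intensity frame (CT_S,BS,FS).

The conditioned CT has fat and bone suppressed and muscle mapped to the
water image's bright landmark, so cross-modality CT-to-MR registration
behaves like a mono-modality problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import (
    LABEL_AIR_INSIDE,
    LABEL_BACKGROUND,
    LABEL_BONE,
    LABEL_FAT,
    LABEL_MUSCLE,
    LabelVolume,
    ValidationError,
    Volume,
)
from .mr_preprocessing import (
    DegenerateInputError,
    StandardScale,
    TissueLandmarks,
    fuzzy_c_means,
    piecewise_linear_map,
)

__all__ = [
    "CTClusterCenters",
    "mask_air",
    "classify_tissues_ct",
    "suppress_bone",
    "standardize_ct_to_mr",
    "body_mask_from_air",
    "condition_ct",
]

log = logging.getLogger(__name__)

AIR_THRESHOLD_HU = -250.0
AIR_HU = -1000.0


@dataclass(frozen=True)
class CTClusterCenters:
    """Fat/muscle/bone cluster centers on the non-air CT histogram (HU)."""

    fat_center: float
    muscle_center: float
    bone_center: float

    def __post_init__(self) -> None:
        if not (self.fat_center < self.muscle_center < self.bone_center):
            raise ValidationError(
                "cluster centers must satisfy fat < muscle < bone: "
                f"({self.fat_center}, {self.muscle_center}, {self.bone_center})"
            )
        if self.fat_center <= AIR_THRESHOLD_HU:
            raise ValidationError(
                f"fat center {self.fat_center} HU is below the air threshold"
            )


def mask_air(ct: Volume, threshold_hu: float = AIR_THRESHOLD_HU) -> Volume:
    """Binary air mask: 1 where HU < threshold (strict), else 0."""
    mask = (ct.data < threshold_hu).astype(np.uint8)
    return Volume(mask, ct.spacing, ct.origin, ct.orientation, "MASK")


def body_mask_from_air(air_mask: Volume, closing_radius_vox: int = 3) -> Volume:
    """Largest connected non-air component, morphologically closed.

    Used by evaluation to exclude the background (couch, surrounding air)
    while keeping interior air pockets inside the body.
    """
    non_air = air_mask.data == 0
    labeled, n = ndimage.label(non_air)
    if n == 0:
        raise ValidationError("no non-air voxels: cannot form a body mask")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    body = labeled == (1 + int(np.argmax(sizes)))
    if closing_radius_vox > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        # pad with edge values so closing does not erode the volume faces
        r = closing_radius_vox
        padded = np.pad(body, r, mode="edge")
        padded = ndimage.binary_closing(padded, structure=struct, iterations=r)
        body = padded[r:-r, r:-r, r:-r]
        body = ndimage.binary_fill_holes(body)
    return Volume(body.astype(np.uint8), air_mask.spacing, air_mask.origin,
                  air_mask.orientation, "MASK")


def classify_tissues_ct(
    ct: Volume,
    air_mask: Volume,
    fuzzifier: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    max_samples: int = 200_000,
) -> tuple[LabelVolume, CTClusterCenters]:
    """FCM (k=3) on non-air CT voxels -> fat / muscle / bone labels.

    Clustering runs on a fixed-seed subsample for speed; hard labels are then
    assigned to every non-air voxel by nearest center.
    """
    if ct.shape != air_mask.shape:
        raise ValidationError("air mask and CT grids differ")
    non_air = air_mask.data == 0
    vals = ct.data[non_air].astype(float)
    if vals.size == 0:
        raise DegenerateInputError("image is all air: nothing to classify")
    if np.unique(vals).size < 3:
        raise DegenerateInputError(
            "fewer than 3 distinct HU values among non-air voxels"
        )
    rng = np.random.default_rng(seed)
    sample = vals if vals.size <= max_samples else rng.choice(vals, max_samples,
                                                              replace=False)
    centers, _ = fuzzy_c_means(sample, k=3, fuzzifier=fuzzifier, tol=tol,
                               max_iter=max_iter, seed=seed)
    # one hard-assignment refinement pass on the full data
    assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
    refined = centers.copy()
    for j in range(3):
        sel = assign == j
        if np.any(sel):
            refined[j] = vals[sel].mean()
    refined = np.sort(refined)
    assign = np.argmin(np.abs(vals[:, None] - refined[None, :]), axis=1)

    labels = np.zeros(ct.shape, dtype=np.int16)
    tissue_codes = np.array([LABEL_FAT, LABEL_MUSCLE, LABEL_BONE], dtype=np.int16)
    labels[non_air] = tissue_codes[assign]
    centers_out = CTClusterCenters(fat_center=float(refined[0]),
                                   muscle_center=float(refined[1]),
                                   bone_center=float(refined[2]))
    log.info("CT cluster centers (HU): fat=%.1f muscle=%.1f bone=%.1f",
             centers_out.fat_center, centers_out.muscle_center,
             centers_out.bone_center)
    return LabelVolume.like(ct, labels), centers_out


def suppress_bone(ct: Volume, labels: LabelVolume, air_hu: float = AIR_HU) -> Volume:
    """Assign air HU to bone-labeled voxels; all others unchanged."""
    if ct.shape != labels.shape:
        raise ValidationError("labels and CT grids differ")
    out = ct.data.astype(float).copy()
    out[labels.labels == LABEL_BONE] = air_hu
    return ct.with_data(out)


def standardize_ct_to_mr(
    ct_bs: Volume,
    centers: CTClusterCenters,
    mr_landmarks: TissueLandmarks,
    scale: StandardScale,
    air_hu: float = AIR_HU,
) -> Volume:
    """Map the bone-suppressed CT into the standardized water-MR frame.

    Anchors: air -> 0, fat center -> dark landmark target (fat is near-air
    dark on water images, so this also suppresses fat), muscle center ->
    bright landmark target.  Monotone, clamped to [0, s_max].
    """
    if mr_landmarks is not None and not (
        mr_landmarks.dark_mode < mr_landmarks.bright_mode
    ):
        raise ValueError("invalid MR landmarks")
    if not (air_hu < centers.fat_center < centers.muscle_center):
        raise ValueError("air/fat/muscle anchor ordering violated")
    out = piecewise_linear_map(
        ct_bs.data.astype(float),
        (air_hu, centers.fat_center, centers.muscle_center),
        (0.0, scale.s_dark, scale.s_bright),
        lo_clip=0.0,
        hi_clip=scale.s_max,
    )
    return ct_bs.with_data(out)


def condition_ct(
    ct: Volume,
    mr_landmarks: TissueLandmarks,
    scale: StandardScale,
    seed: int = 0,
    air_threshold_hu: float = AIR_THRESHOLD_HU,
):
    """Full CT chain: mask air, classify, suppress bone, standardize.

    Returns ``(ct_sbsfs, labels, centers, air_mask)``.
    """
    air = mask_air(ct, air_threshold_hu)
    labels, centers = classify_tissues_ct(ct, air, seed=seed)
    ct_bs = suppress_bone(ct, labels)
    ct_sbsfs = standardize_ct_to_mr(ct_bs, centers, mr_landmarks, scale)
    return ct_sbsfs, labels, centers, air
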