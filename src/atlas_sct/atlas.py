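"""Build, serialize and propagate the co-registered CT-MR atlas.

An atlas pair holds a subject's planning CT deformed onto its own MR grid
(``ct_reg``) next to that subject's standardized fat-enhanced water image
(``mr_wfe``).  Propagation deforms every pair onto a new subject's MR via
landmark-initialized rigid + B-spline registration of the MR images and
carries the CT along with the same field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .config import (
    default_config,
    gre_params_from_config,
    reg_params_from_config,
    scale_from_config,
)
from .ct_conditioning import condition_ct
from .image_core import FormatError, Volume, grids_match, read_volume, write_volume
from .mr_preprocessing import StandardScale, preprocess_mr
from .registration import (
    DeformationField,
    apply_deformation,
    bspline_register,
    initial_alignment,
)

__all__ = [
    "AtlasPair",
    "Atlas",
    "PropagatedEntry",
    "PropagatedAtlas",
    "AtlasBuildError",
    "SubjectData",
    "prepare_atlas_pair",
    "build_atlas",
    "save_atlas",
    "load_atlas",
    "propagate_atlas",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class AtlasBuildError(RuntimeError):
    """No usable atlas pairs could be produced."""


@dataclass
class SubjectData:
    """Raw inputs for one atlas subject."""

    subject_id: str
    ct: Volume
    water: Volume
    fat: Volume
    landmarks: dict  # name -> [x, y, z] mm, shared CT/MR frame


@dataclass
class AtlasPair:
    """One conditioned, co-registered atlas entry."""

    ct_reg: Volume
    mr_wfe: Volume
    subject_id: str
    landmarks: dict = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not grids_match(self.ct_reg, self.mr_wfe):
            raise ValueError(
                f"atlas pair {self.subject_id}: CT and MR grids differ"
            )


@dataclass
class Atlas:
    pairs: list
    standard_scale: StandardScale
    build_config: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.subject_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate subject ids in atlas: {ids}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PropagatedEntry:
    subject_id: str
    ct_deformed: Volume
    mr_deformed: Volume
    field: DeformationField


@dataclass
class PropagatedAtlas:
    entries: list
    target_grid_shape: tuple

    def __len__(self) -> int:
        return len(self.entries)


def _crop_end_slices(vol: Volume, k: int) -> Volume:
    """Drop k artifact-prone end slices along the axial axis."""
    if k <= 0:
        return vol
    return Volume(vol.data[:, :, k:-k], vol.spacing,
                  vol.origin + vol.orientation @ (vol.spacing * np.array([0, 0, k])),
                  vol.orientation, vol.modality_tag)


def prepare_atlas_pair(subject, config: dict | None = None) -> AtlasPair:
    """Condition one subject and register its CT onto its MR grid.

    Runs the full MR chain (bias -> landmarks -> standardize -> fat-enhance)
    and CT chain (air -> cluster -> bone-suppress -> standardize), registers
    the conditioned CT to the standardized water image, and applies the
    resulting field to the ORIGINAL planning CT.
    """
    cfg = config or default_config()
    scale = scale_from_config(cfg)
    seed = int(cfg["seed"])
    crop = int(cfg.get("crop_slices", 0))

    water = _crop_end_slices(subject.water, crop)
    fat = _crop_end_slices(subject.fat, crop)
    ct = _crop_end_slices(subject.ct, crop)

    water_std, fat_std, wfe, lm_water = preprocess_mr(
        water, fat, scale,
        alpha=float(cfg["alpha"]),
        bias_basis_order=int(cfg["bias"]["basis_order"]),
        bias_k=int(cfg["bias"]["k"]),
        bias_iter=int(cfg["bias"]["n_iter"]),
        hist_bins=int(cfg["hist_bins"]),
        smooth_window=int(cfg["smooth_window"]),
        seed=seed,
    )
    ct_sbsfs, labels, centers, _air = condition_ct(ct, lm_water, scale, seed=seed)

    pts = sorted(subject.landmarks)
    fixed_pts = [subject.landmarks[k] for k in pts]
    init = initial_alignment(fixed_pts, fixed_pts)  # same frame: CT ~ MR
    reg_params = reg_params_from_config(cfg)
    field = bspline_register(water_std, ct_sbsfs, init=init, params=reg_params)
    ct_reg = apply_deformation(ct, field, interpolation="linear")

    provenance = {
        "software_version": _pkg_version,
        "ct_cluster_centers": [centers.fat_center, centers.muscle_center,
                               centers.bone_center],
        "water_landmarks": [lm_water.dark_mode, lm_water.valley,
                            lm_water.bright_mode],
        "config": cfg,
    }
    return AtlasPair(ct_reg=ct_reg, mr_wfe=wfe, subject_id=subject.subject_id,
                     landmarks=dict(subject.landmarks), provenance=provenance)


def build_atlas(subjects, config: dict | None = None) -> Atlas:
    """Condition and co-register every subject; skip failures with a log."""
    cfg = config or default_config()
    pairs = []
    for subject in subjects:
        try:
            if not getattr(subject, "landmarks", None):
                raise ValueError("subject has no landmarks")
            pairs.append(prepare_atlas_pair(subject, cfg))
        except Exception as exc:
            log.warning("atlas build: skipping subject %s: %s",
                        getattr(subject, "subject_id", "?"), exc)
    if not pairs:
        raise AtlasBuildError("no subject produced a usable atlas pair")
    return Atlas(pairs=pairs, standard_scale=scale_from_config(cfg),
                 build_config=cfg)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_atlas(atlas: Atlas, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = []
    for pair in atlas.pairs:
        ctf = f"{pair.subject_id}_ctreg.nii.gz"
        mrf = f"{pair.subject_id}_mrwfe.nii.gz"
        write_volume(pair.ct_reg, directory / ctf)
        write_volume(pair.mr_wfe, directory / mrf)
        subjects.append({
            "id": pair.subject_id, "ct_reg": ctf, "mr_wfe": mrf,
            "landmarks": pair.landmarks, "provenance": pair.provenance,
        })
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "standard_scale": {
            "s_dark": atlas.standard_scale.s_dark,
            "s_valley": atlas.standard_scale.s_valley,
            "s_bright": atlas.standard_scale.s_bright,
            "s_max": atlas.standard_scale.s_max,
        },
        "build_config": atlas.build_config,
        "subjects": subjects,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_atlas(directory: str | Path) -> Atlas:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no atlas manifest in {directory}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt atlas manifest: {exc}") from exc
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"unsupported atlas schema version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    scale = StandardScale(**manifest["standard_scale"])
    pairs = []
    for entry in manifest["subjects"]:
        pairs.append(AtlasPair(
            ct_reg=read_volume(directory / entry["ct_reg"], "CT"),
            mr_wfe=read_volume(directory / entry["mr_wfe"], "MR_WFE"),
            subject_id=entry["id"],
            landmarks=entry.get("landmarks", {}),
            provenance=entry.get("provenance", {}),
        ))
    return Atlas(pairs=pairs, standard_scale=scale,
                 build_config=manifest.get("build_config", {}))


# --------------------------------------------------------------------------
# Propagation
# --------------------------------------------------------------------------

def propagate_atlas(atlas: Atlas, target_mr_wfe: Volume, target_landmarks: dict,
                    params=None, config: dict | None = None) -> PropagatedAtlas:
    """Deform every atlas pair onto the target's fat-enhanced water image."""
    if len(atlas) == 0:
        raise ValueError("cannot propagate an empty atlas")
    if target_mr_wfe.modality_tag != "MR_WFE":
        raise ValueError("target must be a standardized fat-enhanced water image")
    if params is None:
        cfg = config or atlas.build_config or default_config()
        params = reg_params_from_config(cfg)

    entries = []
    for pair in atlas.pairs:
        common = sorted(set(target_landmarks) & set(pair.landmarks))
        if common:
            init = initial_alignment(
                [target_landmarks[k] for k in common],
                [pair.landmarks[k] for k in common],
            )
        else:
            init = None
        field = bspline_register(target_mr_wfe, pair.mr_wfe, init=init,
                                 params=params)
        mr_def = apply_deformation(pair.mr_wfe, field, interpolation="linear")
        ct_def = apply_deformation(pair.ct_reg, field, interpolation="linear")
        entries.append(PropagatedEntry(
            subject_id=pair.subject_id, ct_deformed=ct_def,
            mr_deformed=mr_def, field=field,
        ))
        log.info("propagated atlas pair %s onto target grid", pair.subject_id)
    return PropagatedAtlas(entries=entries,
                           target_grid_shape=target_mr_wfe.shape)
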