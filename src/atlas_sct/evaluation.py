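"""Tissue-region MAE evaluation and the leave-one-out / train-test drivers.

The reference for each subject is its deformed planning CT (``ct_reg``);
tissue regions come from ground-truth labels when available (phantoms) or
from CT clustering otherwise.  A body mask excludes the background from the
"entire image" region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .atlas import Atlas, AtlasPair, PropagatedAtlas, prepare_atlas_pair, propagate_atlas
from .config import (
    default_config,
    gre_params_from_config,
    reg_params_from_config,
    scale_from_config,
)
from .ct_conditioning import body_mask_from_air, classify_tissues_ct, mask_air
from .fusion import fuse
from .image_core import (
    LABEL_BONE,
    LABEL_FAT,
    LABEL_MUSCLE,
    LabelVolume,
    Volume,
    grids_match,
)

__all__ = [
    "EvaluationReport",
    "region_masks",
    "mae",
    "PreparedSubject",
    "prepare_subject",
    "leave_one_out",
    "train_test_eval",
    "aggregate_reports",
]

log = logging.getLogger(__name__)

REGIONS = ("entire", "bone", "fat", "muscle")


@dataclass
class EvaluationReport:
    subject_id: str
    mae_hu: dict  # region -> MAE in HU
    n_voxels: dict  # region -> voxel count
    single_atlas_mae: dict = dc_field(default_factory=dict)  # atlas id -> entire-region MAE
    config: dict = dc_field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mae_hu": {k: float(v) for k, v in self.mae_hu.items()},
            "n_voxels": {k: int(v) for k, v in self.n_voxels.items()},
            "single_atlas_mae": {k: float(v) for k, v in self.single_atlas_mae.items()},
        }


def region_masks(reference_labels: LabelVolume, body_mask: Volume) -> dict:
    """Masks for {entire, bone, fat, muscle}: tissue label within the body."""
    if reference_labels.shape != body_mask.shape:
        raise ValueError("labels and body mask grids differ")
    body = body_mask.data.astype(bool)
    if not body.any():
        raise ValueError("empty body mask")

    def _mk(arr):
        return Volume(arr.astype(np.uint8), body_mask.spacing, body_mask.origin,
                      body_mask.orientation, "MASK")

    lab = reference_labels.labels
    return {
        "entire": _mk(body),
        "bone": _mk((lab == LABEL_BONE) & body),
        "fat": _mk((lab == LABEL_FAT) & body),
        "muscle": _mk((lab == LABEL_MUSCLE) & body),
    }


def mae(reference: Volume, test: Volume, mask: Volume) -> float:
    """Mean absolute difference (HU) over the masked voxels."""
    if reference.shape != test.shape or reference.shape != mask.shape:
        raise ValueError("reference, test and mask must share one grid")
    sel = mask.data.astype(bool)
    if not sel.any():
        raise ValueError("empty mask")
    return float(np.mean(np.abs(reference.data[sel] - test.data[sel])))


# --------------------------------------------------------------------------
# Cohort drivers
# --------------------------------------------------------------------------

@dataclass
class PreparedSubject:
    """One subject conditioned once, reusable across leave-one-out splits."""

    subject_id: str
    pair: AtlasPair  # (ct_reg, mr_wfe) on the subject's own grid
    body_mask: Volume
    labels: LabelVolume  # reference tissue regions
    landmarks: dict


def prepare_subject(subject, config: dict | None = None) -> PreparedSubject:
    """Run the per-subject conditioning chain once.

    Ground-truth labels (phantoms) define the evaluation regions when the
    subject carries them; otherwise regions come from clustering the CT.
    """
    cfg = config or default_config()
    pair = prepare_atlas_pair(subject, cfg)

    labels = getattr(subject, "labels", None)
    if labels is None:
        air = mask_air(subject.ct)
        labels, _ = classify_tissues_ct(subject.ct, air, seed=int(cfg["seed"]))
    body = body_mask_from_air(mask_air(subject.ct))
    # keep interior air out of "entire" only if it lies outside the body
    return PreparedSubject(
        subject_id=subject.subject_id, pair=pair, body_mask=body,
        labels=labels, landmarks=dict(subject.landmarks),
    )


def _synthesize(prepared_target: PreparedSubject, atlas_pairs: list,
                cfg: dict):
    """Propagate the given pairs onto the target and fuse."""
    atlas = Atlas(pairs=atlas_pairs, standard_scale=scale_from_config(cfg),
                  build_config=cfg)
    prop = propagate_atlas(atlas, prepared_target.pair.mr_wfe,
                           prepared_target.landmarks,
                           params=reg_params_from_config(cfg))
    gre_params = gre_params_from_config(cfg, body_mask=prepared_target.body_mask)
    sct, gre = fuse(prop, prepared_target.pair.mr_wfe, gre_params)
    return sct, gre, prop


def evaluate_synthesis(prepared: PreparedSubject, sct: Volume,
                       prop: PropagatedAtlas, cfg: dict) -> EvaluationReport:
    masks = region_masks(prepared.labels, prepared.body_mask)
    reference = prepared.pair.ct_reg
    report_mae, counts = {}, {}
    for region, m in masks.items():
        n = int(m.data.sum())
        counts[region] = n
        if n > 0:
            report_mae[region] = mae(reference, sct, m)
    single = {
        e.subject_id: mae(reference, e.ct_deformed, masks["entire"])
        for e in prop.entries
    }
    return EvaluationReport(subject_id=prepared.subject_id, mae_hu=report_mae,
                            n_voxels=counts, single_atlas_mae=single,
                            config=cfg)


def leave_one_out(cohort, config: dict | None = None) -> list:
    """Each subject synthesized from an atlas of all remaining subjects."""
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs a cohort of >= 2 subjects")
    cfg = config or default_config()
    prepared = [prepare_subject(s, cfg) for s in cohort]
    reports = []
    for i, target in enumerate(prepared):
        pairs = [p.pair for j, p in enumerate(prepared) if j != i]
        sct, _gre, prop = _synthesize(target, pairs, cfg)
        reports.append(evaluate_synthesis(target, sct, prop, cfg))
        log.info("leave-one-out %s: entire-region MAE %.1f HU",
                 target.subject_id, reports[-1].mae_hu["entire"])
    return reports


def train_test_eval(train, test, config: dict | None = None) -> list:
    """One atlas from the training subjects, applied to every test subject."""
    train_ids = {s.subject_id for s in train}
    test_ids = {s.subject_id for s in test}
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"train/test subjects overlap: {sorted(overlap)}")
    cfg = config or default_config()
    train_prepared = [prepare_subject(s, cfg) for s in train]
    pairs = [p.pair for p in train_prepared]
    reports = []
    for subject in test:
        target = prepare_subject(subject, cfg)
        sct, _gre, prop = _synthesize(target, pairs, cfg)
        reports.append(evaluate_synthesis(target, sct, prop, cfg))
    return reports


def aggregate_reports(reports) -> dict:
    """Mean and population SD of the per-region MAE across subjects."""
    out = {}
    for region in REGIONS:
        vals = [r.mae_hu[region] for r in reports if region in r.mae_hu]
        if vals:
            arr = np.asarray(vals, dtype=float)
            out[region] = {"mean": float(arr.mean()),
                           "sd": float(arr.std()),
                           "n_subjects": len(vals)}
    return out
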