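"""Synthetic pelvis-like phantom cohorts: paired CT / water-MR / fat-MR
volumes with ground-truth labels, landmarks and deformations.

The generator renders a fixed template label map (body ellipse, fat ring,
muscle interior, two femoral-head spheres, a pelvic-ring annulus, a sacrum
block, one interior air pocket), warps it by a random smooth displacement
field per subject, draws per-tissue intensities, and corrupts the MR
channels with a smooth multiplicative bias and Rician noise.  Everything is
seeded, so cohorts regenerate bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_core import (
    LABEL_AIR_INSIDE,
    LABEL_BACKGROUND,
    LABEL_BONE,
    LABEL_FAT,
    LABEL_MUSCLE,
    LabelVolume,
    Volume,
    write_volume,
)
from .registration import DeformationField

__all__ = [
    "PhantomConfig",
    "PhantomSubject",
    "make_template",
    "make_subject",
    "make_cohort",
    "save_cohort",
]


class ConfigError(ValueError):
    """Phantom configuration cannot produce a valid template."""


# per-label (mean, sd) intensity conventions; not claims about real tissue
_CT_STATS = {
    LABEL_BACKGROUND: (-1000.0, 3.0),
    LABEL_AIR_INSIDE: (-1000.0, 3.0),
    LABEL_FAT: (-100.0, 15.0),
    LABEL_MUSCLE: (40.0, 10.0),
    LABEL_BONE: (700.0, 100.0),
}
_WATER_STATS = {
    LABEL_BACKGROUND: (10.0, 3.0),
    LABEL_AIR_INSIDE: (10.0, 3.0),
    LABEL_FAT: (35.0, 8.0),  # fat is near-air dark on water-only images
    LABEL_MUSCLE: (400.0, 30.0),
    LABEL_BONE: (60.0, 10.0),
}
_FAT_STATS = {
    LABEL_BACKGROUND: (10.0, 3.0),
    LABEL_AIR_INSIDE: (10.0, 3.0),
    LABEL_FAT: (400.0, 30.0),
    LABEL_MUSCLE: (60.0, 10.0),
    LABEL_BONE: (50.0, 10.0),
}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    ct_stats: dict = field(default_factory=lambda: dict(_CT_STATS))
    water_stats: dict = field(default_factory=lambda: dict(_WATER_STATS))
    fat_stats: dict = field(default_factory=lambda: dict(_FAT_STATS))
    deformation_amplitude_mm: float = 5.0
    deformation_smoothness_mm: float = 15.0
    bias_amplitude: float = 0.2
    mr_noise_sigma: float = 5.0
    ct_noise_sigma: float = 0.0
    mr_noise_model: str = "rician"

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ConfigError("phantom grid must be >= 32 voxels per axis")
        if self.deformation_amplitude_mm < 0 or self.bias_amplitude < 0:
            raise ConfigError("amplitudes must be >= 0")
        if self.bias_amplitude >= 1.0:
            raise ConfigError("bias amplitude must be < 1 (gain must stay positive)")
        if self.mr_noise_model not in ("rician", "gaussian"):
            raise ConfigError(f"unknown noise model {self.mr_noise_model!r}")


@dataclass
class PhantomSubject:
    subject_id: str
    ct: Volume
    water: Volume
    fat: Volume
    labels: LabelVolume
    landmarks: dict
    truth_field: DeformationField | None
    seed: int


# --------------------------------------------------------------------------
# Template
# --------------------------------------------------------------------------

def make_template(cfg: PhantomConfig) -> tuple[LabelVolume, dict]:
    """Deterministic pelvis-like label map plus named landmark points (mm)."""
    nx, ny, nz = cfg.shape
    sp = np.asarray(cfg.spacing, dtype=float)
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0

    labels = np.zeros(cfg.shape, dtype=np.int16)

    # body: elliptical cylinder
    ax_body, ay_body = 0.42 * nx, 0.40 * ny
    body = ((ix - cx) / ax_body) ** 2 + ((iy - cy) / ay_body) ** 2 <= 1.0
    labels[body] = LABEL_MUSCLE

    # subcutaneous fat ring: body minus eroded body
    erode_vox = max(3, int(round(0.05 * nx)))
    interior = ndimage.binary_erosion(body, iterations=erode_vox)
    labels[body & ~interior] = LABEL_FAT

    # femoral-head spheres (trochanter analogs)
    r_fem = 0.09 * nx
    lm_l = np.array([cx - 0.24 * nx, cy + 0.04 * ny, cz])
    lm_r = np.array([cx + 0.24 * nx, cy + 0.04 * ny, cz])
    for c in (lm_l, lm_r):
        sph = ((ix - c[0]) * sp[0] / (r_fem * sp[0])) ** 2 + \
              ((iy - c[1]) / r_fem) ** 2 + \
              ((iz - c[2]) * sp[2] / (r_fem * sp[0])) ** 2 <= 1.0
        labels[sph & body] = LABEL_BONE

    # pelvic-ring annulus in the central axial band
    r_ring = 0.16 * min(nx, ny)
    ring_rad = np.sqrt(((ix - cx)) ** 2 + ((iy - cy + 0.02 * ny)) ** 2)
    band = np.abs(iz - cz) <= 0.28 * nz
    ring = (np.abs(ring_rad - r_ring) <= 2.0) & band
    labels[ring & body] = LABEL_BONE

    # sacrum block, posterior midline
    sac = (
        (np.abs(ix - cx) <= 0.06 * nx)
        & (iy - cy >= 0.18 * ny)
        & (iy - cy <= 0.30 * ny)
        & (np.abs(iz - cz) <= 0.3 * nz)
    )
    labels[sac & body] = LABEL_BONE
    lm_sac = np.array([cx, cy + 0.24 * ny, cz])

    # anterior pubic point on the ring (for a non-coplanar 4th landmark)
    lm_pub = np.array([cx, cy - 0.02 * ny - r_ring, cz + 0.15 * nz])

    # interior air pocket ("rectum"), anterior to the sacrum
    r_air = 0.05 * min(nx, ny)
    air = (
        np.sqrt((ix - cx) ** 2 + (iy - cy - 0.10 * ny) ** 2) <= r_air
    ) & (np.abs(iz - cz) <= 0.2 * nz)
    labels[air & interior] = LABEL_AIR_INSIDE

    if not np.any(labels == LABEL_BONE) or not np.any(labels == LABEL_FAT):
        raise ConfigError("grid too small to contain the template structures")

    lv = LabelVolume(labels=labels, spacing=sp, origin=np.zeros(3),
                     orientation=np.eye(3))
    landmarks = {
        "trochanter_l": (lm_l * sp).tolist(),
        "trochanter_r": (lm_r * sp).tolist(),
        "sacrum": (lm_sac * sp).tolist(),
        "pubis": (lm_pub * sp).tolist(),
    }
    return lv, landmarks


# --------------------------------------------------------------------------
# Subject synthesis
# --------------------------------------------------------------------------

def _random_smooth_field(shape, spacing, amplitude_mm, smoothness_mm,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-component white noise smoothed to the given correlation length and
    rescaled so the maximum displacement magnitude equals ``amplitude_mm``."""
    disp = np.zeros(tuple(shape) + (3,))
    if amplitude_mm == 0:
        return disp
    sigma_vox = [smoothness_mm / s for s in spacing]
    for c in range(3):
        noise = rng.standard_normal(shape)
        disp[..., c] = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    mag = np.sqrt(np.sum(disp ** 2, axis=-1))
    peak = mag.max()
    if peak > 0:
        disp *= amplitude_mm / peak
    return disp


def _warp_labels(labels: np.ndarray, disp: np.ndarray, spacing) -> np.ndarray:
    """Nearest-neighbour pull-back warp of a label map (fill: background)."""
    shape = labels.shape
    idx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    coords = [idx[a] + disp[..., a] / spacing[a] for a in range(3)]
    out = ndimage.map_coordinates(labels, coords, order=0, mode="constant",
                                  cval=LABEL_BACKGROUND)
    return out.astype(np.int16)


def _warp_point(point_mm: np.ndarray, disp: np.ndarray, spacing) -> np.ndarray:
    """Invert the pull-back field at one point: find p_s with
    template(p_t) rendered at p_s where p_t = p_s + d(p_s)."""
    p = np.asarray(point_mm, dtype=float).copy()
    target = np.asarray(point_mm, dtype=float)
    for _ in range(20):
        idx = (p / spacing).reshape(3, 1)
        d = np.array([
            ndimage.map_coordinates(disp[..., a], idx, order=1,
                                    mode="nearest")[0]
            for a in range(3)
        ])
        p_new = target - d
        if np.max(np.abs(p_new - p)) < 1e-6:
            p = p_new
            break
        p = p_new
    return p


def render_volumes(labels: LabelVolume, cfg: PhantomConfig,
                   rng: np.random.Generator):
    """Draw per-tissue intensities for (ct, water, fat) from a label map."""
    out = []
    for stats, tag in ((cfg.ct_stats, "CT"), (cfg.water_stats, "MR_WATER"),
                       (cfg.fat_stats, "MR_FAT")):
        img = np.zeros(labels.shape, dtype=float)
        for code, (mean, sd) in stats.items():
            sel = labels.labels == code
            n = int(sel.sum())
            if n == 0:
                continue
            img[sel] = mean + sd * rng.standard_normal(n) if sd > 0 else mean
        if tag != "CT":
            img = np.clip(img, 0.0, None)
        out.append(Volume(img, labels.spacing, labels.origin,
                          labels.orientation, tag))
    return tuple(out)


def _smooth_bias(shape, spacing, amplitude, rng: np.random.Generator,
                 smoothness_mm: float = 40.0) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    sigma_vox = [smoothness_mm / s for s in spacing]
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    peak = np.abs(g).max()
    if peak > 0:
        g = g / peak
    return 1.0 + amplitude * g


def _add_mr_noise(img: np.ndarray, sigma: float, model: str,
                  rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return img
    if model == "rician":
        n1 = rng.standard_normal(img.shape) * sigma
        n2 = rng.standard_normal(img.shape) * sigma
        return np.sqrt((img + n1) ** 2 + n2 ** 2)
    return np.clip(img + rng.standard_normal(img.shape) * sigma, 0.0, None)


def make_subject(cfg: PhantomConfig, seed: int,
                 subject_id: str | None = None) -> PhantomSubject:
    """One phantom subject: warped template + rendered, corrupted volumes."""
    rng = np.random.default_rng(seed)
    template, template_landmarks = make_template(cfg)
    sp = template.spacing

    disp = _random_smooth_field(cfg.shape, sp, cfg.deformation_amplitude_mm,
                                cfg.deformation_smoothness_mm, rng)
    warped = _warp_labels(template.labels, disp, sp)
    labels = LabelVolume(warped, sp, template.origin, template.orientation)

    ct, water, fat = render_volumes(labels, cfg, rng)
    if cfg.ct_noise_sigma > 0:
        ct = ct.with_data(ct.data + rng.standard_normal(ct.shape) * cfg.ct_noise_sigma)

    bias_w = _smooth_bias(cfg.shape, sp, cfg.bias_amplitude, rng)
    bias_f = _smooth_bias(cfg.shape, sp, cfg.bias_amplitude, rng)
    water = water.with_data(
        _add_mr_noise(water.data * bias_w, cfg.mr_noise_sigma,
                      cfg.mr_noise_model, rng))
    fat = fat.with_data(
        _add_mr_noise(fat.data * bias_f, cfg.mr_noise_sigma,
                      cfg.mr_noise_model, rng))

    landmarks = {
        name: _warp_point(np.asarray(p), disp, sp).tolist()
        for name, p in template_landmarks.items()
    }
    truth = DeformationField(disp, sp, template.origin, template.orientation)
    return PhantomSubject(
        subject_id=subject_id or f"phantom_seed{seed}",
        ct=ct, water=water, fat=fat, labels=labels,
        landmarks=landmarks, truth_field=truth, seed=seed,
    )


def make_cohort(cfg: PhantomConfig, n: int, master_seed: int) -> list[PhantomSubject]:
    """n phantom subjects with per-subject seeds derived from a master seed."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n)
    return [
        make_subject(cfg, int(seeds[i]), subject_id=f"phantom_{i:02d}")
        for i in range(n)
    ]


def save_cohort(subjects: list[PhantomSubject], outdir: str | Path,
                cfg: PhantomConfig | None = None) -> Path:
    """Write NIfTI volumes, landmark JSON files and a cohort manifest.

    Returns the path of the cohort YAML consumable by the CLI.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in subjects:
        base = outdir / s.subject_id
        write_volume(s.ct, f"{base}_ct.nii.gz")
        write_volume(s.water, f"{base}_water.nii.gz")
        write_volume(s.fat, f"{base}_fat.nii.gz")
        write_volume(s.labels.as_volume(), f"{base}_labels.nii.gz")
        lm_path = f"{base}_landmarks.json"
        with open(lm_path, "w") as fh:
            json.dump(s.landmarks, fh, indent=2)
        entries.append({
            "id": s.subject_id,
            "ct": f"{base}_ct.nii.gz",
            "water": f"{base}_water.nii.gz",
            "fat": f"{base}_fat.nii.gz",
            "labels": f"{base}_labels.nii.gz",
            "landmarks": lm_path,
            "seed": int(s.seed),
        })
    manifest = {"subjects": entries}
    if cfg is not None:
        manifest["phantom_config"] = {
            "shape": list(cfg.shape), "spacing": list(cfg.spacing),
            "deformation_amplitude_mm": cfg.deformation_amplitude_mm,
            "bias_amplitude": cfg.bias_amplitude,
            "mr_noise_sigma": cfg.mr_noise_sigma,
        }
    cohort_yaml = outdir / "cohort.yaml"
    with open(cohort_yaml, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return cohort_yaml
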