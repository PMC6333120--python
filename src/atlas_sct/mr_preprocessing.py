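"""MR intensity conditioning: bias reduction, landmark standardization, and
the fat-enhanced water image.

The chain applied to every Dixon series is
``correct_bias -> detect_landmarks -> standardize`` and, for the water/fat
pair, ``fat_enhance`` blends the two standardized images into the single
image used for atlas propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_core import GeometryError, ValidationError, Volume, grids_match

__all__ = [
    "TissueLandmarks",
    "StandardScale",
    "BiasField",
    "DegenerateInputError",
    "fuzzy_c_means",
    "correct_bias",
    "detect_landmarks",
    "standardize",
    "fat_enhance",
    "preprocess_mr",
]

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Input lacks the structure required by a clustering operation."""


@dataclass(frozen=True)
class TissueLandmarks:
    """Histogram landmarks: dark-cluster mode, inter-mode valley, bright mode."""

    dark_mode: float
    valley: float
    bright_mode: float
    source_modality: str = "MR_WATER"

    def __post_init__(self) -> None:
        vals = (self.dark_mode, self.valley, self.bright_mode)
        if not all(np.isfinite(vals)) or any(v < 0 for v in vals):
            raise ValidationError(f"landmarks must be finite and >= 0: {vals}")
        if not (self.dark_mode < self.valley < self.bright_mode):
            raise ValidationError(
                f"landmarks must be strictly increasing: {vals}"
            )


@dataclass(frozen=True)
class StandardScale:
    """Target intensity frame for landmark standardization.

    The absolute values are a convention; only the relative placement of the
    dark/valley/bright anchors matters downstream.
    """

    s_dark: float = 100.0
    s_valley: float = 500.0
    s_bright: float = 1000.0
    s_max: float = 1200.0

    def __post_init__(self) -> None:
        if not (0 <= self.s_dark < self.s_valley < self.s_bright < self.s_max):
            raise ValueError(
                "standard scale must satisfy 0 <= dark < valley < bright < max"
            )


@dataclass
class BiasField:
    """Multiplicative gain field estimated slice-by-slice (sagittal)."""

    field: np.ndarray
    basis_order: int

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise ValidationError("bias field must be strictly positive")


# --------------------------------------------------------------------------
# Fuzzy c-means
# --------------------------------------------------------------------------

def _quantile_init(samples: np.ndarray, k: int) -> np.ndarray:
    """Deterministic spread-out initialization for 1-D clustering.

    Quantile seeding avoids the occasional k-means++ draw that lands two
    centers inside one heavy mode and drags FCM into a bad local optimum.
    """
    centers = np.quantile(samples, (np.arange(k) + 0.5) / k)
    if np.unique(centers).size < k:
        uniq = np.unique(samples)
        centers = uniq[np.linspace(0, uniq.size - 1, k).astype(int)]
    return np.sort(centers.astype(float))


def fuzzy_c_means(
    samples,
    k: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    return_objective: bool = False,
):
    """Fuzzy c-means on 1-D intensity samples.

    Returns ``(centers, memberships)`` with centers ascending and memberships
    of shape ``(n_samples, k)`` summing to one per sample.  With
    ``return_objective=True`` the per-iteration objective trace is appended.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise DegenerateInputError("empty sample set")
    if k < 1:
        raise ValueError("k must be >= 1")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    n_distinct = np.unique(samples).size
    if k > n_distinct:
        raise DegenerateInputError(
            f"k={k} exceeds the {n_distinct} distinct sample values"
        )

    if k == 1:
        centers = np.array([samples.mean()])
        memberships = np.ones((samples.size, 1))
        if return_objective:
            obj = float(np.sum((samples - centers[0]) ** 2))
            return centers, memberships, [obj]
        return centers, memberships

    centers = _quantile_init(samples, k)
    m = fuzzifier
    objective: list[float] = []
    for _ in range(max_iter):
        d2 = (samples[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-12)
        inv = (1.0 / d2) ** (1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        objective.append(float(np.sum(um * d2)))
        new_centers = (um * samples[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            break

    order = np.argsort(centers)
    centers = centers[order]
    d2 = np.maximum((samples[:, None] - centers[None, :]) ** 2, 1e-12)
    inv = (1.0 / d2) ** (1.0 / (m - 1.0))
    u = inv / inv.sum(axis=1, keepdims=True)
    if return_objective:
        return centers, u, objective
    return centers, u


# --------------------------------------------------------------------------
# Bias correction
# --------------------------------------------------------------------------

def _poly_basis_2d(shape: tuple[int, int], order: int) -> np.ndarray:
    """Design matrix of 2-D monomials up to total degree ``order``."""
    ny, nz = shape
    y = np.linspace(-1.0, 1.0, ny)
    z = np.linspace(-1.0, 1.0, nz)
    yy, zz = np.meshgrid(y, z, indexing="ij")
    cols = [
        (yy ** p * zz ** q).ravel()
        for p in range(order + 1)
        for q in range(order + 1 - p)
    ]
    return np.column_stack(cols)


def _correct_bias_slice(
    img: np.ndarray,
    basis: np.ndarray,
    k: int,
    fuzzifier: float,
    n_iter: int,
    seed: int,
) -> np.ndarray:
    """Estimate a multiplicative polynomial gain on one sagittal slice.

    Alternates FCM-style center/membership updates with a weighted
    least-squares fit of the gain, minimizing
    sum_k sum_x u_k(x)^m (I(x) - b(x) c_k)^2.
    """
    flat = img.ravel().astype(float)
    fg = flat > 0
    if fg.sum() < k + 1 or np.unique(flat[fg]).size <= k:
        return np.ones_like(flat).reshape(img.shape)

    b = np.ones_like(flat)
    # initialize centers from plain FCM on raw intensities
    centers, _ = fuzzy_c_means(flat[fg], k=k, fuzzifier=fuzzifier,
                               max_iter=50, seed=seed)
    m = fuzzifier
    phi = basis
    for _ in range(n_iter):
        corrected = flat[fg] / b[fg]
        d2 = np.maximum((corrected[:, None] - centers[None, :]) ** 2, 1e-12)
        inv = (1.0 / d2) ** (1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        # center update with the current gain divided out
        centers = (um * corrected[:, None]).sum(axis=0) / np.maximum(
            um.sum(axis=0), 1e-12
        )
        centers = np.sort(centers)
        # gain update: weighted LS of b(x) ~ y(x)/a(x) with weights a(x)
        a = (um * centers[None, :] ** 2).sum(axis=1)
        y = (um * centers[None, :]).sum(axis=1) * flat[fg]
        phif = phi[fg]
        ata = phif.T @ (a[:, None] * phif)
        aty = phif.T @ y
        try:
            beta = np.linalg.solve(ata, aty)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(ata, aty, rcond=None)
        b_new = phi @ beta
        # multiplicative MR bias is gentle; clamp extrapolation outside the body
        b_new = np.clip(b_new, 0.5, 2.0)
        mean_fg = b_new[fg].mean()
        if mean_fg <= 0:
            b_new = np.ones_like(b_new)
        else:
            b_new = b_new / mean_fg
        centers = centers * 1.0  # scale absorbed by normalization
        b = b_new
    return b.reshape(img.shape)


def correct_bias(
    v: Volume,
    basis_order: int = 2,
    k: int = 3,
    fuzzifier: float = 2.0,
    n_iter: int = 20,
    seed: int = 0,
) -> tuple[Volume, BiasField]:
    """Reduce multiplicative intensity inhomogeneity slice-by-slice.

    Applied along the sagittal direction (axis 0), where field
    inhomogeneity is most pronounced.  The per-slice gain is normalized to
    mean 1 over the foreground so the global intensity scale is preserved.
    """
    if v.modality_tag not in ("MR_WATER", "MR_FAT", "MR_WFE"):
        raise ValueError(f"bias correction expects an MR volume, got {v.modality_tag}")
    if np.any(v.data < 0):
        raise ValueError("MR intensities must be non-negative")

    data = v.data.astype(float)
    gain = np.ones_like(data)
    basis = _poly_basis_2d(data.shape[1:], basis_order)
    for i in range(data.shape[0]):
        sl = data[i]
        if not np.any(sl > 0):
            log.warning("bias correction: all-zero sagittal slice %d skipped", i)
            continue
        gain[i] = _correct_bias_slice(sl, basis, k, fuzzifier, n_iter, seed)
    corrected = data / gain
    return v.with_data(corrected), BiasField(field=gain, basis_order=basis_order)


# --------------------------------------------------------------------------
# Landmark detection and standardization
# --------------------------------------------------------------------------

def _smoothed_histogram(values: np.ndarray, bins: int, window: int,
                        lo: float, hi: float):
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    if window > 1:
        kernel = np.ones(window) / window
        counts = np.convolve(counts.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def detect_landmarks(
    v: Volume,
    seed: int = 0,
    hist_bins: int = 256,
    smooth_window: int = 5,
    fuzzifier: float = 2.0,
    max_samples: int = 200_000,
) -> TissueLandmarks:
    """Find (dark mode, valley, bright mode) on a bias-corrected MR image.

    FCM with k=2 on the image intensities splits dark from bright (hard
    assignment at the inter-center midpoint); each cluster's
    smoothed-histogram mode gives a landmark and the full histogram's
    interior minimum between them gives the valley.
    """
    vals = v.data.ravel().astype(float)
    if np.unique(vals).size < 2:
        raise DegenerateInputError("constant image: no two intensity clusters")

    rng = np.random.default_rng(seed)
    sample = vals if vals.size <= max_samples else rng.choice(vals, max_samples,
                                                              replace=False)
    centers, u = fuzzy_c_means(sample, k=2, fuzzifier=fuzzifier, seed=seed)
    # hard split of the *full* volume (dark cluster includes sub-threshold voxels)
    boundary = 0.5 * (centers[0] + centers[1])
    dark = vals[vals <= boundary]
    bright = vals[vals > boundary]
    if dark.size == 0 or bright.size == 0:
        raise DegenerateInputError("degenerate dark/bright split")

    lo, hi = np.percentile(vals, [0.1, 99.9])
    if hi <= lo:
        raise DegenerateInputError("no dynamic range in image")
    counts_d, centers_d = _smoothed_histogram(dark, hist_bins, smooth_window, lo, hi)
    counts_b, centers_b = _smoothed_histogram(bright, hist_bins, smooth_window, lo, hi)
    counts_all, centers_all = _smoothed_histogram(vals, hist_bins, smooth_window, lo, hi)

    dark_mode = float(centers_d[np.argmax(counts_d)])
    bright_mode = float(centers_b[np.argmax(counts_b)])
    if bright_mode <= dark_mode:
        raise DegenerateInputError("cluster modes are not separated")

    interior = (centers_all > dark_mode) & (centers_all < bright_mode)
    if not np.any(interior):
        valley = 0.5 * (dark_mode + bright_mode)
        log.warning("no interior histogram bin between modes; using midpoint")
    else:
        sub = counts_all[interior]
        # ties (e.g. a run of empty bins) resolve to the middle of the run
        minimal = np.flatnonzero(sub <= sub.min() + 1e-12)
        valley = float(centers_all[interior][minimal[len(minimal) // 2]])
        if not (dark_mode < valley < bright_mode):
            valley = 0.5 * (dark_mode + bright_mode)
            log.warning("unimodal histogram between modes; valley set to midpoint")
    lm = TissueLandmarks(dark_mode=max(dark_mode, 0.0), valley=valley,
                         bright_mode=bright_mode, source_modality=v.modality_tag)
    log.info("landmarks (%s): dark=%.2f valley=%.2f bright=%.2f",
             v.modality_tag, lm.dark_mode, lm.valley, lm.bright_mode)
    return lm


def piecewise_linear_map(
    x: np.ndarray,
    anchors_in,
    anchors_out,
    lo_clip: float,
    hi_clip: float,
) -> np.ndarray:
    """Monotone piecewise-linear map through anchor pairs, linearly extended
    beyond the first/last anchor and clamped to [lo_clip, hi_clip]."""
    xi = np.asarray(anchors_in, dtype=float)
    yi = np.asarray(anchors_out, dtype=float)
    if np.any(np.diff(xi) <= 0) or np.any(np.diff(yi) <= 0):
        raise ValueError("anchors must be strictly increasing on both axes")
    y = np.interp(x, xi, yi)
    lo_slope = (yi[1] - yi[0]) / (xi[1] - xi[0])
    hi_slope = (yi[-1] - yi[-2]) / (xi[-1] - xi[-2])
    below = x < xi[0]
    above = x > xi[-1]
    y = np.where(below, yi[0] + (x - xi[0]) * lo_slope, y)
    y = np.where(above, yi[-1] + (x - xi[-1]) * hi_slope, y)
    return np.clip(y, lo_clip, hi_clip)


def standardize(v: Volume, lm: TissueLandmarks, scale: StandardScale) -> Volume:
    """Piecewise-linear remap sending the image landmarks onto the scale."""
    out = piecewise_linear_map(
        v.data.astype(float),
        (lm.dark_mode, lm.valley, lm.bright_mode),
        (scale.s_dark, scale.s_valley, scale.s_bright),
        lo_clip=0.0,
        hi_clip=scale.s_max,
    )
    return v.with_data(out)


def fat_enhance(water_std: Volume, fat_std: Volume, alpha: float = 0.5) -> Volume:
    """Blend standardized water and fat images: (W + alpha * F) / (1 + alpha)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not grids_match(water_std, fat_std):
        raise GeometryError("water and fat images must share one grid")
    blended = (water_std.data.astype(float) + alpha * fat_std.data.astype(float)) / (1.0 + alpha)
    return water_std.with_data(blended, modality_tag="MR_WFE")


def preprocess_mr(
    water: Volume,
    fat: Volume,
    scale: StandardScale,
    alpha: float = 0.5,
    bias_basis_order: int = 2,
    bias_k: int = 3,
    bias_iter: int = 20,
    hist_bins: int = 256,
    smooth_window: int = 5,
    seed: int = 0,
    skip_bias: bool = False,
):
    """Full MR conditioning chain for one subject.

    Returns ``(water_std, fat_std, wfe, water_landmarks)``.
    """
    results = []
    landmarks_water = None
    for vol in (water, fat):
        if skip_bias:
            corrected = vol
        else:
            corrected, _ = correct_bias(vol, basis_order=bias_basis_order,
                                        k=bias_k, n_iter=bias_iter, seed=seed)
        lm = detect_landmarks(corrected, seed=seed, hist_bins=hist_bins,
                              smooth_window=smooth_window)
        if vol is water:
            landmarks_water = lm
        results.append(standardize(corrected, lm, scale))
    water_std, fat_std = results
    wfe = fat_enhance(water_std, fat_std, alpha=alpha)
    return water_std, fat_std, wfe, landmarks_water
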