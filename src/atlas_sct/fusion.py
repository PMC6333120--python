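"""Generalized registration error (GRE) and 1/GRE-weighted CT fusion.

GRE at a voxel is the geometric mean of the squared mean, variance and
Shannon entropy of the in-plane patch of the difference between the target
and one propagated atlas MR image.  A small 2-D search (default radius
2 mm) finds each atlas's best in-plane offset per voxel; the synthetic CT
is the 1/GRE-weighted average of the (offset-corrected) atlas CT values.

The dense per-volume computation runs in a numba kernel; the scalar
``patch_stats`` / ``gre_at`` / ``neighborhood_search`` functions define the
reference semantics and are what the kernel is tested against.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from numba import njit, prange

from .image_core import Volume, grids_match

__all__ = [
    "GREParams",
    "GREMap",
    "patch_stats",
    "gre_at",
    "candidate_offsets",
    "neighborhood_search",
    "gre_search_volume",
    "fuse",
]

log = logging.getLogger(__name__)


@dataclass
class GREParams:
    """Settings for the GRE metric and its in-plane search."""

    patch_radius_vox: int = 2
    entropy_bins: int = 32
    epsilon: float = 1e-6
    search_radius_mm: float = 2.0
    body_mask: Volume | None = None

    def __post_init__(self) -> None:
        if self.patch_radius_vox < 1:
            raise ValueError("patch_radius_vox must be >= 1")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.search_radius_mm < 0:
            raise ValueError("search_radius_mm must be >= 0")


@dataclass
class GREMap:
    """Per-atlas minimum GRE values and winning in-plane offsets."""

    gre_min: np.ndarray  # (n_atlas, nx, ny, nz)
    best_offset: np.ndarray  # (n_atlas, nx, ny, nz, 2) integer voxels

    def __post_init__(self) -> None:
        if self.gre_min.ndim != 4 or self.best_offset.ndim != 5:
            raise ValueError("GREMap arrays have wrong rank")
        if self.best_offset.shape[:4] != self.gre_min.shape:
            raise ValueError("GREMap arrays are inconsistent")


# --------------------------------------------------------------------------
# Reference (scalar) semantics
# --------------------------------------------------------------------------

def patch_stats(diff_patch, entropy_bins: int = 32):
    """(squared mean, population variance, Shannon entropy in bits) of a patch.

    Entropy uses ``entropy_bins`` equal-width bins spanning the patch's own
    [min, max]; a single-valued patch has entropy 0.
    """
    vals = np.asarray(diff_patch, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty patch")
    m = vals.mean()
    m2 = m * m
    var = vals.var()
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        ent = 0.0
    else:
        counts, _ = np.histogram(vals, bins=entropy_bins, range=(lo, hi))
        p = counts[counts > 0] / vals.size
        ent = float(-np.sum(p * np.log2(p)))
    return float(m2), float(var), ent


def candidate_offsets(spacing_in_plane, search_radius_mm: float) -> np.ndarray:
    """Integer in-plane offsets with physical length <= the search radius,
    ordered by (magnitude, row, col) so ties resolve to the smaller offset."""
    si, sj = float(spacing_in_plane[0]), float(spacing_in_plane[1])
    ri = int(math.floor(search_radius_mm / si)) if si > 0 else 0
    rj = int(math.floor(search_radius_mm / sj)) if sj > 0 else 0
    offs = []
    for i in range(-ri, ri + 1):
        for j in range(-rj, rj + 1):
            d = math.hypot(i * si, j * sj)
            if d <= search_radius_mm + 1e-12:
                offs.append((d, i, j))
    offs.sort()
    return np.array([(i, j) for _, i, j in offs], dtype=np.int64)


def _patch_diff(target: np.ndarray, atlas: np.ndarray, voxel, offset,
                radius: int) -> np.ndarray:
    """In-plane difference patch centered at ``voxel``, the atlas patch
    displaced by ``offset``; clipped to the voxels valid in both images."""
    x, y, z = voxel
    oi, oj = int(offset[0]), int(offset[1])
    nx, ny = target.shape[0], target.shape[1]
    vals = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            ti, tj = x + di, y + dj
            ai, aj = ti + oi, tj + oj
            if 0 <= ti < nx and 0 <= tj < ny and 0 <= ai < nx and 0 <= aj < ny:
                vals.append(target[ti, tj, z] - atlas[ai, aj, z])
    return np.array(vals, dtype=float)


def gre_at(target_mr: Volume, atlas_mr: Volume, voxel,
           params: GREParams | None = None, offset=(0, 0)) -> float:
    """GRE = ((m2 + eps) * (var + eps) * (ent + eps)) ** (1/3) at one voxel."""
    params = params or GREParams()
    diff = _patch_diff(target_mr.data, atlas_mr.data, voxel, offset,
                       params.patch_radius_vox)
    if diff.size == 0:
        return float("inf")
    m2, var, ent = patch_stats(diff, params.entropy_bins)
    e = params.epsilon
    return float(((m2 + e) * (var + e) * (ent + e)) ** (1.0 / 3.0))


def neighborhood_search(target_mr: Volume, atlas_mr: Volume, voxel,
                        params: GREParams | None = None):
    """Best in-plane offset (by GRE) within the search radius at one voxel."""
    params = params or GREParams()
    offsets = candidate_offsets(target_mr.spacing[:2], params.search_radius_mm)
    best_off, best = (0, 0), float("inf")
    for off in offsets:
        g = gre_at(target_mr, atlas_mr, voxel, params, offset=off)
        if g < best:  # strict: earlier (smaller-magnitude) offsets win ties
            best, best_off = g, (int(off[0]), int(off[1]))
    return best_off, best


# --------------------------------------------------------------------------
# Dense numba kernel
# --------------------------------------------------------------------------

@njit(cache=True, parallel=True)
def _gre_search_kernel(target, atlas, mask, offsets, radius, bins, eps,
                       gre_out, off_out):  # pragma: no cover - jit
    nx, ny, nz = target.shape
    n_off = offsets.shape[0]
    side = 2 * radius + 1
    for flat in prange(nx * ny * nz):
        z = flat % nz
        y = (flat // nz) % ny
        x = flat // (nz * ny)
        if mask[x, y, z] == 0:
            continue
        best = np.inf
        best_i = 0
        best_j = 0
        buf = np.empty(side * side)
        hist = np.empty(bins, dtype=np.int64)
        for o in range(n_off):
            oi = offsets[o, 0]
            oj = offsets[o, 1]
            cnt = 0
            s = 0.0
            s2 = 0.0
            for di in range(-radius, radius + 1):
                ti = x + di
                ai = ti + oi
                if ti < 0 or ti >= nx or ai < 0 or ai >= nx:
                    continue
                for dj in range(-radius, radius + 1):
                    tj = y + dj
                    aj = tj + oj
                    if tj < 0 or tj >= ny or aj < 0 or aj >= ny:
                        continue
                    d = target[ti, tj, z] - atlas[ai, aj, z]
                    buf[cnt] = d
                    s += d
                    s2 += d * d
                    cnt += 1
            if cnt == 0:
                continue
            mean = s / cnt
            m2 = mean * mean
            var = s2 / cnt - m2
            if var < 0.0:
                var = 0.0
            lo = buf[0]
            hi = buf[0]
            for q in range(1, cnt):
                if buf[q] < lo:
                    lo = buf[q]
                if buf[q] > hi:
                    hi = buf[q]
            ent = 0.0
            if hi > lo:
                for b in range(bins):
                    hist[b] = 0
                width = (hi - lo) / bins
                for q in range(cnt):
                    b = int((buf[q] - lo) / width)
                    if b >= bins:
                        b = bins - 1
                    hist[b] += 1
                for b in range(bins):
                    if hist[b] > 0:
                        p = hist[b] / cnt
                        ent -= p * np.log2(p)
            g = ((m2 + eps) * (var + eps) * (ent + eps)) ** (1.0 / 3.0)
            if g < best:
                best = g
                best_i = oi
                best_j = oj
        gre_out[x, y, z] = best
        off_out[x, y, z, 0] = best_i
        off_out[x, y, z, 1] = best_j


@njit(cache=True, parallel=True)
def _fuse_kernel(cts, gres, offs, mask, fill, out):  # pragma: no cover - jit
    n_atlas, nx, ny, nz = cts.shape
    for flat in prange(nx * ny * nz):
        z = flat % nz
        y = (flat // nz) % ny
        x = flat // (nz * ny)
        if mask[x, y, z] == 0:
            out[x, y, z] = fill
            continue
        wsum = 0.0
        vsum = 0.0
        for a in range(n_atlas):
            w = 1.0 / gres[a, x, y, z]
            xi = x + offs[a, x, y, z, 0]
            yj = y + offs[a, x, y, z, 1]
            if xi < 0:
                xi = 0
            elif xi >= nx:
                xi = nx - 1
            if yj < 0:
                yj = 0
            elif yj >= ny:
                yj = ny - 1
            wsum += w
            vsum += w * cts[a, xi, yj, z]
        out[x, y, z] = vsum / wsum


def gre_search_volume(target_mr: Volume, atlas_mr: Volume,
                      params: GREParams) -> tuple[np.ndarray, np.ndarray]:
    """Dense minimum-GRE map and best offsets for one atlas image."""
    if not grids_match(target_mr, atlas_mr):
        raise ValueError("target and atlas MR must share one grid")
    offsets = candidate_offsets(target_mr.spacing[:2], params.search_radius_mm)
    if params.body_mask is not None:
        mask = params.body_mask.data.astype(np.uint8)
    else:
        mask = np.ones(target_mr.shape, dtype=np.uint8)
    gre = np.full(target_mr.shape, params.epsilon, dtype=np.float64)
    off = np.zeros(target_mr.shape + (2,), dtype=np.int64)
    _gre_search_kernel(
        target_mr.data.astype(np.float64), atlas_mr.data.astype(np.float64),
        mask, offsets, params.patch_radius_vox, params.entropy_bins,
        params.epsilon, gre, off,
    )
    return gre, off


def fuse(prop, target_mr_wfe: Volume, params: GREParams | None = None):
    """1/GRE-weighted fusion of a propagated atlas into a synthetic CT.

    ``prop`` is a PropagatedAtlas (or any object with ``entries`` holding
    ``ct_deformed`` / ``mr_deformed`` volumes on the target grid).  Returns
    ``(sct, gre_map)``; voxels outside the body mask get -1000 HU.
    """
    params = params or GREParams()
    entries = list(prop.entries)
    if not entries:
        raise ValueError("empty propagated atlas")
    for e in entries:
        if not grids_match(e.mr_deformed, target_mr_wfe):
            raise ValueError("propagated entries must be on the target grid")

    gres = np.empty((len(entries),) + target_mr_wfe.shape)
    offs = np.empty((len(entries),) + target_mr_wfe.shape + (2,), dtype=np.int64)
    cts = np.empty((len(entries),) + target_mr_wfe.shape)
    for i, e in enumerate(entries):
        gres[i], offs[i] = gre_search_volume(target_mr_wfe, e.mr_deformed, params)
        cts[i] = e.ct_deformed.data.astype(np.float64)

    if params.body_mask is not None:
        mask = params.body_mask.data.astype(np.uint8)
    else:
        mask = np.ones(target_mr_wfe.shape, dtype=np.uint8)
    out = np.empty(target_mr_wfe.shape, dtype=np.float64)
    _fuse_kernel(cts, gres, offs, mask, -1000.0, out)
    sct = Volume(out, target_mr_wfe.spacing, target_mr_wfe.origin,
                 target_mr_wfe.orientation, "SCT")
    return sct, GREMap(gre_min=gres, best_offset=offs)
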