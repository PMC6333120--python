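import math

import numpy as np
import pytest

from atlas_sct.fusion import (
    GREParams,
    candidate_offsets,
    fuse,
    gre_at,
    gre_search_volume,
    neighborhood_search,
    patch_stats,
)
from atlas_sct.image_core import Volume

from conftest import make_volume


class _Entry:
    def __init__(self, ct, mr):
        self.subject_id = "x"
        self.ct_deformed = ct
        self.mr_deformed = mr


class _Prop:
    def __init__(self, entries):
        self.entries = entries


def _textured(rng, shape=(32, 32, 4), mean=500.0, sd=100.0):
    return make_volume(rng.normal(mean, sd, shape), tag="MR_WFE")


class TestPatchStats:
    def test_all_zero(self):
        assert patch_stats(np.zeros(25)) == (0.0, 0.0, 0.0)

    def test_constant_ten(self):
        m2, var, ent = patch_stats(np.full(25, 10.0))
        assert (m2, var, ent) == (100.0, 0.0, 0.0)

    def test_hand_computed_1234(self):
        m2, var, ent = patch_stats([1.0, 2, 3, 4], entropy_bins=4)
        assert m2 == pytest.approx(6.25)
        assert var == pytest.approx(1.25)
        assert ent == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            patch_stats([])


class TestGreAt:
    def test_identical_images_floor(self, rng):
        v = _textured(rng)
        w = v.with_data(v.data.copy())
        p = GREParams(epsilon=1e-6)
        g = gre_at(v, w, (16, 16, 2), p)
        assert g == pytest.approx(1e-6, rel=1e-6)

    def test_hand_patch_limit(self):
        # 2x2 patch difference [1,2,3,4] -> GRE -> 2.5 as eps -> 0
        target = make_volume(np.array([[[1.0], [2.0]], [[3.0], [4.0]]]))
        atlas = make_volume(np.zeros((2, 2, 1)))
        p = GREParams(patch_radius_vox=1, entropy_bins=4, epsilon=1e-12)
        g = gre_at(target, atlas, (0, 0, 0), p)  # clipped patch = 4 voxels
        assert g == pytest.approx(2.5, abs=1e-6)

    def test_brute_force_oracle(self, rng):
        target = _textured(rng)
        atlas = target.with_data(target.data + rng.normal(0, 30, target.shape))
        p = GREParams()
        for _ in range(30):
            v = tuple(rng.integers(0, n) for n in target.shape)
            # naive oracle: explicit loops + numpy patch stats
            vals = []
            for di in range(-2, 3):
                for dj in range(-2, 3):
                    i, j = v[0] + di, v[1] + dj
                    if 0 <= i < 32 and 0 <= j < 32:
                        vals.append(target.data[i, j, v[2]] - atlas.data[i, j, v[2]])
            m = np.mean(vals)
            var = np.var(vals)
            lo, hi = min(vals), max(vals)
            counts, _ = np.histogram(vals, bins=32, range=(lo, hi))
            pr = counts[counts > 0] / len(vals)
            ent = -np.sum(pr * np.log2(pr))
            e = p.epsilon
            expected = ((m * m + e) * (var + e) * (ent + e)) ** (1 / 3)
            assert gre_at(target, atlas, v, p) == pytest.approx(expected, abs=1e-9)


class TestNeighborhoodSearch:
    def test_thirteen_offsets_at_radius_two(self):
        offs = candidate_offsets((1.0, 1.0), 2.0)
        assert len(offs) == 13
        assert tuple(offs[0]) == (0, 0)  # sorted by magnitude: zero first

    def test_anisotropic_spacing_reduces_candidates(self):
        offs = candidate_offsets((1.0, 2.0), 2.0)
        # j offsets limited to |j| <= 1
        assert all(abs(j) <= 1 for _, j in offs)

    def test_radius_zero_single_candidate(self, rng):
        v = _textured(rng)
        w = v.with_data(v.data + rng.normal(0, 10, v.shape))
        p0 = GREParams(search_radius_mm=0.0)
        off, g = neighborhood_search(v, w, (10, 10, 1), p0)
        assert off == (0, 0)
        assert g == pytest.approx(gre_at(v, w, (10, 10, 1), p0))

    def test_shift_recovery(self, rng):
        data = rng.normal(500, 120, (40, 40, 3))
        target = make_volume(data, tag="MR_WFE")
        shifted = np.roll(data, shift=1, axis=0)  # atlas(x+1) == target(x)...
        atlas = make_volume(shifted, tag="MR_WFE")
        p = GREParams()
        hits = 0
        total = 0
        for i in range(10, 30, 2):
            for j in range(10, 30, 2):
                off, _ = neighborhood_search(target, atlas, (i, j, 1), p)
                total += 1
                if off == (1, 0):
                    hits += 1
        assert hits / total >= 0.95

    def test_kernel_matches_scalar_path(self, rng):
        target = _textured(rng, shape=(24, 24, 3))
        atlas = target.with_data(target.data + rng.normal(0, 25, target.shape))
        p = GREParams()
        gre, off = gre_search_volume(target, atlas, p)
        for _ in range(25):
            v = tuple(rng.integers(0, n) for n in target.shape)
            o_ref, g_ref = neighborhood_search(target, atlas, v, p)
            assert gre[v] == pytest.approx(g_ref, abs=1e-9)
            assert tuple(off[v]) == o_ref


class TestFuse:
    def _prop_with_values(self, shape, ct_values, mr_noise, rng, target):
        entries = []
        for val, noise in zip(ct_values, mr_noise):
            ct = make_volume(np.full(shape, float(val)), tag="CT")
            mr = target.with_data(target.data + rng.normal(0, noise, shape))
            entries.append(_Entry(ct, mr))
        return _Prop(entries)

    def test_weighted_average_arithmetic(self):
        # hand check: gre 1 and 3, values 100 and 200 -> 125
        w = np.array([1.0, 1 / 3])
        vals = np.array([100.0, 200.0])
        assert np.sum(w * vals) / np.sum(w) == pytest.approx(125.0)

    def test_single_pair_identity(self, rng):
        target = _textured(rng, (24, 24, 4))
        ct = make_volume(rng.normal(0, 200, (24, 24, 4)), tag="CT")
        prop = _Prop([_Entry(ct, target.with_data(target.data.copy()))])
        sct, gre = fuse(prop, target, GREParams())
        # identical MR -> zero offsets everywhere -> sct == ct exactly
        np.testing.assert_allclose(sct.data, ct.data, atol=1e-9)

    def test_convexity(self, rng):
        target = _textured(rng, (24, 24, 4))
        prop = self._prop_with_values((24, 24, 4), [0, 100, 300],
                                      [20, 40, 80], rng, target)
        sct, gre = fuse(prop, target, GREParams())
        assert np.all(sct.data >= -1e-9)
        assert np.all(sct.data <= 300 + 1e-9)

    def test_permutation_invariance(self, rng):
        target = _textured(rng, (20, 20, 3))
        prop = self._prop_with_values((20, 20, 3), [0, 100, 300],
                                      [20, 40, 80], rng, target)
        sct1, _ = fuse(prop, target, GREParams())
        prop2 = _Prop(prop.entries[::-1])
        sct2, _ = fuse(prop2, target, GREParams())
        np.testing.assert_allclose(sct1.data, sct2.data, atol=1e-9)

    def test_self_atlas_dominance(self, rng):
        target = _textured(rng, (24, 24, 4))
        entries = [
            _Entry(make_volume(np.full((24, 24, 4), 500.0), tag="CT"),
                   target.with_data(target.data.copy())),
            _Entry(make_volume(np.full((24, 24, 4), -500.0), tag="CT"),
                   target.with_data(target.data + rng.normal(0, 50, (24, 24, 4)))),
        ]
        sct, _ = fuse(_Prop(entries), target, GREParams())
        assert np.all(np.abs(sct.data - 500.0) < 1.0)

    def test_naive_loop_oracle(self, rng):
        """Vectorized fusion equals a per-voxel reference implementation."""
        shape = (12, 12, 3)
        target = _textured(rng, shape)
        prop = self._prop_with_values(shape, [-200, 50, 400],
                                      [15, 30, 60], rng, target)
        p = GREParams()
        sct, _ = fuse(prop, target, p)
        for _ in range(40):
            v = tuple(rng.integers(0, n) for n in shape)
            wsum = vsum = 0.0
            for e in prop.entries:
                off, g = neighborhood_search(target, e.mr_deformed, v, p)
                xi = min(max(v[0] + off[0], 0), shape[0] - 1)
                yj = min(max(v[1] + off[1], 0), shape[1] - 1)
                w = 1.0 / g
                wsum += w
                vsum += w * e.ct_deformed.data[xi, yj, v[2]]
            assert sct.data[v] == pytest.approx(vsum / wsum, abs=1e-6)

    def test_outside_mask_is_air(self, rng):
        target = _textured(rng, (16, 16, 3))
        mask = np.zeros((16, 16, 3), dtype=np.uint8)
        mask[4:12, 4:12, :] = 1
        p = GREParams(body_mask=Volume(mask, target.spacing, target.origin,
                                       target.orientation, "MASK"))
        prop = self._prop_with_values((16, 16, 3), [100], [20], rng, target)
        sct, _ = fuse(prop, target, p)
        assert np.all(sct.data[mask == 0] == -1000.0)
        assert np.all(sct.data[mask == 1] != -1000.0)

    def test_empty_atlas_rejected(self, rng):
        target = _textured(rng, (8, 8, 2))
        with pytest.raises(ValueError):
            fuse(_Prop([]), target, GREParams())

    def test_grid_mismatch_rejected(self, rng):
        target = _textured(rng, (8, 8, 2))
        other = make_volume(rng.normal(500, 10, (8, 8, 2)), origin=(5, 0, 0),
                            tag="MR_WFE")
        prop = _Prop([_Entry(other.with_data(other.data, "CT"), other)])
        with pytest.raises(ValueError):
            fuse(prop, target, GREParams())
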