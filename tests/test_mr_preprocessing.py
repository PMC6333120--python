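import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlas_sct.image_core import GeometryError, Volume
from atlas_sct.mr_preprocessing import (
    DegenerateInputError,
    StandardScale,
    TissueLandmarks,
    correct_bias,
    detect_landmarks,
    fat_enhance,
    fuzzy_c_means,
    standardize,
)

from conftest import make_volume

SCALE = StandardScale()


class TestFuzzyCMeans:
    def test_k1_is_arithmetic_mean(self, rng):
        samples = rng.normal(50, 5, size=300)
        centers, u = fuzzy_c_means(samples, k=1)
        assert centers[0] == pytest.approx(samples.mean())
        np.testing.assert_allclose(u, 1.0)

    def test_two_plateau_symmetry(self):
        samples = np.array([0.0, 0, 0, 10, 10, 10])
        centers, u = fuzzy_c_means(samples, k=2, fuzzifier=2.0, seed=1)
        # by symmetry the centers sit symmetric about 5
        assert centers[0] + centers[1] == pytest.approx(10.0, abs=1e-3)
        assert centers[0] < 5 < centers[1]
        np.testing.assert_allclose(u.sum(axis=1), 1.0)

    def test_two_gaussian_mixture_vs_kmeans_oracle(self):
        rng = np.random.default_rng(77)
        samples = np.concatenate([
            rng.normal(100, 20, 1000), rng.normal(500, 20, 1000)])
        centers, _ = fuzzy_c_means(samples, k=2, seed=3)
        # independent oracle: k-means on the same draw
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(samples[:, None])
        oracle = np.sort(km.cluster_centers_.ravel())
        np.testing.assert_allclose(centers, oracle, atol=10)
        np.testing.assert_allclose(centers, [100, 500], atol=10)

    def test_objective_non_increasing(self, rng):
        samples = rng.normal(0, 1, 500) + 5 * (rng.random(500) > 0.5)
        _, _, trace = fuzzy_c_means(samples, k=2, seed=0, return_objective=True)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            fuzzy_c_means([1.0, 1.0, 2.0], k=3)

    def test_memberships_partition(self, rng):
        samples = rng.normal(0, 1, 200)
        _, u = fuzzy_c_means(samples, k=3, seed=0)
        assert np.all(u >= 0)
        np.testing.assert_allclose(u.sum(axis=1), 1.0)

    def test_deterministic_given_seed(self, rng):
        samples = rng.normal(10, 3, 400)
        c1, _ = fuzzy_c_means(samples, k=2, seed=9)
        c2, _ = fuzzy_c_means(samples, k=2, seed=9)
        np.testing.assert_array_equal(c1, c2)


def _two_tissue_slice_volume(nx=4, ny=48, nz=48, gain=None):
    """Small MR volume of two tissue plateaus, optional per-slice gain."""
    rng = np.random.default_rng(4)
    data = np.where(rng.random((nx, ny, nz)) > 0.5, 100.0, 400.0)
    labels = (data > 200).astype(int)
    if gain is not None:
        data = data * gain[None, :, :]
    return make_volume(data, tag="MR_WATER"), labels


class TestCorrectBias:
    def test_identity_on_unbiased_phantom(self):
        v, _ = _two_tissue_slice_volume()
        corrected, bias = correct_bias(v, n_iter=10)
        assert np.all(np.abs(bias.field - 1.0) < 0.02)

    def test_cov_reduction_under_linear_gain(self):
        ny = 48
        ramp = 1.0 + 0.3 * (np.arange(ny) / (ny - 1))
        gain = np.repeat(ramp[:, None], 48, axis=1)
        v, labels = _two_tissue_slice_volume(gain=gain)
        corrected, _ = correct_bias(v, n_iter=20)

        def tissue_cov(data):
            covs = []
            for t in (0, 1):
                vals = data[labels == t]
                covs.append(vals.std() / vals.mean())
            return covs

        before = tissue_cov(v.data)
        after = tissue_cov(corrected.data)
        for b, a in zip(before, after):
            assert a <= 0.5 * b

    def test_output_nonnegative(self):
        v, _ = _two_tissue_slice_volume()
        corrected, _ = correct_bias(v, n_iter=5)
        assert np.all(corrected.data >= 0)

    def test_all_zero_slice_skipped(self):
        v, _ = _two_tissue_slice_volume()
        data = v.data.copy()
        data[0] = 0.0
        v0 = v.with_data(data)
        corrected, bias = correct_bias(v0, n_iter=5)
        np.testing.assert_array_equal(bias.field[0], 1.0)

    def test_rejects_ct(self, rng):
        ct = make_volume(rng.normal(0, 100, (4, 8, 8)), tag="CT")
        with pytest.raises(ValueError):
            correct_bias(ct)


class TestDetectLandmarks:
    def test_two_mode_synthetic(self):
        rng = np.random.default_rng(8)
        data = np.where(rng.random((64, 64, 32)) > 0.5,
                        rng.normal(500, 20, (64, 64, 32)),
                        rng.normal(50, 10, (64, 64, 32)))
        v = make_volume(np.clip(data, 0, None))
        lm = detect_landmarks(v)
        bin_width = (np.percentile(data, 99.9) - np.percentile(data, 0.1)) / 256
        assert lm.dark_mode == pytest.approx(50, abs=2 * bin_width)
        assert lm.bright_mode == pytest.approx(500, abs=2 * bin_width)
        assert 50 < lm.valley < 500

    def test_constant_image_rejected(self):
        v = make_volume(np.full((8, 8, 8), 7.0))
        with pytest.raises(DegenerateInputError):
            detect_landmarks(v)

    def test_landmark_ordering_invariant(self, tiny_subject):
        lm = detect_landmarks(tiny_subject.water)
        assert 0 <= lm.dark_mode < lm.valley < lm.bright_mode


class TestStandardize:
    LM = TissueLandmarks(dark_mode=40.0, valley=150.0, bright_mode=420.0)

    def test_landmark_fixed_points(self):
        v = make_volume(np.array([[[40.0, 150.0, 420.0]]]))
        out = standardize(v, self.LM, SCALE)
        np.testing.assert_allclose(out.data.ravel(), [100.0, 500.0, 1000.0])

    def test_segment_midpoint_linearity(self):
        mid_in = 0.5 * (self.LM.dark_mode + self.LM.valley)
        v = make_volume(np.full((1, 1, 1), mid_in))
        out = standardize(v, self.LM, SCALE)
        assert out.data[0, 0, 0] == pytest.approx(0.5 * (SCALE.s_dark + SCALE.s_valley))

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(-100, 2000), b=st.floats(-100, 2000))
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        v = make_volume(np.array([[[lo, hi]]]))
        out = standardize(v, self.LM, SCALE)
        assert out.data[0, 0, 0] <= out.data[0, 0, 1]

    def test_output_clamped(self):
        v = make_volume(np.array([[[-500.0, 1e6]]]))
        out = standardize(v, self.LM, SCALE)
        assert out.data.min() >= 0
        assert out.data.max() <= SCALE.s_max

    def test_standardize_then_detect_is_fixed_point(self):
        # triangular mixture: sharp modes and a genuine interior valley whose
        # mapped tails stay inside [0, s_max] (no clip spikes)
        rng = np.random.default_rng(3)
        n = 64 * 64 * 32
        sel = rng.random(n) > 0.5
        data = np.where(sel, rng.triangular(200, 420, 440, n),
                        rng.triangular(0, 25, 300, n))
        v = make_volume(data.reshape(64, 64, 32))
        lm = detect_landmarks(v)
        out = standardize(v, lm, SCALE)
        lm2 = detect_landmarks(out)
        hist_range = np.percentile(out.data, 99.9) - np.percentile(out.data, 0.1)
        bin_width = hist_range / 256
        assert lm2.dark_mode == pytest.approx(SCALE.s_dark, abs=bin_width)
        assert lm2.valley == pytest.approx(SCALE.s_valley, abs=bin_width)
        assert lm2.bright_mode == pytest.approx(SCALE.s_bright, abs=bin_width)


class TestFatEnhance:
    def test_direct_arithmetic(self):
        w = make_volume(np.full((2, 2, 2), 120.0))
        f = make_volume(np.full((2, 2, 2), 60.0), tag="MR_FAT")
        out = fat_enhance(w, f, alpha=0.5)
        np.testing.assert_allclose(out.data, 100.0)
        assert out.modality_tag == "MR_WFE"

    def test_alpha_zero_is_water(self, rng):
        w = make_volume(rng.uniform(0, 1000, (4, 4, 4)))
        f = make_volume(rng.uniform(0, 1000, (4, 4, 4)), tag="MR_FAT")
        out = fat_enhance(w, f, alpha=0.0)
        np.testing.assert_array_equal(out.data, w.data)

    def test_water_zero_case(self):
        w = make_volume(np.zeros((1, 1, 1)))
        f = make_volume(np.full((1, 1, 1), 90.0), tag="MR_FAT")
        assert fat_enhance(w, f, 0.5).data[0, 0, 0] == pytest.approx(30.0)

    def test_convex_combination(self, rng):
        w = make_volume(rng.uniform(0, 1000, (5, 5, 5)))
        f = make_volume(rng.uniform(0, 1000, (5, 5, 5)), tag="MR_FAT")
        out = fat_enhance(w, f, alpha=0.7)
        lo = np.minimum(w.data, f.data)
        hi = np.maximum(w.data, f.data)
        assert np.all(out.data >= lo - 1e-9)
        assert np.all(out.data <= hi + 1e-9)

    def test_grid_mismatch_rejected(self, rng):
        w = make_volume(rng.uniform(0, 1, (4, 4, 4)))
        f = make_volume(rng.uniform(0, 1, (4, 4, 4)), origin=(1, 0, 0), tag="MR_FAT")
        with pytest.raises(GeometryError):
            fat_enhance(w, f)

    def test_negative_alpha_rejected(self, rng):
        w = make_volume(rng.uniform(0, 1, (2, 2, 2)))
        with pytest.raises(ValueError):
            fat_enhance(w, w.with_data(w.data, "MR_FAT"), alpha=-0.1)


class TestInvariants:
    def test_landmark_invariants_enforced(self):
        with pytest.raises(Exception):
            TissueLandmarks(dark_mode=500, valley=100, bright_mode=1000)
        with pytest.raises(Exception):
            TissueLandmarks(dark_mode=-5, valley=100, bright_mode=1000)

    def test_scale_invariants_enforced(self):
        with pytest.raises(ValueError):
            StandardScale(s_dark=500, s_valley=100)
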