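"""Feature maps, fusion rules, and the end-to-end enhancement pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endofuse.config import PipelineConfig
from endofuse.decomposition import GuidedFilterParams, mlwtgf_decompose
from endofuse.fusion import (
    WeightMaps,
    compute_weights,
    enhance,
    enhance_detailed,
    fuse_and_reconstruct,
    fuse_detail,
    fuse_ll,
    local_contrast_map,
    local_entropy_map,
)
from endofuse.metrics import cii, global_entropy

from _oracles import contrast_map_loop, entropy_map_loop, weights_loop


class TestFeatureMaps:
    def test_constant_plane_zero_contrast_and_entropy(self):
        plane = np.full((8, 8), 0.3)
        assert np.all(local_contrast_map(plane) == 0)
        assert np.all(local_entropy_map(plane, 8) == 0)

    def test_isolated_spike_contrast(self):
        plane = np.zeros((9, 9))
        plane[4, 4] = 9.0
        assert local_contrast_map(plane)[4, 4] == 9.0

    def test_nine_distinct_values_entropy(self):
        plane = np.zeros((9, 9))
        plane[3:6, 3:6] = np.arange(9).reshape(3, 3) / 8.0
        ent = local_entropy_map(plane, 16)
        assert np.isclose(ent[4, 4], np.log2(9))

    def test_contrast_matches_literal_loop_exactly(self, rng):
        plane = rng.random((8, 8))
        assert np.array_equal(local_contrast_map(plane), contrast_map_loop(plane))

    def test_entropy_matches_literal_loop_exactly(self, rng):
        plane = rng.random((8, 8))
        assert np.array_equal(local_entropy_map(plane, 8), entropy_map_loop(plane, 8))


class TestWeights:
    def test_identical_planes_get_equal_thirds(self, rng):
        plane = rng.random((8, 8))
        w = compute_weights((plane, plane, plane), 0.4, 0.6)
        assert np.allclose(w.w1, 1 / 3)
        assert np.allclose(w.w2, 1 / 3)
        assert np.allclose(w.w3, 1 / 3)

    def test_featureless_plane_excluded(self, rng):
        textured = rng.random((8, 8))
        flat = np.full((8, 8), 0.5)
        w = compute_weights((flat, textured, textured), 0.4, 0.6)
        active = local_contrast_map(textured) > 0
        assert np.all(w.w1[active] == 0)
        assert np.allclose(w.w2[active], 0.5)
        assert np.allclose(w.w3[active], 0.5)

    def test_matches_per_pixel_oracle_exactly(self, rng):
        bands = tuple(rng.random((8, 8)) for _ in range(3))
        w = compute_weights(bands, 0.4, 0.6, bins=8)
        expected = weights_loop(bands, 0.4, 0.6, 8)
        assert np.array_equal(w.stack, expected)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_weights_sum_to_one_everywhere(self, seed):
        r = np.random.default_rng(seed)
        bands = tuple(r.random((8, 8)) for _ in range(3))
        w = compute_weights(bands, 0.4, 0.6)
        assert np.abs(w.w1 + w.w2 + w.w3 - 1.0).max() <= 1e-12

    def test_invalid_gammas_rejected(self):
        plane = np.zeros((8, 8))
        with pytest.raises(ValueError):
            compute_weights((plane, plane, plane), 0.0, 0.0)
        with pytest.raises(ValueError):
            compute_weights((plane, plane, plane), -0.1, 0.5)


class TestFusionRules:
    def test_ll_max_and_dominance(self, rng):
        a1, a2, a3 = (rng.random((8, 8)) for _ in range(3))
        fused = fuse_ll(a1, a2, a3)
        for a in (a1, a2, a3):
            assert np.all(fused >= a)
        assert np.array_equal(fuse_ll(a1, a1, a1), a1)

    def test_detail_selection_weight(self, rng):
        b1, b2, b3 = (rng.random((8, 8)) for _ in range(3))
        w = WeightMaps(
            w1=np.ones((8, 8)), w2=np.zeros((8, 8)), w3=np.zeros((8, 8)),
            gamma1=0.4, gamma2=0.6,
        )
        assert np.array_equal(fuse_detail((b1, b2, b3), w), b1)

    def test_detail_convex_combination_bounds(self, rng):
        bands = tuple(rng.standard_normal((8, 8)) for _ in range(3))
        w = compute_weights(bands, 0.4, 0.6)
        fused = fuse_detail(bands, w)
        stack = np.stack(bands)
        assert np.all(fused <= stack.max(axis=0) + 1e-12)
        assert np.all(fused >= stack.min(axis=0) - 1e-12)

    def test_identical_bands_fuse_to_themselves(self, rng):
        v = rng.standard_normal((8, 8))
        w = compute_weights((v, v, v), 0.4, 0.6)
        assert np.abs(fuse_detail((v, v, v), w) - v).max() < 1e-12


class TestFuseAndReconstruct:
    def test_three_identical_self_bandsets_reproduce_plane(self, rng):
        plane = rng.random((32, 32))
        bs = mlwtgf_decompose(
            plane, gf=GuidedFilterParams(radius=2, eps=0.0), detail_mode="self"
        )
        out = fuse_and_reconstruct((bs, bs, bs))
        assert np.abs(out - plane).max() < 1e-6

    def test_permutation_invariance_bitwise(self, dark_phantom):
        cfg = PipelineConfig()
        res = enhance_detailed(dark_phantom.image, cfg)
        bs = res.bandsets
        ref = fuse_and_reconstruct(bs)
        for perm in [(1, 2, 0), (2, 0, 1), (2, 1, 0), (0, 2, 1), (1, 0, 2)]:
            out = fuse_and_reconstruct(tuple(bs[i] for i in perm))
            assert np.array_equal(out, ref)

    def test_mixed_bandsets_rejected(self, rng):
        p = rng.random((32, 32))
        bs1 = mlwtgf_decompose(p, wavelet_name="haar")
        bs2 = mlwtgf_decompose(p, wavelet_name="db2")
        with pytest.raises(ValueError):
            fuse_and_reconstruct((bs1, bs1, bs2))


class TestEnhance:
    def test_flat_midgray_stays_flat(self):
        img = np.full((64, 64, 3), 0.5)
        out = enhance(img)
        assert out.shape == img.shape
        assert out.max() - out.min() <= 2 / 255

    def test_dark_phantom_gains_entropy_and_contrast(self, dark_phantom):
        cfg = PipelineConfig(llf_levels=3)
        out = enhance(dark_phantom.image, cfg)
        assert out.shape == dark_phantom.image.shape
        assert np.isfinite(out).all()
        assert out.min() >= 0 and out.max() <= 1
        assert global_entropy(out) > global_entropy(dark_phantom.image)
        assert cii(out, dark_phantom.image) > 1.0

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            enhance(np.full((4, 4, 3), 0.5))

    def test_chosen_gamma_reported(self, dark_phantom):
        res = enhance_detailed(dark_phantom.image, PipelineConfig(llf_levels=3))
        assert res.subimages.chosen_gamma in res.config.gamma_grid
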