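"""Wavelet transform, guided filter, and the combined decomposition."""

import numpy as np
import pytest

from endofuse.decomposition import (
    GuidedFilterParams,
    dwt2,
    guided_filter,
    idwt2,
    mlwtgf_decompose,
)

from _oracles import guided_filter_loop


class TestDWT:
    def test_2x2_constant_haar(self):
        ll, lh, hl, hh = dwt2(np.ones((2, 2)), "haar")
        assert np.allclose(ll, 2.0)
        for band in (lh, hl, hh):
            assert np.allclose(band, 0.0)

    @pytest.mark.parametrize("wavelet", ["haar", "db2", "sym4"])
    def test_perfect_reconstruction(self, rng, wavelet):
        plane = rng.random((64, 64))
        bands = dwt2(plane, wavelet)
        back = idwt2(*bands, wavelet_name=wavelet, original_shape=plane.shape)
        assert np.abs(back - plane).max() < 1e-10

    def test_odd_dimensions_roundtrip(self, rng):
        plane = rng.random((33, 47))
        bands = dwt2(plane, "haar")
        assert bands[0].shape == (17, 24)
        back = idwt2(*bands, wavelet_name="haar", original_shape=plane.shape)
        assert np.abs(back - plane).max() < 1e-10

    def test_directional_energy_separation(self):
        img = np.zeros((16, 16))
        img[7:, :] = 1.0  # horizontal edge straddling a dyadic pair
        _, lh, hl, hh = dwt2(img, "haar")
        assert np.abs(lh).max() > 0.5
        assert np.abs(hl).max() < 1e-10
        assert np.abs(hh).max() < 1e-10

    def test_idwt_linearity(self, rng):
        b1 = dwt2(rng.random((32, 32)), "haar")
        b2 = dwt2(rng.random((32, 32)), "haar")
        lhs = idwt2(
            *(2.0 * x + 3.0 * y for x, y in zip(b1, b2)), wavelet_name="haar"
        )
        rhs = 2.0 * idwt2(*b1, wavelet_name="haar") + 3.0 * idwt2(
            *b2, wavelet_name="haar"
        )
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_zero_bands_give_zero_plane(self):
        z = np.zeros((8, 8))
        assert np.all(idwt2(z, z, z, z, wavelet_name="haar") == 0)

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError):
            dwt2(np.zeros((8, 8)), "not-a-wavelet")

    def test_mismatched_band_shapes_rejected(self):
        with pytest.raises(ValueError):
            idwt2(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((3, 4)), np.zeros((4, 4)))


class TestGuidedFilter:
    def test_self_guidance_identity(self, rng):
        plane = rng.random((16, 16))
        out = guided_filter(plane, plane, GuidedFilterParams(radius=2, eps=0.0))
        assert np.abs(out - plane).max() < 1e-6

    @pytest.mark.parametrize("radius", [1, 2, 4])
    @pytest.mark.parametrize("eps", [0.0, 0.01, 0.1])
    def test_matches_per_window_least_squares_oracle(self, rng, radius, eps):
        p = rng.random((16, 16))
        g = rng.random((16, 16))
        mine = guided_filter(p, g, GuidedFilterParams(radius=radius, eps=eps))
        assert np.abs(mine - guided_filter_loop(p, g, radius, eps)).max() < 1e-8

    def test_constant_guidance_gives_double_box_average(self, rng):
        p = rng.random((16, 16))
        g = np.full((16, 16), 0.5)
        mine = guided_filter(p, g, GuidedFilterParams(radius=2, eps=0.01))
        assert np.abs(mine - guided_filter_loop(p, g, 2, 0.01)).max() < 1e-8

    def test_huge_eps_approaches_double_box_average(self, rng):
        from scipy.ndimage import uniform_filter

        p = rng.random((16, 16))
        g = rng.random((16, 16))
        out = guided_filter(p, g, GuidedFilterParams(radius=2, eps=1e8))
        double_box = uniform_filter(uniform_filter(p, 5, mode="reflect"), 5, mode="reflect")
        assert np.abs(out - double_box).max() < 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GuidedFilterParams(radius=0)
        with pytest.raises(ValueError):
            GuidedFilterParams(eps=-1.0)
        with pytest.raises(ValueError):
            guided_filter(np.zeros((3, 3)), np.zeros((4, 4)), GuidedFilterParams())


class TestMlwtgf:
    @pytest.mark.parametrize("mode", ["cross", "self"])
    def test_constant_intensity_gives_zero_refined_bands(self, mode):
        bs = mlwtgf_decompose(np.full((32, 32), 0.5), detail_mode=mode)
        for band in bs.refined:
            assert np.abs(band).max() < 1e-8

    def test_self_mode_eps_zero_keeps_raw_bands(self, rng):
        plane = rng.random((32, 32))
        bs = mlwtgf_decompose(
            plane, gf=GuidedFilterParams(radius=2, eps=0.0), detail_mode="self"
        )
        assert np.abs(bs.refined_lh - bs.lh).max() < 1e-6
        assert np.abs(bs.refined_hl - bs.hl).max() < 1e-6
        assert np.abs(bs.refined_hh - bs.hh).max() < 1e-6

    def test_cross_mode_refined_bands_have_zero_mean(self, dark_phantom):
        bs = mlwtgf_decompose(dark_phantom.image.mean(axis=2), detail_mode="cross")
        for band in bs.refined:
            assert abs(band.mean()) < 1e-12

    def test_cross_mode_transfers_guidance_structure(self):
        # localized horizontal stripes: strong LH band, near-empty HH band;
        # the LH-guided refined component must inherit the LH structure
        n = 64
        y, x = np.mgrid[0:n, 0:n] / n
        env = np.exp(-((y - 0.5) ** 2 + (x - 0.5) ** 2) / 0.03)
        noise = np.random.default_rng(42).standard_normal((n, n))
        plane = np.clip(
            0.5 + 0.25 * np.sin(2 * np.pi * y * n / 4) * env + 0.01 * noise, 0, 1
        )
        bs = mlwtgf_decompose(plane, detail_mode="cross")

        def corr(a, b):
            af = np.abs(a).ravel()
            bf = np.abs(b).ravel()
            af = af - af.mean()
            bf = bf - bf.mean()
            return float((af @ bf) / np.sqrt((af @ af) * (bf @ bf)))

        assert corr(bs.refined_lh, bs.lh) > corr(bs.refined_lh, bs.hh) + 0.5

    def test_raw_bands_reconstruct_source(self, rng):
        plane = rng.random((32, 32))
        bs = mlwtgf_decompose(plane, wavelet_name="db2")
        back = idwt2(
            bs.ll, bs.lh, bs.hl, bs.hh, wavelet_name="db2", original_shape=plane.shape
        )
        assert np.abs(back - plane).max() < 1e-8

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            mlwtgf_decompose(np.zeros((16, 16)), detail_mode="other")
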