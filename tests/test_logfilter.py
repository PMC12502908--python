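"""Laplacian-of-Gaussian filter: kernels, separability, boundary zero-sum, scale invariance."""

import numpy as np
import pytest
from scipy import ndimage

from ssfembed.logfilter import (
    ScaleSpec,
    log_response,
    make_gaussian_1d,
    make_log_1d,
    make_log_kernel_dense,
    multiscale_log,
    support_radius_for,
)

from conftest import disk_image


def dense_renormalized_response(volume, sigmas):
    """Independent oracle: dense d-dim convolution with per-voxel zero-sum correction.

    At every position the effective kernel (restricted to in-image support) is
    shifted by its own mean, so its weights sum to zero there.
    """
    K = make_log_kernel_dense(tuple(sigmas))
    ones_img = np.ones_like(volume)
    raw = ndimage.correlate(volume, K, mode="constant", cval=0.0)
    ksum = ndimage.correlate(ones_img, K, mode="constant", cval=0.0)
    count = ndimage.correlate(ones_img, np.ones_like(K), mode="constant", cval=0.0)
    box = ndimage.correlate(volume, np.ones_like(K), mode="constant", cval=0.0)
    return raw - (ksum / count) * box


class TestKernels:
    @pytest.mark.parametrize("sigma,support", [(1.0, 4), (2.0, 8), (0.7, 3)])
    def test_gaussian_normalized_and_symmetric(self, sigma, support):
        k = make_gaussian_1d(sigma, support)
        assert len(k) == 2 * support + 1
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(k, k[::-1])

    def test_gaussian_delta_limit(self):
        k = make_gaussian_1d(0.05, 1)
        assert np.allclose(k, [0.0, 1.0, 0.0], atol=1e-10)

    def test_gaussian_center_matches_direct_summation(self):
        # center entry is exp(0) / sum_x exp(-x^2 / (2 sigma^2)) for sigma=2
        sigma, support = 2.0, 6
        xs = np.arange(-support, support + 1)
        expected = 1.0 / np.exp(-(xs**2) / (2 * sigma**2)).sum()
        assert make_gaussian_1d(sigma, support)[support] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("sigma", [0.8, 1.5, 3.0])
    def test_log1d_even_function(self, sigma):
        k = make_log_1d(sigma, support_radius_for(sigma))
        assert np.allclose(k, k[::-1])

    def test_log1d_matches_formula(self):
        # ((x/s)^2 - 1) * normalized Gaussian, evaluated by brute force
        sigma, support = 1.5, 6
        xs = np.arange(-support, support + 1, dtype=float)
        g = np.exp(-0.5 * (xs / sigma) ** 2)
        g /= g.sum()
        expected = ((xs / sigma) ** 2 - 1.0) * g
        assert np.allclose(make_log_1d(sigma, support), expected, atol=1e-12)

    def test_separable_assembly_equals_dense_2d(self):
        sigmas = (1.3, 2.1)
        supports = tuple(support_radius_for(s) for s in sigmas)
        gy = make_gaussian_1d(sigmas[0], supports[0])
        gx = make_gaussian_1d(sigmas[1], supports[1])
        ly = make_log_1d(sigmas[0], supports[0])
        lx = make_log_1d(sigmas[1], supports[1])
        assembled = np.outer(ly, gx) + np.outer(gy, lx)
        dense = make_log_kernel_dense(sigmas, supports)
        assert np.abs(assembled - dense).max() < 1e-10

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, bad):
        with pytest.raises(ValueError):
            make_gaussian_1d(bad, 3)
        with pytest.raises(ValueError):
            make_log_1d(bad, 3)


class TestResponse:
    @pytest.mark.parametrize("radius", [2.0, 5.0])
    def test_constant_image_zero_everywhere(self, radius):
        # zero-sum kernel at every position, boundaries included
        spec = ScaleSpec((radius,), (1.0, 1.0))
        resp = log_response(np.full((20, 20), 3.7), spec).values
        assert np.abs(resp).max() < 1e-10

    def test_dark_disk_extremum_at_center(self):
        img, center = disk_image(21, 5.0)
        spec = ScaleSpec((5.0,), (1.0, 1.0))
        resp = log_response(img, spec).values
        assert np.unravel_index(np.argmax(resp), resp.shape) == center
        assert resp[center] > 0  # dark blob on bright background -> positive

    def test_separable_equals_dense_on_random_volume(self, rng):
        spec = ScaleSpec((1.0,), (1.0, 1.2, 0.8))
        vol = rng.uniform(0, 1, (15, 15, 7))
        sep = log_response(vol, spec).values
        sigmas = spec.sigmas_voxels(1.0)
        dense = dense_renormalized_response(vol, sigmas)
        R = [support_radius_for(s) for s in sigmas]
        inner = tuple(slice(r, -r) for r in R)
        assert np.abs(sep[inner] - dense[inner]).max() < 1e-8

    def test_boundary_matches_dense_renormalized_oracle(self, rng):
        # the zero-sum re-centering must hold at protruding positions too
        spec = ScaleSpec((2.0,), (1.0, 1.0))
        img = rng.uniform(0, 1, (17, 17))
        sep = log_response(img, spec).values
        dense = dense_renormalized_response(img, spec.sigmas_voxels(2.0))
        assert np.abs(sep - dense).max() < 1e-8

    def test_linearity(self, rng):
        spec = ScaleSpec((3.0,), (1.0, 1.0))
        img = rng.uniform(0, 1, (25, 25))
        base = log_response(img, spec).values
        scaled = log_response(2.5 * img + 7.0, spec).values
        assert np.allclose(scaled, 2.5 * base, atol=1e-9)

    def test_scale_invariance_across_radii(self):
        vals = []
        for r in (4, 6, 8, 12):
            img, center = disk_image(int(6 * r) + 31, float(r))
            spec = ScaleSpec((float(r),), (1.0, 1.0))
            vals.append(log_response(img, spec).values[center])
        spread = (max(vals) - min(vals)) / np.mean(vals)
        assert spread < 0.05

    def test_unresolvable_radius_names_axis(self):
        spec = ScaleSpec((0.3,), (1.0, 1.0))
        with pytest.raises(ValueError, match="axis"):
            log_response(np.zeros((10, 10)), spec)

    def test_anisotropic_axis_named(self):
        # z axis coarser: sigma drops below the resolvable floor there first
        spec = ScaleSpec((1.0,), (3.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="'z'"):
            log_response(np.zeros((5, 10, 10)), spec)


class TestMultiscale:
    def test_single_radius_equals_log_response(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        spec = ScaleSpec((4.0,), (1.0, 1.0))
        single = log_response(img, spec).values
        multi = multiscale_log(img, spec)
        assert np.array_equal(single, multi.values)
        assert np.all(multi.scale_index == 0)

    def test_matched_scale_wins_at_disk_center(self):
        img, center = disk_image(41, 5.0)
        multi = multiscale_log(img, ScaleSpec((3.0, 5.0, 7.0), (1.0, 1.0)))
        assert multi.winning_radius(center) == 5.0

    def test_empty_radius_list_rejected(self):
        with pytest.raises(ValueError):
            ScaleSpec((), (1.0, 1.0))
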