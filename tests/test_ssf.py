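"""Signaling structure function: metric contracts, calibration, volumes, quantization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from ssfembed.logfilter import ScaleSpec, make_log_kernel_dense, support_radius_for
from ssfembed.phantoms import KTRPhantomSpec, ktr_phantom
from ssfembed.ssf import (
    Detection,
    SSFVolume,
    build_ssf_volume,
    cn_fraction,
    cn_ratio,
    mip_z,
    quantize,
    reference_response,
    ssf_at_centroids,
    ssf_from_intensities,
    velocity_ssf,
)

from conftest import disk_image


class TestIntensityFunction:
    @pytest.mark.parametrize(
        "c,n,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.0), (0.0, 1.0, -1.0)]
    )
    def test_reference_points(self, c, n, expected):
        assert ssf_from_intensities(c, n) == pytest.approx(expected)

    @given(
        c=st.floats(0, 1), n=st.floats(0, 1), dc=st.floats(-0.2, 0.2), dn=st.floats(-0.2, 0.2)
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_shift_invariance(self, c, n, dc, dn):
        # perturbing (c, n) by a fixed vector changes H by a fixed amount,
        # independent of where in intensity space the cell sits
        c2, n2 = np.clip(c + dc, 0, 1), np.clip(n + dn, 0, 1)
        dc_eff, dn_eff = c2 - c, n2 - n
        delta = ssf_from_intensities(c2, n2) - ssf_from_intensities(c, n)
        assert delta == pytest.approx(dc_eff - dn_eff, abs=1e-12)

    def test_antisymmetry_on_grid(self):
        grid = np.linspace(0, 1, 11)
        for c in grid:
            for n in grid:
                assert ssf_from_intensities(c, n) == pytest.approx(
                    -ssf_from_intensities(n, c)
                )
                assert -1.0 <= ssf_from_intensities(c, n) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ssf_from_intensities(1.2, 0.0)

    def test_cn_ratio_is_not_shift_invariant(self):
        # the same (dc, dn) step produces very different C/N changes at
        # different base points: the baseline readout is non-metric
        step = (0.1, -0.1)
        deltas = []
        for c, n in [(0.3, 0.8), (0.8, 0.3), (0.5, 0.15)]:
            deltas.append(cn_ratio(c + step[0], n + step[1]) - cn_ratio(c, n))
        assert np.ptp(deltas) > 0.5

    def test_cn_fraction_error_grows_with_nuclear_brightening(self):
        # along the activation axis (c, n) = ((1+a)/2, (1-a)/2), the C/(C+N)
        # error against the true activation grows as the nucleus brightens
        # (i.e. as activation falls and n rises)
        errors = []
        for a in np.linspace(0.9, 0.1, 5):  # decreasing activation -> brighter nucleus
            c, n = (1 + a) / 2, (1 - a) / 2
            errors.append(abs(cn_fraction(c, n) - a))
        assert np.all(np.diff(errors) > 0)


class TestReferenceResponse:
    def test_deterministic_and_self_normalizing(self):
        v1 = reference_response(5.0, (1.0, 1.0))
        v2 = reference_response(5.0, (1.0, 1.0))
        assert v1 == v2 > 0
        # ideal fully-activated phantom divided by its own reference -> 1
        img, center = disk_image(65, 5.0)
        spec = ScaleSpec((5.0,), (1.0, 1.0))
        det = Detection(t=0, y=center[0], x=center[1])
        ssf_at_centroids({"k": img[None]}, [det], spec, normalized=True)
        assert det.ssf["k"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_dense_kernel_oracle(self):
        radius = 3.0
        ref = reference_response(radius, (1.0, 1.0))
        spec = ScaleSpec((radius,), (1.0, 1.0))
        sigmas = spec.sigmas_voxels(radius)
        img, _ = disk_image(41, radius)
        K = make_log_kernel_dense(sigmas)
        raw = ndimage.correlate(img, K, mode="constant", cval=0.0)
        box = ndimage.correlate(img, np.ones_like(K), mode="constant", cval=0.0)
        dense = raw - (K.sum() / K.size) * box
        R = support_radius_for(max(sigmas))
        inner = (slice(R, -R),) * 2
        assert ref == pytest.approx(dense[inner].max(), abs=1e-8)


class TestSSFAtCentroids:
    def test_fully_activated_phantom_reads_one(self, scales_2d):
        img, _, center = ktr_phantom(KTRPhantomSpec(activation=1.0))
        det = Detection(t=0, y=center[0], x=center[1])
        ssf_at_centroids({"ktr": img[None]}, [det], scales_2d, normalized=True)
        assert det.ssf["ktr"] == pytest.approx(1.0, abs=0.02)

    def test_constant_image_reads_zero(self, scales_2d):
        det = Detection(t=0, y=16.0, x=16.0)
        ssf_at_centroids(
            {"ktr": np.full((1, 33, 33), 0.5)}, [det], scales_2d, normalized=True
        )
        assert det.ssf["ktr"] == pytest.approx(0.0, abs=1e-9)

    def test_out_of_bounds_centroid_skipped(self, scales_2d):
        det = Detection(t=0, y=-5.0, x=16.0)
        ssf_at_centroids({"ktr": np.zeros((1, 33, 33))}, [det], scales_2d)
        assert "ktr" not in det.ssf


class TestVolumes:
    def test_empty_and_single_detection(self):
        assert not build_ssf_volume([], (4, 8, 8), "a").values.any()
        det = Detection(t=2, y=4.0, x=3.0, ssf={"a": 0.5})
        vol = build_ssf_volume([det], (4, 8, 8), "a")
        nz = np.argwhere(vol.values)
        assert nz.tolist() == [[2, 4, 3]] and vol.values[2, 4, 3] == 0.5

    def test_distinct_detections_counted(self, rng):
        coords = {(int(t), int(y), int(x)) for t, y, x in rng.integers(0, 8, (30, 3))}
        dets = [Detection(t=t, y=float(y), x=float(x), ssf={"a": 0.3}) for t, y, x in coords]
        vol = build_ssf_volume(dets, (8, 8, 8), "a")
        assert np.count_nonzero(vol.values) == len(coords)

    def test_collision_keeps_max_magnitude(self):
        dets = [
            Detection(t=0, y=1.0, x=1.0, ssf={"a": 0.2}),
            Detection(t=0, y=1.2, x=1.1, ssf={"a": -0.7}),
        ]
        vol = build_ssf_volume(dets, (1, 4, 4), "a")
        assert vol.values[0, 1, 1] == -0.7


class TestVelocitySSF:
    def _track(self, positions):
        return [
            Detection(t=t, y=float(y), x=float(x)) for t, (y, x) in enumerate(positions)
        ]

    def test_stationary_track_zero(self):
        vol = velocity_ssf([self._track([(3, 3)] * 5)], 2.0, (5, 8, 8))
        assert not vol.values.any()

    def test_constant_speed_normalized_by_gate(self):
        track = self._track([(1, 1 + 2 * t) for t in range(5)])
        vol = velocity_ssf([track], 4.0, (5, 8, 16))
        nz = vol.values[vol.values != 0]
        assert np.allclose(nz, 0.5)  # speed 2 / gate 4

    def test_random_walk_matches_brute_force(self, rng):
        pos = np.cumsum(rng.normal(0, 0.4, (10, 2)), axis=0) + 8
        track = self._track(pos)
        gate = 5.0
        vol = velocity_ssf([track], gate, (10, 16, 16))
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        for i, (y, x) in enumerate(pos):
            if i == 0:
                expect = steps[0]
            elif i == len(pos) - 1:
                expect = steps[-1]
            else:
                expect = 0.5 * (steps[i - 1] + steps[i])
            t, iy, ix = i, int(np.ceil(y - 0.5)), int(np.ceil(x - 0.5))
            assert vol.values[t, iy, ix] == pytest.approx(min(expect / gate, 1.0))

    def test_nonpositive_gate_rejected(self):
        with pytest.raises(ValueError):
            velocity_ssf([], 0.0, (1, 4, 4))


class TestMip:
    def test_single_nonzero_survives_and_zero_stays_zero(self):
        vol = np.zeros((2, 3, 4, 4))
        vol[1, 2, 1, 1] = -0.4
        proj = mip_z(vol)
        assert proj.values[1, 1, 1] == -0.4
        assert np.count_nonzero(proj.values) == 1
        assert not mip_z(np.zeros((2, 3, 4, 4))).values.any()

    def test_signed_max_magnitude(self):
        vol = np.zeros((1, 2, 1, 1))
        vol[0, 0, 0, 0] = 0.2
        vol[0, 1, 0, 0] = -0.7
        assert mip_z(vol).values[0, 0, 0] == -0.7


def brute_force_code(value, edges):
    """Independent bin search: count edges at or below the value, plus one."""
    code = 1
    for e in edges:
        if value >= e:
            code += 1
    return min(code, 255)


class TestQuantize:
    def _volume(self, values):
        arr = np.zeros((1, 1, len(values) + 1))
        arr[0, 0, : len(values)] = values
        return SSFVolume(arr)

    def test_midpoint_maps_to_128(self):
        # values symmetric about 0.5, with 0.5 itself present: the voxel at
        # exactly the pooled mean lands in the central code
        values = [0.3, 0.7, 0.4, 0.6, 0.5]
        [q] = quantize([self._volume(values)])
        assert q.mean == pytest.approx(0.5)
        assert q.values[0, 0, 4] == 128
        assert brute_force_code(0.5, q.bin_edges) == 128

    def test_clipping_and_background(self):
        vol = self._volume([0.1, 0.2, 0.3, 0.4])
        [q] = quantize([vol])
        mu, sd = q.mean, q.std
        assert brute_force_code(mu - 2 * sd, q.bin_edges) == 1
        assert brute_force_code(mu + 2 * sd, q.bin_edges) == 255
        assert q.values[0, 0, -1] == 0  # reserved background code

    def test_codes_match_brute_force_bin_search(self, rng):
        values = rng.uniform(-1, 1, 200)
        vol = self._volume(values)
        [q] = quantize([vol])
        for v, code in zip(values, q.values[0, 0, :200]):
            assert code == brute_force_code(v, q.bin_edges)

    def test_pooling_shared_across_volumes(self, rng):
        a = self._volume(rng.uniform(0, 1, 50))
        b = self._volume(rng.uniform(-1, 0, 50))
        qa, qb = quantize([a, b])
        assert np.array_equal(qa.bin_edges, qb.bin_edges)
        assert qa.mean == qb.mean and qa.std == qb.std

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_value(self, values):
        values = [v for v in values if v != 0]
        if len(values) < 2:
            return
        vol = self._volume(values)
        [q] = quantize([vol])
        codes = q.values[0, 0, : len(values)]
        order = np.argsort(values)
        assert np.all(np.diff(codes[order].astype(int)) >= 0)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            quantize([SSFVolume(np.zeros((1, 2, 2)))])
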