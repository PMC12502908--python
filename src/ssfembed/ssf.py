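"""The cell signaling structure function (SSF) and its volume representations.

A kinase translocation reporter (KTR) reads out kinase activity by shuttling
between nucleus and cytoplasm: activation darkens the nucleus relative to the
surrounding cytoplasm.  With per-channel intensities normalized to [0, 1], the
SSF encodes the signaling state of a cell as the signed scalar

    H = c - n   in [-1, 1],

where c is the cytoplasmic and n the nuclear intensity.  Unlike the
conventional cytonuclear ratio C/N, H is a metric function of (c, n): a fixed
perturbation of the intensity pair moves H by a fixed amount regardless of
where in intensity space the cell sits, which is what makes downstream metric
embeddings valid.

In practice H is measured without segmentation: the scale-invariant LoG
response at the cell centroid, at a radius matched to the nucleus, jointly
estimates c and n.  Dividing by the response of an ideal dark spheroid on a
unit background (the reference response) calibrates the filter output to the
[-1, 1] activation scale.

SSF values are assembled into sparse (time, y, x) volumes — zero everywhere
except at cell centroids — which are the unit of comparison for the
compression distances downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .logfilter import (
    ResponseVolume,
    ScaleSpec,
    log_response,
    multiscale_log,
    support_radius_for,
)

__all__ = [
    "Detection",
    "SSFVolume",
    "QuantizedVolume",
    "ssf_from_intensities",
    "reference_response",
    "ssf_at_centroids",
    "build_ssf_volume",
    "velocity_ssf",
    "mip_z",
    "quantize",
    "normalize_channel",
]

logger = logging.getLogger(__name__)

N_QUANT_EDGES = 254  # linearly spaced boundaries; codes 1..255, 0 = no cell


@dataclass
class Detection:
    """One cell at one time point."""

    t: int
    y: float
    x: float
    z: float = 0.0
    radius_um: float = 0.0
    ssf: dict[str, float] = field(default_factory=dict)


@dataclass
class SSFVolume:
    """Sparse (time, y, x) signed SSF array; zero means "no cell here"."""

    values: np.ndarray  # float, shape (T, Y, X), entries in [-1, 1]
    channel: str = ""
    movie_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SSFVolume values must be 3D (time, y, x)")


@dataclass
class QuantizedVolume:
    """8-bit version of an SSF volume; code 0 reserved for background."""

    values: np.ndarray  # uint8, shape (T, Y, X)
    bin_edges: np.ndarray  # 254 edges shared across the experiment
    mean: float
    std: float
    channel: str = ""
    movie_id: str = ""


def ssf_from_intensities(c: float, n: float) -> float:
    """Signed signaling state c - n for normalized intensities c, n in [0, 1]."""
    c = float(c)
    n = float(n)
    if not (0.0 <= c <= 1.0 and 0.0 <= n <= 1.0):
        raise ValueError(f"intensities must lie in [0, 1], got c={c}, n={n}")
    return c - n


def cn_ratio(c: float, n: float) -> float:
    """Conventional cytonuclear ratio C/N — the non-metric baseline readout."""
    return float(c) / float(n)


def cn_fraction(c: float, n: float) -> float:
    """The C/(C+N) variant; better behaved than C/N but still non-metric."""
    return float(c) / (float(c) + float(n))


def normalize_channel(values: np.ndarray, robust: bool = False) -> np.ndarray:
    """Min-max normalize one channel of a movie to [0, 1].

    With ``robust=True`` the 0.1 and 99.9 percentiles are used as the range
    (then clipped), guarding against hot pixels.
    """
    values = np.asarray(values, dtype=float)
    if robust:
        lo, hi = np.percentile(values, [0.1, 99.9])
    else:
        lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros_like(values)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


@lru_cache(maxsize=128)
def _reference_response_cached(
    radius_um: float, voxel_size_um: tuple[float, ...], sigma_rule: str
) -> float:
    spec = ScaleSpec((radius_um,), voxel_size_um, sigma_rule=sigma_rule)
    sigmas = spec.sigmas_voxels(radius_um)
    r_vox = [radius_um / v for v in voxel_size_um]
    half = [int(math.ceil(r)) + 2 * support_radius_for(s) for r, s in zip(r_vox, sigmas)]
    grids = np.meshgrid(*[np.arange(-h, h + 1, dtype=float) for h in half], indexing="ij")
    inside = sum((g / r) ** 2 for g, r in zip(grids, r_vox)) <= 1.0
    img = np.ones_like(grids[0])
    img[inside] = 0.0
    resp = log_response(img, spec).values
    return float(resp.max())


def reference_response(
    radius_um: float,
    voxel_size_um: tuple[float, ...],
    sigma_rule: str = "sqrt_d",
) -> float:
    """Extremal LoG response of an ideal zero-intensity spheroid on unit background.

    This is the calibration constant that maps raw filter responses onto the
    [-1, 1] activation scale: an ideal fully activated cell divided by its own
    reference response reads exactly 1.  Deterministic and cached per
    (radius, voxel size, dimensionality).
    """
    return _reference_response_cached(
        float(radius_um), tuple(float(v) for v in voxel_size_um), sigma_rule
    )


def round_to_voxel(coord: float) -> int:
    """Nearest voxel, ties toward the lower index."""
    return int(math.ceil(coord - 0.5))


def ssf_at_centroids(
    channels: dict[str, np.ndarray],
    detections: list[Detection],
    scales: ScaleSpec,
    calibrate: bool = True,
    normalized: bool = False,
) -> list[Detection]:
    """Fill each detection's per-channel SSF from multiscale LoG responses.

    Parameters
    ----------
    channels : dict
        Channel name -> movie array of shape (T, Y, X) or (T, Z, Y, X).
        Intensities are min-max normalized to [0, 1] per channel over the
        whole movie unless ``normalized`` says they already are.
    detections : list of Detection
        Centroids at which to evaluate; modified in place and returned.
    scales : ScaleSpec
        Radius sweep; per voxel the maximum-magnitude response wins and the
        winning radius selects the calibration constant.
    calibrate : bool
        Divide by the reference response of the winning radius (on by
        default); the result is clipped to [-1, 1].  Sign convention: bright
        cytoplasm / dark nucleus (an activated KTR) gives a positive SSF.
    """
    if not detections:
        return detections
    norm = {
        name: (np.asarray(arr, dtype=float) if normalized else normalize_channel(arr))
        for name, arr in channels.items()
    }
    by_frame: dict[int, list[Detection]] = {}
    skipped = 0
    some = next(iter(norm.values()))
    spatial_shape = some.shape[1:]
    is_3d = some.ndim == 4
    for det in detections:
        idx = (round_to_voxel(det.z), round_to_voxel(det.y), round_to_voxel(det.x))
        if not is_3d:
            idx = idx[1:]
        if any(i < 0 or i >= s for i, s in zip(idx, spatial_shape)) or not (
            0 <= det.t < some.shape[0]
        ):
            skipped += 1
            continue
        by_frame.setdefault(int(det.t), []).append(det)
    if skipped:
        logger.warning("skipped %d detections with out-of-bounds centroids", skipped)

    for t, dets in by_frame.items():
        for name, arr in norm.items():
            resp = multiscale_log(arr[t], scales)
            for det in dets:
                idx = (round_to_voxel(det.z), round_to_voxel(det.y), round_to_voxel(det.x))
                if not is_3d:
                    idx = idx[1:]
                value = float(resp.values[idx])
                r_win = resp.winning_radius(idx)
                det.radius_um = r_win
                if calibrate:
                    value /= reference_response(
                        r_win, scales.voxel_size_um, scales.sigma_rule
                    )
                    value = float(np.clip(value, -1.0, 1.0))
                det.ssf[name] = value
    return detections


def build_ssf_volume(
    detections: list[Detection],
    shape: tuple[int, int, int],
    channel: str,
    movie_id: str = "",
) -> SSFVolume:
    """Scatter per-detection SSF values into a sparse (time, y, x) volume.

    Collisions (two detections rounding to the same voxel) keep the value of
    larger magnitude.
    """
    values = np.zeros(shape, dtype=float)
    for det in detections:
        if channel not in det.ssf:
            continue
        t = int(det.t)
        y = round_to_voxel(det.y)
        x = round_to_voxel(det.x)
        if not (0 <= t < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
            continue
        v = det.ssf[channel]
        if abs(v) >= abs(values[t, y, x]):
            values[t, y, x] = v
    return SSFVolume(values=values, channel=channel, movie_id=movie_id)


def velocity_ssf(
    tracks,
    gate_um_per_frame: float,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, ...] = (1.0, 1.0),
    movie_id: str = "",
) -> SSFVolume:
    """Per-centroid normalized cell speed as a sparse SSF volume.

    At each interior track point the value is the mean of the two adjacent
    per-frame displacement magnitudes (in um) divided by the velocity gate,
    clipped to [0, 1]; endpoints use their single available displacement.
    """
    if gate_um_per_frame <= 0:
        raise ValueError("gate must be positive")
    vz = voxel_size_um if len(voxel_size_um) == 3 else (1.0,) + tuple(voxel_size_um)
    values = np.zeros(shape, dtype=float)
    for track in tracks:
        pts = track.points if hasattr(track, "points") else track
        if len(pts) < 2:
            continue
        coords = np.array([(p.z * vz[0], p.y * vz[1], p.x * vz[2]) for p in pts])
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        for i, p in enumerate(pts):
            if i == 0:
                speed = steps[0]
            elif i == len(pts) - 1:
                speed = steps[-1]
            else:
                speed = 0.5 * (steps[i - 1] + steps[i])
            v = min(speed / gate_um_per_frame, 1.0)
            t, y, x = int(p.t), round_to_voxel(p.y), round_to_voxel(p.x)
            if 0 <= t < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]:
                values[t, y, x] = v
    return SSFVolume(values=values, channel="velocity", movie_id=movie_id)


def mip_z(ssf_4d: np.ndarray, channel: str = "", movie_id: str = "") -> SSFVolume:
    """Signed maximum-intensity projection along z: (T, Z, Y, X) -> (T, Y, X).

    Per (t, y, x) column the value of maximal absolute magnitude is kept with
    its sign, so inhibition is not erased by weaker activation.
    """
    arr = np.asarray(ssf_4d, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a 4D (time, z, y, x) array")
    idx = np.abs(arr).argmax(axis=1)
    values = np.take_along_axis(arr, idx[:, None], axis=1)[:, 0]
    return SSFVolume(values=values, channel=channel, movie_id=movie_id)


def quantize(volumes: list[SSFVolume]) -> list[QuantizedVolume]:
    """Quantize SSF volumes to 8 bits with a bin mapping shared across the experiment.

    All nonzero voxels of all input volumes are pooled into a multiset V;
    254 linearly spaced boundaries on (mean(V) - std(V), mean(V) + std(V))
    define 255 bins mapped to codes 1..255 (values below the range saturate to
    1, above to 255); zeros stay 0.  Sharing the mapping keeps volumes of one
    experiment comparable byte-for-byte for the compressor.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    pooled = np.concatenate([v.values[v.values != 0].ravel() for v in volumes])
    if pooled.size == 0:
        raise ValueError("all volumes are zero: nothing to quantize")
    mu = float(pooled.mean())
    sd = float(pooled.std())
    degenerate = sd == 0.0  # all nonzero voxels identical -> midscale code
    edges = np.linspace(mu - sd, mu + sd, N_QUANT_EDGES)
    out = []
    for v in volumes:
        codes = np.zeros(v.values.shape, dtype=np.uint8)
        nz = v.values != 0
        if degenerate:
            codes[nz] = 128
        else:
            codes[nz] = np.searchsorted(edges, v.values[nz], side="right") + 1
        out.append(
            QuantizedVolume(
                values=codes,
                bin_edges=edges,
                mean=mu,
                std=sd,
                channel=v.channel,
                movie_id=v.movie_id,
            )
        )
    return out
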