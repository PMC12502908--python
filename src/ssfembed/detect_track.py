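"""Unsupervised cell centroid detection and simple frame-to-frame linking.

Detection is segmentation-free: the nuclear (H2B) channel is denoised, the
calibrated multiscale LoG response is thresholded — a bright nucleus gives a
*negative* response, so foreground is response < -threshold — and touching
cells are separated by a watershed on the combined (summed) multiscale
response of all channels.  Each region yields one detection at its
intensity-weighted centroid together with the winning radius of the sweep.

Linking is greedy mutual-nearest-neighbor between consecutive frames with a
displacement gate; that is all the velocity readout needs (adjacent-frame
displacements), deliberately far short of a full multi-frame tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.restoration import denoise_nl_means
from skimage.segmentation import watershed

from .logfilter import ScaleSpec, log_response
from .ssf import Detection, normalize_channel, reference_response

__all__ = ["Track", "denoise", "detect_cells", "link_tracks"]


@dataclass
class Track:
    """Detections on strictly consecutive frames."""

    track_id: int
    points: list[Detection] = field(default_factory=list)

    def __len__(self):
        return len(self.points)


def denoise(
    volume: np.ndarray,
    patch_size: int = 7,
    patch_distance: int = 10,
    h: float | None = None,
) -> np.ndarray:
    """Non-local means denoising, frame by frame for stacks.

    The filtering strength ``h`` defaults to 1.15 times the per-frame noise
    standard deviation estimated by wavelet-based sigma estimation; pass an
    explicit value to override.
    """
    from skimage.restoration import estimate_sigma

    volume = np.asarray(volume, dtype=float)

    def _one(frame):
        sigma = float(estimate_sigma(frame))
        strength = h if h is not None else 1.15 * sigma
        if strength <= 0:
            return frame.copy()
        return denoise_nl_means(
            frame,
            patch_size=patch_size,
            patch_distance=patch_distance,
            h=strength,
            sigma=sigma,
            fast_mode=True,
        )

    if volume.ndim == 2:
        return _one(volume)
    return np.stack([_one(f) for f in volume])


def calibrated_multiscale(frame: np.ndarray, scales: ScaleSpec):
    """Multiscale LoG with each radius's response divided by its reference response.

    Returns (values, scale_index); calibration puts every scale on the common
    [-1, 1] activation scale so the empirical SSF threshold applies uniformly.
    """
    best = None
    best_idx = None
    for i, r in enumerate(scales.radii_um):
        ref = reference_response(r, scales.voxel_size_um, scales.sigma_rule)
        resp = log_response(frame, scales, radius_um=r).values / ref
        if best is None:
            best, best_idx = resp, np.zeros(frame.shape, dtype=np.intp)
        else:
            take = np.abs(resp) > np.abs(best)
            best = np.where(take, resp, best)
            best_idx[take] = i
    return best, best_idx


def detect_cells(
    channels: dict[str, np.ndarray],
    scales: ScaleSpec,
    h2b_channel: str,
    threshold: float = 0.01,
    min_separation_um: float | None = None,
    marker_rel_depth: float = 0.1,
) -> list[Detection]:
    """Detect cell centroids on every frame from the nuclear-channel SSF.

    Foreground is where the calibrated H2B response is below ``-threshold``
    (the empirical SSF threshold, default 0.01).  Touching cells are split by
    a watershed on the summed multiscale responses of all channels, seeded at
    local minima of that combined response.  A marker must be deeper than
    ``max(threshold, marker_rel_depth * deepest minimum in the frame)``: the
    relative floor rejects shallow minima carved out of residual correlated
    noise, which can clear the tiny absolute threshold while remaining an
    order of magnitude shallower than any true nucleus.  Foreground with no
    marker is discarded.
    """
    if h2b_channel not in channels:
        raise ValueError(f"H2B channel {h2b_channel!r} not among {sorted(channels)}")
    norm = {name: normalize_channel(arr) for name, arr in channels.items()}
    n_frames = next(iter(norm.values())).shape[0]
    if min_separation_um is None:
        min_separation_um = min(scales.radii_um)
    min_sep_vox = max(1, int(round(min_separation_um / min(scales.voxel_size_um))))

    detections: list[Detection] = []
    for t in range(n_frames):
        h2b_resp, scale_idx = calibrated_multiscale(norm[h2b_channel][t], scales)
        foreground = h2b_resp < -threshold
        if not foreground.any():
            continue
        combined = h2b_resp.copy()
        for name, arr in norm.items():
            if name == h2b_channel:
                continue
            resp, _ = calibrated_multiscale(arr[t], scales)
            combined += resp
        # nuclei are minima of the combined response; seed watershed there
        depth_floor = max(threshold, marker_rel_depth * float(-combined.min()))
        peaks = peak_local_max(
            -combined,
            min_distance=min_sep_vox,
            threshold_abs=depth_floor,
            labels=cc_label(foreground),
        )
        if len(peaks) == 0:
            continue
        markers = np.zeros(combined.shape, dtype=np.int32)
        for i, p in enumerate(peaks, start=1):
            markers[tuple(p)] = i
        regions = watershed(combined, markers=markers, mask=foreground)
        weights = np.abs(combined)
        for lab in range(1, regions.max() + 1):
            mask = regions == lab
            if not mask.any():
                continue
            w = weights[mask]
            coords = np.argwhere(mask)
            centroid = (coords * w[:, None]).sum(axis=0) / w.sum()
            peak_vox = tuple(coords[np.argmax(w)])
            radius = scales.radii_um[int(scale_idx[peak_vox])]
            if combined.ndim == 2:
                det = Detection(t=t, y=centroid[0], x=centroid[1], radius_um=radius)
            else:
                det = Detection(
                    t=t, z=centroid[0], y=centroid[1], x=centroid[2], radius_um=radius
                )
            detections.append(det)
    return detections


def _positions_um(dets: list[Detection], voxel_size_um) -> np.ndarray:
    vz = voxel_size_um if len(voxel_size_um) == 3 else (1.0,) + tuple(voxel_size_um)
    return np.array([(d.z * vz[0], d.y * vz[1], d.x * vz[2]) for d in dets])


def link_tracks(
    detections: list[Detection],
    gate_um_per_frame: float,
    voxel_size_um: tuple[float, ...] = (1.0, 1.0),
) -> list[Track]:
    """Greedy mutual-nearest-neighbor linking between consecutive frames.

    A link is made only when two detections are each other's nearest neighbor
    in the next/previous frame and their displacement is within the gate;
    anything unlinked starts a new track.
    """
    if gate_um_per_frame <= 0:
        raise ValueError("gate must be positive")
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(int(d.t), []).append(d)
    if not by_frame:
        return []

    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}  # index into current frame's dets -> track

    frames = sorted(by_frame)
    prev_dets: list[Detection] = []
    for fi, t in enumerate(frames):
        dets = by_frame[t]
        new_open: dict[int, Track] = {}
        linked_cur: set[int] = set()
        contiguous = fi > 0 and frames[fi - 1] == t - 1
        if contiguous and prev_dets and dets:
            dist = cdist(
                _positions_um(prev_dets, voxel_size_um),
                _positions_um(dets, voxel_size_um),
            )
            nn_fwd = dist.argmin(axis=1)
            nn_bwd = dist.argmin(axis=0)
            for i, j in enumerate(nn_fwd):
                if nn_bwd[j] == i and dist[i, j] <= gate_um_per_frame and i in open_tracks:
                    track = open_tracks[i]
                    track.points.append(dets[j])
                    new_open[j] = track
                    linked_cur.add(j)
        for j, d in enumerate(dets):
            if j not in linked_cur:
                track = Track(track_id=len(tracks), points=[d])
                tracks.append(track)
                new_open[j] = track
        open_tracks = new_open
        prev_dets = dets
    return tracks
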