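"""Synthetic inputs: KTR activation phantoms, constant-velocity SSF corpora,
and raw moving-nuclei movies.

These generators define the study conditions the rest of the package is
exercised on:

* ``ktr_phantom`` — a single cell as a dark nucleus (intensity 0) on a bright
  field (intensity 1).  Shot noise parameterizes activation: at activation
  ``a`` each compartment flips a fraction p = (1 - a)/2 of its pixels to the
  opposite intensity, so the expected compartment intensities are
  (c, n) = ((1 + a)/2, (1 - a)/2) and the expected SSF is exactly ``a``.
* ``velocity_phantom_set`` — 2D+time SSF volumes of 10 tracks per image
  moving at per-track constant speed drawn from Normal(class mean, 0.5),
  class means {1, 3, 5} px/frame; the speed is written at each centroid on a
  velocity channel and a uniform random value in [1, 255] on a second
  channel.  Three classes, 100 images per class at full scale.
* ``moving_cells_movie`` — raw Gaussian-blob nuclei with known ground-truth
  tracks, for exercising detection and linking.

All outputs are deterministic functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssf import SSFVolume, round_to_voxel

__all__ = [
    "KTRPhantomSpec",
    "VelocityPhantomSpec",
    "VelocityPhantom",
    "ktr_phantom",
    "velocity_phantom_set",
    "moving_cells_movie",
]


@dataclass(frozen=True)
class KTRPhantomSpec:
    """Geometry and noise model of the single-cell KTR phantom.

    The cytoplasm is the annulus between the nucleus radius and the outer
    radius; pixels beyond the annulus are clean background at intensity 1.
    The default size is odd so the cell is centered on a voxel, matching the
    voxel-centered disk used for the reference-response calibration.
    """

    image_size: int = 65
    nucleus_radius_px: float = 5.0
    cytoplasm_radius_px: float = 20.0
    activation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError("activation must lie in [0, 1]")
        if not 0 < self.nucleus_radius_px < self.cytoplasm_radius_px < self.image_size / 2:
            raise ValueError(
                "need 0 < nucleus radius < cytoplasm radius < image half-size"
            )


def ktr_phantom(spec: KTRPhantomSpec, rng: np.random.Generator | None = None):
    """One noisy phantom image plus its ground-truth activation.

    Base image: nucleus disk 0 on background 1.  Shot noise flips each
    nuclear pixel to 1 and each cytoplasmic pixel to 0 independently with
    probability p = (1 - activation)/2; at activation 0.6 that is the
    20%-white / 20%-black ("40% shot noise") condition and the phantom
    represents a cell at 60% activation.

    Returns (image, activation, center) with center the nucleus centroid in
    (y, x) voxels.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    nucleus = r2 <= spec.nucleus_radius_px**2
    cytoplasm = (r2 > spec.nucleus_radius_px**2) & (r2 <= spec.cytoplasm_radius_px**2)
    img = np.ones((n, n))
    img[nucleus] = 0.0
    p = (1.0 - spec.activation) / 2.0
    if p > 0:
        flips = rng.random((n, n)) < p
        img[nucleus & flips] = 1.0
        img[cytoplasm & flips] = 0.0
    return img, spec.activation, (c, c)


@dataclass(frozen=True)
class VelocityPhantomSpec:
    """Constant-velocity SSF corpus: three speed classes of simulated motion."""

    n_tracks: int = 10
    class_means: tuple[float, ...] = (1.0, 3.0, 5.0)
    sigma: float = 0.5
    n_images_per_class: int = 100
    frames: int = 64
    field_size: int = 128
    value_range: tuple[int, int] = (1, 255)
    seed: int = 0

    def __post_init__(self):
        if any(m <= 0 for m in self.class_means):
            raise ValueError("class mean speeds must be positive")
        if self.n_tracks < 1 or self.n_images_per_class < 1 or self.frames < 2:
            raise ValueError("counts must be positive (and frames >= 2)")

    @property
    def speed_norm(self) -> float:
        """Normalization constant keeping velocity values in (0, 1]: max mean + 3 sigma."""
        return max(self.class_means) + 3.0 * self.sigma


@dataclass
class VelocityPhantom:
    """One synthetic movie: velocity and random channels plus ground truth."""

    velocity: SSFVolume
    random: SSFVolume
    label: int
    speeds: np.ndarray  # true per-track speed, px/frame
    tracks: list[np.ndarray]  # per track, (frames, 2) float (y, x) positions


def _truncated_normal_speed(rng: np.random.Generator, mean: float, sigma: float) -> float:
    while True:
        s = rng.normal(mean, sigma)
        if s > 0:
            return float(s)


def _reflect(pos: float, size: float) -> float:
    period = 2.0 * size
    pos = pos % period
    return period - pos if pos > size else pos


def velocity_phantom_set(spec: VelocityPhantomSpec) -> list[VelocityPhantom]:
    """Generate the full corpus (n_images_per_class movies per speed class).

    Per movie: ``n_tracks`` tracks with uniform random start positions and
    headings, per-track constant speed ~ Normal(class mean, sigma) truncated
    positive, reflecting boundaries.  At each rounded centroid, channel one
    carries speed / (max class mean + 3 sigma) and channel two an independent
    uniform integer in [1, 255] rescaled to (0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    size = float(spec.field_size - 1)
    lo, hi = spec.value_range
    out = []
    for label, mean in enumerate(spec.class_means):
        for i in range(spec.n_images_per_class):
            vel = np.zeros((spec.frames, spec.field_size, spec.field_size))
            rnd = np.zeros_like(vel)
            speeds = np.empty(spec.n_tracks)
            tracks = []
            for k in range(spec.n_tracks):
                speed = _truncated_normal_speed(rng, mean, spec.sigma)
                speeds[k] = speed
                theta = rng.uniform(0, 2 * np.pi)
                vy, vx = speed * np.sin(theta), speed * np.cos(theta)
                y, x = rng.uniform(0, size), rng.uniform(0, size)
                pos = np.empty((spec.frames, 2))
                for t in range(spec.frames):
                    pos[t] = (_reflect(y + t * vy, size), _reflect(x + t * vx, size))
                    iy, ix = round_to_voxel(pos[t, 0]), round_to_voxel(pos[t, 1])
                    vel[t, iy, ix] = speed / spec.speed_norm
                    rnd[t, iy, ix] = rng.integers(lo, hi + 1) / float(hi)
                tracks.append(pos)
            movie_id = f"class{label}_img{i}"
            out.append(
                VelocityPhantom(
                    velocity=SSFVolume(vel, channel="velocity", movie_id=movie_id),
                    random=SSFVolume(rnd, channel="random", movie_id=movie_id),
                    label=label,
                    speeds=speeds,
                    tracks=tracks,
                )
            )
    return out


def moving_cells_movie(
    n_cells: int,
    speeds,
    radius_px: float = 5.0,
    frames: int = 16,
    field_size: int = 128,
    noise: float = 0.0,
    seed: int = 0,
):
    """Raw nuclear-channel movie of Gaussian-blob nuclei with known tracks.

    Bright blobs (peak 1) on dark background move at the given constant
    per-cell speeds with random headings and reflecting boundaries; optional
    additive Gaussian noise of standard deviation ``noise`` (fraction of the
    dynamic range).  Returns (movie (T, Y, X), tracks) with tracks the exact
    per-cell (frames, 2) positions.
    """
    rng = np.random.default_rng(seed)
    speeds = np.broadcast_to(np.asarray(speeds, float), (n_cells,))
    size = float(field_size - 1)
    yy, xx = np.mgrid[:field_size, :field_size].astype(float)
    movie = np.zeros((frames, field_size, field_size))
    tracks = []
    margin = 2.5 * radius_px
    starts: list[tuple[float, float]] = []
    for k in range(n_cells):
        theta = rng.uniform(0, 2 * np.pi)
        vy, vx = speeds[k] * np.sin(theta), speeds[k] * np.cos(theta)
        # rejection-sample starts so nuclei begin well separated (>= 4 radii)
        for _ in range(1000):
            y = rng.uniform(margin, size - margin)
            x = rng.uniform(margin, size - margin)
            if all(np.hypot(y - sy, x - sx) >= 4 * radius_px for sy, sx in starts):
                break
        starts.append((y, x))
        pos = np.empty((frames, 2))
        for t in range(frames):
            pos[t] = (_reflect(y + t * vy, size), _reflect(x + t * vx, size))
        tracks.append(pos)
    sig = radius_px / 2.0
    for t in range(frames):
        for pos in tracks:
            movie[t] += np.exp(
                -((yy - pos[t][0]) ** 2 + (xx - pos[t][1]) ** 2) / (2 * sig**2)
            )
        np.clip(movie[t], 0, 1, out=movie[t])
    if noise > 0:
        movie = movie + rng.normal(0, noise, movie.shape)
    return movie, tracks
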