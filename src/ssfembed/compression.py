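"""Lossless-compression size oracles and the normalized compression distance.

The normalized information distance between two objects — the length of the
shortest program converting one into the other, normalized by the larger
complexity — is uncomputable; the normalized compression distance (NCD)
approximates it with a real compressor Z:

    NCD(x, y) = (Z(xy) - min(Z(x), Z(y))) / max(Z(x), Z(y)),

where xy is the concatenation.  Applied to quantized SSF volumes it measures
spatiotemporal pattern dissimilarity between whole movies with no model of the
expected dynamics.  NCD values are backend-dependent; every distance matrix
records which backend produced it.

Backends: an external FLIF binary (3D-capable lossless image codec) when
installed, and built-in stream backends (LZMA, the default, and zlib) applied
to the raw voxel stream in fixed (t, y, x) order.  LZMA's large dictionary is
what lets Z(xy) pick up redundancy between the two halves of a concatenated
pair; windowed codecs lose that ability once volumes outgrow the window.
"""

from __future__ import annotations

import hashlib
import lzma
import shutil
import subprocess
import tempfile
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ssf import QuantizedVolume

__all__ = [
    "CompressionBackend",
    "LzmaBackend",
    "ZlibBackend",
    "FlifBackend",
    "BackendUnavailableError",
    "get_backend",
    "compressed_size",
    "concat_volumes",
    "ncd",
    "pairwise_ncd",
    "DistanceMatrix",
]


class BackendUnavailableError(RuntimeError):
    """Raised when a requested compression backend cannot run (e.g. no FLIF binary)."""


class CompressionBackend:
    """Deterministic lossless byte-count oracle for 8-bit 3D volumes."""

    name = "abstract"

    def compress_bytes(self, volume: np.ndarray) -> bytes:
        raise NotImplementedError

    def size(self, volume: np.ndarray) -> int:
        volume = np.ascontiguousarray(volume, dtype=np.uint8)
        return len(self.compress_bytes(volume))


class LzmaBackend(CompressionBackend):
    """LZMA over the raw voxel stream in (t, y, x) order.  Default backend."""

    name = "lzma"

    def __init__(self, preset: int = 6):
        self.preset = preset

    def compress_bytes(self, volume: np.ndarray) -> bytes:
        return lzma.compress(volume.tobytes(order="C"), preset=self.preset)

    def decompress(self, data: bytes, shape: tuple[int, ...]) -> np.ndarray:
        return np.frombuffer(lzma.decompress(data), dtype=np.uint8).reshape(shape)


class ZlibBackend(CompressionBackend):
    """zlib over the raw voxel stream; only suitable for volumes under its 32 KB window."""

    name = "zlib"

    def __init__(self, level: int = 9):
        self.level = level

    def compress_bytes(self, volume: np.ndarray) -> bytes:
        return zlib.compress(volume.tobytes(order="C"), self.level)

    def decompress(self, data: bytes, shape: tuple[int, ...]) -> np.ndarray:
        return np.frombuffer(zlib.decompress(data), dtype=np.uint8).reshape(shape)


class FlifBackend(CompressionBackend):
    """External FLIF binary invoked per volume via temporary files.

    The volume's time axis is passed as FLIF's third (frame) dimension by
    writing a multi-frame PAM/PNG sequence.  Raises
    :class:`BackendUnavailableError` if the binary is not on PATH — never a
    silent fallback.
    """

    name = "flif"

    def __init__(self, binary: str = "flif"):
        self.binary = binary
        if shutil.which(binary) is None:
            raise BackendUnavailableError(
                f"FLIF binary {binary!r} not found on PATH; use the built-in "
                "'lzma' backend or install FLIF"
            )

    def compress_bytes(self, volume: np.ndarray) -> bytes:
        import imageio.v3 as iio  # optional path, only reached when FLIF exists

        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            pngs = []
            for t in range(volume.shape[0]):
                p = tmp / f"frame{t:05d}.png"
                iio.imwrite(p, volume[t])
                pngs.append(str(p))
            out = tmp / "out.flif"
            subprocess.run(
                [self.binary, "-e", "--overwrite", *pngs, str(out)],
                check=True,
                capture_output=True,
            )
            return out.read_bytes()


_BACKENDS = {"lzma": LzmaBackend, "zlib": ZlibBackend, "flif": FlifBackend}


def get_backend(name: str, **kwargs) -> CompressionBackend:
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}")
    return cls(**kwargs)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise NCD matrix with provenance."""

    values: np.ndarray
    ids: list[str]
    backend: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")


def _as_array(volume) -> np.ndarray:
    arr = volume.values if isinstance(volume, QuantizedVolume) else np.asarray(volume)
    return np.ascontiguousarray(arr, dtype=np.uint8)


def compressed_size(volume, backend: CompressionBackend) -> int:
    """Byte count of the volume's lossless compressed representation."""
    return backend.size(_as_array(volume))


def concat_volumes(x, y) -> np.ndarray:
    """Concatenate two volumes along the time axis (x first).

    Time axes of unequal length are allowed (no padding needed for a plain
    concatenation); spatial shapes must agree.
    """
    ax, ay = _as_array(x), _as_array(y)
    if ax.shape[1:] != ay.shape[1:]:
        raise ValueError(f"spatial shapes differ: {ax.shape[1:]} vs {ay.shape[1:]}")
    return np.concatenate([ax, ay], axis=0)


def ncd(x, y, backend: CompressionBackend) -> float:
    """Symmetrized normalized compression distance between two volumes.

    Both concatenation orders are compressed and the two NCD values averaged,
    cancelling the compressor's slight order dependence.  An all-zero pair is
    defined as distance 0.
    """
    ax, ay = _as_array(x), _as_array(y)
    zx, zy = backend.size(ax), backend.size(ay)
    if not ax.any() and not ay.any():
        import logging

        logging.getLogger(__name__).warning("NCD of two all-zero volumes defined as 0")
        return 0.0
    lo, hi = min(zx, zy), max(zx, zy)
    zxy = backend.size(concat_volumes(ax, ay))
    zyx = backend.size(concat_volumes(ay, ax))
    return 0.5 * ((zxy - lo) / hi + (zyx - lo) / hi)


def pairwise_ncd(
    volumes: list,
    backend: CompressionBackend,
    ids: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise NCD matrix over a corpus of quantized volumes.

    Singleton compressed sizes are computed once (N calls); each unordered
    pair is compressed once in canonical order i<j (N(N-1)/2 calls), so the
    matrix is symmetric by construction.  The diagonal is forced to zero, and
    byte-identical volumes (detected by content hash) are likewise assigned
    distance zero: a real compressor reports a slightly positive self-NCD,
    but the information distance between identical objects is zero and the
    downstream embedding needs a proper dissimilarity.
    """
    n = len(volumes)
    if n < 2:
        raise ValueError("need at least two volumes")
    arrays = [_as_array(v) for v in volumes]
    if ids is None:
        ids = [
            getattr(v, "movie_id", "") or f"volume{i}" for i, v in enumerate(volumes)
        ]
    hashes = [content_hash(a) for a in arrays]
    singles = [backend.size(a) for a in arrays]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if hashes[i] == hashes[j]:
                continue
            try:
                zxy = backend.size(concat_volumes(arrays[i], arrays[j]))
            except Exception as exc:  # noqa: BLE001 - annotate the offending pair
                raise RuntimeError(
                    f"backend {backend.name!r} failed on pair ({ids[i]}, {ids[j]})"
                ) from exc
            lo, hi = min(singles[i], singles[j]), max(singles[i], singles[j])
            D[i, j] = D[j, i] = (zxy - lo) / hi if hi > 0 else 0.0
    return DistanceMatrix(values=D, ids=list(ids), backend=backend.name)


def content_hash(volume) -> str:
    """Stable content key used for caching compressed sizes across pipeline stages."""
    arr = _as_array(volume)
    h = hashlib.sha1()
    h.update(str(arr.shape).encode())
    h.update(arr.tobytes(order="C"))
    return h.hexdigest()
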