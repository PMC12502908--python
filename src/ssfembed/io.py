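"""Serialization: TIFF volumes, CSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .compression import DistanceMatrix
from .embedding import EmbeddingSpace
from .ssf import Detection, QuantizedVolume, SSFVolume

__all__ = [
    "read_movie",
    "save_ssf_volume",
    "load_ssf_volume",
    "save_quantized_volume",
    "load_quantized_volume",
    "detections_to_csv",
    "detections_from_csv",
    "save_distance_matrix",
    "load_distance_matrix",
    "save_embedding",
    "write_json",
]


def read_movie(path, axes: str | None = None) -> np.ndarray:
    """Read a multipage TIFF movie into a (T, C, Z, Y, X) array.

    The axis layout is taken from the TIFF metadata when present; otherwise
    pass ``axes`` (a subset/permutation of "TCZYX", e.g. "TYX").  Missing axes
    get length-1 dimensions.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        arr = series.asarray()
        layout = axes or series.axes
    layout = layout.upper().replace("S", "C").replace("Q", "T")
    if len(layout) != arr.ndim:
        raise ValueError(f"axes {layout!r} do not match array with {arr.ndim} dims")
    order = [layout.index(a) for a in "TCZYX" if a in layout]
    arr = np.transpose(arr, order)
    present = [a for a in "TCZYX" if a in layout]
    for i, a in enumerate("TCZYX"):
        if a not in present:
            arr = np.expand_dims(arr, i)
    return arr


def save_ssf_volume(volume: SSFVolume, path) -> None:
    tifffile.imwrite(
        str(path),
        volume.values.astype(np.float32),
        metadata={"axes": "TYX", "channel": volume.channel, "movie_id": volume.movie_id},
    )


def load_ssf_volume(path, channel: str = "", movie_id: str = "") -> SSFVolume:
    values = tifffile.imread(str(path)).astype(float)
    if values.ndim == 2:
        values = values[None]
    return SSFVolume(values=values, channel=channel, movie_id=movie_id)


def save_quantized_volume(volume: QuantizedVolume, path) -> None:
    path = Path(path)
    tifffile.imwrite(str(path), volume.values, metadata={"axes": "TYX"})
    sidecar = {
        "bin_edges": list(map(float, volume.bin_edges)),
        "mean": volume.mean,
        "std": volume.std,
        "channel": volume.channel,
        "movie_id": volume.movie_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_quantized_volume(path) -> QuantizedVolume:
    path = Path(path)
    values = tifffile.imread(str(path))
    if values.ndim == 2:
        values = values[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    return QuantizedVolume(
        values=values.astype(np.uint8),
        bin_edges=np.asarray(meta["bin_edges"]),
        mean=meta["mean"],
        std=meta["std"],
        channel=meta.get("channel", ""),
        movie_id=meta.get("movie_id", ""),
    )


def detections_to_csv(detections: list[Detection], path, movie_id: str = "", track_ids=None) -> None:
    rows = []
    channels = sorted({ch for d in detections for ch in d.ssf})
    for i, d in enumerate(detections):
        row = {
            "movie_id": movie_id,
            "track_id": track_ids[i] if track_ids is not None else -1,
            "t": d.t,
            "x": d.x,
            "y": d.y,
            "z": d.z,
            "radius_um": d.radius_um,
        }
        for ch in channels:
            row[f"ssf_{ch}"] = d.ssf.get(ch, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def detections_from_csv(path) -> list[Detection]:
    df = pd.read_csv(path)
    ssf_cols = [c for c in df.columns if c.startswith("ssf_")]
    out = []
    for _, row in df.iterrows():
        ssf = {
            c[len("ssf_") :]: float(row[c]) for c in ssf_cols if not pd.isna(row[c])
        }
        out.append(
            Detection(
                t=int(row["t"]),
                y=float(row["y"]),
                x=float(row["x"]),
                z=float(row.get("z", 0.0)),
                radius_um=float(row.get("radius_um", 0.0)),
                ssf=ssf,
            )
        )
    return out


def save_distance_matrix(D: DistanceMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(D.values, index=D.ids, columns=D.ids).to_csv(path)
    path.with_suffix(".json").write_text(json.dumps({"backend": D.backend}))


def load_distance_matrix(path) -> DistanceMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = {}
    if path.with_suffix(".json").exists():
        meta = json.loads(path.with_suffix(".json").read_text())
    return DistanceMatrix(
        values=df.to_numpy(float),
        ids=[str(i) for i in df.index],
        backend=meta.get("backend", "unknown"),
    )


def save_embedding(space: EmbeddingSpace, path) -> None:
    path = Path(path)
    cols = {f"dim{j}": space.coordinates[:, j] for j in range(space.coordinates.shape[1])}
    pd.DataFrame({"movie_id": space.ids, **cols}).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "eigenvalues": list(map(float, space.eigenvalues)),
                "total_inertia": space.total_inertia,
                "dropped_mass": space.dropped_mass,
            }
        )
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
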