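"""Cluster structure function: scoring how meaningful an embedding is.

The cluster structure function (CSF) asks, for a labeled partition of a
corpus, how cheaply each member is described by its cluster.  In compression
form the optimality deficiency of member y_i of cluster Y is

    delta(Y, y_i) = Z(Y) + log2(|Y|) - Z(y_i),

with Z the compressed size of the concatenated cluster; describing y_i as "an
element of Y plus its ordinal" should cost little more than describing y_i
directly when the cluster is a meaningful model.  Compressing whole clusters
of large movies is intractable, so the working form evaluates the same idea in
the embedding: the deficiency of a point is its Euclidean distance to its own
cluster centroid.  Lower CSF means the embedding represents the partition more
meaningfully.

Aggregation: per-cluster mean deficiencies are averaged across the K clusters
(mean and std over the K per-cluster means).  A per-element variant (mean/std
over all n deficiencies) is also reported, since both summaries are useful
when comparing conditions.  Paired comparisons between two conditions measured
on the same movies use the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .compression import CompressionBackend, compressed_size, concat_volumes
from .embedding import EmbeddingSpace

__all__ = ["Partition", "CSFResult", "csf_rkhs", "csf_compression", "compare_paired_csf"]

#: Refuse to concatenate clusters beyond this many voxels (use csf_rkhs instead).
MAX_CLUSTER_VOXELS = 256 * 1024 * 1024


@dataclass
class Partition:
    """Class label per movie."""

    labels: list

    def __post_init__(self):
        if not self.labels:
            raise ValueError("partition needs at least one label")

    @property
    def classes(self) -> list:
        return sorted(set(self.labels), key=str)

    @property
    def K(self) -> int:
        return len(self.classes)

    def members(self, cls) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == cls]


@dataclass
class CSFResult:
    mean: float
    std: float
    per_cluster_means: dict
    per_element_deficiencies: np.ndarray
    per_element_mean: float = 0.0
    per_element_std: float = 0.0
    method: str = ""
    extra: dict = field(default_factory=dict)


def _aggregate(deficiencies: np.ndarray, partition: Partition, method: str) -> CSFResult:
    per_cluster = {}
    for cls in partition.classes:
        idx = partition.members(cls)
        if not idx:
            raise ValueError(f"cluster {cls!r} has no members")
        per_cluster[cls] = float(np.mean(deficiencies[idx]))
    cluster_means = np.array(list(per_cluster.values()))
    return CSFResult(
        mean=float(cluster_means.mean()),
        std=float(cluster_means.std(ddof=0)),
        per_cluster_means=per_cluster,
        per_element_deficiencies=deficiencies,
        per_element_mean=float(deficiencies.mean()),
        per_element_std=float(deficiencies.std(ddof=0)),
        method=method,
    )


def csf_rkhs(embedding: EmbeddingSpace | np.ndarray, partition: Partition) -> CSFResult:
    """CSF in the embedding: distance of each point to its own cluster centroid."""
    coords = (
        embedding.coordinates if isinstance(embedding, EmbeddingSpace) else np.asarray(embedding, float)
    )
    if coords.shape[0] != len(partition.labels):
        raise ValueError("one label per embedded point required")
    deficiencies = np.empty(coords.shape[0])
    for cls in partition.classes:
        idx = partition.members(cls)
        centroid = coords[idx].mean(axis=0)
        deficiencies[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    return _aggregate(deficiencies, partition, method="rkhs")


def csf_compression(
    groups: dict | list,
    backend: CompressionBackend,
    log_base: float = 2.0,
) -> CSFResult:
    """CSF directly by compression: delta(Y, y_i) = Z(Y) + log2(|Y|) - Z(y_i).

    ``groups`` maps cluster label -> list of quantized volumes (or is a list
    of lists, labeled 0..K-1).  Z is in bytes; the log term is in the
    Kolmogorov convention (base 2 by default, configurable).  Guarded by a
    total-voxel limit per cluster — past it, use :func:`csf_rkhs`, which
    exists precisely because concatenating many large movies is intractable.
    """
    if not isinstance(groups, dict):
        groups = {i: g for i, g in enumerate(groups)}
    labels = []
    deficiencies = []
    for cls, members in groups.items():
        if not members:
            raise ValueError(f"cluster {cls!r} has no members")
        total_vox = sum(int(np.prod(m.values.shape)) for m in members)
        if total_vox > MAX_CLUSTER_VOXELS:
            raise ValueError(
                f"cluster {cls!r} has {total_vox} voxels, beyond the concatenation "
                "limit; compute the CSF in the embedding (csf_rkhs) instead"
            )
        joint = members[0].values
        for m in members[1:]:
            joint = concat_volumes(joint, m)
        z_joint = backend.size(np.ascontiguousarray(joint, dtype=np.uint8))
        log_card = math.log(len(members), log_base)
        for m in members:
            deficiencies.append(z_joint + log_card - compressed_size(m, backend))
            labels.append(cls)
    partition = Partition(labels=labels)
    return _aggregate(np.asarray(deficiencies, float), partition, method="compression")


def compare_paired_csf(deficiencies_a, deficiencies_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-element deficiencies."""
    a = np.asarray(deficiencies_a, float)
    b = np.asarray(deficiencies_b, float)
    if a.shape != b.shape:
        raise ValueError("paired deficiency vectors must have equal length")
    if np.all(a == b):
        return 1.0  # no nonzero differences: nothing to rank
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
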