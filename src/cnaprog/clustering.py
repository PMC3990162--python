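"""Unsupervised hierarchical clustering of per-sample CNA profiles.

Agglomerative average-linkage (UPGMA-style) clustering on Euclidean
distances, with a chance-adjusted Rand index to quantify how well a k=2 cut
separates the progressive/carcinoma samples from normal/non-progressive ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .core_io import CNACall, Direction, Group, ProbeProfile, SampleMeta

__all__ = [
    "SampleFeatureMatrix",
    "Dendrogram",
    "build_feature_matrix",
    "cluster_samples",
    "cluster_separation",
    "to_newick",
]


@dataclass(frozen=True)
class SampleFeatureMatrix:
    """Samples x genomic-bin features; no missing values (empty bins are 0)."""

    sample_ids: tuple[str, ...]
    columns: tuple[tuple[str, int], ...]  # (chromosome, bin start)
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("values shape does not match sample_ids x columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over samples."""

    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing (monotone linkage)")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def build_feature_matrix(
    data: Sequence[ProbeProfile] | Mapping[str, Sequence[CNACall]],
    mode: str = "binned_log2",
    bin_size: int = 100_000,
    standardize: bool = False,
) -> SampleFeatureMatrix:
    """Turn profiles (``binned_log2``) or calls (``call_indicator``) into a
    sample-by-bin matrix.

    binned_log2: mean probe log2 per fixed-width bin; all profiles must share
    one probe grid; bins with no probes carry 0. call_indicator: +1/-1 for
    bins overlapped by a gain/loss call, 0 elsewhere.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mode == "binned_log2":
        profiles = list(data)  # type: ignore[arg-type]
        if not profiles:
            raise ValueError("no profiles")
        first = profiles[0]
        for p in profiles[1:]:
            if not p.same_grid(first):
                raise ValueError(f"probe grid mismatch for sample {p.sample_id}")
        bins = sorted(
            {(c, int(pos) // bin_size * bin_size) for c, pos in zip(first.chromosomes, first.positions)},
            key=lambda b: (int(b[0][3:]), b[1]),
        )
        index = {b: i for i, b in enumerate(bins)}
        col = np.array(
            [index[(c, int(pos) // bin_size * bin_size)] for c, pos in zip(first.chromosomes, first.positions)]
        )
        counts = np.bincount(col, minlength=len(bins))
        values = np.zeros((len(profiles), len(bins)))
        for i, p in enumerate(profiles):
            sums = np.bincount(col, weights=p.log2, minlength=len(bins))
            values[i] = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
        sample_ids = tuple(p.sample_id for p in profiles)
    elif mode == "call_indicator":
        calls: Mapping[str, Sequence[CNACall]] = data  # type: ignore[assignment]
        sample_ids = tuple(calls.keys())
        bin_set: set[tuple[str, int]] = set()
        for cs in calls.values():
            for call in cs:
                if call.direction is Direction.NEUTRAL:
                    continue
                iv = call.interval
                for b in range(iv.start // bin_size, (iv.end - 1) // bin_size + 1):
                    bin_set.add((iv.chromosome, b * bin_size))
        bins = sorted(bin_set, key=lambda b: (int(b[0][3:]), b[1]))
        index = {b: i for i, b in enumerate(bins)}
        values = np.zeros((len(sample_ids), len(bins)))
        for i, sid in enumerate(sample_ids):
            for call in calls[sid]:
                if call.direction is Direction.NEUTRAL:
                    continue
                sign = 1.0 if call.direction is Direction.GAIN else -1.0
                iv = call.interval
                for b in range(iv.start // bin_size, (iv.end - 1) // bin_size + 1):
                    values[i, index[(iv.chromosome, b * bin_size)]] = sign
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if standardize:
        sd = values.std(axis=0, ddof=0)
        values = (values - values.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return SampleFeatureMatrix(sample_ids=tuple(sample_ids), columns=tuple(bins), values=values)


def cluster_samples(matrix: SampleFeatureMatrix) -> Dendrogram:
    """Agglomerative average-linkage tree on Euclidean distances."""
    if len(matrix.sample_ids) < 2:
        raise ValueError("clustering needs at least 2 samples")
    dist = pdist(matrix.values, metric="euclidean")
    linkage = hierarchy.linkage(dist, method="average")
    return Dendrogram(linkage=linkage, sample_ids=matrix.sample_ids)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting the tree into k clusters."""
    return hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")


def cluster_separation(
    dendrogram: Dendrogram,
    metas: Sequence[SampleMeta],
    k: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate the k-cluster cut against lesion-fate labels and score
    the agreement with the adjusted Rand index.

    Labels: ``progressive`` = PL or OSCC samples; ``control`` = normal or
    non-progressive samples.
    """
    if k > len(dendrogram.sample_ids):
        raise ValueError("k exceeds number of samples")
    meta_by_id = {m.sample_id: m for m in metas}
    missing = [s for s in dendrogram.sample_ids if s not in meta_by_id]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    clusters = cut_dendrogram(dendrogram, k)
    labels = [
        "progressive" if meta_by_id[s].group in (Group.PL, Group.OSCC) else "control"
        for s in dendrogram.sample_ids
    ]
    contingency = pd.crosstab(
        pd.Series(labels, name="group"), pd.Series(clusters, name="cluster")
    )
    score = float(adjusted_rand_score(labels, clusters))
    return contingency, score


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize the merge tree to Newick with merge-height branch lengths."""
    n = len(dendrogram.sample_ids)
    tree = hierarchy.to_tree(dendrogram.linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return dendrogram.sample_ids[node.id]
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            length = node.dist - (0.0 if child.is_leaf() else child.dist)
            parts.append(f"{walk(child)}:{length:.6g}")
        return f"({','.join(parts)})"

    return walk(tree) + ";"
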