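"""Agglomerative clustering of conformers in dihedral space.

Conformers are grouped bottom-up under the Ward criterion with Euclidean
distances on the raw (unscaled) torsion columns: at each step the pair of
clusters whose merge least increases the total within-cluster variance is
joined.  One linkage tree serves every requested cluster count, so the
partition at k clusters is always a refinement of the partition at k - 1.

Torsions are deliberately left in degrees without standardization:
rescaling the columns would silently change the Ward geometry, and all
columns already share a unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .dihedrals import FeatureMatrix
from .ensemble import ConformerEnsemble


@dataclass
class ClusterAssignment:
    """Per-conformer cluster labels (0-based, contiguous) for one cluster
    count."""

    labels: np.ndarray
    n_clusters: int

    def members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for idx, lab in enumerate(self.labels):
            out.setdefault(int(lab), []).append(idx)
        return out


class ClusterModel:
    """Ward linkage tree over a feature matrix; yields nested partitions.

    Degenerate input (no variable dihedrals) puts every conformer in one
    cluster regardless of the requested count.
    """

    def __init__(self, features: FeatureMatrix | np.ndarray):
        values = features.values if isinstance(features, FeatureMatrix) else features
        self._values = np.asarray(values, dtype=float)
        self.m = self._values.shape[0]
        self.degenerate = self._values.shape[1] == 0 or self.m < 2
        self._linkage = None if self.degenerate else linkage(
            self._values, method="ward", metric="euclidean")

    def cut(self, n_clusters: int) -> ClusterAssignment:
        if not 1 <= n_clusters <= self.m:
            raise ValueError(f"n_clusters must be in [1, {self.m}]")
        if self.degenerate:
            if n_clusters > 1:
                warnings.warn(
                    "no variable dihedrals: all conformers fall in one cluster")
            return ClusterAssignment(np.zeros(self.m, dtype=int), n_clusters)
        raw = fcluster(self._linkage, t=n_clusters, criterion="maxclust")
        # relabel to 0-based in order of first appearance
        remap: dict[int, int] = {}
        labels = np.empty(self.m, dtype=int)
        for idx, lab in enumerate(raw):
            labels[idx] = remap.setdefault(int(lab), len(remap))
        return ClusterAssignment(labels, n_clusters)


def agglomerate(
    features: FeatureMatrix | np.ndarray,
    n_clusters: int,
    method: str = "ward",
    random_state: int | None = 0,
) -> ClusterAssignment:
    """Partition conformers into ``n_clusters`` groups.

    ``method="ward"`` (default) uses the hierarchical Ward/Euclidean
    criterion.  The alternative engines ``"kmeans"``, ``"birch"`` and
    ``"gmm"`` are exposed behind the same contract for benchmarking; they
    are not hierarchical and carry no guarantee of nested partitions.
    """
    if method == "ward":
        return ClusterModel(features).cut(n_clusters)
    values = features.values if isinstance(features, FeatureMatrix) else features
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if not 1 <= n_clusters <= m:
        raise ValueError(f"n_clusters must be in [1, {m}]")
    if values.shape[1] == 0 or m < 2:
        warnings.warn("no variable dihedrals: all conformers fall in one cluster")
        return ClusterAssignment(np.zeros(m, dtype=int), n_clusters)
    if method == "kmeans":
        from sklearn.cluster import KMeans
        raw = KMeans(n_clusters=n_clusters, n_init=10,
                     random_state=random_state).fit_predict(values)
    elif method == "birch":
        from sklearn.cluster import Birch
        raw = Birch(n_clusters=n_clusters).fit_predict(values)
    elif method == "gmm":
        from sklearn.mixture import GaussianMixture
        raw = GaussianMixture(n_components=n_clusters,
                              random_state=random_state).fit_predict(values)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(int(r), len(remap)) for r in raw])
    return ClusterAssignment(labels, n_clusters)


def representatives(
    assign: ClusterAssignment, ens: ConformerEnsemble
) -> list[int]:
    """Lowest-FF-energy member of each cluster, ordered by that energy.

    The ensemble is energy-sorted, so the minimum-u_ff member of a cluster
    is simply its smallest conformer index.
    """
    reps = [min(members) for members in assign.members().values()]
    return sorted(reps, key=lambda i: (ens.u_ff[i], i))
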