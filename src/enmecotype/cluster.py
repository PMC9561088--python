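"""Hierarchical clustering of populations into candidate ecotypes.

Following the protocol, populations are clustered on the Euclidean
distances between *rows* of a similarity matrix (each population described
by its similarity profile to all others), under four linkages (single,
complete, average, Ward).  The linkage with the largest agglomerative
coefficient — AC = mean over objects of (1 - first-merge height /
final-merge height) — is retained, the tree cut into k groups, and member
maps combined per ecotype by cell-wise maximum of their cumulative
surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .maxent import SuitabilityMap
from .similarity import SimilarityMatrix

LINKAGES = ("single", "complete", "average", "ward")
#: tie-break preference when agglomerative coefficients are equal
LINKAGE_PREFERENCE = ("ward", "average", "complete", "single")


@dataclass
class ClusterTree:
    """Merge sequence of an agglomerative clustering + its strength."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    method: str
    ac: float

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Dendrogram in Newick format with merge heights as branch lengths."""
        n = self.n
        heights = {i: 0.0 for i in range(n)}
        names = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + step
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            names[node] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            heights[node] = h
        return names[n + len(self.merges) - 1] + ";"


@dataclass
class EcotypeAssignment:
    """Population -> ecotype labels from one metric/linkage."""

    assignment: dict[str, int]
    k: int
    metric: str
    linkage_method: str

    def labels_for(self, populations: list[str]) -> np.ndarray:
        return np.array([self.assignment[p] for p in populations])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": list(self.assignment),
                "ecotype": list(self.assignment.values()),
                "metric": self.metric,
            }
        )


def row_distance(s: SimilarityMatrix) -> pd.DataFrame:
    """Euclidean distances between rows of the similarity matrix."""
    v = np.asarray(s.values, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("similarity matrix must be square")
    diff = v[:, None, :] - v[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=s.labels, columns=s.labels)


def agglomerative_coefficient(merges: np.ndarray, n: int) -> float:
    """AC = mean over objects of (1 - first-merge height / final height)."""
    final = merges[-1, 2]
    if final <= 0:
        return 0.0
    first = np.empty(n)
    seen = np.zeros(n, dtype=bool)
    member_leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(merges):
        leaves = member_leaves[int(a)] + member_leaves[int(b)]
        for leaf in leaves:
            if not seen[leaf]:
                first[leaf] = h
                seen[leaf] = True
        member_leaves[n + step] = leaves
    return float(np.mean(1.0 - first / final))


def hac(d: pd.DataFrame | np.ndarray, method: str = "ward") -> ClusterTree:
    """Agglomerative clustering of a distance matrix under one linkage."""
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}")
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        labels = [f"obj{i + 1}" for i in range(dm.shape[0])]
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least two objects")
    condensed = squareform(dm, checks=False)
    merges = linkage(condensed, method=method)
    ac = agglomerative_coefficient(merges, n)
    return ClusterTree(labels=labels, merges=merges, method=method, ac=ac)


def select_linkage(trees: dict[str, ClusterTree]) -> str:
    """Largest agglomerative coefficient; ties prefer ward > average > complete > single."""
    if not trees:
        raise ValueError("no trees")
    order = {m: i for i, m in enumerate(LINKAGE_PREFERENCE)}
    best = sorted(
        trees.items(), key=lambda kv: (-kv[1].ac, order.get(kv[0], len(order)))
    )[0]
    return best[0]


def cut_assign(tree: ClusterTree, k: int, metric: str = "") -> EcotypeAssignment:
    """Cut the tree into exactly k groups, numbered by first appearance."""
    if not 1 <= k <= tree.n:
        raise ValueError(f"k={k} out of range [1, {tree.n}]")
    raw = fcluster(tree.merges, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        # maxclust can undershoot on ties; fall back to cutting by height rank
        raw = fcluster(tree.merges, t=k, criterion="maxclust_monocrit",
                       monocrit=np.arange(len(tree.merges), dtype=float))
    relabel: dict[int, int] = {}
    out = {}
    for pop, c in zip(tree.labels, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[pop] = relabel[c]
    return EcotypeAssignment(
        assignment=out, k=len(set(out.values())), metric=metric,
        linkage_method=tree.method,
    )


def choose_k(
    tree: ClusterTree,
    d: pd.DataFrame | np.ndarray,
    k_range=None,
    override: int | None = None,
) -> int:
    """k maximising mean silhouette width on the distance matrix (config override wins)."""
    if override is not None:
        return int(override)
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d)
    n = tree.n
    ks = list(k_range) if k_range is not None else list(range(2, n))
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("empty k range")
    best_k, best_s = ks[0], -np.inf
    for k in ks:
        labels = cut_assign(tree, k).labels_for(tree.labels)
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(dm, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


def ecotype_maps(
    maps: dict[str, SuitabilityMap], assignment: EcotypeAssignment
) -> dict[int, np.ndarray]:
    """Per-ecotype cumulative surface: cell-wise maximum over member maps."""
    missing = [p for p in maps if p not in assignment.assignment]
    if missing:
        raise ValueError(f"populations without an ecotype: {missing}")
    out: dict[int, np.ndarray] = {}
    for pop, surf in maps.items():
        e = assignment.assignment[pop]
        if e not in out:
            out[e] = surf.cumulative.copy()
        else:
            out[e] = np.fmax(out[e], surf.cumulative)
    return dict(sorted(out.items()))
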