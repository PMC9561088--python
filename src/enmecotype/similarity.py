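"""Pairwise comparison of suitability maps.

Two families of statistics: the product-moment correlation of the logistic
surfaces over jointly valid cells, and distributional overlap of the raw
surfaces after renormalising each to sum one on the shared mask — the
Hellinger-affinity overlap I = 1 - 1/2 * sum (sqrt p - sqrt q)^2 and
Schoener's D = 1 - 1/2 * sum |p - q|.  Both overlaps live in [0, 1], equal
one iff the distributions coincide, and satisfy I >= D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .maxent import SuitabilityMap

MIN_SHARED_CELLS = 10


class SimilarityError(ValueError):
    """Degenerate map-comparison input."""


def _joint_vectors(a: SuitabilityMap, b: SuitabilityMap, output: str):
    if a.raw.shape != b.raw.shape:
        raise SimilarityError("maps are on different grids")
    joint = a.mask & b.mask
    va = getattr(a, output)[joint]
    vb = getattr(b, output)[joint]
    ok = np.isfinite(va) & np.isfinite(vb)
    va, vb = va[ok], vb[ok]
    if va.size < MIN_SHARED_CELLS:
        raise SimilarityError(
            f"only {va.size} jointly valid cells (minimum {MIN_SHARED_CELLS})"
        )
    return va, vb


def pearson_maps(a: SuitabilityMap, b: SuitabilityMap) -> float:
    """Pearson correlation of the logistic surfaces on the shared mask."""
    va, vb = _joint_vectors(a, b, "logistic")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise SimilarityError("constant map: correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def _normalised(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        raise SimilarityError("all-zero suitability map")
    return v / total


def niche_overlap_i(a: SuitabilityMap, b: SuitabilityMap) -> float:
    """Hellinger-based niche overlap I of the renormalised raw surfaces."""
    va, vb = _joint_vectors(a, b, "raw")
    p, q = _normalised(va), _normalised(vb)
    return float(1.0 - 0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def schoener_d(a: SuitabilityMap, b: SuitabilityMap) -> float:
    """Schoener's D of the renormalised raw surfaces."""
    va, vb = _joint_vectors(a, b, "raw")
    p, q = _normalised(va), _normalised(vb)
    return float(1.0 - 0.5 * np.sum(np.abs(p - q)))


_METRICS = {
    "pearson_r": pearson_maps,
    "overlap_I": niche_overlap_i,
    "schoener_D": schoener_d,
}


@dataclass
class SimilarityMatrix:
    """Labelled square population-by-population similarity matrix."""

    labels: list[str]
    values: np.ndarray
    metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        recs = [
            {"pop_a": a, "pop_b": b, "value": self.values[i, j]}
            for i, a in enumerate(self.labels)
            for j, b in enumerate(self.labels)
            if i < j
        ]
        return pd.DataFrame(recs)


def similarity_matrix(
    maps: dict[str, SuitabilityMap] | Sequence[SuitabilityMap],
    metric: str = "overlap_I",
) -> SimilarityMatrix:
    """All-pairs similarity, computed once per pair and mirrored; diagonal 1."""
    if metric not in _METRICS:
        raise SimilarityError(f"unknown metric {metric!r}")
    if isinstance(maps, dict):
        labels, surfs = list(maps), list(maps.values())
    else:
        surfs = list(maps)
        labels = [f"pop{i + 1}" for i in range(len(surfs))]
    n = len(surfs)
    if n < 2:
        raise SimilarityError("need at least two maps")
    fn = _METRICS[metric]
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(surfs[i], surfs[j])
    return SimilarityMatrix(labels=labels, values=values, metric=metric)
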