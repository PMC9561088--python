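"""Feature transforms for the maximum-entropy niche model.

Continuous covariates are min-max scaled over the background and expanded
into the classic feature classes: linear (L), quadratic (Q), product (P),
threshold (T) and hinge (H).  Categorical covariates always receive one
indicator feature per level (class C) regardless of the requested set.
Hinge and threshold knots sit at evenly spaced interior quantiles of the
background distribution, which bounds the feature count independently of
the number of distinct values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("L", "Q", "P", "H", "T", "C")

# Per-class base regularization constants, piecewise linear in the presence
# sample size m (the defaults popularised by mainstream maxent software).
_BETA_TABLE: dict[str, tuple[list[float], list[float]]] = {
    "L": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "Q": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "P": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "C": ([0, 10, 17], [0.65, 0.5, 0.25]),
    "T": ([0, 100], [2.0, 1.0]),
    "H": ([0], [0.5]),
}


def base_constant(fclass: str, m: int) -> float:
    """Default regularization constant for a feature class at presence count m."""
    xs, ys = _BETA_TABLE[fclass]
    return float(np.interp(m, xs, ys))


@dataclass(frozen=True)
class FeatureSpec:
    """One fitted feature: class, source variable(s) and knot/level."""

    variables: tuple[str, ...]
    fclass: str  # L | Q | P | H | T | C
    knot: float | None = None
    direction: str | None = None  # hinge: "forward" | "reverse"
    level: float | None = None  # categorical level

    @property
    def label(self) -> str:
        v = "*".join(self.variables)
        if self.fclass == "H":
            return f"H:{v}:{self.direction}@{self.knot:.6g}"
        if self.fclass == "T":
            return f"T:{v}@{self.knot:.6g}"
        if self.fclass == "C":
            return f"C:{v}={self.level:g}"
        return f"{self.fclass}:{v}"


class FeatureBuilder:
    """Builds and re-applies the feature expansion fitted on a background sample.

    Scaling bounds, knots and categorical levels are frozen at construction
    from the background table; :meth:`transform` re-applies them to any
    other table (projection values outside the training bounds are clamped
    to [0, 1] after scaling, with the clamp count reported).
    """

    def __init__(
        self,
        background: pd.DataFrame,
        kinds: Mapping[str, str],
        fc_set: Sequence[str] = ("L",),
        n_knots: int = 30,
    ):
        fc_set = tuple(dict.fromkeys(fc_set))
        bad = [c for c in fc_set if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(f"unknown feature classes: {bad}")
        if not fc_set:
            raise ValueError("fc_set must not be empty")
        self.fc_set = fc_set
        self.n_knots = int(n_knots)
        self.variables = [c for c in background.columns if c in kinds]
        if not self.variables:
            self.variables = list(background.columns)
            kinds = {c: "continuous" for c in self.variables}
        self.kinds = {v: kinds.get(v, "continuous") for v in self.variables}
        self.continuous = [v for v in self.variables if self.kinds[v] == "continuous"]
        self.categorical = [v for v in self.variables if self.kinds[v] == "categorical"]

        self.bounds: dict[str, tuple[float, float]] = {}
        self.knots: dict[str, np.ndarray] = {}
        self.levels: dict[str, np.ndarray] = {}
        for v in self.continuous:
            col = background[v].to_numpy(dtype=float)
            lo, hi = float(np.nanmin(col)), float(np.nanmax(col))
            if hi <= lo:
                hi = lo + 1.0  # constant layer: degenerate but usable
            self.bounds[v] = (lo, hi)
            if {"H", "T"} & set(self.fc_set):
                qs = (np.arange(self.n_knots) + 1) / (self.n_knots + 1)
                knots = np.quantile(col, qs)
                # strictly interior knots only
                eps = 1e-12 * (hi - lo)
                self.knots[v] = np.clip(knots, lo + eps, hi - eps)
        for v in self.categorical:
            self.levels[v] = np.unique(background[v].to_numpy(dtype=float))

        self.specs: list[FeatureSpec] = self._build_specs()

    def _build_specs(self) -> list[FeatureSpec]:
        specs: list[FeatureSpec] = []
        if "L" in self.fc_set:
            specs += [FeatureSpec((v,), "L") for v in self.continuous]
        if "Q" in self.fc_set:
            specs += [FeatureSpec((v,), "Q") for v in self.continuous]
        if "P" in self.fc_set:
            specs += [
                FeatureSpec((a, b), "P") for a, b in combinations(self.continuous, 2)
            ]
        if "T" in self.fc_set:
            for v in self.continuous:
                specs += [FeatureSpec((v,), "T", knot=float(k)) for k in self.knots[v]]
        if "H" in self.fc_set:
            for v in self.continuous:
                for k in self.knots[v]:
                    specs.append(FeatureSpec((v,), "H", knot=float(k), direction="forward"))
                    specs.append(FeatureSpec((v,), "H", knot=float(k), direction="reverse"))
        # categorical layers always get their indicators
        for v in self.categorical:
            specs += [FeatureSpec((v,), "C", level=float(l)) for l in self.levels[v]]
        if not specs:
            raise ValueError("feature expansion produced no features")
        return specs

    @property
    def n_features(self) -> int:
        return len(self.specs)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.specs]

    def classes(self) -> np.ndarray:
        return np.array([s.fclass for s in self.specs])

    def _scaled(self, table: pd.DataFrame) -> tuple[dict[str, np.ndarray], int]:
        scaled, clamped = {}, 0
        for v in self.continuous:
            lo, hi = self.bounds[v]
            z = (table[v].to_numpy(dtype=float) - lo) / (hi - lo)
            clamped += int(np.sum((z < 0) | (z > 1)))
            scaled[v] = np.clip(z, 0.0, 1.0)
        return scaled, clamped

    def transform(self, table: pd.DataFrame) -> tuple[np.ndarray, int]:
        """Feature matrix for the table's rows; returns (matrix, clamp count)."""
        missing = [v for v in self.variables if v not in table.columns]
        if missing:
            raise ValueError(f"table missing model variables: {missing}")
        scaled, clamped = self._scaled(table)
        n = len(table)
        out = np.empty((n, self.n_features), dtype=float)
        for j, s in enumerate(self.specs):
            if s.fclass == "L":
                out[:, j] = scaled[s.variables[0]]
            elif s.fclass == "Q":
                out[:, j] = scaled[s.variables[0]] ** 2
            elif s.fclass == "P":
                out[:, j] = scaled[s.variables[0]] * scaled[s.variables[1]]
            elif s.fclass == "T":
                raw = table[s.variables[0]].to_numpy(dtype=float)
                out[:, j] = (raw > s.knot).astype(float)
            elif s.fclass == "H":
                v = s.variables[0]
                raw = table[v].to_numpy(dtype=float)
                lo, hi = self.bounds[v]
                raw = np.clip(raw, lo, hi)
                if s.direction == "forward":
                    out[:, j] = np.maximum(0.0, (raw - s.knot) / (hi - s.knot))
                else:
                    out[:, j] = np.maximum(0.0, (s.knot - raw) / (s.knot - lo))
            elif s.fclass == "C":
                raw = table[s.variables[0]].to_numpy(dtype=float)
                out[:, j] = (raw == s.level).astype(float)
        return out, clamped

    def feature_variable_credit(self) -> list[dict[str, float]]:
        """Per feature: variable -> credit share (products split evenly)."""
        credits = []
        for s in self.specs:
            share = 1.0 / len(s.variables)
            credits.append({v: share for v in s.variables})
        return credits

    def to_dict(self) -> dict:
        return {
            "fc_set": list(self.fc_set),
            "n_knots": self.n_knots,
            "kinds": self.kinds,
            "bounds": {v: list(b) for v, b in self.bounds.items()},
            "knots": {v: k.tolist() for v, k in self.knots.items()},
            "levels": {v: l.tolist() for v, l in self.levels.items()},
            "features": [
                {
                    "variables": list(s.variables),
                    "fclass": s.fclass,
                    "knot": s.knot,
                    "direction": s.direction,
                    "level": s.level,
                }
                for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureBuilder":
        obj = cls.__new__(cls)
        obj.fc_set = tuple(d["fc_set"])
        obj.n_knots = d["n_knots"]
        obj.kinds = dict(d["kinds"])
        obj.variables = list(obj.kinds)
        obj.continuous = [v for v in obj.variables if obj.kinds[v] == "continuous"]
        obj.categorical = [v for v in obj.variables if obj.kinds[v] == "categorical"]
        obj.bounds = {v: tuple(b) for v, b in d["bounds"].items()}
        obj.knots = {v: np.asarray(k) for v, k in d["knots"].items()}
        obj.levels = {v: np.asarray(l) for v, l in d["levels"].items()}
        obj.specs = [
            FeatureSpec(
                tuple(f["variables"]), f["fclass"], knot=f["knot"],
                direction=f["direction"], level=f["level"],
            )
            for f in d["features"]
        ]
        return obj
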