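"""L1-regularised maximum-entropy (Gibbs) presence-background model.

The model is the distribution ``raw(x) = exp(lambda . f(x)) / Z`` over the
background cells that minimises

    f(lambda) = -mean_presence[lambda . f(x)]
                + log sum_background exp(lambda . f(x))
                + sum_j beta_j |lambda_j|

with per-feature bounds ``beta_j = BM * c_class(m) * s_j / sqrt(m)`` where
``m`` is the presence count, ``s_j`` the presence-sample standard deviation
of feature j, ``c_class`` the published per-class default constant
(piecewise linear in m) and BM the global beta multiplier.  Fitting uses
cyclic coordinate descent with a proximal-Newton soft-threshold step and a
halving line search, so the objective is non-increasing at every accepted
update; every accepted update's gain increase is recorded so percent
contribution can later be credited to variables along the training path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureBuilder, base_constant
from .raster import EnvStack


class MaxentError(ValueError):
    """Invalid input to the maxent fitter."""


def _logsumexp(eta: np.ndarray) -> float:
    c = float(np.max(eta))
    return c + float(np.log(np.sum(np.exp(eta - c))))


@dataclass
class MaxentModel:
    """A fitted maximum-entropy niche model."""

    builder: FeatureBuilder
    lambdas: np.ndarray
    betas: np.ndarray
    log_z: float  # over the training background
    entropy: float  # of the fitted distribution over the background
    bm: float
    n_presence: int
    n_background: int
    objective: float
    presence_mean: np.ndarray  # empirical presence feature means
    trace: list[tuple[int, float]] = field(default_factory=list)
    n_sweeps: int = 0
    converged: bool = True
    background_ref: str = ""

    @property
    def k_nonzero(self) -> int:
        return int(np.count_nonzero(self.lambdas))

    def eta(self, features: np.ndarray) -> np.ndarray:
        return features @ self.lambdas

    def raw_from_features(self, features: np.ndarray) -> np.ndarray:
        """raw(x) relative to the *training* normaliser."""
        return np.exp(self.eta(features) - self.log_z)

    def to_dict(self) -> dict:
        return {
            "builder": self.builder.to_dict(),
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "bm": self.bm,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "objective": self.objective,
            "presence_mean": self.presence_mean.tolist(),
            "trace": [[int(j), float(d)] for j, d in self.trace],
            "n_sweeps": self.n_sweeps,
            "converged": self.converged,
            "background_ref": self.background_ref,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        return cls(
            builder=FeatureBuilder.from_dict(d["builder"]),
            lambdas=np.asarray(d["lambdas"]),
            betas=np.asarray(d["betas"]),
            log_z=d["log_z"],
            entropy=d["entropy"],
            bm=d["bm"],
            n_presence=d["n_presence"],
            n_background=d["n_background"],
            objective=d["objective"],
            presence_mean=np.asarray(d["presence_mean"]),
            trace=[(j, delta) for j, delta in d["trace"]],
            n_sweeps=d["n_sweeps"],
            converged=d["converged"],
            background_ref=d["background_ref"],
        )


def regularization_bounds(
    presence: np.ndarray, classes: np.ndarray, bm: float
) -> np.ndarray:
    """beta_j = BM * c_class(m) * s_j / sqrt(m), with a small floor on s_j."""
    m = presence.shape[0]
    if m >= 2:
        s = presence.std(axis=0, ddof=1)
    else:
        s = np.zeros(presence.shape[1])
    s = np.maximum(s, 1e-3)  # keep every coefficient weakly penalised
    consts = np.array([base_constant(c, m) for c in classes])
    return bm * consts * s / np.sqrt(m)


def fit_maxent(
    features: np.ndarray,
    presence_idx: np.ndarray,
    bm: float = 1.0,
    builder: FeatureBuilder | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 500,
    background_ref: str = "",
) -> MaxentModel:
    """Fit the model on one feature matrix.

    ``presence_idx`` marks the presence rows; every *other* row is a
    background cell, and the fitted distribution is normalised over those
    background rows.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise MaxentError("features must be a 2-D matrix")
    if not np.all(np.isfinite(features)):
        raise MaxentError("non-finite feature values")
    presence_idx = np.asarray(presence_idx, dtype=int)
    if presence_idx.size == 0:
        raise MaxentError("at least one presence row is required")
    n_rows, n_feat = features.shape
    is_presence = np.zeros(n_rows, dtype=bool)
    is_presence[presence_idx] = True
    bg = features[~is_presence]
    pres = features[presence_idx]
    n_bg = bg.shape[0]
    if n_bg == 0:
        raise MaxentError("no background rows")
    m = pres.shape[0]

    classes = (
        builder.classes()
        if builder is not None
        else np.array(["L"] * n_feat)
    )
    betas = regularization_bounds(pres, classes, bm)
    p_mean = pres.mean(axis=0)

    lam = np.zeros(n_feat)
    eta = np.zeros(n_bg)
    log_z = float(np.log(n_bg))
    obj = log_z  # -p_mean.0 + logZ + 0
    trace: list[tuple[int, float]] = []

    n_sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        n_sweeps = sweep + 1
        obj_start = obj
        # current background weights (unnormalised, max-shifted)
        for j in range(n_feat):
            fj = bg[:, j]
            w = np.exp(eta - np.max(eta))
            s_w = w.sum()
            e_q = float(w @ fj) / s_w
            g = -p_mean[j] + e_q
            # screen: zero coefficient already KKT-satisfied
            if lam[j] == 0.0 and abs(g) <= betas[j]:
                continue
            e_q2 = float(w @ (fj * fj)) / s_w
            h = max(e_q2 - e_q * e_q, 1e-12)
            z = lam[j] - g / h
            new = np.sign(z) * max(abs(z) - betas[j] / h, 0.0)
            delta = new - lam[j]
            if delta == 0.0:
                continue
            # halving line search on the true objective
            accepted = False
            for _ in range(40):
                cand_lam_j = lam[j] + delta
                cand_eta = eta + delta * fj
                cand_log_z = _logsumexp(cand_eta)
                cand_obj = (
                    obj
                    - p_mean[j] * delta
                    + (cand_log_z - log_z)
                    + betas[j] * (abs(cand_lam_j) - abs(lam[j]))
                )
                if cand_obj <= obj + 1e-13:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-15:
                    break
            if accepted and cand_obj < obj:
                trace.append((j, obj - cand_obj))
                lam[j] = cand_lam_j
                eta = cand_eta
                log_z = cand_log_z
                obj = cand_obj
        if obj_start - obj < tol:
            converged = True
            break

    w = np.exp(eta - log_z)
    entropy = float(-np.sum(np.where(w > 0, w * np.log(np.maximum(w, 1e-300)), 0.0)))
    return MaxentModel(
        builder=builder,
        lambdas=lam,
        betas=betas,
        log_z=log_z,
        entropy=entropy,
        bm=bm,
        n_presence=m,
        n_background=n_bg,
        objective=obj,
        presence_mean=p_mean,
        trace=trace,
        n_sweeps=n_sweeps,
        converged=converged,
        background_ref=background_ref,
    )


def fit_on_tables(
    background: pd.DataFrame,
    presence: pd.DataFrame,
    kinds: dict[str, str],
    fc_set=("L",),
    bm: float = 1.0,
    n_knots: int = 30,
    tol: float = 1e-7,
    max_sweeps: int = 500,
    background_ref: str = "",
) -> MaxentModel:
    """Convenience wrapper: build features from a background table and fit."""
    builder = FeatureBuilder(background, kinds, fc_set=fc_set, n_knots=n_knots)
    f_bg, _ = builder.transform(background)
    f_pres, _ = builder.transform(presence)
    features = np.vstack([f_bg, f_pres])
    presence_idx = np.arange(len(f_bg), len(f_bg) + len(f_pres))
    return fit_maxent(
        features, presence_idx, bm=bm, builder=builder, tol=tol,
        max_sweeps=max_sweeps, background_ref=background_ref,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass
class SuitabilityMap:
    """Raw, logistic and cumulative suitability surfaces on one grid."""

    raw: np.ndarray  # sums to 1 over valid cells
    logistic: np.ndarray  # in (0, 1)
    cumulative: np.ndarray  # in [0, 100]
    mask: np.ndarray
    clamp_count: int = 0

    def vector(self, output: str = "raw") -> np.ndarray:
        return getattr(self, output)[self.mask]


def _cumulative(raw: np.ndarray) -> np.ndarray:
    """cumulative(x) = 100 * sum of raw mass over cells with raw <= raw(x)."""
    order = np.argsort(raw, kind="stable")
    sorted_raw = raw[order]
    csum = np.cumsum(sorted_raw)
    # ties share the mass of every cell at their value
    idx = np.searchsorted(sorted_raw, raw, side="right") - 1
    return 100.0 * csum[idx] / csum[-1]


def predict(model: MaxentModel, stack: EnvStack) -> SuitabilityMap:
    """Project a fitted model onto a stack, renormalising over its valid cells."""
    table = stack.background_table()
    feats, clamped = model.builder.transform(table)
    eta = model.eta(feats)
    log_z = _logsumexp(eta)
    raw_v = np.exp(eta - log_z)
    logistic_v = _logistic_from_raw(raw_v, model.entropy)
    cum_v = _cumulative(raw_v)
    shape = stack.shape
    rows = table["row"].to_numpy()
    cols = table["col"].to_numpy()
    out = {}
    for name, vec in (("raw", raw_v), ("logistic", logistic_v), ("cumulative", cum_v)):
        g = np.full(shape, np.nan)
        g[rows, cols] = vec
        out[name] = g
    return SuitabilityMap(
        raw=out["raw"], logistic=out["logistic"], cumulative=out["cumulative"],
        mask=stack.mask.copy(), clamp_count=clamped,
    )


def _logistic_from_raw(raw: np.ndarray, entropy: float) -> np.ndarray:
    q = raw * np.exp(entropy)
    return q / (1.0 + q)


def predict_rows(model: MaxentModel, table: pd.DataFrame) -> np.ndarray:
    """Training-normalised raw values at arbitrary covariate rows."""
    feats, _ = model.builder.transform(table)
    return model.raw_from_features(feats)


def gain(model: MaxentModel, presence_features: np.ndarray) -> tuple[float, float]:
    """(gain, regularized gain) of the model on a presence feature matrix.

    Gain is the mean presence log-likelihood improvement over the uniform
    background baseline: ``mean log raw + log |B|``.
    """
    eta_p = presence_features @ model.lambdas
    g = float(np.mean(eta_p) - model.log_z + np.log(model.n_background))
    reg = g - float(np.sum(model.betas * np.abs(model.lambdas)))
    return g, reg
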