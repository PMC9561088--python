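"""Model accuracy and variable-importance statistics.

AUC is the rank (Mann-Whitney) probability that a presence outscores a
background cell, with ties counted one half — invariant to any monotone
transform of the scores.  Variable importance comes three ways: jackknife
gains (each variable fitted alone and left out), percent contribution
(gain increases credited along the coordinate-descent training path) and
permutation importance (training-AUC drop after permuting one variable
across presence and background rows jointly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent import MaxentModel, fit_on_tables, gain


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC with midrank tie handling."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def _model_scores(model: MaxentModel, table: pd.DataFrame) -> np.ndarray:
    feats, _ = model.builder.transform(table)
    return feats @ model.lambdas  # monotone in raw


def model_auc(
    model: MaxentModel, presence: pd.DataFrame, background: pd.DataFrame
) -> float:
    return auc(_model_scores(model, presence), _model_scores(model, background))


@dataclass
class JackknifeResult:
    table: pd.DataFrame  # variable, gain_with_only, gain_without, auc_with_only, ...
    reference_gain: float
    reference_auc_test: float


def jackknife(
    background: pd.DataFrame,
    presence_train: pd.DataFrame,
    presence_test: pd.DataFrame,
    kinds: dict[str, str],
    variables: list[str],
    fc_set=("L",),
    bm: float = 1.0,
    n_knots: int = 30,
) -> JackknifeResult:
    """With-only / without gains and test AUC per variable.

    Fits two sub-models per variable (the variable alone, and everything
    except it) plus the all-variables reference.  A single-variable
    selection leaves the without-model undefined (flagged as NaN).
    """
    if len(variables) < 1:
        raise ValueError("at least one variable required")

    def _fit(cols: list[str]) -> MaxentModel:
        return fit_on_tables(
            background[cols], presence_train[cols],
            {v: kinds[v] for v in cols}, fc_set=fc_set, bm=bm, n_knots=n_knots,
        )

    def _stats(model: MaxentModel, cols: list[str]):
        f_tr, _ = model.builder.transform(presence_train[cols])
        f_te, _ = model.builder.transform(presence_test[cols])
        g_train, _ = gain(model, f_tr)
        g_test, _ = gain(model, f_te)
        a = model_auc(model, presence_test[cols], background[cols])
        return g_train, g_test, a

    ref = _fit(list(variables))
    ref_train, ref_test, ref_auc = _stats(ref, list(variables))
    rows = []
    for v in variables:
        only = _fit([v])
        g_tr_o, g_te_o, auc_o = _stats(only, [v])
        rest = [u for u in variables if u != v]
        if rest:
            without = _fit(rest)
            g_tr_w, g_te_w, auc_w = _stats(without, rest)
        else:
            g_tr_w = g_te_w = auc_w = float("nan")
        rows.append(
            {
                "variable": v,
                "gain_with_only": g_tr_o,
                "test_gain_with_only": g_te_o,
                "auc_with_only": auc_o,
                "gain_without": g_tr_w,
                "test_gain_without": g_te_w,
                "auc_without": auc_w,
            }
        )
    return JackknifeResult(
        table=pd.DataFrame(rows), reference_gain=ref_train, reference_auc_test=ref_auc
    )


def percent_contribution(model: MaxentModel) -> pd.Series:
    """Percent contribution per variable from the training-path trace.

    Each accepted coordinate update's increase in regularised gain is
    credited to the updated feature's source variable(s) (product features
    split evenly); negative credits are floored at zero and the totals
    normalised to 100%.
    """
    if not model.trace:
        raise ValueError("model carries no training trace")
    credits = model.builder.feature_variable_credit()
    totals: dict[str, float] = {v: 0.0 for v in model.builder.variables}
    for j, delta in model.trace:
        for v, share in credits[j].items():
            totals[v] += share * delta
    s = pd.Series(totals).clip(lower=0.0)
    total = s.sum()
    if total <= 0:
        return s * 0.0
    return 100.0 * s / total


def permutation_importance(
    model: MaxentModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    seed: int = 0,
) -> pd.Series:
    """Training-AUC drop per permuted variable, floored at 0, normalised to 100%.

    Each variable is permuted jointly across the presence and background
    rows (so the permutation respects the pooled empirical distribution),
    the model re-scored, and the AUC drop recorded.
    """
    rng = np.random.default_rng(seed)
    base = model_auc(model, presence, background)
    n_p = len(presence)
    drops = {}
    for v in model.builder.variables:
        combined = pd.concat(
            [presence.reset_index(drop=True), background.reset_index(drop=True)],
            ignore_index=True,
        )
        combined[v] = rng.permutation(combined[v].to_numpy())
        perm_p = combined.iloc[:n_p]
        perm_b = combined.iloc[n_p:]
        drops[v] = base - model_auc(model, perm_p, perm_b)
    s = pd.Series(drops).clip(lower=0.0)
    total = s.sum()
    if total <= 0:
        return s * 0.0
    return 100.0 * s / total


def response_curve(
    model: MaxentModel,
    background: pd.DataFrame,
    variable: str,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Logistic output along one variable, others fixed at background means.

    Categorical variables are swept over their observed levels instead of a
    numeric grid.
    """
    if variable not in model.builder.variables:
        raise ValueError(f"unknown variable {variable!r}")
    if model.builder.kinds[variable] == "categorical":
        grid = model.builder.levels[variable]
    else:
        lo, hi = model.builder.bounds[variable]
        grid = np.linspace(lo, hi, n_grid)
    rows = {}
    for v in model.builder.variables:
        if v == variable:
            rows[v] = grid
        elif model.builder.kinds[v] == "categorical":
            col = background[v].to_numpy(dtype=float)
            levels, counts = np.unique(col, return_counts=True)
            rows[v] = np.full(len(grid), levels[np.argmax(counts)])
        else:
            rows[v] = np.full(len(grid), float(background[v].mean()))
    table = pd.DataFrame(rows)
    feats, _ = model.builder.transform(table)
    raw = np.exp(feats @ model.lambdas - model.log_z)
    q = raw * np.exp(model.entropy)
    return pd.DataFrame({"value": grid, "logistic": q / (1.0 + q)})
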