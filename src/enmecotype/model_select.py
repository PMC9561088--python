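"""Feature-class / beta-multiplier selection by small-sample AIC.

Candidate models are the Cartesian product of feature-class sets and beta
multipliers.  Each candidate is scored with AICc where the likelihood is
the presence log-likelihood of the raw distribution normalised over the
study grid and K counts the non-zero coefficients.  The packaged default
grid pairs the 15 non-empty subsets of {L, Q, H, T} plus the full
{L, Q, P, H, T} set with beta multipliers 1..12 — 192 candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .maxent import MaxentModel, fit_on_tables
from .occurrences import OccurrenceSet


def _default_fc_sets() -> list[tuple[str, ...]]:
    base = ("L", "Q", "H", "T")
    sets: list[tuple[str, ...]] = []
    for r in range(1, 5):
        sets += [c for c in combinations(base, r)]
    sets.append(("L", "Q", "P", "H", "T"))
    return sets


DEFAULT_FC_SETS: list[tuple[str, ...]] = _default_fc_sets()
DEFAULT_BM_RANGE: list[float] = [float(b) for b in range(1, 13)]


def enumerate_grid(
    fc_list: Sequence[Sequence[str]] | None = None,
    bm_range: Sequence[float] | None = None,
) -> list[tuple[tuple[str, ...], float]]:
    """Stable-order candidate list: fc_list order x ascending BM."""
    fc_list = [tuple(fc) for fc in (fc_list if fc_list is not None else DEFAULT_FC_SETS)]
    bm_range = list(bm_range if bm_range is not None else DEFAULT_BM_RANGE)
    if not fc_list:
        raise ValueError("fc_list must not be empty")
    if not bm_range:
        raise ValueError("bm_range must not be empty")
    return [(fc, float(bm)) for fc in fc_list for bm in sorted(bm_range)]


def aicc(model: MaxentModel, presence_features: np.ndarray) -> tuple[int, float, float, bool]:
    """(K, loglik, AICc, valid) for a fitted model.

    K = number of non-zero coefficients; loglik sums presence log raw with
    raw normalised over the study grid; the model is invalid whenever
    n - K - 1 <= 0 (the correction term's denominator).
    """
    n = presence_features.shape[0]
    k = model.k_nonzero
    eta_p = presence_features @ model.lambdas
    loglik = float(np.sum(eta_p - model.log_z))
    valid = (n - k - 1) > 0
    if valid:
        value = 2 * k - 2 * loglik + (2 * k * (k + 1)) / (n - k - 1)
    else:
        value = float("inf")
    return k, loglik, value, valid


@dataclass
class ModelGridResult:
    """Scored candidate grid."""

    table: pd.DataFrame  # fc_set, bm, K, loglik, aicc, valid

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_best(grid: ModelGridResult) -> tuple[tuple[str, ...], float]:
    """Minimum-AICc valid candidate; ties broken by smaller K, smaller BM, grid order."""
    df = grid.table
    valid = df[df["valid"]]
    if valid.empty:
        raise ValueError("no valid candidate models (n - K - 1 <= 0 everywhere)")
    ranked = valid.reset_index().sort_values(
        by=["aicc", "K", "bm", "index"], kind="stable"
    )
    best = ranked.iloc[0]
    return tuple(best["fc_set"].split("+")), float(best["bm"])


def tune(
    background: pd.DataFrame,
    presence: pd.DataFrame,
    kinds: dict[str, str],
    fc_list: Sequence[Sequence[str]] | None = None,
    bm_range: Sequence[float] | None = None,
    n_knots: int = 30,
    tol: float = 1e-7,
    max_sweeps: int = 500,
) -> ModelGridResult:
    """Fit and score every candidate on the same background/presence tables."""
    rows = []
    for fc, bm in enumerate_grid(fc_list, bm_range):
        model = fit_on_tables(
            background, presence, kinds, fc_set=fc, bm=bm,
            n_knots=n_knots, tol=tol, max_sweeps=max_sweeps,
        )
        f_pres, _ = model.builder.transform(presence)
        k, loglik, value, valid = aicc(model, f_pres)
        rows.append(
            {"fc_set": "+".join(fc), "bm": bm, "K": k, "loglik": loglik,
             "aicc": value, "valid": valid}
        )
    return ModelGridResult(table=pd.DataFrame(rows))


def partition(
    occ: OccurrenceSet,
    test_frac: float = 0.25,
    k: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """75/25-style split plus spatially structured folds on the training part.

    The test set holds ``round(test_frac * n)`` randomly drawn points; the
    training points are then sorted by longitude and cut into ``k``
    contiguous blocks, giving regionally structured cross-validation folds.
    Returns (train_idx, test_idx, fold_labels aligned with train_idx).
    """
    n = len(occ)
    n_test = int(round(test_frac * n))
    if n - n_test < k or n_test < 1:
        raise ValueError(f"too few points (n={n}) for test_frac={test_frac}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    lon = occ.points["lon"].to_numpy()[train_idx]
    order = np.argsort(lon, kind="stable")
    n_train = len(train_idx)
    sizes = np.full(k, n_train // k)
    sizes[: n_train % k] += 1
    folds = np.empty(n_train, dtype=int)
    start = 0
    for i, sz in enumerate(sizes):
        folds[order[start:start + sz]] = i
        start += sz
    return train_idx, test_idx, folds
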