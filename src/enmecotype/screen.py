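"""Covariate screening: correlation pruning, PCA inspection, and an
iterative uncorrelated/high-contribution selection.

Pairwise association is always measured with Spearman's rank correlation
(the covariates are generally non-normal, which a Shapiro-Wilk report
documents).  The iterative selection alternates, per beta multiplier:
fit the niche model on the current variable set, drop variables whose
percent contribution falls below a threshold, then break remaining
correlated pairs in favour of the higher-contribution member, until the
set is stable; the stable set with the smallest AICc across the multiplier
list is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import percent_contribution
from .maxent import fit_on_tables
from .model_select import aicc
from .occurrences import OccurrenceSet
from .raster import EnvStack, extract_at

#: association-strength bands for |r_s|
STRENGTH_BANDS = (
    (0.8, "very strong"),
    (0.6, "strong"),
    (0.4, "moderate"),
    (0.2, "weak"),
    (0.0, "very weak"),
)


def strength_label(r: float) -> str:
    a = abs(r)
    for lo, label in STRENGTH_BANDS:
        if a >= lo:
            return label
    return "very weak"


def normality_check(table: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk W and p per variable (annotation only; pipeline uses ranks).

    Constant variables are flagged degenerate rather than failing.
    """
    rows = []
    for col in table.columns:
        x = table[col].dropna().to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"variable {col!r}: need >= 3 values")
        if np.ptp(x) == 0:
            rows.append({"variable": col, "W": np.nan, "p": np.nan, "degenerate": True})
            continue
        w, p = stats.shapiro(x)
        rows.append({"variable": col, "W": float(w), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)


@dataclass
class CorrelationReport:
    """Spearman correlation matrix, p-values and strength labels."""

    r: pd.DataFrame
    p: pd.DataFrame

    @property
    def variables(self) -> list[str]:
        return list(self.r.index)

    def strengths(self) -> pd.DataFrame:
        return self.r.map(strength_label)


def spearman_matrix(table: pd.DataFrame) -> CorrelationReport:
    """Pairwise Spearman r (midrank ties) with two-sided p-values."""
    df = table.dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 complete rows")
    cols = list(df.columns)
    for c in cols:
        if df[c].isna().all():
            raise ValueError(f"variable {c!r} is all-missing")
    n = len(cols)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = stats.spearmanr(df[cols[i]], df[cols[j]])
            r[i, j] = r[j, i] = res.statistic if np.isfinite(res.statistic) else 0.0
            p[i, j] = p[j, i] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return CorrelationReport(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
    )


def prune_correlated(
    report: CorrelationReport,
    threshold: float = 0.6,
    priority: Sequence[str] = (),
) -> tuple[list[str], list[dict]]:
    """Greedy pruning: keep a variable iff |r_s| < threshold vs everything kept.

    Candidates are visited in (priority rank, name) order, so within any
    correlated group the highest-priority member survives and the outcome
    is independent of the input column order.  Returns (kept, trace).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    variables = report.variables
    if not variables:
        raise ValueError("empty correlation report")
    rank = {v: i for i, v in enumerate(priority)}
    order = sorted(variables, key=lambda v: (rank.get(v, len(rank)), v))
    kept: list[str] = []
    trace: list[dict] = []
    for v in order:
        clash = [u for u in kept if abs(report.r.loc[v, u]) >= threshold]
        if clash:
            trace.append({"variable": v, "action": "drop",
                          "reason": f"correlated-with-better:{clash[0]}"})
        else:
            kept.append(v)
            trace.append({"variable": v, "action": "keep", "reason": ""})
    return sorted(kept, key=variables.index), trace


def pca_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Standardised PCA: (loadings per variable x component, % variance explained)."""
    from sklearn.decomposition import PCA

    df = table.dropna()
    if df.shape[1] < 2 or len(df) < 3:
        raise ValueError("need >= 2 variables and >= 3 rows")
    constant = [c for c in df.columns if np.ptp(df[c].to_numpy(dtype=float)) == 0]
    if constant:
        import warnings

        warnings.warn(f"dropping constant variables: {constant}", stacklevel=2)
        df = df.drop(columns=constant)
    x = (df - df.mean()) / df.std(ddof=1)
    pca = PCA()
    pca.fit(x.to_numpy())
    comps = [f"PC{i + 1}" for i in range(pca.n_components_)]
    loadings = pd.DataFrame(pca.components_.T, index=df.columns, columns=comps)
    var_pct = pd.Series(100.0 * pca.explained_variance_ratio_, index=comps)
    return loadings, var_pct


@dataclass
class SelectionResult:
    """Outcome of the iterative uncorrelated/high-contribution selection."""

    selected: list[str]
    trace: list[dict] = field(default_factory=list)
    score_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def mvs_select(
    stack: EnvStack,
    occ: OccurrenceSet,
    contrib_threshold: float = 5.0,
    corr_threshold: float = 0.6,
    bm_list: Sequence[float] = tuple(range(1, 13)),
    fc_set: Sequence[str] = ("L", "Q"),
    n_knots: int = 10,
    min_occurrences: int = 15,
    max_iter: int = 20,
) -> SelectionResult:
    """Iterative variable selection over the environmental stack.

    Correlations are computed on background cells (the model's domain);
    contributions come from the training-path credit of a model fitted on
    the current set.  One stable set is found per beta multiplier and the
    minimum-AICc stable set wins.
    """
    if len(stack.names) < 2:
        raise ValueError("need at least two variables")
    if len(occ) < min_occurrences:
        raise ValueError(
            f"{len(occ)} occurrences < required minimum {min_occurrences}"
        )
    background = stack.background_table().drop(columns=["row", "col"])
    pres_rows = extract_at(stack, occ.lonlat())
    pres = pres_rows[pres_rows["status"] == "ok"][stack.names]
    if len(pres) < min_occurrences:
        raise ValueError("too few occurrences fall on valid cells")
    corr = spearman_matrix(background[stack.continuous_names()])

    trace: list[dict] = []
    scores = []
    best: tuple[float, list[str]] | None = None
    for bm in bm_list:
        current = list(stack.names)
        for it in range(max_iter):
            model = fit_on_tables(
                background[current], pres[current],
                {v: stack.kind[v] for v in current},
                fc_set=fc_set, bm=bm, n_knots=n_knots,
            )
            contrib = percent_contribution(model)
            low = [v for v in current if contrib[v] < contrib_threshold]
            if low and len(low) < len(current):
                for v in low:
                    trace.append({"bm": bm, "iteration": it, "variable": v,
                                  "action": "drop", "reason": "low-contribution",
                                  "contribution": float(contrib[v])})
                current = [v for v in current if v not in low]
                continue
            if low and len(low) == len(current):
                # degenerate: everything under threshold — keep the best one
                keep = contrib.idxmax()
                for v in current:
                    if v != keep:
                        trace.append({"bm": bm, "iteration": it, "variable": v,
                                      "action": "drop", "reason": "low-contribution",
                                      "contribution": float(contrib[v])})
                current = [keep]
            # correlated pairs among survivors: drop the lower-contribution member
            cont_now = [v for v in current if stack.kind[v] == "continuous"]
            dropped = set()
            for i, a in enumerate(cont_now):
                for b in cont_now[i + 1:]:
                    if a in dropped or b in dropped:
                        continue
                    if abs(corr.r.loc[a, b]) >= corr_threshold:
                        loser = a if contrib[a] < contrib[b] else b
                        winner = b if loser == a else a
                        dropped.add(loser)
                        trace.append({"bm": bm, "iteration": it, "variable": loser,
                                      "action": "drop",
                                      "reason": f"correlated-with-better:{winner}",
                                      "contribution": float(contrib[loser])})
            if not dropped:
                break
            current = [v for v in current if v not in dropped]
            if not current:
                raise ValueError(f"all variables eliminated (bm={bm}); trace: {trace}")
        # score the stable set
        model = fit_on_tables(
            background[current], pres[current],
            {v: stack.kind[v] for v in current},
            fc_set=fc_set, bm=bm, n_knots=n_knots,
        )
        f_pres, _ = model.builder.transform(pres[current])
        k, loglik, value, valid = aicc(model, f_pres)
        scores.append({"bm": bm, "variables": "+".join(current), "K": k,
                       "loglik": loglik, "aicc": value, "valid": valid})
        if valid and (best is None or value < best[0]):
            best = (value, current)
    if best is None:
        raise ValueError(f"no valid stable model; trace: {trace}")
    return SelectionResult(
        selected=best[1], trace=trace, score_table=pd.DataFrame(scores)
    )
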