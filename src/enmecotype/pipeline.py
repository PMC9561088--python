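"""End-to-end protocol: stack -> occurrences -> screening -> parameter
selection -> per-population models -> similarity -> ecotype clustering.

Every stage writes its artefacts under one run directory and can be rerun
in isolation from the serialized outputs of the stage before it; the
monolithic :func:`run_pipeline` simply chains the stages.  The JSON run
report carries no timestamps, so identical configurations and seeds
reproduce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import similarity as sim
from .evaluate import (jackknife, model_auc, percent_contribution,
                       permutation_importance, response_curve)
from .maxent import MaxentModel, fit_on_tables, predict
from .model_select import partition, select_best, tune
from .occurrences import OccurrenceSet, SamplingTable, expand_all, parse_sampling_table
from .raster import EnvStack, align_stack, extract_at, read_manifest, write_grid
from .screen import mvs_select, normality_check, pca_summary, spearman_matrix
from .synth import make_scenario


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    out_dir: str = "run"
    seed: int = 1
    # input: either a synthetic scenario or files
    synthetic: bool = True
    layer_manifest: str | None = None
    sampling_table: str | None = None
    # occurrence expansion
    n_extra: int = 9
    area_km2: float = 1.2
    # screening
    corr_threshold: float = 0.6
    contrib_threshold: float = 5.0
    priority: list[str] = field(default_factory=list)
    mvs_bm_list: list[float] = field(default_factory=lambda: [1.0, 2.0])
    mvs_fc_set: list[str] = field(default_factory=lambda: ["H"])
    mvs_n_knots: int = 10
    # parameter grid
    fc_sets: list[list[str]] = field(default_factory=lambda: [["L", "Q"], ["H"]])
    bm_values: list[float] = field(default_factory=lambda: [1.0, 2.0])
    # evaluation
    test_frac: float = 0.25
    k_folds: int = 10
    n_knots: int = 6
    # clustering
    k_override: int | None = 4
    metrics: list[str] = field(default_factory=lambda: ["overlap_I", "pearson_r"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


class RunLog:
    """Append-only plain-text audit log of seeds, thresholds and choices."""

    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def record(self, key: str, value) -> None:
        self.lines.append(f"{key} = {value}")
        self.path.write_text("\n".join(self.lines) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stack_dir(out: Path) -> Path:
    return out / "stack"


def stage_simulate(config: RunConfig, out: Path, log: RunLog):
    """Generate (or load) the stack and sampling table; write the layer files."""
    sdir = _stack_dir(out)
    sdir.mkdir(parents=True, exist_ok=True)
    if config.synthetic:
        scenario = make_scenario(seed=config.seed)
        stack = scenario.stack
        table = scenario.table
        scenario.truth_labels.to_csv(out / "truth_labels.csv", index=False)
        log.record("simulate.seed", config.seed)
    else:
        if not config.layer_manifest or not config.sampling_table:
            raise PipelineError(
                "simulate", "non-synthetic runs need layer_manifest and sampling_table"
            )
        try:
            grids, groups, kinds = read_manifest(config.layer_manifest)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        template = next(iter(grids.values()))
        stack = align_stack(grids, template, groups=groups, kinds=kinds)
        table = parse_sampling_table(config.sampling_table)
    manifest_rows = []
    for name in stack.names:
        path = sdir / f"{name}.asc"
        write_grid(stack.layers[name], path)
        manifest_rows.append({"name": name, "group": stack.groups[name],
                              "kind": stack.kind[name], "path": path.name})
    pd.DataFrame(manifest_rows).to_csv(sdir / "manifest.csv", index=False)
    table.rows.to_csv(out / "sampling_table.csv", index=False)
    log.record("simulate.n_layers", len(stack.names))
    log.record("simulate.n_districts", len(table.districts))
    return stack, table


def load_stack(out: Path) -> EnvStack:
    grids, groups, kinds = read_manifest(_stack_dir(out) / "manifest.csv")
    template = next(iter(grids.values()))
    return align_stack(grids, template, groups=groups, kinds=kinds)


def stage_occurrences(config: RunConfig, out: Path, log: RunLog,
                      table: SamplingTable) -> OccurrenceSet:
    occ = expand_all(table, n_extra=config.n_extra, area_km2=config.area_km2,
                     seed=config.seed)
    occ.points.to_csv(out / "occurrences.csv", index=False)
    log.record("occurrences.seed", config.seed)
    log.record("occurrences.n_points", len(occ))
    return occ


def stage_screen(config: RunConfig, out: Path, log: RunLog,
                 stack: EnvStack, occ: OccurrenceSet) -> list[str]:
    """Correlation + normality + PCA reports, then the iterative selection."""
    try:
        pres = extract_at(stack, occ.lonlat())
        ok = pres[pres["status"] == "ok"][stack.names]
        cont = [n for n in stack.names if stack.kind[n] == "continuous"]
        normality_check(ok[cont]).to_csv(out / "normality.csv", index=False)
        report = spearman_matrix(ok[cont])
        report.r.to_csv(out / "correlation.csv")
        _, var_pct = pca_summary(ok[cont])
        var_pct.rename("variance_pct").to_csv(out / "pca_variance.csv")
        selection = mvs_select(
            stack, occ,
            contrib_threshold=config.contrib_threshold,
            corr_threshold=config.corr_threshold,
            bm_list=config.mvs_bm_list,
            fc_set=tuple(config.mvs_fc_set),
            n_knots=config.mvs_n_knots,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc
    (out / "selection.json").write_text(json.dumps({
        "selected": selection.selected,
        "trace": selection.trace,
        "scores": selection.score_table.to_dict(orient="records"),
    }, sort_keys=True, indent=2, default=float))
    log.record("screen.corr_threshold", config.corr_threshold)
    log.record("screen.contrib_threshold", config.contrib_threshold)
    log.record("screen.selected", selection.selected)
    return selection.selected


def _tables_for(stack: EnvStack, occ: OccurrenceSet, selected: list[str]):
    sub = stack.subset(selected)
    background = sub.background_table().drop(columns=["row", "col"])
    rows = extract_at(sub, occ.lonlat())
    keep = rows["status"] == "ok"
    pres = rows.loc[keep, selected].reset_index(drop=True)
    kept_idx = np.nonzero(keep.to_numpy())[0]
    return sub, background, pres, kept_idx


def stage_tune(config: RunConfig, out: Path, log: RunLog,
               stack: EnvStack, occ: OccurrenceSet,
               selected: list[str]) -> tuple[tuple[str, ...], float]:
    _, background, pres, _ = _tables_for(stack, occ, selected)
    kinds = {v: stack.kind[v] for v in selected}
    try:
        grid = tune(background, pres, kinds,
                    fc_list=config.fc_sets, bm_range=config.bm_values,
                    n_knots=config.n_knots)
        fc, bm = select_best(grid)
    except Exception as exc:
        raise PipelineError("tune", str(exc)) from exc
    grid.to_csv(out / "model_grid.csv")
    (out / "chosen_parameters.json").write_text(json.dumps(
        {"fc_set": list(fc), "bm": bm}, sort_keys=True, indent=2))
    log.record("tune.n_candidates", len(grid.table))
    log.record("tune.chosen", f"fc={'+'.join(fc)} bm={bm}")
    return fc, bm


def stage_fit(config: RunConfig, out: Path, log: RunLog,
              stack: EnvStack, occ: OccurrenceSet, selected: list[str],
              fc: tuple[str, ...], bm: float) -> dict:
    """Pooled model plus one model per district; saves model JSON sidecars."""
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    sub, background, _, _ = _tables_for(stack, occ, selected)
    kinds = {v: stack.kind[v] for v in selected}
    results = {"districts": {}, "pooled": {}}

    def _fit_split(name: str, occ_subset: OccurrenceSet, do_cv: bool):
        train_idx, test_idx, folds = partition(
            occ_subset, test_frac=config.test_frac, k=config.k_folds,
            seed=occ_subset.seed,
        )
        rows = extract_at(sub, occ_subset.lonlat())
        ok = rows["status"] == "ok"
        pres_all = rows.loc[ok, selected].reset_index(drop=True)
        pos = {orig: i for i, orig in enumerate(np.nonzero(ok.to_numpy())[0])}
        tr = pres_all.iloc[[pos[i] for i in train_idx if i in pos]]
        te = pres_all.iloc[[pos[i] for i in test_idx if i in pos]]
        model = fit_on_tables(background, tr, kinds, fc_set=fc, bm=bm,
                              n_knots=config.n_knots, background_ref=name)
        auc_train = model_auc(model, tr, background)
        auc_test = model_auc(model, te, background) if len(te) else float("nan")
        # regionalised k-fold CV on the training part (pooled model only;
        # per-district refits would dominate runtime without informing maps)
        cv_aucs = []
        for f_id in sorted(set(folds)) if do_cv else []:
            hold = [pos[i] for i, lab in zip(train_idx, folds)
                    if lab == f_id and i in pos]
            keep = [pos[i] for i, lab in zip(train_idx, folds)
                    if lab != f_id and i in pos]
            if not hold or not keep:
                continue
            m_cv = fit_on_tables(background, pres_all.iloc[keep], kinds,
                                 fc_set=fc, bm=bm, n_knots=config.n_knots)
            cv_aucs.append(model_auc(m_cv, pres_all.iloc[hold], background))
        model.save(mdir / f"{name}.json")
        return model, {
            "n_train": int(len(tr)), "n_test": int(len(te)),
            "auc_train": float(auc_train), "auc_test": float(auc_test),
            "cv_auc_mean": float(np.mean(cv_aucs)) if cv_aucs else float("nan"),
        }

    pooled_model, pooled_stats = _fit_split("pooled", occ, do_cv=True)
    results["pooled"] = pooled_stats
    districts = list(dict.fromkeys(occ.points["district"]))
    for d in districts:
        pts = occ.points[occ.points["district"] == d].reset_index(drop=True)
        d_occ = OccurrenceSet(points=pts, seed=occ.seed)
        try:
            _, stats_d = _fit_split(d, d_occ, do_cv=False)
        except Exception as exc:
            raise PipelineError("fit", f"district {d!r}: {exc}") from exc
        results["districts"][d] = stats_d
    (out / "fit_stats.json").write_text(
        json.dumps(results, sort_keys=True, indent=2))
    log.record("fit.fc_set", "+".join(fc))
    log.record("fit.bm", bm)
    log.record("fit.n_models", 1 + len(districts))
    return results


def stage_evaluate(config: RunConfig, out: Path, log: RunLog,
                   stack: EnvStack, occ: OccurrenceSet,
                   selected: list[str], fc: tuple[str, ...], bm: float) -> dict:
    """Pooled-model importance statistics and response curves."""
    sub, background, pres, _ = _tables_for(stack, occ, selected)
    kinds = {v: stack.kind[v] for v in selected}
    train_idx, test_idx, _ = partition(occ, test_frac=config.test_frac,
                                       k=config.k_folds, seed=occ.seed)
    rows = extract_at(sub, occ.lonlat())
    ok = rows["status"] == "ok"
    pres_all = rows.loc[ok, selected].reset_index(drop=True)
    pos = {orig: i for i, orig in enumerate(np.nonzero(ok.to_numpy())[0])}
    tr = pres_all.iloc[[pos[i] for i in train_idx if i in pos]]
    te = pres_all.iloc[[pos[i] for i in test_idx if i in pos]]
    model = MaxentModel.load(out / "models" / "pooled.json")
    try:
        contrib = percent_contribution(model)
        perm = permutation_importance(model, tr, background, seed=config.seed)
        jk = jackknife(background, tr, te, kinds, selected,
                       fc_set=fc, bm=bm, n_knots=config.n_knots) \
            if len(selected) >= 2 else None
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    curves = []
    for v in selected:
        c = response_curve(model, background, v)
        c.insert(0, "variable", v)
        curves.append(c)
    pd.concat(curves, ignore_index=True).to_csv(out / "response_curves.csv",
                                                index=False)
    if jk is not None:
        jk.table.to_csv(out / "jackknife.csv", index=False)
    result = {
        "percent_contribution": {k: float(v) for k, v in contrib.items()},
        "permutation_importance": {k: float(v) for k, v in perm.items()},
        "jackknife_reference_gain": float(jk.reference_gain) if jk else None,
    }
    (out / "evaluation.json").write_text(json.dumps(result, sort_keys=True, indent=2))
    log.record("evaluate.permutation_seed", config.seed)
    return result


def stage_compare(config: RunConfig, out: Path, log: RunLog,
                  stack: EnvStack, selected: list[str]) -> dict[str, sim.SimilarityMatrix]:
    """Project every district model and compute both similarity matrices."""
    sub = stack.subset(selected)
    mdir = out / "models"
    maps = {}
    for path in sorted(mdir.glob("*.json")):
        if path.stem == "pooled":
            continue
        maps[path.stem] = predict(MaxentModel.load(path), sub)
    if len(maps) < 2:
        raise PipelineError("compare", "need at least two district models")
    matrices = {}
    for metric in config.metrics:
        try:
            m = sim.similarity_matrix(maps, metric=metric)
        except sim.SimilarityError as exc:
            raise PipelineError("compare", f"metric {metric}: {exc}") from exc
        m.to_frame().to_csv(out / f"similarity_{metric}.csv")
        m.to_long().to_csv(out / f"similarity_{metric}_long.csv", index=False)
        matrices[metric] = m
    log.record("compare.metrics", config.metrics)
    return matrices


def _match_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Relabel b to best match a (Hungarian assignment on the contingency table)."""
    from scipy.optimize import linear_sum_assignment

    la, lb = np.unique(a), np.unique(b)
    cont = np.zeros((len(la), len(lb)))
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            cont[i, j] = np.sum((a == x) & (b == y))
    ri, ci = linear_sum_assignment(-cont)
    mapping = {lb[j]: la[i] for i, j in zip(ri, ci)}
    return np.array([mapping.get(x, -1) for x in b])


def load_matrices(config: RunConfig, out: Path) -> dict[str, sim.SimilarityMatrix]:
    """Read the serialized similarity matrices of a run directory."""
    matrices = {}
    for metric in config.metrics:
        path = out / f"similarity_{metric}.csv"
        if not path.exists():
            raise PipelineError("cluster", f"missing similarity matrix {path}")
        df = pd.read_csv(path, index_col=0)
        matrices[metric] = sim.SimilarityMatrix(
            labels=list(df.index), values=df.to_numpy(), metric=metric)
    return matrices


def stage_cluster(config: RunConfig, out: Path, log: RunLog,
                  matrices: dict[str, sim.SimilarityMatrix]) -> dict:
    """Four-linkage clustering per metric, AC-based linkage choice, k-cut."""
    results = {}
    assignments = {}
    frames = []
    for metric, matrix in matrices.items():
        d = cl.row_distance(matrix)
        trees = {m: cl.hac(d, m) for m in cl.LINKAGES}
        chosen = cl.select_linkage(trees)
        tree = trees[chosen]
        k = cl.choose_k(tree, d, override=config.k_override)
        assign = cl.cut_assign(tree, k, metric=metric)
        (out / f"dendrogram_{metric}.nwk").write_text(tree.to_newick() + "\n")
        frames.append(assign.to_frame())
        assignments[metric] = assign
        results[metric] = {
            "agglomerative_coefficients": {m: float(t.ac) for m, t in trees.items()},
            "chosen_linkage": chosen,
            "k": int(k),
            "assignment": assign.assignment,
        }
        log.record(f"cluster.{metric}.linkage", chosen)
        log.record(f"cluster.{metric}.k", k)
    pd.concat(frames, ignore_index=True).to_csv(out / "assignments.csv", index=False)
    # cross-metric disagreements
    disagreements: list[str] = []
    metrics = list(assignments)
    if len(metrics) >= 2:
        pops = list(assignments[metrics[0]].assignment)
        a = assignments[metrics[0]].labels_for(pops)
        b = assignments[metrics[1]].labels_for(pops)
        b_mapped = _match_labels(a, b)
        disagreements = [p for p, x, y in zip(pops, a, b_mapped) if x != y]
    results["cross_metric_disagreements"] = sorted(disagreements)
    (out / "clustering.json").write_text(
        json.dumps(results, sort_keys=True, indent=2))
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full protocol; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "log.txt")
    log.record("seed", config.seed)
    stack, table = stage_simulate(config, out, log)
    occ = stage_occurrences(config, out, log, table)
    selected = stage_screen(config, out, log, stack, occ)
    fc, bm = stage_tune(config, out, log, stack, occ, selected)
    fit_stats = stage_fit(config, out, log, stack, occ, selected, fc, bm)
    evaluation = stage_evaluate(config, out, log, stack, occ, selected, fc, bm)
    stage_compare(config, out, log, stack, selected)
    # cluster from the serialized matrices so stage-wise reruns are identical
    clustering = stage_cluster(config, out, log, load_matrices(config, out))

    report = {
        "seed": config.seed,
        "selected_variables": selected,
        "chosen_fc_set": list(fc),
        "chosen_bm": bm,
        "pooled": fit_stats["pooled"],
        "district_auc": {
            d: {"train": s["auc_train"], "test": s["auc_test"]}
            for d, s in fit_stats["districts"].items()
        },
        "percent_contribution": evaluation["percent_contribution"],
        "clustering": clustering,
    }
    truth_path = out / "truth_labels.csv"
    if truth_path.exists():
        from sklearn.metrics import adjusted_rand_score

        truth = pd.read_csv(truth_path)
        truth_map = dict(zip(truth["district"], truth["ecotype"]))
        ari = {}
        for metric in config.metrics:
            assign = clustering[metric]["assignment"]
            pops = sorted(assign)
            pred = [assign[p] for p in pops]
            true = [truth_map[p] for p in pops]
            ari[metric] = float(adjusted_rand_score(true, pred))
        report["ari_vs_truth"] = ari
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    return report
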