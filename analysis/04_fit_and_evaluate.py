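#!/usr/bin/env python
"""Fit the pooled and per-district niche models and evaluate them.

Fits one maximum-entropy model on all pooled occurrences (75/25 split with
regionalised ten-fold cross-validation) and one per district, then reports
AUC, jackknife gains, percent contribution and permutation importance for
the pooled model.
"""

import json
from pathlib import Path

import pandas as pd

from enmecotype.occurrences import OccurrenceSet
from enmecotype.pipeline import (RunConfig, RunLog, load_stack, stage_evaluate,
                                 stage_fit)

RUN = Path("results/run")
SEED = 1


def main() -> None:
    cfg = RunConfig(out_dir=str(RUN), seed=SEED)
    log = RunLog(RUN / "log.txt")
    stack = load_stack(RUN)
    occ = OccurrenceSet(points=pd.read_csv(RUN / "occurrences.csv"), seed=SEED)
    selected = json.loads((RUN / "selection.json").read_text())["selected"]
    chosen = json.loads((RUN / "chosen_parameters.json").read_text())
    fc, bm = tuple(chosen["fc_set"]), chosen["bm"]
    stats = stage_fit(cfg, RUN, log, stack, occ, selected, fc, bm)
    evaluation = stage_evaluate(cfg, RUN, log, stack, occ, selected, fc, bm)
    pooled = stats["pooled"]
    print(f"pooled model: AUC train {pooled['auc_train']:.3f}, "
          f"test {pooled['auc_test']:.3f}, CV mean {pooled['cv_auc_mean']:.3f}")
    d_auc = [s["auc_train"] for s in stats["districts"].values()]
    print(f"district models: n={len(d_auc)}, training AUC "
          f"{min(d_auc):.3f}-{max(d_auc):.3f}")
    contrib = pd.Series(evaluation["percent_contribution"]).sort_values(ascending=False)
    print("percent contribution:")
    print(contrib.round(1).to_string())


if __name__ == "__main__":
    main()
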