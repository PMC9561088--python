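#!/usr/bin/env python
"""Choose the feature-class set and beta multiplier by corrected AIC.

Fits every candidate of the configured feature-class x beta-multiplier
grid on the pooled occurrences over the selected variables and prints the
AICc ranking; downstream models use the winner.
"""

import json
from pathlib import Path

import pandas as pd

from enmecotype.occurrences import OccurrenceSet
from enmecotype.pipeline import RunConfig, RunLog, load_stack, stage_tune

RUN = Path("results/run")
SEED = 1


def main() -> None:
    cfg = RunConfig(out_dir=str(RUN), seed=SEED)
    log = RunLog(RUN / "log.txt")
    stack = load_stack(RUN)
    occ = OccurrenceSet(points=pd.read_csv(RUN / "occurrences.csv"), seed=SEED)
    selected = json.loads((RUN / "selection.json").read_text())["selected"]
    fc, bm = stage_tune(cfg, RUN, log, stack, occ, selected)
    grid = pd.read_csv(RUN / "model_grid.csv")
    print(grid.sort_values("aicc").to_string(index=False))
    print(f"\nchosen: feature classes {'+'.join(fc)}, beta multiplier {bm}")


if __name__ == "__main__":
    main()
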