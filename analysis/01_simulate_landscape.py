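#!/usr/bin/env python
"""Generate the synthetic study landscape and sampling design.

Builds the packaged 64x64 environmental stack (three climatic driver
layers, two correlated distractors, two fine-grained noise decoys, one
categorical land-cover layer), plants four ecotype suitability surfaces,
draws 16 districts x 2 villages from them, and expands every village to
ten occurrence points.  All downstream steps read the artefacts written
under the run directory.
"""

from pathlib import Path

from enmecotype.pipeline import RunConfig, RunLog, stage_occurrences, stage_simulate

RUN = Path("results/run")
SEED = 1


def main() -> None:
    cfg = RunConfig(out_dir=str(RUN), seed=SEED)
    RUN.mkdir(parents=True, exist_ok=True)
    log = RunLog(RUN / "log.txt")
    stack, table = stage_simulate(cfg, RUN, log)
    occ = stage_occurrences(cfg, RUN, log, table)
    print(f"landscape: {stack.shape[0]}x{stack.shape[1]} grid, "
          f"{len(stack.names)} layers ({', '.join(stack.names)})")
    print(f"design: {len(table.districts)} districts, {table.n_villages} villages, "
          f"{len(occ)} occurrence points")
    print(f"artefacts under {RUN}/ (stack/, sampling_table.csv, occurrences.csv)")


if __name__ == "__main__":
    main()
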