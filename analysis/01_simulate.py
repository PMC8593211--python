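#!/usr/bin/env python
"""Simulate the four-group cohort (FF/FR x context/flavor predictors).

Generates the full conditioning dataset — 40 animals, 8 paired sessions,
one control (Malt-Malt) and one experimental (Malt-CM) day each — under the
default generative preset, and writes the raw event streams in the tidy
dialect. Event CSVs are large, so they go under scratch/; downstream
analyses write their small derived tables under results/.

Run from the repository root:  python analysis/01_simulate.py [--seed N]
"""

import argparse
import dataclasses
from pathlib import Path

from anclick.cli import _provenance
from anclick.io import write_events
from anclick.simulate import SimulationParams, simulate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("scratch/cohort"))
args = parser.parse_args()

params = SimulationParams(seed=args.seed)  # full-scale preset: n = 10 per cell
manifest, logs = simulate_cohort(params)
args.out.mkdir(parents=True, exist_ok=True)
header = _provenance(params.seed, dataclasses.asdict(params))
write_events(logs, args.out / "events.csv", header=header)
with open(args.out / "cohort.csv", "w") as fh:
    fh.write(f"# {header}\n")
    manifest.to_frame().to_csv(fh, index=False)

n_events = sum(len(l) for l in logs)
print(f"simulated {len(manifest)} animals x {params.n_sessions} paired sessions")
print(f"  -> {len(logs)} event logs, {n_events} events, written to {args.out}/")
print("  suppression preset: A=%.2f rho=%.2f midpoint=s%g" % (
    params.anc_amplitude, params.rho, params.learning_midpoint))
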