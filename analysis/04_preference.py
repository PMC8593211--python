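#!/usr/bin/env python
"""Flavor preference test: pre- vs post-conditioning lick totals.

Simulates the two-sipper preference test (10 forced-choice then 30
free-choice trials per epoch) for the cohort, summarizes total licks per
flavor and trial type, and runs the two-way within-subject ANOVA
(pre/post x flavor) on free-choice totals — the design that asks whether
conditioning raised intake of both flavors (main effect of epoch) without
favoring the CM-predicting one (no interaction).

Run:  python analysis/04_preference.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd

from anclick.contrast import preference_anova, summarize_preference
from anclick.simulate import SimulationParams, cohort_manifest, simulate_preference_test

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

params = SimulationParams(seed=args.seed)
manifest = cohort_manifest(params)
trials = pd.concat(
    [simulate_preference_test(params, e) for e in ("pre", "post")], ignore_index=True
)
summary = summarize_preference(trials, manifest)
args.out_dir.mkdir(parents=True, exist_ok=True)
summary.to_csv(args.out_dir / "preference.csv", index=False)

free = summary[summary.trial_type == "free"].groupby(["epoch", "flavor"])["total_licks"].mean()
print("mean free-choice licks per animal:")
print(free.to_string())
effects = preference_anova(summary)
print("\n2-way RM ANOVA (pre/post x flavor, free-choice totals):")
for e in effects:
    print("  " + str(e))
pd.DataFrame([vars(e) for e in effects]).to_csv(args.out_dir / "preference_anova.csv", index=False)
print(f"\nwrote preference.csv, preference_anova.csv -> {args.out_dir}/")
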