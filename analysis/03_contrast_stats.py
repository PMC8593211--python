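#!/usr/bin/env python
"""Run the contrast analysis and the within-subject statistical battery.

Per group (diet x predictor) and per metric/phase: two-way repeated-measures
ANOVA (Condition x Session), Bonferroni per-session post-hocs and the
emergence session (first session with a corrected significant
control/experimental difference). Then the cross-group comparison: the
three-way mixed ANOVA (Diet, Predictor between; Session within, with
Greenhouse-Geisser-corrected Session df) on normalized phase-1 total licks
(experimental / control).

Run:  python analysis/03_contrast_stats.py
"""

import argparse
from pathlib import Path

import pandas as pd

from anclick.contrast import build_contrast_table, contrast_long, join_groups
from anclick.io import read_cohort, read_metrics
from anclick.stats import (
    bonferroni_posthoc,
    effects_frame,
    emergence_session,
    mixed_anova_3way,
    posthoc_frame,
    rm_anova_2way,
)

parser = argparse.ArgumentParser()
parser.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
parser.add_argument("--cohort", type=Path, default=Path("scratch/cohort/cohort.csv"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

table = read_metrics(args.metrics)
manifest = read_cohort(args.cohort)
args.out_dir.mkdir(parents=True, exist_ok=True)

anova_frames, posthoc_frames, emergence_rows = [], [], []
for metric, phase in [
    ("total_licks", "phase1"), ("total_licks", "phase2"),
    ("licks_per_cluster", "phase1"), ("licks_per_cluster", "phase2"),
    ("total_clusters", "phase1"), ("total_clusters", "phase2"),
    ("premature_entries", "phase1"),
]:
    sub = join_groups(table[(table.metric_name == metric) & (table.phase == phase)], manifest)
    for (diet, pred), grp in sub.groupby(["diet", "predictor"]):
        effects = rm_anova_2way(grp)
        ph = bonferroni_posthoc(grp)
        em = emergence_session(ph)
        ef = effects_frame(effects)
        for df_, extra in ((ef, None), (posthoc_frame(ph), None)):
            df_.insert(0, "metric", metric)
            df_.insert(1, "phase", phase)
            df_.insert(2, "diet", diet)
            df_.insert(3, "predictor", pred)
        anova_frames.append(ef)
        posthoc_frames.append(posthoc_frame(ph).assign(metric=metric, phase=phase,
                                                       diet=diet, predictor=pred))
        emergence_rows.append((metric, phase, diet, pred, em))
        if metric == "total_licks" and phase == "phase1":
            inter = effects[2]
            print(f"[{diet}/{pred}] phase-1 total licks: {inter}; emergence session: {em}")

pd.concat(anova_frames, ignore_index=True).to_csv(args.out_dir / "anova.csv", index=False)
pd.concat(posthoc_frames, ignore_index=True).to_csv(args.out_dir / "posthoc.csv", index=False)
pd.DataFrame(emergence_rows, columns=["metric", "phase", "diet", "predictor",
                                      "emergence_session"]).to_csv(
    args.out_dir / "emergence.csv", index=False)

# cross-group comparison on normalized phase-1 licking
contrast = build_contrast_table(table)
norm = join_groups(contrast_long(contrast, "total_licks", "phase1"), manifest)
effects3 = mixed_anova_3way(norm, gg="session-main")
effects_frame(effects3).to_csv(args.out_dir / "anova_3way_normalized.csv", index=False)
print("\n3-way mixed ANOVA on normalized phase-1 total licks:")
for e in effects3:
    print("  " + str(e))
print(f"\nwrote anova.csv, posthoc.csv, emergence.csv, anova_3way_normalized.csv -> {args.out_dir}/")
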