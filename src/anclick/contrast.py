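"""Pairing of control/experimental days, normalized contrast tables, and the
flavor preference test summary.

Each paired session consists of a control day (Malt in both phases, "MM")
followed by an experimental day (Malt then CM, "MC"). The contrast measure
normalizes experimental by control: normalized = experimental / control, so
1 means no contrast and values below 1 on phase-1 licking indicate
anticipatory negative contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CohortManifest, EventLog, ValidationError
from .stats import AnovaEffect, rm_anova_2way


class PairingError(ValueError):
    """A paired session is missing its control or experimental counterpart."""


def pair_days(logs: list[EventLog]) -> list[tuple[EventLog, EventLog]]:
    """Order one animal's logs into (control, experimental) pairs per session.

    Requires exactly one MM and one MC day per paired_session index; orphan
    or duplicated days raise :class:`PairingError` naming the offender.
    """
    if not logs:
        return []
    animals = {l.animal_id for l in logs}
    if len(animals) > 1:
        raise PairingError(f"pair_days expects one animal, got {sorted(animals)}")
    by_session: dict[int, dict[str, EventLog]] = {}
    for log in logs:
        slot = by_session.setdefault(log.paired_session, {})
        if log.condition in slot:
            raise PairingError(
                f"animal {log.animal_id}: two {log.condition} days for session {log.paired_session}"
            )
        slot[log.condition] = log
    pairs = []
    for s in sorted(by_session):
        slot = by_session[s]
        missing = [c for c in ("MM", "MC") if c not in slot]
        if missing:
            raise PairingError(
                f"animal {next(iter(animals))}: session {s} missing {missing[0]} day"
            )
        pairs.append((slot["MM"], slot["MC"]))
    return pairs


def normalized_value(control_value: float, experimental_value: float) -> float:
    """experimental / control; NaN (flagged missing) when control is 0."""
    if control_value == 0:
        return float("nan")
    return experimental_value / control_value


def build_contrast_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Wide contrast rows from a long metric table.

    For every (animal, session, phase, metric): control_value (MM),
    experimental_value (MC), and normalized = MC / MM (NaN, with
    ``control_zero`` flag, when the control value is 0). Raises
    :class:`PairingError` when a day is missing its counterpart.
    """
    required = {"animal_id", "paired_session", "condition", "phase", "metric_name", "value"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValidationError(f"metric table missing column(s) {sorted(missing)}")
    wide = metrics.pivot_table(
        index=["animal_id", "paired_session", "phase", "metric_name"],
        columns="condition",
        values="value",
        aggfunc="first",
        dropna=False,
    )
    for cond in ("MM", "MC"):
        if cond not in wide.columns:
            raise PairingError(f"no {cond} days in the metric table")
    # a missing day means every metric of that day is absent, a NaN metric value
    # (e.g. licks_per_cluster with no clusters) is legitimate — detect orphan
    # days at the (animal, session) level on total_licks presence
    probe = metrics.pivot_table(
        index=["animal_id", "paired_session"], columns="condition",
        values="value", aggfunc="count",
    ).reindex(columns=["MM", "MC"])
    orphan = probe.isna().any(axis=1) | (probe == 0).any(axis=1)
    if orphan.any():
        a, s = probe.index[orphan][0]
        side = "MM" if pd.isna(probe.loc[(a, s), "MM"]) or probe.loc[(a, s), "MM"] == 0 else "MC"
        raise PairingError(f"animal {a}: session {s} missing {side} day")
    out = wide.reset_index().rename(columns={"MM": "control_value", "MC": "experimental_value"})
    out.columns.name = None
    ctrl = out["control_value"].to_numpy(dtype=float)
    expv = out["experimental_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(ctrl == 0, np.nan, expv / ctrl)
    out["normalized"] = norm
    out["control_zero"] = ctrl == 0
    return out


def contrast_long(contrast: pd.DataFrame, metric_name: str, phase: str) -> pd.DataFrame:
    """Slice one metric/phase of a contrast table into the tidy layout the
    3-way model consumes (value = normalized ratio)."""
    sub = contrast[(contrast["metric_name"] == metric_name) & (contrast["phase"] == phase)]
    return sub[["animal_id", "paired_session", "normalized"]].rename(columns={"normalized": "value"})


def join_groups(table: pd.DataFrame, manifest: CohortManifest) -> pd.DataFrame:
    """Attach diet / predictor labels from the manifest (inner join on animal_id)."""
    labels = manifest.to_frame()[["animal_id", "diet", "predictor"]]
    return table.merge(labels, on="animal_id", how="inner")


# ---------------------------------------------------------------------------
# flavor preference test

def summarize_preference(
    trials: pd.DataFrame, manifest: CohortManifest | None = None
) -> pd.DataFrame:
    """Total licks per (animal, epoch, flavor, trial_type) from preference trials.

    Validates the trial structure per (animal, epoch): 10 forced then 30 free
    trials, forced trials licking exactly one sipper. When a manifest is
    given, flavors are additionally labeled CS+ / CS- from its ``cs_plus``
    assignment.
    """
    req = {"animal_id", "epoch", "trial_index", "trial_type", "flavor", "licks_A", "licks_B"}
    missing = req - set(trials.columns)
    if missing:
        raise ValidationError(f"preference trials missing column(s) {sorted(missing)}")
    for (animal, epoch), grp in trials.groupby(["animal_id", "epoch"]):
        grp = grp.sort_values("trial_index")
        types = grp["trial_type"].tolist()
        if types != ["forced"] * 10 + ["free"] * 30:
            raise ValidationError(
                f"animal {animal} epoch {epoch}: expected 10 forced then 30 free trials"
            )
        forced = grp[grp["trial_type"] == "forced"]
        both = (forced["licks_A"] > 0) & (forced["licks_B"] > 0)
        if both.any():
            raise ValidationError(
                f"animal {animal} epoch {epoch}: forced trial with licks on both sippers"
            )
    rows = []
    for (animal, epoch, ttype), grp in trials.groupby(["animal_id", "epoch", "trial_type"]):
        for flavor, col in (("A", "licks_A"), ("B", "licks_B")):
            rows.append((animal, epoch, ttype, flavor, int(grp[col].sum())))
    out = pd.DataFrame(rows, columns=["animal_id", "epoch", "trial_type", "flavor", "total_licks"])
    if manifest is not None:
        cs = {a.animal_id: a.cs_plus for a in manifest.animals}
        out["cs_role"] = [
            "CS+" if cs.get(a) == f else "CS-" for a, f in zip(out["animal_id"], out["flavor"])
        ]
    return out


def preference_anova(summary: pd.DataFrame, trial_type: str = "free") -> list[AnovaEffect]:
    """Two-way within-subject ANOVA on preference totals: epoch (pre/post) x
    flavor, the pre/post comparison reported for the flavor-predictor groups."""
    sub = summary[summary["trial_type"] == trial_type].copy()
    sub = sub.rename(columns={"total_licks": "value"})
    return rm_anova_2way(
        sub, dv="value", within=("epoch", "flavor"), names=("PrePost", "Flavor")
    )
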