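"""Generative simulator of the two-phase anticipatory-negative-contrast paradigm.

A simulated test day reproduces the protocol's event stream: sipper 1
extended for phase 1 (5 min), a 20-s inter-phase interval (IPI) with both
sippers retracted, then sipper 2 for phase 2 (5 min). Licking is a cluster
process: cluster initiations follow a homogeneous Poisson process at rate
``lambda`` (clusters/min), cluster sizes are ``1 + Poisson(mu - 1)`` licks,
within-cluster inter-lick intervals are Gamma distributed (mean ~0.14 s,
i.e. ~7 Hz licking) truncated below the 500-ms cluster threshold, and
consecutive clusters are separated by at least ``threshold + Exp(pause)`` so
that threshold segmentation recovers the generative partition exactly.

The paradigm's psychology enters through two condition/session-dependent
modulations on experimental (Malt-CM) days:

* phase-1 suppression: a logistic learning curve ``A * logistic((s - s0)/tau)``
  scales down the phase-1 Malt parameters, split between cluster rate
  (incentive, share ``1 - rho``) and cluster size (palatability, share
  ``rho``) — lambda_eff = lambda * (1 - supp * (1 - rho)),
  mu_eff = mu * (1 - supp * rho). rho = 1 mimics the contextual-predictor
  signature (licks per cluster changes), rho = 0 the flavor signature
  (total licks change without licks-per-cluster changes);
* anticipation: premature entries to the phase-2 port during phase 1 and
  the IPI follow a Poisson process whose rate grows with the same learning
  curve.

Phase 2 uses the Malt parameters on control days and the CM parameters
(longer clusters, more of them) on experimental days.

Reproducibility: one master seed; each (animal, day) gets an independent
substream keyed by its indices, so enlarging a cohort never perturbs
existing event streams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ENTRY, EXTEND, LICK, RETRACT, AnimalInfo, CohortManifest, EventLog
from .microstructure import cluster_sizes, derive_phase_windows

__all__ = [
    "SimulationParams",
    "learning_suppression",
    "simulate_day",
    "simulate_cohort",
    "simulate_preference_test",
    "recover_params",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters of the synthetic cohort.

    Rates are per minute, durations in seconds. The cluster-process defaults
    (mu_malt = 6 licks/cluster, lam_malt = 8 clusters/min, ~7 Hz within-cluster
    licking) are field conventions for rodent licking, not measured values;
    the CM parameters double palatability and raise incentive so the phase-2
    contrast is visible at cohort size n = 10 per group.
    """

    n_per_cell: int = 10          # animals per (diet x predictor) cell
    n_sessions: int = 8           # paired control/experimental sessions
    phase1_s: float = 300.0
    ipi_s: float = 20.0
    phase2_s: float = 300.0
    threshold_s: float = 0.5      # cluster-defining ILI threshold
    ili_mean_s: float = 0.14      # within-cluster inter-lick interval mean (~7 Hz)
    ili_shape: float = 8.0        # gamma shape of the ILI distribution
    pause_mean_s: float = 2.0     # exponential part of the inter-cluster pause
    mu_malt: float = 6.0          # mean licks per cluster, maltodextrin
    lam_malt: float = 8.0         # cluster initiations per minute, maltodextrin
    mu_cm: float = 12.0           # mean licks per cluster, condensed-milk mix
    lam_cm: float = 12.0          # cluster initiations per minute, CM
    anc_amplitude: float = 0.4    # A: maximal fractional phase-1 suppression
    rho: float = 0.5              # palatability share of the suppression
    learning_midpoint: float = 4.0   # s0 of the logistic learning curve (sessions)
    learning_steepness: float = 1.0  # tau of the logistic learning curve
    entry_rate_base: float = 1.0         # premature entries/min, baseline
    entry_rate_anticipatory: float = 4.0  # extra entries/min at full learning
    pref_weight_a: float = 1.0    # preference-test flavor weights
    pref_weight_b: float = 1.0
    pref_post_multiplier: float = 2.0  # both weights scale up after conditioning
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_malt", "lam_malt", "mu_cm", "lam_cm", "ili_mean_s",
                     "pause_mean_s", "threshold_s", "phase1_s", "ipi_s", "phase2_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.anc_amplitude < 1.0):
            raise ValueError("anc_amplitude must be in [0, 1)")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.mu_malt < 1 or self.mu_cm < 1:
            raise ValueError("mean cluster size must be >= 1 lick")

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


def learning_suppression(params: SimulationParams, session: int | np.ndarray) -> np.ndarray:
    """Logistic learning curve A * logistic((session - s0)/tau): monotone
    non-decreasing in session and bounded in [0, A)."""
    s = np.asarray(session, dtype=float)
    z = (s - params.learning_midpoint) / params.learning_steepness
    return params.anc_amplitude / (1.0 + np.exp(-z))


def _day_rng(params: SimulationParams, animal_index: int, day_index: int) -> np.random.Generator:
    """Independent per-(animal, day) substream derived from the master seed."""
    ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(animal_index, day_index))
    return np.random.default_rng(ss)


def _cluster_train(
    rng: np.random.Generator,
    duration_s: float,
    lam_per_min: float,
    mu: float,
    params: SimulationParams,
) -> np.ndarray:
    """Lick times (seconds from window start) of one window's cluster process.

    Anchor times come from a homogeneous Poisson process at ``lam_per_min``;
    each cluster starts at max(anchor, previous end + threshold + Exp(pause)),
    so the realized cluster count stays rate-unbiased (anchors are only
    delayed, not thinned) while inter-cluster gaps always exceed the
    segmentation threshold. Clusters running past the window end are
    truncated at the boundary; none start beyond it.
    """
    rate = lam_per_min / 60.0
    n = rng.poisson(rate * duration_s)
    if n == 0:
        return np.empty(0)
    anchors = np.sort(rng.random(n) * duration_s)
    sizes = 1 + rng.poisson(max(mu - 1.0, 0.0), n)
    total = int(sizes.sum())

    # within-cluster ILIs, truncated below the cluster threshold
    ili = rng.gamma(params.ili_shape, params.ili_mean_s / params.ili_shape, total)
    bad = ili > params.threshold_s
    while bad.any():
        ili[bad] = rng.gamma(params.ili_shape, params.ili_mean_s / params.ili_shape, int(bad.sum()))
        bad = ili > params.threshold_s
    starts_idx = np.cumsum(sizes) - sizes
    ili[starts_idx] = 0.0
    within = np.cumsum(ili)
    within = within - np.repeat(within[starts_idx], sizes)
    cluster_dur = within[np.cumsum(sizes) - 1]

    # enforce start_i >= end_{i-1} + pause via a prefix-max recurrence
    pauses = params.threshold_s + rng.exponential(params.pause_mean_s, n)
    shift = np.concatenate(([0.0], cluster_dur[:-1] + pauses[1:]))
    B = np.cumsum(shift)
    starts = np.maximum.accumulate(anchors - B) + B

    times = np.repeat(starts, sizes) + within
    return times[times < duration_s]


def _poisson_times(rng: np.random.Generator, rate_per_min: float, duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_per_min / 60.0 * duration_s)
    return np.sort(rng.random(n) * duration_s)


def simulate_day(
    params: SimulationParams,
    animal_index: int,
    session: int,
    condition: str,
    animal_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> EventLog:
    """Simulate one test day's EventLog.

    ``condition`` is "MM" (control, day 1 of the pair) or "MC"
    (experimental, day 2). The per-day random substream is keyed by
    (animal_index, day_index) unless an explicit ``rng`` is passed.
    """
    if condition not in ("MM", "MC"):
        raise ValueError("condition must be 'MM' or 'MC'")
    experimental = condition == "MC"
    day_index = 2 * (session - 1) + (1 if experimental else 0)
    if rng is None:
        rng = _day_rng(params, animal_index, day_index)

    supp = float(learning_suppression(params, session)) if experimental else 0.0
    lam1 = params.lam_malt * (1.0 - supp * (1.0 - params.rho))
    mu1 = params.mu_malt * (1.0 - supp * params.rho)
    mu1 = max(mu1, 1.0)
    if experimental:
        lam2, mu2 = params.lam_cm, params.mu_cm
    else:
        lam2, mu2 = params.lam_malt, params.mu_malt

    t1, tipi, t2 = params.phase1_s, params.ipi_s, params.phase2_s
    p2_start = t1 + tipi
    end = p2_start + t2

    licks1 = _cluster_train(rng, t1, lam1, mu1, params)
    licks2 = p2_start + _cluster_train(rng, t2, lam2, mu2, params)

    # premature entries to the phase-2 port: baseline plus learning-scaled anticipation
    rate_p2 = params.entry_rate_base + supp * params.entry_rate_anticipatory
    ent_p2_phase1 = _poisson_times(rng, rate_p2, t1)
    ent_p2_ipi = t1 + _poisson_times(rng, rate_p2, tipi)
    ent_p1_ipi = t1 + _poisson_times(rng, params.entry_rate_base, tipi)
    ent_p1_phase2 = p2_start + _poisson_times(rng, params.entry_rate_base, t2)

    ts = [np.array([0.0]), licks1, ent_p2_phase1,
          np.array([t1]), ent_p1_ipi, ent_p2_ipi,
          np.array([p2_start]), licks2, ent_p1_phase2,
          np.array([end])]
    kinds = [np.full(len(a), k, dtype=np.int8) for a, k in zip(
        ts, [EXTEND, LICK, ENTRY, RETRACT, ENTRY, ENTRY, EXTEND, LICK, ENTRY, RETRACT])]
    ports = [np.full(len(a), p, dtype=np.int8) for a, p in zip(
        ts, [1, 1, 2, 1, 1, 2, 2, 2, 1, 2])]

    timestamps = np.concatenate(ts)
    order = np.argsort(timestamps, kind="stable")
    return EventLog(
        animal_id=animal_id or f"R{animal_index + 1:02d}",
        test_day=day_index + 1,
        paired_session=session,
        condition=condition,
        timestamps=timestamps[order],
        kinds=np.concatenate(kinds)[order],
        ports=np.concatenate(ports)[order],
    )


def cohort_manifest(params: SimulationParams) -> CohortManifest:
    """Manifest for the 2 x 2 (diet x predictor) cohort with round-robin
    counterbalancing of first sipper side and CS+ assignment."""
    animals = []
    idx = 0
    for diet in ("FF", "FR"):
        for predictor in ("context", "flavor"):
            for j in range(params.n_per_cell):
                animals.append(
                    AnimalInfo(
                        animal_id=f"R{idx + 1:02d}",
                        diet=diet,
                        predictor=predictor,
                        first_sipper_side="left" if idx % 2 == 0 else "right",
                        cs_plus=("B" if (idx // 2) % 2 == 0 else "A"),
                    )
                )
                idx += 1
    return CohortManifest(animals)


def simulate_cohort(params: SimulationParams) -> tuple[CohortManifest, list[EventLog]]:
    """Simulate the full cohort: for every animal, ``n_sessions`` paired
    control/experimental days (2 logs per session, control first)."""
    manifest = cohort_manifest(params)
    logs: list[EventLog] = []
    for i, animal in enumerate(manifest.animals):
        for s in range(1, params.n_sessions + 1):
            logs.append(simulate_day(params, i, s, "MM", animal_id=animal.animal_id))
            logs.append(simulate_day(params, i, s, "MC", animal_id=animal.animal_id))
    return manifest, logs


# ---------------------------------------------------------------------------
# flavor preference test

def simulate_preference_test(
    params: SimulationParams,
    epoch: str,
    weights: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Simulate the flavor preference test for the whole cohort.

    Per animal and epoch ("pre"/"post"): 10 forced-choice trials (one sipper,
    flavors alternating) then 30 free-choice trials (both sippers). A trial
    ends 30 s after sipper extension or 10 s after first contact, whichever
    is earlier. Licking on each sipper is the Malt cluster process scaled by
    that flavor's preference weight; after conditioning both weights scale
    by ``pref_post_multiplier`` (intake rises for both flavors).

    Returns a tidy frame: animal_id, epoch, trial_index, trial_type, flavor
    (presented flavor, "both" on free trials), licks_A, licks_B.
    """
    if epoch not in ("pre", "post"):
        raise ValueError("epoch must be 'pre' or 'post'")
    if weights is None:
        w = (params.pref_weight_a, params.pref_weight_b)
        if epoch == "post":
            w = (w[0] * params.pref_post_multiplier, w[1] * params.pref_post_multiplier)
    else:
        w = weights
    manifest = cohort_manifest(params)
    rows = []
    for i, animal in enumerate(manifest.animals):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed,
                                   spawn_key=(i, 10_000 + (0 if epoch == "pre" else 1)))
        )
        for trial in range(40):
            forced = trial < 10
            trial_type = "forced" if forced else "free"
            presented = ("A" if trial % 2 == 0 else "B") if forced else "both"
            licks = {"A": 0, "B": 0}
            for flavor, weight in zip(("A", "B"), w):
                if forced and flavor != presented:
                    continue
                if weight <= 0:
                    continue
                latency = rng.exponential(2.0)
                if latency >= 30.0:
                    continue
                avail = min(30.0, latency + 10.0) - latency
                licks[flavor] = len(_cluster_train(rng, avail, params.lam_malt * weight,
                                                   params.mu_malt, params))
            rows.append(
                (animal.animal_id, epoch, trial + 1, trial_type, presented,
                 licks["A"], licks["B"])
            )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "epoch", "trial_index", "trial_type", "flavor",
                 "licks_A", "licks_B"],
    )


# ---------------------------------------------------------------------------
# validation harness

def recover_params(
    logs: list[EventLog], threshold_s: float = 0.5
) -> pd.DataFrame:
    """Estimate the cluster-process parameters from simulated (or real) logs.

    Pooled over animals per (phase, condition): mu_hat = total licks / total
    clusters, lam_hat = clusters per minute of phase time.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for log in logs:
        windows = derive_phase_windows(log)
        for wdw in windows:
            if wdw.active_port is None:
                continue
            licks = log.lick_times(wdw.active_port)
            licks = licks[wdw.contains(licks)]
            sizes = cluster_sizes(licks, threshold_s)
            key = (wdw.label, log.condition)
            rec = acc.setdefault(key, [0.0, 0.0, 0.0])  # licks, clusters, minutes
            rec[0] += float(sizes.sum())
            rec[1] += float(len(sizes))
            rec[2] += wdw.duration_s / 60.0
    rows = []
    for (phase, cond), (licks, clusters, minutes) in sorted(acc.items()):
        rows.append(
            {
                "phase": phase,
                "condition": cond,
                "mu_hat": licks / clusters if clusters else float("nan"),
                "lam_hat": clusters / minutes if minutes else float("nan"),
                "total_licks": licks,
                "total_clusters": clusters,
            }
        )
    return pd.DataFrame(rows)
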