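"""Simulation studies that validate the pipeline end to end.

These routines exercise simulator -> microstructure -> statistics at
cohort scale and return summary numbers: type-I calibration of the
within-subject ANOVA under the null simulator, generative-parameter
recovery, and the regime dissociation (palatability- vs incentive-carried
suppression). They are used by the test suite, the acceptance script and
the analysis drivers alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .microstructure import PHASE1, derive_phase_windows, summarize_phase
from .simulate import SimulationParams, learning_suppression, simulate_day
from .stats import rm_anova_2way_array

__all__ = [
    "phase1_group_array",
    "type1_calibration",
    "null_normalized_ratio",
    "parameter_recovery",
    "regime_dissociation",
]


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds (< 2^31) derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) & 0x7FFFFFFF


def phase1_group_array(
    params: SimulationParams, n_animals: int, metrics: tuple[str, ...] = ("total_licks",)
) -> dict[str, np.ndarray]:
    """Simulate one group of animals and return dense (n, condition, session)
    arrays of phase-1 metrics (condition axis ordered MM, MC).

    This is the fast path the large replicate studies use; it runs the same
    simulate_day -> derive_phase_windows -> summarize_phase chain as the CSV
    pipeline, without materializing tables.
    """
    k = params.n_sessions
    out = {m: np.empty((n_animals, 2, k)) for m in metrics}
    for i in range(n_animals):
        for s in range(1, k + 1):
            for ci, cond in enumerate(("MM", "MC")):
                log = simulate_day(params, i, s, cond)
                w1 = derive_phase_windows(log)[0]
                summ = summarize_phase(log, w1, params.threshold_s)
                for m in metrics:
                    out[m][i, ci, s - 1] = getattr(summ, m)
    return {m: a[:, :, :] for m, a in out.items()}


def type1_calibration(
    n_cohorts: int = 2000,
    n_animals: int = 10,
    n_sessions: int = 8,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the Condition main effect under the null simulator.

    With anc_amplitude = 0 the two conditions' phase-1 processes are
    identical, so the two-way within-subject ANOVA's Condition effect should
    reject at the nominal rate.
    """
    seeds = child_seeds(seed, n_cohorts)
    rej = 0
    for s in seeds:
        params = SimulationParams(seed=int(s), n_sessions=n_sessions, anc_amplitude=0.0)
        y = phase1_group_array(params, n_animals)["total_licks"]
        effects = rm_anova_2way_array(y)
        if effects[0].p < alpha:
            rej += 1
    rate = rej / n_cohorts
    se = (alpha * (1 - alpha) / n_cohorts) ** 0.5
    return {"rate": rate, "n_cohorts": n_cohorts, "binomial_se": se}


def null_normalized_ratio(n_animals: int = 10, seed: int = 0) -> dict:
    """Mean normalized (MC/MM) phase-1 total licks under the null simulator,
    with its standard error; should sit within ~1.96 SE of 1."""
    params = SimulationParams(seed=seed, anc_amplitude=0.0)
    y = phase1_group_array(params, n_animals)["total_licks"]
    ratios = (y[:, 1, :] / y[:, 0, :]).ravel()
    ratios = ratios[np.isfinite(ratios)]
    return {
        "mean": float(ratios.mean()),
        "se": float(ratios.std(ddof=1) / np.sqrt(len(ratios))),
        "n": len(ratios),
    }


def parameter_recovery(n_animals: int = 20, seed: int = 0) -> dict:
    """Recover mu (licks/cluster) and lambda (clusters/min) from a simulated
    cohort, and compare the late-session experimental/control licks-per-cluster
    ratio with its closed-form expectation 1 - A*rho*logistic(s).
    """
    params = SimulationParams(seed=seed)  # defaults: mu 6, lam 8, A 0.4, rho 0.5
    k = params.n_sessions
    licks = np.zeros((n_animals, 2, k))
    clusters = np.zeros((n_animals, 2, k))
    minutes = params.phase1_s / 60.0
    for i in range(n_animals):
        for s in range(1, k + 1):
            for ci, cond in enumerate(("MM", "MC")):
                log = simulate_day(params, i, s, cond)
                w1 = derive_phase_windows(log)[0]
                summ = summarize_phase(log, w1, params.threshold_s)
                licks[i, ci, s - 1] = summ.total_licks
                clusters[i, ci, s - 1] = summ.total_clusters

    mu_hat = licks[:, 0, :].sum() / clusters[:, 0, :].sum()
    lam_hat = clusters[:, 0, :].sum() / (n_animals * k * minutes)

    s_late = k  # last session: learning curve near asymptote
    lpc = licks / np.where(clusters > 0, clusters, np.nan)
    ratio_per_animal = lpc[:, 1, s_late - 1] / lpc[:, 0, s_late - 1]
    ratio_per_animal = ratio_per_animal[np.isfinite(ratio_per_animal)]
    ratio_hat = float(np.mean(ratio_per_animal))
    ratio_se = float(np.std(ratio_per_animal, ddof=1) / np.sqrt(len(ratio_per_animal)))
    supp = float(learning_suppression(params, s_late))
    ratio_expected = 1.0 - supp * params.rho

    return {
        "mu_hat": float(mu_hat),
        "mu_true": params.mu_malt,
        "lam_hat": float(lam_hat),
        "lam_true": params.lam_malt,
        "lpc_ratio_hat": ratio_hat,
        "lpc_ratio_se": ratio_se,
        "lpc_ratio_expected": ratio_expected,
        "n_animals": n_animals,
    }


def regime_dissociation(
    n_cohorts: int = 100,
    n_animals: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection rates of the Condition x Session interaction under the two
    suppression regimes.

    rho = 1 puts all phase-1 suppression into cluster size: the interaction
    should appear in licks per cluster (the contextual-predictor signature).
    rho = 0 puts it all into cluster rate: the interaction should appear in
    total licks but NOT licks per cluster (the flavor-predictor signature).
    """
    seeds = child_seeds(seed, 2 * n_cohorts)
    out = {}
    for ridx, rho in enumerate((1.0, 0.0)):
        hits_lpc = 0
        hits_total = 0
        for c in range(n_cohorts):
            params = SimulationParams(seed=int(seeds[ridx * n_cohorts + c]), rho=rho)
            arrays = phase1_group_array(
                params, n_animals, metrics=("total_licks", "licks_per_cluster")
            )
            p_lpc = rm_anova_2way_array(arrays["licks_per_cluster"])[2].p
            p_tot = rm_anova_2way_array(arrays["total_licks"])[2].p
            hits_lpc += p_lpc < alpha
            hits_total += p_tot < alpha
        out[rho] = {
            "interaction_rate_licks_per_cluster": hits_lpc / n_cohorts,
            "interaction_rate_total_licks": hits_total / n_cohorts,
        }
    return {"rho1": out[1.0], "rho0": out[0.0], "n_cohorts": n_cohorts}
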