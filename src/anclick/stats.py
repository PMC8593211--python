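"""Within-subject statistical battery.

Implements the repeated-measures models the contrast analysis relies on:

* two-way fully within-subject ANOVA, Condition (2) x Session (k), each
  effect tested against its own subject-by-effect interaction;
* three-way mixed ANOVA with Diet and Predictor between subjects and
  Session within, with Greenhouse-Geisser sphericity correction of the
  Session degrees of freedom;
* Bonferroni-corrected per-session paired post-hocs and the derived
  "emergence session" (first session with a corrected significant
  difference);
* classical paired and pooled-variance unpaired t-tests.

All models assume complete balanced designs; incomplete animals are dropped
listwise with a logged count. Sums of squares are partitioned directly from
cell means (balanced designs make Type I/II/III identical), so the
decomposition SS_total = sum of effect and error SS holds to machine
precision and is asserted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer subjects (or subjects per cell) than the model can estimate."""


@dataclass(frozen=True)
class AnovaEffect:
    """One model term: F statistic, (possibly epsilon-corrected) df and p."""

    term: str
    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float | None = None

    def __str__(self) -> str:
        eps = f", eps={self.epsilon:.3f}" if self.epsilon is not None else ""
        return f"{self.term}: F({self.df_num:.4g},{self.df_den:.4g}) = {self.F:.2f}, p = {self.p:.4g}{eps}"


@dataclass(frozen=True)
class PosthocRow:
    session: int
    mean_diff: float
    t: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    n_pairs: int
    testable: bool = True


def effects_frame(effects: list[AnovaEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": e.term,
                "F": e.F,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "p": e.p,
                "epsilon": e.epsilon if e.epsilon is not None else np.nan,
            }
            for e in effects
        ]
    )


def posthoc_frame(rows: list[PosthocRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# helpers

def _f_p(F: float, df1: float, df2: float) -> float:
    return float(sps.f.sf(F, df1, df2))


def _complete_pivot(
    table: pd.DataFrame, dv: str, subject: str, factors: list[str]
) -> tuple[np.ndarray, list[str], list[list]]:
    """Pivot a tidy table to a dense (subject, *factor) array, listwise-deleting
    subjects with any missing cell."""
    levels = [sorted(table[f].unique()) for f in factors]
    wide = table.pivot_table(index=subject, columns=factors, values=dv, aggfunc="mean")
    complete = wide.dropna(axis=0)
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("listwise deletion: dropped %d incomplete subject(s)", dropped)
    n_cells = int(np.prod([len(l) for l in levels]))
    if complete.shape[1] != n_cells:
        missing = n_cells - complete.shape[1]
        raise InsufficientDataError(f"{missing} design cell(s) entirely empty")
    # order columns by factor levels
    if len(factors) == 1:
        complete = complete[levels[0]]
    else:
        complete = complete[pd.MultiIndex.from_product(levels)]
    subjects = list(complete.index)
    y = complete.to_numpy(dtype=float).reshape(len(subjects), *[len(l) for l in levels])
    return y, subjects, levels


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space orthogonal to the mean."""
    h = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(h[:, : k - 1])
    return q.T  # (k-1, k)


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from a k x k covariance matrix
    of the repeated measures.

    epsilon = tr(M)^2 / ((k-1) tr(M^2)) with M the double-centered
    covariance; equals 1 exactly under compound symmetry and for k = 2,
    and is bounded below by 1/(k-1).
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be a square matrix")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    if not np.all(np.isfinite(S)):
        raise ValueError("covariance contains non-finite entries")
    H = np.eye(k) - 1.0 / k
    M = H @ S @ H
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0 or tr <= 0:
        raise ValueError("degenerate covariance: within-subject variance is zero")
    eps = (tr * tr) / ((k - 1) * tr2)
    return float(min(1.0, eps))


# ---------------------------------------------------------------------------
# two-way within-subject ANOVA

def rm_anova_2way_array(
    y: np.ndarray, names: tuple[str, str] = ("Condition", "Session"), gg: bool = False
) -> list[AnovaEffect]:
    """Two-way within-subject ANOVA on a dense (n, a, b) array.

    Each effect is tested against its subject-by-effect interaction
    (univariate mixed-model F ratios). With ``gg=True`` terms with more than
    one numerator df get Greenhouse-Geisser corrected df and p.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected (subjects, factorA, factorB) array")
    n, a, b = y.shape
    if n < 2:
        raise InsufficientDataError("need at least 2 subjects")
    m = y.mean()
    A = y.mean(axis=(0, 2))
    B = y.mean(axis=(0, 1))
    S = y.mean(axis=(1, 2))
    AB = y.mean(axis=0)
    AS = y.mean(axis=2)
    BS = y.mean(axis=1)

    ss_a = n * b * float(((A - m) ** 2).sum())
    ss_b = n * a * float(((B - m) ** 2).sum())
    ss_ab = n * float(((AB - A[:, None] - B[None, :] + m) ** 2).sum())
    ss_s = a * b * float(((S - m) ** 2).sum())
    ss_as = b * float(((AS - S[:, None] - A[None, :] + m) ** 2).sum())
    ss_bs = a * float(((BS - S[:, None] - B[None, :] + m) ** 2).sum())
    ss_tot = float(((y - m) ** 2).sum())
    ss_abs = ss_tot - (ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    # SS decomposition must close (balanced design)
    assert abs(ss_tot - (ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs + ss_abs)) <= 1e-8 * max(1.0, ss_tot)

    terms = [
        (names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), a),
        (names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), b),
        (f"{names[0]} x {names[1]}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), None),
    ]
    out = []
    for term, ss_eff, df1, ss_err, df2, k in terms:
        if ss_err <= 0:
            F = math.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
            out.append(AnovaEffect(term, F, df1, df2, p))
            continue
        F = (ss_eff / df1) / (ss_err / df2)
        eps = None
        d1, d2 = float(df1), float(df2)
        if gg and df1 > 1:
            eps = _term_epsilon(y, term, names)
            d1, d2 = d1 * eps, d2 * eps
        out.append(AnovaEffect(term, float(F), d1, d2, _f_p(F, d1, d2), eps))
    return out


def _term_epsilon(y: np.ndarray, term: str, names: tuple[str, str]) -> float:
    """GG epsilon for one within term of an (n, a, b) layout, from the
    covariance of the orthonormal effect contrasts applied per subject."""
    n, a, b = y.shape
    if term == names[0]:
        scores = y.mean(axis=2)          # (n, a)
        K = _orthonormal_contrast(a)
    elif term == names[1]:
        scores = y.mean(axis=1)          # (n, b)
        K = _orthonormal_contrast(b)
    else:
        scores = y.reshape(n, a * b)
        K = np.kron(_orthonormal_contrast(a), _orthonormal_contrast(b))
    Z = scores @ K.T                     # (n, df)
    Scov = np.cov(Z, rowvar=False)
    Scov = np.atleast_2d(Scov)
    tr = np.trace(Scov)
    tr2 = np.trace(Scov @ Scov)
    if tr2 <= 0:
        return 1.0
    r = Z.shape[1]
    return float(min(1.0, tr * tr / (r * tr2)))


def rm_anova_2way(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "animal_id",
    within: tuple[str, str] = ("condition", "paired_session"),
    names: tuple[str, str] = ("Condition", "Session"),
    gg: bool = False,
) -> list[AnovaEffect]:
    """Tidy-table front end of :func:`rm_anova_2way_array`.

    Subjects missing any (condition, session) cell are dropped listwise with
    a warning; fewer than 2 remaining subjects is an error.
    """
    y, subjects, _ = _complete_pivot(table, dv, subject, list(within))
    if len(subjects) < 2:
        raise InsufficientDataError(f"only {len(subjects)} complete subject(s)")
    return rm_anova_2way_array(y, names=names, gg=gg)


# ---------------------------------------------------------------------------
# three-way mixed ANOVA (Diet x Predictor between, Session within)

def mixed_anova_3way_array(
    y: np.ndarray,
    names: tuple[str, str, str] = ("Diet", "Predictor", "Session"),
    gg: str = "session-main",
) -> list[AnovaEffect]:
    """Mixed ANOVA on a dense (d, p, n, k) array: two 2-level (or more)
    between factors, one k-level within factor, n subjects per between cell.

    Between effects are tested against subjects-within-groups; within
    effects against the Session x subjects-within-groups error. ``gg``
    selects which within terms get Greenhouse-Geisser corrected df:
    ``"never"``, ``"session-main"`` (default) or ``"all-within"``. The
    epsilon estimate (from the pooled within-group covariance of the
    repeated measures) is attached to every within term regardless.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 4:
        raise ValueError("expected (diet, predictor, subject, session) array")
    d, p, n, k = y.shape
    if n < 2:
        raise InsufficientDataError("need at least 2 subjects per between-group cell")
    N = d * p * n
    m = y.mean()

    D = y.mean(axis=(1, 2, 3))
    P = y.mean(axis=(0, 2, 3))
    W = y.mean(axis=(0, 1, 2))
    DP = y.mean(axis=(2, 3))
    DW = y.mean(axis=(1, 2))
    PW = y.mean(axis=(0, 2))
    DPW = y.mean(axis=2)
    subj = y.mean(axis=3)  # (d, p, n) subject means

    ss_d = n * p * k * float(((D - m) ** 2).sum())
    ss_p = n * d * k * float(((P - m) ** 2).sum())
    ss_w = N * float(((W - m) ** 2).sum())
    ss_dp = n * k * float(((DP - D[:, None] - P[None, :] + m) ** 2).sum())
    ss_dw = n * p * float(((DW - D[:, None] - W[None, :] + m) ** 2).sum())
    ss_pw = n * d * float(((PW - P[:, None] - W[None, :] + m) ** 2).sum())
    ss_dpw = n * float(
        (
            (
                DPW
                - DP[:, :, None]
                - DW[:, None, :]
                - PW[None, :, :]
                + D[:, None, None]
                + P[None, :, None]
                + W[None, None, :]
                - m
            )
            ** 2
        ).sum()
    )
    ss_subj = k * float(((subj - DP[:, :, None]) ** 2).sum())  # subjects within groups
    ss_tot = float(((y - m) ** 2).sum())
    ss_wsubj = ss_tot - (ss_d + ss_p + ss_dp + ss_subj + ss_w + ss_dw + ss_pw + ss_dpw)
    ss_wsubj = max(ss_wsubj, 0.0)

    df_subj = N - d * p
    df_wsubj = (k - 1) * df_subj

    # pooled within-group covariance of the k repeated measures
    flat = y.reshape(d * p, n, k)
    pooled = np.zeros((k, k))
    for g in range(d * p):
        c = flat[g] - flat[g].mean(axis=0)
        pooled += c.T @ c
    pooled /= max(N - d * p, 1)
    eps = greenhouse_geisser_epsilon(pooled) if k > 2 else 1.0

    out: list[AnovaEffect] = []

    def add(term, ss_eff, df1, ss_err, df2, within_term=False, correct=False):
        if ss_err <= 0:
            F = math.inf if ss_eff > 0 else 0.0
            out.append(AnovaEffect(term, F, df1, df2, 0.0 if ss_eff > 0 else 1.0,
                                   eps if within_term else None))
            return
        F = (ss_eff / df1) / (ss_err / df2)
        d1, d2 = float(df1), float(df2)
        if correct:
            d1, d2 = d1 * eps, d2 * eps
        out.append(AnovaEffect(term, float(F), d1, d2, _f_p(F, d1, d2),
                               eps if within_term else None))

    gg_main = gg in ("session-main", "all-within")
    gg_all = gg == "all-within"
    nd, np_, nw = names
    add(nd, ss_d, d - 1, ss_subj, df_subj)
    add(np_, ss_p, p - 1, ss_subj, df_subj)
    add(f"{nd} x {np_}", ss_dp, (d - 1) * (p - 1), ss_subj, df_subj)
    add(nw, ss_w, k - 1, ss_wsubj, df_wsubj, within_term=True, correct=gg_main)
    add(f"{nw} x {nd}", ss_dw, (k - 1) * (d - 1), ss_wsubj, df_wsubj, within_term=True, correct=gg_all)
    add(f"{nw} x {np_}", ss_pw, (k - 1) * (p - 1), ss_wsubj, df_wsubj, within_term=True, correct=gg_all)
    add(f"{nw} x {nd} x {np_}", ss_dpw, (k - 1) * (d - 1) * (p - 1), ss_wsubj, df_wsubj,
        within_term=True, correct=gg_all)
    return out


def mixed_anova_3way(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "animal_id",
    between: tuple[str, str] = ("diet", "predictor"),
    within: str = "paired_session",
    names: tuple[str, str, str] = ("Diet", "Predictor", "Session"),
    gg: str = "session-main",
) -> list[AnovaEffect]:
    """Tidy-table front end of :func:`mixed_anova_3way_array`.

    ``table`` must carry one row per (subject, session) with constant
    between-group labels per subject.
    """
    y_flat, subjects, (sess_levels,) = _complete_pivot(table, dv, subject, [within])
    labels = table.drop_duplicates(subset=[subject]).set_index(subject)
    b1_levels = sorted(table[between[0]].unique())
    b2_levels = sorted(table[between[1]].unique())
    cells: dict[tuple, list[np.ndarray]] = {}
    for i, s in enumerate(subjects):
        key = (labels.loc[s, between[0]], labels.loc[s, between[1]])
        cells.setdefault(key, []).append(y_flat[i])
    counts = {key: len(v) for key, v in cells.items()}
    if len(counts) != len(b1_levels) * len(b2_levels):
        raise InsufficientDataError("empty between-group cell")
    if min(counts.values()) < 2:
        raise InsufficientDataError(f"between-group cell with < 2 subjects: {counts}")
    if len(set(counts.values())) != 1:
        raise InsufficientDataError(f"unbalanced between-group cells: {counts}")
    n = next(iter(counts.values()))
    k = y_flat.shape[1]
    y = np.empty((len(b1_levels), len(b2_levels), n, k))
    for (i, b1) in enumerate(b1_levels):
        for (j, b2) in enumerate(b2_levels):
            y[i, j] = np.stack(cells[(b1, b2)])
    return mixed_anova_3way_array(y, names=names, gg=gg)


# ---------------------------------------------------------------------------
# t-tests, post-hocs, emergence

def paired_t(before: np.ndarray, after: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; zero-variance zero-mean differences give
    t = 0, p = 1 by convention."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise ValueError("paired samples must have equal length")
    n = len(before)
    if n < 2:
        raise InsufficientDataError("need at least 2 pairs")
    diff = after - before
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:
            return 0.0, n - 1, 1.0
        return math.copysign(math.inf, diff.mean()), n - 1, 0.0
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def unpaired_t(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test, pooled-variance (Student) by default
    with a Welch option."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(df), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def bonferroni_posthoc(
    table: pd.DataFrame,
    m: int | None = None,
    dv: str = "value",
    subject: str = "animal_id",
    condition: str = "condition",
    session: str = "paired_session",
    control_level: str = "MM",
    alpha: float = 0.05,
) -> list[PosthocRow]:
    """Per-session paired t-tests (experimental minus control within animal)
    with Bonferroni correction over the m sessions of the family.

    p_bonferroni = min(1, m * p_raw); sessions with fewer than 2 complete
    pairs are flagged untestable rather than dropped.
    """
    sessions = sorted(table[session].unique())
    if m is None:
        m = len(sessions)
    rows: list[PosthocRow] = []
    for s in sessions:
        sub = table[table[session] == s]
        wide = sub.pivot_table(index=subject, columns=condition, values=dv, aggfunc="mean").dropna()
        levels = [c for c in wide.columns]
        if len(levels) != 2 or len(wide) < 2:
            rows.append(PosthocRow(int(s), math.nan, math.nan, math.nan, math.nan,
                                   False, len(wide), testable=False))
            continue
        exp_level = [c for c in levels if c != control_level][0]
        ctrl = wide[control_level].to_numpy()
        expv = wide[exp_level].to_numpy()
        t, _, p_raw = paired_t(ctrl, expv)
        p_b = min(1.0, m * p_raw)
        rows.append(
            PosthocRow(
                session=int(s),
                mean_diff=float((expv - ctrl).mean()),
                t=t,
                p_raw=p_raw,
                p_bonferroni=p_b,
                significant=bool(p_b < alpha),
                n_pairs=len(wide),
            )
        )
    return rows


def emergence_session(posthoc: list[PosthocRow]) -> int | None:
    """First session (smallest index) whose Bonferroni-corrected comparison
    is significant; None when no session is."""
    for row in sorted(posthoc, key=lambda r: r.session):
        if row.testable and row.significant:
            return row.session
    return None
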