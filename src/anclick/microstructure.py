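"""Phase windows and lick-microstructure variables.

A test day has two 5-min drinking phases separated by a 20-s inter-phase
interval (IPI) with both sippers retracted. Within a phase, licking is
segmented into clusters: maximal runs of licks with no inter-lick interval
exceeding 500 ms. Cluster size (licks per cluster) indexes palatability
("liking"); cluster count indexes incentive value ("wanting"). Entries to
the port whose sipper is not extended are premature entries, a second
anticipation measure.

All windows are half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ENTRY, EXTEND, LICK, RETRACT, EventLog, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_S = 0.5
DEFAULT_SCHEDULE = (300.0, 20.0, 300.0)  # phase1, IPI, phase2 durations in s

PHASE1, IPI, PHASE2 = "phase1", "IPI", "phase2"

METRIC_NAMES = (
    "total_licks",
    "total_clusters",
    "licks_per_cluster",
    "premature_entries",
    "ipi_entries_port1",
    "ipi_entries_port2",
)


class StructureError(ValueError):
    """Sipper extension/retraction events are unpaired, overlapping or inverted."""


@dataclass(frozen=True)
class PhaseWindow:
    label: str          # phase1 | IPI | phase2
    start_s: float
    end_s: float
    active_port: int | None  # None during the IPI

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"{self.label}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.start_s) & (t < self.end_s)


@dataclass(frozen=True)
class LickCluster:
    start_s: float
    end_s: float
    n_licks: int


@dataclass
class PhaseSummary:
    """Per-phase microstructure variables; licks_per_cluster is NaN (missing),
    never 0, when the phase has no clusters."""

    label: str
    total_licks: int
    total_clusters: int
    licks_per_cluster: float  # NaN when total_clusters == 0
    premature_entries: int
    inactive_port_licks: int = 0  # hardware noise, excluded from totals


def derive_phase_windows(
    log: EventLog, schedule: tuple[float, float, float] = DEFAULT_SCHEDULE
) -> list[PhaseWindow]:
    """Cut the day's three windows from sipper events, or use the fixed schedule.

    If sipper_extend/retract events are present: phase 1 runs from the first
    extension of sipper 1 to its retraction, the IPI from that retraction to
    the extension of sipper 2, and phase 2 from that extension to its
    retraction. Without sipper events the default [0,300), [300,320),
    [320,620) schedule applies.
    """
    ext1 = log.times_of(EXTEND, 1)
    ret1 = log.times_of(RETRACT, 1)
    ext2 = log.times_of(EXTEND, 2)
    ret2 = log.times_of(RETRACT, 2)
    n_sipper = len(ext1) + len(ret1) + len(ext2) + len(ret2)
    if n_sipper == 0:
        d1, dipi, d2 = schedule
        return [
            PhaseWindow(PHASE1, 0.0, d1, active_port=1),
            PhaseWindow(IPI, d1, d1 + dipi, active_port=None),
            PhaseWindow(PHASE2, d1 + dipi, d1 + dipi + d2, active_port=2),
        ]
    if not (len(ext1) == len(ret1) == len(ext2) == len(ret2) == 1):
        raise StructureError(
            f"{log.animal_id} day {log.test_day}: expected exactly one extend/retract "
            f"pair per sipper, got ext1={len(ext1)} ret1={len(ret1)} "
            f"ext2={len(ext2)} ret2={len(ret2)}"
        )
    if not (ext1[0] < ret1[0] <= ext2[0] < ret2[0]):
        raise StructureError(
            f"{log.animal_id} day {log.test_day}: sipper events out of order "
            f"(ext1={ext1[0]}, ret1={ret1[0]}, ext2={ext2[0]}, ret2={ret2[0]})"
        )
    return [
        PhaseWindow(PHASE1, float(ext1[0]), float(ret1[0]), active_port=1),
        PhaseWindow(IPI, float(ret1[0]), float(ext2[0]), active_port=None),
        PhaseWindow(PHASE2, float(ext2[0]), float(ret2[0]), active_port=2),
    ]


def segment_clusters(
    lick_timestamps: np.ndarray, threshold_s: float = DEFAULT_THRESHOLD_S
) -> list[LickCluster]:
    """Split sorted lick times into clusters at inter-lick intervals > threshold.

    The split is strict: a gap exactly equal to ``threshold_s`` stays within
    a cluster ("no inter-lick intervals > 500 ms"). Single licks form
    clusters of size 1.
    """
    t = np.asarray(lick_timestamps, dtype=float)
    if t.ndim != 1:
        raise ValueError("lick_timestamps must be 1-D")
    if len(t) == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("lick_timestamps must be sorted")
    # indices where a NEW cluster starts (gap strictly above threshold)
    breaks = np.flatnonzero(np.diff(t) > threshold_s) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(t)]))
    return [
        LickCluster(start_s=float(t[i]), end_s=float(t[j - 1]), n_licks=int(j - i))
        for i, j in zip(starts, ends)
    ]


def cluster_sizes(
    lick_timestamps: np.ndarray, threshold_s: float = DEFAULT_THRESHOLD_S
) -> np.ndarray:
    """Sizes of the clusters of :func:`segment_clusters`, as an int array."""
    t = np.asarray(lick_timestamps, dtype=float)
    if len(t) == 0:
        return np.array([], dtype=int)
    if np.any(np.diff(t) < 0):
        raise ValueError("lick_timestamps must be sorted")
    breaks = np.flatnonzero(np.diff(t) > threshold_s) + 1
    return np.diff(np.concatenate(([0], breaks, [len(t)])))


def summarize_phase(
    log: EventLog,
    window: PhaseWindow,
    threshold_s: float = DEFAULT_THRESHOLD_S,
    min_cluster_size: int = 1,
) -> PhaseSummary:
    """Microstructure summary of one phase window.

    Licks are attributed to the window's active port; licks at the inactive
    port (hardware noise) are counted separately, excluded from totals, and
    logged. Entries to the non-active port count as premature entries.
    During the IPI (no active port) total_licks is whatever licking is
    recorded inside the window at either port and premature entries are all
    entries (both sippers retracted).
    """
    in_win = window.contains(log.timestamps)
    lick_mask = in_win & (log.kinds == LICK)
    entry_mask = in_win & (log.kinds == ENTRY)

    if window.active_port is None:
        licks = log.timestamps[lick_mask]
        inactive = 0
        premature = int(entry_mask.sum())
    else:
        active = lick_mask & (log.ports == window.active_port)
        licks = log.timestamps[active]
        inactive = int((lick_mask & ~active).sum())
        if inactive:
            logger.warning(
                "%s day %s %s: %d lick(s) at inactive port excluded from totals",
                log.animal_id, log.test_day, window.label, inactive,
            )
        premature = int((entry_mask & (log.ports != window.active_port)).sum())

    sizes = cluster_sizes(licks, threshold_s)
    if min_cluster_size > 1:
        sizes = sizes[sizes >= min_cluster_size]
    total_licks = int(sizes.sum())
    total_clusters = int(len(sizes))
    lpc = float(total_licks) / total_clusters if total_clusters else float("nan")
    if min_cluster_size <= 1:
        assert total_licks == len(licks)  # conservation: sum of cluster sizes
    return PhaseSummary(
        label=window.label,
        total_licks=total_licks,
        total_clusters=total_clusters,
        licks_per_cluster=lpc,
        premature_entries=premature,
        inactive_port_licks=inactive,
    )


def ipi_entries(log: EventLog, ipi: PhaseWindow) -> tuple[int, int]:
    """Port-entry counts (port1, port2) within the inter-phase interval."""
    in_win = ipi.contains(log.timestamps) & (log.kinds == ENTRY)
    return int((in_win & (log.ports == 1)).sum()), int((in_win & (log.ports == 2)).sum())


def residual_licks(log: EventLog, windows: list[PhaseWindow]) -> int:
    """Licks recorded outside every analysis window (reported, never dropped)."""
    lick_mask = log.kinds == LICK
    outside = lick_mask.copy()
    for w in windows:
        outside &= ~w.contains(log.timestamps)
    return int(outside.sum())


def day_metrics(
    log: EventLog,
    threshold_s: float = DEFAULT_THRESHOLD_S,
    schedule: tuple[float, float, float] = DEFAULT_SCHEDULE,
    min_cluster_size: int = 1,
) -> pd.DataFrame:
    """Long-format metric rows for one test day.

    Emits total_licks / total_clusters / licks_per_cluster / premature_entries
    for phase1 and phase2, and ipi_entries_port1 / ipi_entries_port2 for the
    IPI window.
    """
    windows = derive_phase_windows(log, schedule)
    rows = []
    for w in windows:
        if w.label == IPI:
            p1, p2 = ipi_entries(log, w)
            rows.append((IPI, "ipi_entries_port1", float(p1)))
            rows.append((IPI, "ipi_entries_port2", float(p2)))
            continue
        s = summarize_phase(log, w, threshold_s, min_cluster_size)
        rows.append((w.label, "total_licks", float(s.total_licks)))
        rows.append((w.label, "total_clusters", float(s.total_clusters)))
        rows.append((w.label, "licks_per_cluster", s.licks_per_cluster))
        rows.append((w.label, "premature_entries", float(s.premature_entries)))
    out = pd.DataFrame(rows, columns=["phase", "metric_name", "value"])
    out.insert(0, "animal_id", log.animal_id)
    out.insert(1, "paired_session", log.paired_session)
    out.insert(2, "condition", log.condition)
    return out


def metrics_table(
    logs: list[EventLog],
    threshold_s: float = DEFAULT_THRESHOLD_S,
    schedule: tuple[float, float, float] = DEFAULT_SCHEDULE,
    min_cluster_size: int = 1,
) -> pd.DataFrame:
    """Concatenated :func:`day_metrics` over a cohort's EventLogs."""
    if not logs:
        return pd.DataFrame(
            columns=["animal_id", "paired_session", "condition", "phase", "metric_name", "value"]
        )
    return pd.concat(
        [day_metrics(l, threshold_s, schedule, min_cluster_size) for l in logs],
        ignore_index=True,
    )
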