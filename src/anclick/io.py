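"""Reading, validation and writing of the tidy event-log / cohort / metric formats.

The on-disk dialect is deliberately minimal plain CSV:

``cohort.csv``
    columns ``animal_id,diet,predictor,first_sipper_side,cs_plus``
``events.csv``
    columns ``animal_id,test_day,paired_session,condition,kind,port,timestamp_s``
    with ``condition in {MM, MC}`` and
    ``kind in {lick, entry, sipper_extend, sipper_retract}``
``metrics.csv``
    long format ``animal_id,paired_session,condition,phase,metric_name,value``

The deposited raw acquisition format (MED-PC output) is not parsed here;
:func:`read_events` defines the adapter surface a converter should target.
Timestamps are seconds from session start (house light on); all analysis
windows downstream are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# event kind codes (compact int8 representation inside EventLog)
LICK = 0
ENTRY = 1
EXTEND = 2
RETRACT = 3

KIND_NAMES = {LICK: "lick", ENTRY: "entry", EXTEND: "sipper_extend", RETRACT: "sipper_retract"}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}

DIETS = ("FF", "FR")
PREDICTORS = ("context", "flavor")
SIDES = ("left", "right")
CONDITIONS = ("MM", "MC")  # control (Malt-Malt) / experimental (Malt-CM)

EVENT_COLUMNS = ["animal_id", "test_day", "paired_session", "condition", "kind", "port", "timestamp_s"]
COHORT_COLUMNS = ["animal_id", "diet", "predictor", "first_sipper_side", "cs_plus"]
METRIC_COLUMNS = ["animal_id", "paired_session", "condition", "phase", "metric_name", "value"]


class FormatError(ValueError):
    """The file does not match the documented dialect (missing columns, empty file...)."""


class ValidationError(ValueError):
    """The file parses but violates an invariant (bad enum, duplicate id, negative time...)."""


@dataclass(frozen=True)
class AnimalInfo:
    """One cohort-manifest row: identity plus counterbalancing assignment."""

    animal_id: str
    diet: str                 # FF (free-fed) or FR (food-restricted)
    predictor: str            # context or flavor
    first_sipper_side: str    # left or right
    cs_plus: str              # which context/flavor predicts CM
    extra: Mapping[str, str] = field(default_factory=dict)


@dataclass
class CohortManifest:
    """Validated cohort manifest; unknown columns are preserved in ``extra``."""

    animals: list[AnimalInfo]

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.animals]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate animal_id(s): {sorted(dupes)}")
        for a in self.animals:
            if a.diet not in DIETS:
                raise ValidationError(f"animal {a.animal_id}: diet {a.diet!r} not in {DIETS}")
            if a.predictor not in PREDICTORS:
                raise ValidationError(f"animal {a.animal_id}: predictor {a.predictor!r} not in {PREDICTORS}")
            if a.first_sipper_side not in SIDES:
                raise ValidationError(
                    f"animal {a.animal_id}: first_sipper_side {a.first_sipper_side!r} not in {SIDES}"
                )

    def ids(self) -> list[str]:
        return [a.animal_id for a in self.animals]

    def __len__(self) -> int:
        return len(self.animals)

    def __getitem__(self, animal_id: str) -> AnimalInfo:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a
        raise KeyError(animal_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.animals:
            row = {
                "animal_id": a.animal_id,
                "diet": a.diet,
                "predictor": a.predictor,
                "first_sipper_side": a.first_sipper_side,
                "cs_plus": a.cs_plus,
            }
            row.update(a.extra)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class EventLog:
    """All timestamped events of one animal on one test day.

    Events are stored column-wise (numpy arrays) and kept sorted by time;
    ``kinds`` uses the int8 codes LICK/ENTRY/EXTEND/RETRACT.
    """

    animal_id: str
    test_day: int
    paired_session: int
    condition: str  # "MM" (control) or "MC" (experimental)
    timestamps: np.ndarray
    kinds: np.ndarray
    ports: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=np.int8)
        self.ports = np.asarray(self.ports, dtype=np.int8)
        if not (len(self.timestamps) == len(self.kinds) == len(self.ports)):
            raise ValidationError("timestamps/kinds/ports length mismatch")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition {self.condition!r} not in {CONDITIONS}")
        if len(self.timestamps) and self.timestamps.min() < 0:
            raise ValidationError("negative timestamp in EventLog")
        if np.any(np.diff(self.timestamps) < 0):
            order = np.argsort(self.timestamps, kind="stable")
            self.timestamps = self.timestamps[order]
            self.kinds = self.kinds[order]
            self.ports = self.ports[order]

    def __len__(self) -> int:
        return len(self.timestamps)

    def times_of(self, kind: int, port: int | None = None) -> np.ndarray:
        mask = self.kinds == kind
        if port is not None:
            mask &= self.ports == port
        return self.timestamps[mask]

    def lick_times(self, port: int | None = None) -> np.ndarray:
        return self.times_of(LICK, port)

    def entry_times(self, port: int | None = None) -> np.ndarray:
        return self.times_of(ENTRY, port)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "test_day": self.test_day,
                "paired_session": self.paired_session,
                "condition": self.condition,
                "kind": [KIND_NAMES[k] for k in self.kinds],
                "port": self.ports.astype(int),
                "timestamp_s": self.timestamps,
            }
        )


def read_cohort(path: str | Path) -> CohortManifest:
    """Read and validate ``cohort.csv``.

    Unknown columns are preserved per-animal in :attr:`AnimalInfo.extra`.
    Raises :class:`FormatError` for an empty file or missing required column,
    :class:`ValidationError` for enum violations or duplicate ids.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected columns {COHORT_COLUMNS}") from None
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in COHORT_COLUMNS]
    animals = [
        AnimalInfo(
            animal_id=str(r["animal_id"]),
            diet=str(r["diet"]),
            predictor=str(r["predictor"]),
            first_sipper_side=str(r["first_sipper_side"]),
            cs_plus=str(r["cs_plus"]),
            extra={c: r[c] for c in extra_cols},
        )
        for _, r in df.iterrows()
    ]
    if not animals:
        raise FormatError(f"{path}: no animals listed")
    return CohortManifest(animals)


def write_cohort(manifest: CohortManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def read_events_report(
    path: str | Path, manifest: CohortManifest | None = None
) -> tuple[list[EventLog], pd.DataFrame]:
    """Read ``events.csv`` into one EventLog per (animal, test_day).

    Returns ``(logs, rejected)`` where ``rejected`` holds rows referencing
    animals absent from the manifest — input rows are never silently dropped:
    ``len(input) == sum(len(log)) + len(rejected)``.

    Negative timestamps raise :class:`ValidationError` citing the offending
    row; out-of-order timestamps are sorted with a logged warning (hardware
    logs can interleave channels).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected columns {EVENT_COLUMNS}") from None
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    bad_kind = ~df["kind"].isin(KIND_CODES)
    if bad_kind.any():
        row = int(df.index[bad_kind][0]) + 2  # 1-based + header
        raise ValidationError(f"{path} row {row}: kind {df.loc[bad_kind, 'kind'].iloc[0]!r} unknown")
    bad_port = ~df["port"].isin([1, 2])
    if bad_port.any():
        row = int(df.index[bad_port][0]) + 2
        raise ValidationError(f"{path} row {row}: port must be 1 or 2")
    neg = df["timestamp_s"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 2
        raise ValidationError(
            f"{path} row {row}: negative timestamp {df.loc[neg, 'timestamp_s'].iloc[0]}"
        )
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(df.index[bad_cond][0]) + 2
        raise ValidationError(f"{path} row {row}: condition must be one of {CONDITIONS}")

    if manifest is not None:
        known = set(manifest.ids())
        reject_mask = ~df["animal_id"].astype(str).isin(known)
    else:
        reject_mask = pd.Series(False, index=df.index)
    rejected = df[reject_mask].copy()
    if len(rejected):
        logger.warning(
            "%s: rejected %d row(s) for animals absent from the manifest: %s",
            path, len(rejected), sorted(rejected["animal_id"].astype(str).unique()),
        )
    df = df[~reject_mask]

    logs: list[EventLog] = []
    for (animal, day), grp in df.groupby(["animal_id", "test_day"], sort=True):
        cond = grp["condition"].unique()
        if len(cond) > 1:
            raise ValidationError(f"{path}: animal {animal} day {day} mixes conditions {list(cond)}")
        sess = grp["paired_session"].unique()
        if len(sess) > 1:
            raise ValidationError(f"{path}: animal {animal} day {day} mixes sessions {list(sess)}")
        ts = grp["timestamp_s"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            logger.warning("%s: animal %s day %s timestamps out of order; sorting", path, animal, day)
        logs.append(
            EventLog(
                animal_id=str(animal),
                test_day=int(day),
                paired_session=int(sess[0]),
                condition=str(cond[0]),
                timestamps=ts,
                kinds=np.array([KIND_CODES[k] for k in grp["kind"]], dtype=np.int8),
                ports=grp["port"].to_numpy(dtype=np.int8),
            )
        )
    return logs, rejected


def read_events(path: str | Path, manifest: CohortManifest | None = None) -> list[EventLog]:
    """:func:`read_events_report` without the rejected-row report."""
    logs, _ = read_events_report(path, manifest)
    return logs


def write_events(logs: Iterable[EventLog], path: str | Path, header: str | None = None) -> None:
    """Serialize EventLogs to the events.csv dialect (deterministic row order)."""
    frames = [log.to_frame() for log in logs]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=EVENT_COLUMNS)
    )
    df = df.sort_values(["animal_id", "test_day", "timestamp_s"], kind="stable")
    _write_csv(df[EVENT_COLUMNS], path, header)


def validate_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format metric-table schema and the one-record-per-key invariant."""
    missing = [c for c in METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"metric table missing column(s) {missing}")
    key = ["animal_id", "paired_session", "condition", "phase", "metric_name"]
    if table.duplicated(subset=key).any():
        dupes = table[table.duplicated(subset=key, keep=False)][key].drop_duplicates()
        raise ValidationError(f"duplicate metric records:\n{dupes.to_string(index=False)}")
    vals = table["value"].to_numpy(dtype=float)
    if np.any(np.isinf(vals)):
        raise ValidationError("non-finite (inf) metric values; use NaN to flag missing")
    return table


def write_metrics(table: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a validated metric table with deterministic row order.

    Missing values serialize as empty fields and round-trip as NaN.
    """
    table = validate_metrics(table)
    out = table[METRIC_COLUMNS].sort_values(
        ["animal_id", "paired_session", "condition", "phase", "metric_name"], kind="stable"
    )
    _write_csv(out, path, header)


def read_metrics(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected columns {METRIC_COLUMNS}") from None
    return validate_metrics(df)


def _write_csv(df: pd.DataFrame, path: str | Path, header: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
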