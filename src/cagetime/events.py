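"""Event-log data model, CSV dialect, and temporal filters.

An event log is one timestamped row per hardware event from a group-housing
operant cage: corner visits, LED stimulus onsets/offsets, and nose pokes,
each attributed to a chipped animal.  The CSV dialect is deliberately plain —
one event per row, ISO-8601 timestamps, an explicit ``event_kind`` column —
so that vendor exports can be adapted via a column-mapping schema.

Temporal filtering implements the analysis convention used throughout the
package: on each injection day only activity in a fixed evening window
(default 16:00–24:00, half-open) is analysed, and the three injection days
of a condition are pooled into one log.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_KINDS = ("visit_start", "visit_end", "stimulus_on", "stimulus_off", "nosepoke")
SIDES = ("left", "right")

#: canonical column order of the CSV dialect
CANONICAL_COLUMNS = (
    "timestamp",
    "animal_id",
    "corner",
    "event_kind",
    "side",
    "stimulus_duration_s",
)

#: the five stimulus durations (s) of the bisection protocol
DEFAULT_DURATIONS = (1.0, 1.65, 2.5, 3.25, 4.0)

DEFAULT_WINDOW = ("16:00", "24:00")


class SchemaError(ValueError):
    """A mandatory column is missing or the header does not match the schema."""


class ParseError(ValueError):
    """A row of the event log could not be parsed (reported with line numbers)."""


class ConfigurationError(ValueError):
    """The requested filtering/pooling is inconsistent with the injection calendar."""


@dataclass(frozen=True)
class EventRecord:
    """One timestamped hardware event attributed to a chipped animal."""

    timestamp: pd.Timestamp
    animal_id: str
    corner: int
    event_kind: str
    side: str | None = None
    stimulus_duration_s: float | None = None


@dataclass
class SessionLog:
    """An ordered event stream plus the injection calendar.

    Parameters
    ----------
    events
        DataFrame with the canonical columns, sorted by timestamp (stable).
    injections
        Mapping condition label -> list of injection timestamps.  Injection
        *dates* define which calendar days belong to a condition; conditions
        must be disjoint over dates.
    """

    events: pd.DataFrame
    injections: dict[str, list[pd.Timestamp]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.events.columns]
        if missing:
            raise SchemaError(f"event frame missing columns: {missing}")
        self.events = self.events.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        seen: dict[dt.date, str] = {}
        for cond, times in self.injections.items():
            for t in times:
                d = pd.Timestamp(t).date()
                if seen.get(d, cond) != cond:
                    raise ConfigurationError(
                        f"injection date {d} assigned to both {seen[d]!r} and {cond!r}"
                    )
                seen[d] = cond

    def __len__(self) -> int:
        return len(self.events)

    def condition_days(self, condition: str) -> list[dt.date]:
        """Sorted unique injection dates of one condition."""
        if condition not in self.injections:
            raise ConfigurationError(f"unknown condition {condition!r}")
        return sorted({pd.Timestamp(t).date() for t in self.injections[condition]})

    def animal_ids(self) -> list[str]:
        return sorted(self.events["animal_id"].unique())

    def records(self):
        """Iterate the log as :class:`EventRecord` objects."""
        for row in self.events.itertuples(index=False):
            side = row.side if isinstance(row.side, str) and row.side else None
            dur = None if pd.isna(row.stimulus_duration_s) else float(row.stimulus_duration_s)
            yield EventRecord(
                timestamp=row.timestamp,
                animal_id=str(row.animal_id),
                corner=int(row.corner),
                event_kind=row.event_kind,
                side=side,
                stimulus_duration_s=dur,
            )


def _parse_clock(value: str | dt.time) -> float:
    """Clock time -> seconds of day; the string '24:00' maps to 86400."""
    if isinstance(value, dt.time):
        return value.hour * 3600 + value.minute * 60 + value.second
    hh, mm = value.split(":")[:2]
    return int(hh) * 3600 + int(mm) * 60


def validate_log(log: SessionLog, duration_set: tuple[float, ...] | None = None) -> None:
    """Check the structural invariants of an event log.

    Raises :class:`ParseError` if timestamps decrease, a ``visit_end`` has no
    matching open ``visit_start`` for the same animal/corner, or a stimulus
    duration falls outside ``duration_set``.
    """
    ev = log.events
    if len(ev) == 0:
        return
    ts = ev["timestamp"].to_numpy()
    if (np.diff(ts.astype("datetime64[ns]").astype(np.int64)) < 0).any():
        raise ParseError("timestamps are not non-decreasing")
    open_visits: dict[tuple[str, int], int] = {}
    for row in ev.itertuples():
        key = (row.animal_id, int(row.corner))
        if row.event_kind == "visit_start":
            open_visits[key] = open_visits.get(key, 0) + 1
        elif row.event_kind == "visit_end":
            if open_visits.get(key, 0) <= 0:
                raise ParseError(
                    f"visit_end without matching visit_start for {key} at {row.timestamp}"
                )
            open_visits[key] -= 1
    if duration_set is not None:
        durs = ev.loc[ev["event_kind"] == "stimulus_on", "stimulus_duration_s"]
        bad = durs[~durs.round(6).isin(np.round(duration_set, 6))]
        if len(bad):
            stamps = ev.loc[bad.index, "timestamp"].tolist()
            raise ParseError(f"stimulus durations outside configured set at {stamps}")


def read_event_log(
    path,
    schema: dict[str, str] | None = None,
    injections: dict[str, list] | None = None,
    duration_set: tuple[float, ...] | None = None,
) -> SessionLog:
    """Read an event-log CSV into a :class:`SessionLog`.

    Parameters
    ----------
    schema
        Optional mapping from canonical column names to the names used in the
        file, so foreign exports can be adapted without rewriting them.
    injections
        Condition label -> list of injection date-times (parseable strings or
        timestamps), attached to the returned log.
    duration_set
        When given, stimulus durations are validated against this set.
    """
    raw = pd.read_csv(path, dtype={"animal_id": str})
    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in ("timestamp", "animal_id", "event_kind") if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    for optional in ("corner", "side", "stimulus_duration_s"):
        if optional not in raw.columns:
            raw[optional] = 1 if optional == "corner" else np.nan

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ParseError(f"{path}: malformed timestamp on line(s) {lines}")
    raw["timestamp"] = ts
    raw["stimulus_duration_s"] = pd.to_numeric(raw["stimulus_duration_s"], errors="coerce")
    raw["side"] = raw["side"].where(raw["side"].isin(SIDES), None)

    unknown = ~raw["event_kind"].isin(EVENT_KINDS)
    n_skipped = int(unknown.sum())
    if n_skipped:
        logger.warning("%s: skipped %d rows with unknown event_kind", path, n_skipped)
    raw = raw.loc[~unknown]
    raw = raw.sort_values("timestamp", kind="stable").reset_index(drop=True)

    inj = {
        cond: [pd.Timestamp(t) for t in times] for cond, times in (injections or {}).items()
    }
    log = SessionLog(events=raw, injections=inj)
    if duration_set is not None:
        validate_log(log, duration_set)
    logger.info("%s: parsed %d records (%d skipped)", path, len(log), n_skipped)
    return log


def write_event_log(log: SessionLog, path) -> None:
    """Write a log in the canonical CSV dialect (stable, byte-reproducible)."""
    out = log.events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out["stimulus_duration_s"] = out["stimulus_duration_s"].map(
        lambda v: "" if pd.isna(v) else format(float(v), "g")
    )
    out["side"] = out["side"].fillna("")
    out.to_csv(path, index=False)


def _visit_ids(ev: pd.DataFrame) -> np.ndarray:
    """Per-animal running visit index (0 before the first visit_start)."""
    starts = (ev["event_kind"] == "visit_start").astype(int)
    return starts.groupby(ev["animal_id"], sort=False).cumsum().to_numpy()


def filter_analysis_window(
    log: SessionLog,
    condition: str | None = None,
    window_start: str | dt.time = DEFAULT_WINDOW[0],
    window_end: str | dt.time = DEFAULT_WINDOW[1],
    days: list[dt.date] | None = None,
) -> SessionLog:
    """Keep only events in ``[window_start, window_end)`` on injection days.

    Days are the injection dates of ``condition`` unless ``days`` is given
    explicitly.  A visit straddling the window boundary is kept iff its
    ``visit_start`` falls inside the window; non-visit events are judged by
    their own timestamp.  Idempotent.
    """
    ws, we = _parse_clock(window_start), _parse_clock(window_end)
    if not ws < we:
        raise ConfigurationError("window_start must precede window_end")
    if days is None:
        if condition is None:
            raise ConfigurationError("either condition or explicit days required")
        days = log.condition_days(condition)
    day_set = set(days)

    ev = log.events
    if len(ev) == 0:
        return SessionLog(events=ev.copy(), injections=log.injections)
    sod = (
        ev["timestamp"].dt.hour * 3600
        + ev["timestamp"].dt.minute * 60
        + ev["timestamp"].dt.second
        + ev["timestamp"].dt.microsecond / 1e6
    ).to_numpy()
    date = ev["timestamp"].dt.date.to_numpy()
    own_ok = np.array([d in day_set for d in date]) & (sod >= ws) & (sod < we)

    vid = _visit_ids(ev)
    key = pd.MultiIndex.from_arrays([ev["animal_id"], vid])
    is_start = (ev["event_kind"] == "visit_start").to_numpy()
    start_ok = pd.Series(own_ok & is_start, index=key)
    visit_ok = start_ok.groupby(level=[0, 1], sort=False).any()
    in_visit = vid > 0
    keep = np.where(in_visit, visit_ok.reindex(key).to_numpy(), own_ok)
    kept = ev.loc[keep].reset_index(drop=True)
    logger.info(
        "window filter [%s, %s) on %d day(s): %d -> %d records",
        window_start, window_end, len(day_set), len(ev), len(kept),
    )
    return SessionLog(events=kept, injections=log.injections)


def pool_condition_days(
    log: SessionLog,
    condition: str,
    n_days: int = 3,
    window_start: str | dt.time = DEFAULT_WINDOW[0],
    window_end: str | dt.time = DEFAULT_WINDOW[1],
) -> SessionLog:
    """Concatenate the window-filtered logs of the first ``n_days`` injection
    days of ``condition`` into one pooled log."""
    days = log.condition_days(condition)
    if len(days) < n_days:
        raise ConfigurationError(
            f"condition {condition!r} has {len(days)} injection day(s), need {n_days}"
        )
    parts = [
        filter_analysis_window(log, window_start=window_start, window_end=window_end,
                               days=[d]).events
        for d in days[:n_days]
    ]
    pooled = pd.concat(parts, ignore_index=True)
    return SessionLog(events=pooled, injections=log.injections)
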