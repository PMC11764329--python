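"""Segment event streams into trials and classify responses.

Every LED ``stimulus_on`` event opens exactly one trial.  Nose pokes strictly
before stimulus offset are *premature* (they do not stop the trial); the
first poke at or after offset is the *timed* response and fixes the choice
side; a trial with no poke at all is an *omission*.  A trial ends at
``visit_end`` or at the next ``stimulus_on``, whichever comes first.

Correctness is defined only for the two anchor durations (1 s -> short side,
4 s -> long side); intermediate durations are probe stimuli and are never
reinforced.  An incorrectly answered anchor is re-presented under the
repeat-until-correct contingency, tracked via ``repeat_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import DEFAULT_DURATIONS, SessionLog, ParseError, _visit_ids

ANCHOR_SHORT = 1.0
ANCHOR_LONG = 4.0
#: reinforcement mapping: short stimulus -> left bottle, long -> right
DEFAULT_SIDE_MAP = {"short": "left", "long": "right"}

CLASSIFICATIONS = ("timed", "premature_only", "omission")


@dataclass
class Trial:
    """One stimulus presentation with its classified response."""

    animal_id: str
    visit_index: int
    stimulus_duration_s: float
    stimulus_onset: pd.Timestamp
    response_side: str | None
    response_latency_s: float | None
    classification: str
    correct: bool | None
    repeat_index: int
    n_premature_pokes: int
    condition: str | None = None


@dataclass
class ChoiceTable:
    """Per animal x condition counts of long/short timed choices per duration.

    ``p_long[t]`` is NaN (undefined, flagged) when no timed response was
    recorded at duration ``t``.
    """

    animal_id: str
    condition: str
    durations: tuple[float, ...]
    n_long: dict[float, int]
    n_short: dict[float, int]

    @property
    def p_long(self) -> dict[float, float]:
        out = {}
        for t in self.durations:
            n = self.n_long[t] + self.n_short[t]
            out[t] = self.n_long[t] / n if n > 0 else float("nan")
        return out

    def n_timed(self, t: float) -> int:
        return self.n_long[t] + self.n_short[t]

    def defined_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t, p_long, n) arrays restricted to durations with >=1 timed response."""
        p = self.p_long
        ts = np.array([t for t in self.durations if not np.isnan(p[t])])
        return ts, np.array([p[t] for t in ts]), np.array([self.n_timed(t) for t in ts])


@dataclass
class AnimalSummary:
    """Activity totals for one animal in one condition.

    ``total_activity`` counts timed responses only; omissions and premature
    pokes are tallied separately.  Percentages are NaN when there is no timed
    activity (undefined, not zero).
    """

    animal_id: str
    condition: str
    total_activity: int
    omissions: int
    prematures: int

    @property
    def pct_premature(self) -> float:
        return 100.0 * self.prematures / self.total_activity if self.total_activity else float("nan")

    @property
    def pct_omission(self) -> float:
        return 100.0 * self.omissions / self.total_activity if self.total_activity else float("nan")


@dataclass
class LearningCheck:
    """Per-anchor and pooled error percentages against a learning threshold."""

    threshold_pct: float
    per_anchor_error_pct: dict[float, float]
    per_anchor_met: dict[float, bool]
    pooled_error_pct: float
    pooled_met: bool
    overall_met: bool


def _is_anchor(dur: float) -> bool:
    return np.isclose(dur, ANCHOR_SHORT) or np.isclose(dur, ANCHOR_LONG)


def _correct_side(dur: float, side_map: dict[str, str]) -> str | None:
    if np.isclose(dur, ANCHOR_SHORT):
        return side_map["short"]
    if np.isclose(dur, ANCHOR_LONG):
        return side_map["long"]
    return None


def build_trials(
    log: SessionLog,
    durations: tuple[float, ...] = DEFAULT_DURATIONS,
    side_map: dict[str, str] | None = None,
    condition: str | None = None,
) -> list[Trial]:
    """Build one :class:`Trial` per ``stimulus_on`` event in the log.

    Raises :class:`ParseError` if a stimulus carries a duration outside the
    configured set, listing the offending timestamps.
    """
    side_map = side_map or DEFAULT_SIDE_MAP
    ev = log.events
    if len(ev) == 0:
        return []
    stim = ev.loc[ev["event_kind"] == "stimulus_on", "stimulus_duration_s"]
    bad = stim[~stim.round(6).isin(np.round(durations, 6))]
    if len(bad):
        stamps = ev.loc[bad.index, "timestamp"].tolist()
        raise ParseError(f"stimulus_on with unknown duration at {stamps}")

    vid = _visit_ids(ev)
    order = np.lexsort((np.arange(len(ev)), vid, ev["animal_id"].to_numpy()))
    trials: list[Trial] = []

    # state for the currently open trial of the animal being scanned
    cur: dict | None = None
    prev_in_visit: Trial | None = None
    cur_key: tuple[str, int] | None = None

    def close() -> None:
        nonlocal cur, prev_in_visit
        if cur is None:
            return
        onset_ns = cur["onset_ns"]
        dur = cur["dur"]
        if cur["timed_ns"] is not None:
            latency = (cur["timed_ns"] - onset_ns) / 1e9
            side = cur["timed_side"]
            cls = "timed"
        elif cur["n_premature"] > 0:
            latency, side, cls = None, None, "premature_only"
        else:
            latency, side, cls = None, None, "omission"
        corr_side = _correct_side(dur, side_map)
        correct = None if corr_side is None or side is None else side == corr_side
        repeat = 0
        if (
            prev_in_visit is not None
            and _is_anchor(dur)
            and np.isclose(prev_in_visit.stimulus_duration_s, dur)
            and prev_in_visit.classification == "timed"
            and prev_in_visit.correct is False
        ):
            repeat = prev_in_visit.repeat_index + 1
        trial = Trial(
            animal_id=cur["animal"],
            visit_index=cur["visit"],
            stimulus_duration_s=dur,
            stimulus_onset=pd.Timestamp(onset_ns),
            response_side=side,
            response_latency_s=latency,
            classification=cls,
            correct=correct,
            repeat_index=repeat,
            n_premature_pokes=cur["n_premature"],
            condition=condition,
        )
        trials.append(trial)
        prev_in_visit = trial
        cur = None

    ts_ns = ev["timestamp"].astype("datetime64[ns]").to_numpy().astype(np.int64)
    kinds = ev["event_kind"].to_numpy()
    animals = ev["animal_id"].to_numpy()
    sides = ev["side"].to_numpy()
    durs = ev["stimulus_duration_s"].to_numpy()

    for i in order:
        key = (animals[i], int(vid[i]))
        if key != cur_key:
            close()
            prev_in_visit = None
            cur_key = key
        kind = kinds[i]
        t = int(ts_ns[i])
        if kind == "stimulus_on":
            close()
            cur = {
                "animal": animals[i],
                "visit": int(vid[i]),
                "onset_ns": t,
                "dur": float(durs[i]),
                "offset_ns": t + int(float(durs[i]) * 1e9),
                "timed_ns": None,
                "timed_side": None,
                "n_premature": 0,
            }
        elif kind == "stimulus_off":
            if cur is not None:
                cur["offset_ns"] = t
        elif kind == "nosepoke":
            if cur is None:
                continue  # poke outside any trial (e.g. before first stimulus)
            if t < cur["offset_ns"]:
                cur["n_premature"] += 1
            elif cur["timed_ns"] is None:
                cur["timed_ns"] = t
                cur["timed_side"] = sides[i]
        elif kind == "visit_end":
            close()
    close()
    return trials


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """Tidy per-trial table for export and inspection."""
    return pd.DataFrame(
        {
            "animal_id": [t.animal_id for t in trials],
            "condition": [t.condition for t in trials],
            "visit_index": [t.visit_index for t in trials],
            "stimulus_duration_s": [t.stimulus_duration_s for t in trials],
            "stimulus_onset": [t.stimulus_onset for t in trials],
            "response_side": [t.response_side for t in trials],
            "response_latency_s": [t.response_latency_s for t in trials],
            "classification": [t.classification for t in trials],
            "correct": [t.correct for t in trials],
            "repeat_index": [t.repeat_index for t in trials],
            "n_premature_pokes": [t.n_premature_pokes for t in trials],
        }
    )


def build_choice_table(
    trials: list[Trial],
    condition: str,
    durations: tuple[float, ...] = DEFAULT_DURATIONS,
    side_map: dict[str, str] | None = None,
    include_repeats: bool = True,
) -> ChoiceTable:
    """Count long/short timed choices per duration for one animal.

    Repeat presentations are included by default; ``include_repeats=False``
    restricts to first presentations for sensitivity analysis.
    """
    side_map = side_map or DEFAULT_SIDE_MAP
    animals = {t.animal_id for t in trials}
    if len(animals) > 1:
        raise ValueError(f"choice table expects one animal, got {sorted(animals)}")
    long_side = side_map["long"]
    n_long = {float(t): 0 for t in durations}
    n_short = {float(t): 0 for t in durations}
    for tr in trials:
        if tr.classification != "timed":
            continue
        if not include_repeats and tr.repeat_index > 0:
            continue
        key = float(tr.stimulus_duration_s)
        if tr.response_side == long_side:
            n_long[key] += 1
        else:
            n_short[key] += 1
    animal = animals.pop() if animals else ""
    return ChoiceTable(
        animal_id=animal,
        condition=condition,
        durations=tuple(float(t) for t in durations),
        n_long=n_long,
        n_short=n_short,
    )


def summarize_activity(trials: list[Trial], condition: str = "") -> AnimalSummary:
    """Activity totals: timed responses, omissions, premature pokes."""
    animals = {t.animal_id for t in trials}
    if len(animals) > 1:
        raise ValueError(f"summary expects one animal, got {sorted(animals)}")
    return AnimalSummary(
        animal_id=animals.pop() if animals else "",
        condition=condition,
        total_activity=sum(t.classification == "timed" for t in trials),
        omissions=sum(t.classification == "omission" for t in trials),
        prematures=sum(t.n_premature_pokes for t in trials),
    )


def check_learning_criterion(
    trials: list[Trial],
    threshold_pct: float = 20.0,
    side_map: dict[str, str] | None = None,
) -> LearningCheck:
    """Error percentage at each anchor and pooled, against the threshold.

    Only timed anchor trials enter; an anchor with no timed trials yields a
    NaN error percentage and fails the criterion (undefined, flagged).  The
    pooled variant mirrors the early cohorts' criterion that did not separate
    the two anchors.
    """
    per_err: dict[float, float] = {}
    per_met: dict[float, bool] = {}
    total_wrong = total = 0
    for anchor in (ANCHOR_SHORT, ANCHOR_LONG):
        rel = [
            t for t in trials
            if t.classification == "timed" and np.isclose(t.stimulus_duration_s, anchor)
        ]
        n = len(rel)
        wrong = sum(not t.correct for t in rel)
        err = 100.0 * wrong / n if n else float("nan")
        per_err[anchor] = err
        per_met[anchor] = bool(n and err <= threshold_pct)
        total_wrong += wrong
        total += n
    pooled = 100.0 * total_wrong / total if total else float("nan")
    pooled_met = bool(total and pooled <= threshold_pct)
    return LearningCheck(
        threshold_pct=threshold_pct,
        per_anchor_error_pct=per_err,
        per_anchor_met=per_met,
        pooled_error_pct=pooled,
        pooled_met=pooled_met,
        overall_met=all(per_met.values()),
    )
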