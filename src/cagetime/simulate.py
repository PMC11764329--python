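"""Synthetic event-log generator for a virtual bisection-task cohort.

The generator emits the same CSV event dialect the analysis consumes, so the
whole pipeline is testable without hardware data.  Its defaults encode the
study conditions of a group-housed rat cohort: five stimulus durations
{1, 1.65, 2.5, 3.25, 4} s each presented with probability 0.2, visits as a
Poisson stream inside the 16:00-24:00 evening window on three injection days
per condition, repeat-until-correct at the two anchor durations, omission
and premature events at their observed rates, and between-animal
heterogeneity of the true psychometric parameters drawn from truncated
normals.  The drug condition is modelled as a pure shift of the bisection
point plus an independent multiplicative drop of the visit rate.

Every generated log is accompanied by a ground-truth table (the parameters
actually drawn per animal and condition) for parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .events import DEFAULT_DURATIONS, DEFAULT_WINDOW, SessionLog, _parse_clock
from .psychometrics import psychometric_model
from .trials import ANCHOR_LONG, ANCHOR_SHORT, ChoiceTable, DEFAULT_SIDE_MAP


@dataclass
class SimulationConfig:
    """Ground truth and protocol parameters of the virtual cohort.

    Rate and effect defaults correspond to a saline total activity of about
    220 timed responses per animal over three 8-h windows, a drug condition
    with roughly half that activity, omissions at ~14% and premature pokes
    at ~20% of timed activity, and a drug-induced bisection-point shift of
    +0.24 s against a between-animal sd of 0.55 s.
    """

    n_animals: int = 22
    durations: tuple[float, ...] = DEFAULT_DURATIONS
    presentation_prob: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    conditions: tuple[str, str] = ("saline", "clomipramine")

    # between-animal ground truth (saline), s
    d50_mean: float = 2.18
    d50_sd: float = 0.55
    eps_mean: float = 0.36
    eps_sd: float = 0.12
    eps_min: float = 0.05

    # drug effect: pure D50 shift (s) + activity drop
    d50_shift_mean: float = 0.24
    d50_shift_sd: float = 0.32
    drug_activity_factor: float = 0.52

    # behavioural rates
    visit_rate: float = 11.0          # visits/hour in the analysis window
    visit_rate_cv: float = 0.4        # between-animal lognormal CV of the rate
    visit_rate_floor: float = 0.35    # lower bound on the per-animal rate multiplier
    omission_prob: float = 0.14       # per stimulus presentation
    premature_prob: float = 0.20      # extra early poke per presentation
    repeat_on_error: bool = True
    max_repeats: int = 25
    latency_mean_s: float = 0.5       # exponential tail beyond stimulus offset
    stimulus_jitter_s: float = 0.1    # +/- jitter on logged stimulus_off

    # calendar
    window: tuple[str, str] = DEFAULT_WINDOW
    n_days_per_condition: int = 3
    start_date: str = "2024-03-01"
    visit_schedule: str = "poisson"   # "poisson" | "regular" (dense runs)
    corners: tuple[int, ...] = (1, 2, 3)
    side_map: dict = field(default_factory=lambda: dict(DEFAULT_SIDE_MAP))

    def __post_init__(self) -> None:
        p = np.asarray(self.presentation_prob, dtype=float)
        if len(p) != len(self.durations):
            raise ValueError("presentation_prob must match durations in length")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"presentation probabilities sum to {p.sum()}, not 1")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("presentation probabilities must lie in [0, 1]")
        for name in ("d50_sd", "eps_sd", "d50_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("omission_prob", "premature_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.visit_schedule not in ("poisson", "regular"):
            raise ValueError(f"unknown visit_schedule {self.visit_schedule!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("durations", "presentation_prob", "conditions", "window", "corners"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def injection_calendar(config: SimulationConfig) -> dict[str, list[pd.Timestamp]]:
    """Injection timestamps: consecutive saline days, then drug every other day."""
    d0 = pd.Timestamp(config.start_date)
    sal, drug = config.conditions
    n = config.n_days_per_condition
    cal = {
        sal: [d0 + pd.Timedelta(days=i) + pd.Timedelta(hours=15, minutes=40)
              for i in range(n)],
        drug: [d0 + pd.Timedelta(days=n + 1 + 2 * i) + pd.Timedelta(hours=15, minutes=40)
               for i in range(n)],
    }
    return cal


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal draw truncated below at ``lo`` by redrawing."""
    if sd == 0:
        return max(mean, lo)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    return lo + abs(rng.normal(0, sd))  # pathological config; keep going


def draw_ground_truth(config: SimulationConfig, rng: np.random.Generator,
                      animal_ids: list[str]) -> pd.DataFrame:
    """Per animal x condition true parameters and behavioural rates."""
    sal, drug = config.conditions
    if config.visit_rate_cv > 0:
        # lognormal with unit mean so the cohort-average rate stays visit_rate
        sigma = float(np.sqrt(np.log1p(config.visit_rate_cv**2)))
    rows = []
    for animal in animal_ids:
        d50 = rng.normal(config.d50_mean, config.d50_sd) if config.d50_sd else config.d50_mean
        eps = _truncnorm(rng, config.eps_mean, config.eps_sd, config.eps_min)
        shift = (rng.normal(config.d50_shift_mean, config.d50_shift_sd)
                 if config.d50_shift_sd else config.d50_shift_mean)
        rate = config.visit_rate
        if config.visit_rate_cv > 0:
            rate *= max(float(rng.lognormal(-sigma**2 / 2, sigma)),
                        config.visit_rate_floor)
        rows.append(dict(animal_id=animal, condition=sal, d50=d50, epsilon=eps,
                         visit_rate=rate,
                         omission_prob=config.omission_prob,
                         premature_prob=config.premature_prob))
        rows.append(dict(animal_id=animal, condition=drug, d50=d50 + shift, epsilon=eps,
                         visit_rate=rate * config.drug_activity_factor,
                         omission_prob=config.omission_prob,
                         premature_prob=config.premature_prob))
    return pd.DataFrame(rows)


def _visit_starts(rng: np.random.Generator, rate_per_hour: float, window_s: float,
                  schedule: str) -> np.ndarray:
    hours = window_s / 3600.0
    if schedule == "regular":
        n = int(round(rate_per_hour * hours))
        return (np.arange(n) + 0.5) * (window_s / max(n, 1))
    n = rng.poisson(rate_per_hour * hours)
    return np.sort(rng.uniform(0.0, window_s, size=n))


def _simulate_visit(
    rng: np.random.Generator,
    events: list,
    animal: str,
    corner: int,
    t0: float,
    config: SimulationConfig,
    d50: float,
    eps: float,
    omission_p: float,
    premature_p: float,
) -> float:
    """Emit one visit's events starting at absolute second ``t0``; returns end time."""
    durations = np.asarray(config.durations)
    probs = np.asarray(config.presentation_prob)
    long_side, short_side = config.side_map["long"], config.side_map["short"]

    events.append((t0, animal, corner, "visit_start", None, None))
    cursor = t0 + 0.2
    dur = float(rng.choice(durations, p=probs))
    n_rep = 0
    last = cursor
    while True:
        on_t = cursor
        events.append((on_t, animal, corner, "stimulus_on", None, dur))
        jitter = rng.uniform(-config.stimulus_jitter_s, config.stimulus_jitter_s)
        off_t = on_t + dur + jitter
        events.append((off_t, animal, corner, "stimulus_off", None, None))
        last = off_t
        if rng.random() < premature_p:
            pk = on_t + rng.uniform(0.05, max(dur - 0.05, 0.06))
            side = long_side if rng.random() < 0.5 else short_side
            events.append((pk, animal, corner, "nosepoke", side, None))
        if rng.random() < omission_p:
            side = None  # omission: chain stops, no timed poke
        else:
            poke_t = off_t + 0.01 + rng.exponential(config.latency_mean_s)
            p_long = float(psychometric_model(dur, d50, eps))
            side = long_side if rng.random() < p_long else short_side
            events.append((poke_t, animal, corner, "nosepoke", side, None))
            last = poke_t
        is_anchor = np.isclose(dur, ANCHOR_SHORT) or np.isclose(dur, ANCHOR_LONG)
        correct_side = short_side if np.isclose(dur, ANCHOR_SHORT) else long_side
        if (
            config.repeat_on_error
            and is_anchor
            and side is not None
            and side != correct_side
            and n_rep < config.max_repeats
        ):
            n_rep += 1
            cursor = last + 0.5
            continue
        break
    end = last + 0.4
    events.append((end, animal, corner, "visit_end", None, None))
    return end


def _animal_condition_events(
    rng: np.random.Generator,
    events: list,
    animal: str,
    config: SimulationConfig,
    truth_row: pd.Series,
    day_bases: list[float],
    window_s: float,
) -> None:
    for base in day_bases:
        starts = _visit_starts(rng, truth_row["visit_rate"], window_s,
                               config.visit_schedule)
        prev_end = -np.inf
        for s in starts:
            t0 = max(base + s, prev_end + 0.3)
            if t0 - base >= window_s:
                break  # visit pushed past the window; dropped
            corner = int(rng.choice(np.asarray(config.corners)))
            prev_end = _simulate_visit(
                rng, events, animal, corner, t0, config,
                d50=truth_row["d50"], eps=truth_row["epsilon"],
                omission_p=truth_row["omission_prob"],
                premature_p=truth_row["premature_prob"],
            )


def _events_to_frame(events: list) -> pd.DataFrame:
    df = pd.DataFrame(
        events,
        columns=["t", "animal_id", "corner", "event_kind", "side", "stimulus_duration_s"],
    )
    df["timestamp"] = pd.to_datetime((df["t"] * 1e6).round().astype(np.int64), unit="us")
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return df[["timestamp", "animal_id", "corner", "event_kind", "side",
               "stimulus_duration_s"]]


def simulate_cohort(
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    ground_truth: pd.DataFrame | None = None,
) -> tuple[SessionLog, pd.DataFrame]:
    """Simulate the full cohort across both conditions.

    Returns the event log (with its injection calendar) and the ground-truth
    table.  A pre-drawn ``ground_truth`` frame may be supplied to pin
    per-animal parameters (e.g. for degenerate constructions).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    animal_ids = [f"rat{i + 1:02d}" for i in range(config.n_animals)]
    if ground_truth is None:
        ground_truth = draw_ground_truth(config, rng, animal_ids)
    cal = injection_calendar(config)
    ws = _parse_clock(config.window[0])
    window_s = _parse_clock(config.window[1]) - ws

    events: list = []
    for animal in ground_truth["animal_id"].unique():
        for cond in config.conditions:
            row = ground_truth.query("animal_id == @animal and condition == @cond")
            if row.empty:
                continue
            day_bases = [t.normalize().timestamp() + ws for t in cal[cond]]
            _animal_condition_events(rng, events, animal, config, row.iloc[0],
                                     day_bases, window_s)
    log = SessionLog(events=_events_to_frame(events), injections=cal)
    return log, ground_truth


def make_degenerate_animal(
    config: SimulationConfig,
    mode: str,
    animal_id: str = "deg01",
    seed: int | np.random.Generator = 0,
) -> tuple[SessionLog, pd.DataFrame]:
    """One constructed pathological animal.

    ``low_activity``: visit rate so low that an anchor duration gathers
    fewer than 10 timed responses.  ``one_sided``: responds "long" at every
    duration (saturated curve, non-identifiable fit).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "low_activity":
        d50, eps, rate = config.d50_mean, config.eps_mean, 0.25
    elif mode == "one_sided":
        d50, eps, rate = -6.0, config.eps_mean, config.visit_rate
    else:
        raise ValueError(f"unknown degenerate mode {mode!r}")
    sal, drug = config.conditions
    rows = []
    for cond, factor in ((sal, 1.0), (drug, config.drug_activity_factor)):
        rows.append(dict(animal_id=animal_id, condition=cond, d50=d50, epsilon=eps,
                         visit_rate=rate * factor,
                         omission_prob=config.omission_prob,
                         premature_prob=config.premature_prob))
    truth = pd.DataFrame(rows)
    sub = dataclasses.replace(config, n_animals=1)
    return simulate_cohort(sub, rng, ground_truth=truth)


def combine_logs(logs: list[SessionLog]) -> SessionLog:
    """Merge logs that share an injection calendar (e.g. cohort + degenerates)."""
    events = pd.concat([l.events for l in logs], ignore_index=True)
    events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return SessionLog(events=events, injections=logs[0].injections)


def simulate_choice_counts(
    d50: float,
    epsilon: float,
    n_per_duration: int,
    seed: int | np.random.Generator = 0,
    durations: tuple[float, ...] = DEFAULT_DURATIONS,
    animal_id: str = "sim",
    condition: str = "sim",
) -> ChoiceTable:
    """Trial-level shortcut: binomial choice counts straight from the true curve.

    Bypasses the event stream for fast parameter sweeps; the event-level
    generator remains the reference path for end-to-end tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_long, n_short = {}, {}
    for t in durations:
        p = float(psychometric_model(t, d50, epsilon))
        k = int(rng.binomial(n_per_duration, p))
        n_long[float(t)] = k
        n_short[float(t)] = n_per_duration - k
    return ChoiceTable(animal_id=animal_id, condition=condition,
                       durations=tuple(float(t) for t in durations),
                       n_long=n_long, n_short=n_short)
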