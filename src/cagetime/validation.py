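"""Calibration and parameter-recovery studies of the pipeline.

These helpers run the package against data it generated itself, where the
truth is known: a sweep verifying that the fitted curve sits at P = 0.5 at
its point of maximum derivative, a check of the stimulus presentation
schedule, and dense end-to-end recovery of the bisection point.  They back
both the test suite and the standalone analysis scripts.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .events import pool_condition_days, read_event_log, write_event_log
from .psychometrics import PsychometricFit, fit_psychometric
from .simulate import SimulationConfig, simulate_choice_counts, simulate_cohort
from .trials import build_choice_table, build_trials


@dataclass
class SweepResult:
    fits: list[PsychometricFit]
    max_midpoint_deviation: float
    n_animals: int


def sweep_midpoint_deviation(
    n_animals: int = 100,
    d50_range: tuple[float, float] = (1.3, 3.6),
    eps_range: tuple[float, float] = (0.2, 1.4),
    n_per_duration: int = 200,
    seed: int = 0,
) -> SweepResult:
    """Fit a sweep of synthetic animals spanning the plausible parameter box
    and report the worst |P(t_at_max_slope) - 0.5| over the converged fits.

    By construction of the probit model this deviation is zero whenever the
    fitted D50 lies inside the slope domain; the sweep verifies that the
    full fit -> derivative-maximisation chain preserves it numerically.
    """
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_animals):
        d50 = rng.uniform(*d50_range)
        eps = rng.uniform(*eps_range)
        table = simulate_choice_counts(d50, eps, n_per_duration, rng)
        fits.append(fit_psychometric(table))
    devs = [f.midpoint_deviation for f in fits if f.converged]
    return SweepResult(fits=fits, max_midpoint_deviation=float(np.max(devs)),
                       n_animals=n_animals)


@dataclass
class ScheduleResult:
    shares_pct: dict[float, float]
    n_trials: int
    worst_duration: float
    worst_share_pct: float


def presentation_shares(
    n_trials: int = 10_000,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> ScheduleResult:
    """Empirical presentation percentage per duration in a simulated
    experimental phase, counting first presentations (the schedule's own
    draws, not error-driven repeats).

    ``worst_share_pct`` is the share of the duration furthest from the
    nominal 20%.
    """
    if config is None:
        # one dense virtual animal; regular visit stream to reach n_trials
        rate = n_trials / (3 * 8.0) * 1.05
        config = SimulationConfig(n_animals=1, visit_rate=rate, visit_rate_cv=0.0,
                                  visit_schedule="regular",
                                  drug_activity_factor=0.005)
    log, _ = simulate_cohort(config, seed)
    pooled = pool_condition_days(log, config.conditions[0],
                                 n_days=config.n_days_per_condition,
                                 window_start=config.window[0],
                                 window_end=config.window[1])
    trials = [t for t in build_trials(pooled, durations=config.durations)
              if t.repeat_index == 0]
    n = len(trials)
    shares = {}
    for d in config.durations:
        k = sum(np.isclose(t.stimulus_duration_s, d) for t in trials)
        shares[float(d)] = 100.0 * k / n
    nominal = 100.0 / len(config.durations)
    worst = max(shares, key=lambda d: abs(shares[d] - nominal))
    return ScheduleResult(shares_pct=shares, n_trials=n, worst_duration=worst,
                          worst_share_pct=shares[worst])


@dataclass
class RecoveryResult:
    fit: PsychometricFit
    true_d50: float
    true_epsilon: float
    n_per_duration: int
    min_timed_per_duration: int


def dense_d50_recovery(
    true_d50: float,
    true_epsilon: float = 0.36,
    n_per_duration: int = 10_000,
    seed: int = 0,
    workdir: str | None = None,
) -> RecoveryResult:
    """End-to-end bisection-point recovery on dense synthetic data.

    One virtual animal with fixed true parameters generates about
    ``n_per_duration`` presentations per duration (25 virtual injection
    days, evenly spaced visits).  The log is serialised to CSV, read back,
    window-filtered and pooled, classified into trials, tabulated, and fit
    by nonlinear least squares — the exact production path.
    """
    n_days = 25
    rate = n_per_duration * 5 / (n_days * 8.0) * 1.02
    config = SimulationConfig(
        n_animals=1, d50_mean=true_d50, d50_sd=0.0,
        eps_mean=true_epsilon, eps_sd=0.0,
        d50_shift_mean=0.0, d50_shift_sd=0.0,
        visit_rate=rate, visit_rate_cv=0.0, visit_schedule="regular",
        n_days_per_condition=n_days, drug_activity_factor=0.002,
    )
    log, _ = simulate_cohort(config, seed)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        path = Path(tmp) / "events.csv"
        write_event_log(log, path)
        log = read_event_log(path, injections={
            c: list(log.injections[c]) for c in log.injections})
    cond = config.conditions[0]
    pooled = pool_condition_days(log, cond, n_days=n_days,
                                 window_start=config.window[0],
                                 window_end=config.window[1])
    trials = build_trials(pooled, durations=config.durations, condition=cond)
    table = build_choice_table(trials, cond, durations=config.durations)
    fit = fit_psychometric(table)
    min_timed = min(table.n_timed(t) for t in table.durations)
    return RecoveryResult(fit=fit, true_d50=true_d50, true_epsilon=true_epsilon,
                          n_per_duration=n_per_duration,
                          min_timed_per_duration=min_timed)
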