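import numpy as np
import pandas as pd
import pytest

from cagetime.events import SessionLog
from cagetime.pipeline import RunConfig, run_pipeline
from cagetime.simulate import SimulationConfig


def make_log(rows, injections=None):
    """Build a SessionLog from (timestamp, animal, corner, kind, side, dur) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["timestamp", "animal_id", "corner", "event_kind", "side",
                 "stimulus_duration_s"],
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    inj = {c: [pd.Timestamp(t) for t in ts] for c, ts in (injections or {}).items()}
    return SessionLog(events=df, injections=inj)


def visit_rows(animal, start, dur, pokes, corner=1, with_off=True):
    """One visit: stimulus at start+0.2s, pokes as (offset_s_from_onset, side)."""
    t0 = pd.Timestamp(start)
    on = t0 + pd.Timedelta(seconds=0.2)
    rows = [(t0, animal, corner, "visit_start", None, None),
            (on, animal, corner, "stimulus_on", None, dur)]
    if with_off:
        rows.append((on + pd.Timedelta(seconds=dur), animal, corner,
                     "stimulus_off", None, None))
    last = on + pd.Timedelta(seconds=dur)
    for off_s, side in pokes:
        t = on + pd.Timedelta(seconds=off_s)
        rows.append((t, animal, corner, "nosepoke", side, None))
        last = max(last, t)
    rows.append((last + pd.Timedelta(seconds=0.5), animal, corner,
                 "visit_end", None, None))
    return sorted(rows, key=lambda r: r[0])


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-animal simulated cohort, reused across tests (read-only)."""
    cfg = SimulationConfig(n_animals=4)
    from cagetime.simulate import simulate_cohort

    log, truth = simulate_cohort(cfg, seed=42)
    return cfg, log, truth


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full pipeline run on the constructed 25-animal cohort (22 normal +
    2 low-activity + 1 one-sided), fixed seed."""
    out = tmp_path_factory.mktemp("study")
    cfg = RunConfig(sim=SimulationConfig(n_animals=22),
                    n_degenerate_low_activity=2, n_degenerate_one_sided=1,
                    seed=0, outdir=str(out))
    return run_pipeline(cfg)
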