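"""Classify the cohort's events into trials, build per-animal choice tables,
fit the probit psychometric function per animal and condition, and apply the
exclusion rules.  Writes trials, choice tables, fits, activity summaries and
the exclusion report to results/; the cohort of 25 is expected to reduce to
22 analyzable animals.
"""

from pathlib import Path

import pandas as pd

from cagetime.events import pool_condition_days, read_event_log
from cagetime.psychometrics import apply_exclusions, fit_psychometric
from cagetime.simulate import SimulationConfig, injection_calendar
from cagetime.trials import (build_choice_table, build_trials, summarize_activity,
                             trials_to_frame)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = SimulationConfig.from_yaml(ROOT / "cohort" / "sim_config.yaml")
    log = read_event_log(ROOT / "cohort" / "events.csv",
                         injections=injection_calendar(config),
                         duration_set=config.durations)

    all_trials, tables, fits, summaries = [], {}, {}, {}
    for cond in config.conditions:
        pooled = pool_condition_days(log, cond, n_days=config.n_days_per_condition,
                                     window_start=config.window[0],
                                     window_end=config.window[1])
        trials = build_trials(pooled, durations=config.durations, condition=cond)
        all_trials.extend(trials)
        by_animal: dict[str, list] = {}
        for t in trials:
            by_animal.setdefault(t.animal_id, []).append(t)
        for animal, ts in sorted(by_animal.items()):
            table = build_choice_table(ts, cond, durations=config.durations)
            tables.setdefault(animal, {})[cond] = table
            fits.setdefault(animal, {})[cond] = fit_psychometric(table)
            summaries.setdefault(animal, {})[cond] = summarize_activity(ts, cond)

    reports = apply_exclusions(fits, tables, config.conditions)
    retained = sorted(a for a, r in reports.items() if r.retained)

    trials_to_frame(all_trials).to_csv(ROOT / "trials.csv", index=False)
    rows = []
    for animal, by_cond in sorted(tables.items()):
        for cond, tb in by_cond.items():
            p = tb.p_long
            for t in tb.durations:
                rows.append(dict(animal_id=animal, condition=cond, duration_s=t,
                                 n_long=tb.n_long[t], n_short=tb.n_short[t],
                                 p_long=p[t]))
    pd.DataFrame(rows).to_csv(ROOT / "choice_tables.csv", index=False)
    pd.DataFrame([
        dict(animal_id=a, condition=c, d50=f.d50, epsilon=f.epsilon, slope=f.slope,
             n_iterations=f.n_iterations, converged=f.converged, valid=f.valid)
        for a, bc in sorted(fits.items()) for c, f in bc.items()
    ]).to_csv(ROOT / "fits.csv", index=False)
    pd.DataFrame([
        dict(animal_id=a, condition=c, total_activity=s.total_activity,
             omissions=s.omissions, prematures=s.prematures,
             pct_omission=s.pct_omission, pct_premature=s.pct_premature)
        for a, bc in sorted(summaries.items()) for c, s in bc.items()
    ]).to_csv(ROOT / "activity_summaries.csv", index=False)
    pd.DataFrame([
        dict(animal_id=a, retained=r.retained, reasons=";".join(r.reasons))
        for a, r in sorted(reports.items())
    ]).to_csv(ROOT / "exclusions.csv", index=False)

    print(f"fitted {len(fits)} animals; retained {len(retained)}")
    for a, r in sorted(reports.items()):
        if not r.retained:
            print(f"  excluded {a}: {', '.join(r.reasons)}")


if __name__ == "__main__":
    main()
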