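"""Validation studies against known ground truth.

Three checks: (1) a 100-animal sweep confirming the fitted curve sits at
P = 0.5 at its point of maximum derivative; (2) the presentation schedule
delivers each of the five durations 20% of the time; (3) dense end-to-end
recovery of the bisection point at the two group-mean values.  Writes
results/recovery.csv.
"""

from pathlib import Path

import pandas as pd

from cagetime.validation import (dense_d50_recovery, presentation_shares,
                                 sweep_midpoint_deviation)

SEED = 0
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    rows = []

    sweep = sweep_midpoint_deviation(seed=SEED)
    print(f"midpoint sweep: max |P(t*) - 0.5| = {sweep.max_midpoint_deviation:.2e} "
          f"over {sweep.n_animals} fits (bound 0.01)")
    rows.append(dict(check="midpoint_deviation_max",
                     value=sweep.max_midpoint_deviation, n=sweep.n_animals))

    sched = presentation_shares(10_000, seed=SEED + 1)
    print(f"presentation shares over {sched.n_trials} trials (nominal 20%):")
    for d, s in sched.shares_pct.items():
        print(f"  {d:4.2f} s: {s:5.2f}%")
        rows.append(dict(check=f"share_pct_{d}", value=s, n=sched.n_trials))

    for label, true_d50 in (("saline", 2.18), ("clomipramine", 2.42)):
        rec = dense_d50_recovery(true_d50, 0.36, 10_000, seed=SEED + 2)
        err = rec.fit.d50 - true_d50
        print(f"dense recovery [{label}]: true D50 = {true_d50:.2f} s, "
              f"fitted = {rec.fit.d50:.4f} s (error {err:+.4f})")
        rows.append(dict(check=f"recovered_d50_{label}", value=rec.fit.d50,
                         n=rec.n_per_duration))

    pd.DataFrame(rows).to_csv(ROOT / "recovery.csv", index=False)


if __name__ == "__main__":
    main()
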