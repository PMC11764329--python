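"""Generate the virtual study cohort: 22 normal animals plus 3 constructed
degenerate ones (2 low-activity, 1 one-sided responder), across three saline
and three drug injection days, and write the raw event log with its
ground-truth sidecar to results/cohort/.
"""

from pathlib import Path

import pandas as pd

from cagetime.events import write_event_log
from cagetime.simulate import (SimulationConfig, combine_logs,
                               make_degenerate_animal, simulate_cohort)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(n_animals=22)
    import numpy as np
    rng = np.random.default_rng(SEED)
    log, truth = simulate_cohort(config, rng)
    parts, truths = [log], [truth]
    for k in range(2):
        dlog, dtruth = make_degenerate_animal(config, "low_activity",
                                              animal_id=f"degL{k + 1:02d}", seed=rng)
        parts.append(dlog); truths.append(dtruth)
    dlog, dtruth = make_degenerate_animal(config, "one_sided",
                                          animal_id="degS01", seed=rng)
    parts.append(dlog); truths.append(dtruth)

    log = combine_logs(parts)
    truth = pd.concat(truths, ignore_index=True)
    write_event_log(log, OUT / "events.csv")
    truth.to_csv(OUT / "ground_truth.csv", index=False)
    config.to_yaml(OUT / "sim_config.yaml")

    n_animals = log.events["animal_id"].nunique()
    print(f"wrote {len(log)} events for {n_animals} animals "
          f"({config.n_animals} normal + 3 degenerate) to {OUT}")
    print("injection days:",
          {c: [str(d) for d in log.condition_days(c)] for c in config.conditions})


if __name__ == "__main__":
    main()
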