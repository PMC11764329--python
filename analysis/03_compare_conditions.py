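"""Condition comparison over the retained cohort: normality-gated paired
tests with Hedge's g for D50, slope and the activity measures, plus the
difference-score correlations checking that the bisection-point shift is
unrelated to the activity drop.  Writes comparisons, correlations and a
group summary table; renders the two-condition psychometric figure.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from cagetime.compare import COMPARISON_TAILS, compare_paired, correlate_differences
from cagetime.psychometrics import psychometric_model

ROOT = Path(__file__).resolve().parents[1] / "results"
CONDITIONS = ("saline", "clomipramine")


def main() -> None:
    fits = pd.read_csv(ROOT / "fits.csv")
    acts = pd.read_csv(ROOT / "activity_summaries.csv")
    excl = pd.read_csv(ROOT / "exclusions.csv")
    choice = pd.read_csv(ROOT / "choice_tables.csv")
    retained = sorted(excl.loc[excl["retained"], "animal_id"])

    wide = {}
    for cond in CONDITIONS:
        f = fits.query("condition == @cond").set_index("animal_id").loc[retained]
        a = acts.query("condition == @cond").set_index("animal_id").loc[retained]
        wide[cond] = dict(D50=f["d50"].to_numpy(), slope=f["slope"].to_numpy(),
                          epsilon=f["epsilon"].to_numpy(),
                          total_activity=a["total_activity"].to_numpy(),
                          omissions=a["omissions"].to_numpy(),
                          prematures=a["prematures"].to_numpy(),
                          pct_omission=a["pct_omission"].to_numpy(),
                          pct_premature=a["pct_premature"].to_numpy())

    sal, drug = CONDITIONS
    comps = [compare_paired(wide[sal][p], wide[drug][p], parameter_name=p, tail=tail)
             for p, tail in COMPARISON_TAILS.items()]
    pd.DataFrame([dataclasses.asdict(c) for c in comps]).to_csv(
        ROOT / "comparisons.csv", index=False)

    d50_diff = wide[drug]["D50"] - wide[sal]["D50"]
    corrs = [correlate_differences(
                 d50_diff, wide[drug][other] - wide[sal][other],
                 pair_of_parameters=("D50", other))
             for other in ("total_activity", "omissions")]
    pd.DataFrame([dataclasses.asdict(c) for c in corrs]).to_csv(
        ROOT / "correlations.csv", index=False)

    rows = []
    for cond in CONDITIONS:
        for p in ("D50", "slope", "total_activity", "omissions", "prematures"):
            v = wide[cond][p]
            rows.append(dict(condition=cond, parameter=p, n=len(v), mean=v.mean(),
                             sd=v.std(ddof=1), min=v.min(), max=v.max()))
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "group_summary.csv", index=False)

    _figure(wide, choice, retained)

    print(f"n = {len(retained)} retained animals")
    for c in comps:
        print(f"  {c.parameter_name:15s} {c.test_used:8s} tail={c.tail} "
              f"stat={c.statistic:8.3f} p={c.p_value:.4g} g={c.hedges_g:6.3f}")
    for c in corrs:
        print(f"  diff-corr D50 vs {c.pair_of_parameters[1]:15s} "
              f"r({c.df}) = {c.r:6.3f}, p = {c.p_value:.3f}")
    print(summary.round(2).to_string(index=False))


def _figure(wide, choice, retained) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.linspace(0, 4, 201)
    fig, ax = plt.subplots(figsize=(5.2, 3.8))
    colors = dict(zip(CONDITIONS, ("tab:blue", "tab:green")))
    for cond in CONDITIONS:
        curves = np.vstack([psychometric_model(grid, d, e) for d, e
                            in zip(wide[cond]["D50"], wide[cond]["epsilon"])])
        mean_curve = curves.mean(axis=0)
        sub = choice.query("condition == @cond and animal_id in @retained")
        pts = sub.groupby("duration_s")["p_long"].agg(["mean", "std"])
        ax.plot(grid, mean_curve, color=colors[cond], label=cond)
        ax.errorbar(pts.index, pts["mean"], yerr=pts["std"], fmt="o",
                    color=colors[cond], capsize=3, ms=4)
        ax.plot([np.interp(0.5, mean_curve, grid)], [0.5], "o", color="red", ms=6)
    ax.axhline(0.5, color="0.8", lw=0.8, ls="--")
    ax.set_xlabel("stimulus duration (s)")
    ax.set_ylabel("P(long response)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(ROOT / "psychometric.png", dpi=150)
    plt.close(fig)


if __name__ == "__main__":
    main()
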