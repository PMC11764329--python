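"""End-to-end orchestration: simulate/load -> classify -> fit -> exclude -> compare.

One :func:`run_pipeline` call produces the full report bundle: per-animal
trial tables, choice tables, psychometric fits, the exclusion report, the
condition-comparison battery, difference-score correlations, a group summary
(mean (sd) and range per parameter and condition), and a two-condition
psychometric figure.  Everything is written as tidy CSV so every report line
is traceable to an intermediate file, and a fixed seed reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import (COMPARISON_TAILS, ConditionComparison, DifferenceCorrelation,
                      compare_paired, correlate_differences)
from .events import (DEFAULT_DURATIONS, DEFAULT_WINDOW, SessionLog,
                     pool_condition_days, read_event_log, write_event_log)
from .psychometrics import (ExclusionReport, ExclusionThresholds, PsychometricFit,
                            apply_exclusions, fit_psychometric)
from .simulate import SimulationConfig, combine_logs, make_degenerate_animal, simulate_cohort
from .trials import (AnimalSummary, ChoiceTable, build_choice_table, build_trials,
                     summarize_activity, trials_to_frame)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulate mode or input-log mode)."""

    sim: SimulationConfig | None = None
    input_log: str | None = None
    injections: dict[str, list] | None = None       # input-log mode calendar
    conditions: tuple[str, str] = ("saline", "clomipramine")
    durations: tuple[float, ...] = DEFAULT_DURATIONS
    window: tuple[str, str] = DEFAULT_WINDOW
    n_days: int = 3
    thresholds: ExclusionThresholds = field(default_factory=ExclusionThresholds)
    include_repeats: bool = True
    g_variant: str = "diff"
    correlation_method: str = "pearson"
    n_degenerate_low_activity: int = 0
    n_degenerate_one_sided: int = 0
    outdir: str | None = None
    seed: int = 0
    make_figure: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_log is None):
            raise ValueError("exactly one of sim / input_log must be provided")


@dataclass
class PipelineResult:
    log: SessionLog
    ground_truth: pd.DataFrame | None
    trials: pd.DataFrame
    tables: dict[str, dict[str, ChoiceTable]]
    fits: dict[str, dict[str, PsychometricFit]]
    summaries: dict[str, dict[str, AnimalSummary]]
    exclusions: dict[str, ExclusionReport]
    retained: list[str]
    comparisons: list[ConditionComparison]
    correlations: list[DifferenceCorrelation]
    summary_table: pd.DataFrame
    plot_data: dict | None = None
    outdir: Path | None = None

    def parameter_vectors(self, parameter: str) -> dict[str, np.ndarray]:
        """Per-condition vectors of one parameter over retained animals."""
        out = {}
        conds = next(iter(self.fits.values())).keys() if self.fits else []
        for cond in conds:
            vals = []
            for animal in self.retained:
                vals.append(_parameter_value(self, animal, cond, parameter))
            out[cond] = np.asarray(vals, dtype=float)
        return out


def _parameter_value(res: PipelineResult, animal: str, cond: str, parameter: str) -> float:
    if parameter == "D50":
        return res.fits[animal][cond].d50
    if parameter == "slope":
        return res.fits[animal][cond].slope
    summ = res.summaries[animal][cond]
    return float(getattr(summ, parameter))


def _acquire_log(config: RunConfig, outdir: Path | None):
    if config.sim is not None:
        rng = np.random.default_rng(config.seed)
        log, truth = simulate_cohort(config.sim, rng)
        parts = [log]
        truths = [truth]
        for k in range(config.n_degenerate_low_activity):
            dlog, dtruth = make_degenerate_animal(
                config.sim, "low_activity", animal_id=f"degL{k + 1:02d}", seed=rng)
            parts.append(dlog)
            truths.append(dtruth)
        for k in range(config.n_degenerate_one_sided):
            dlog, dtruth = make_degenerate_animal(
                config.sim, "one_sided", animal_id=f"degS{k + 1:02d}", seed=rng)
            parts.append(dlog)
            truths.append(dtruth)
        log = combine_logs(parts) if len(parts) > 1 else log
        truth = pd.concat(truths, ignore_index=True)
        if outdir is not None:
            write_event_log(log, outdir / "events.csv")
            truth.to_csv(outdir / "ground_truth.csv", index=False)
            config.sim.to_yaml(outdir / "sim_config.yaml")
        return log, truth
    log = read_event_log(config.input_log, injections=config.injections,
                         duration_set=config.durations)
    return log, None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    log, truth = _acquire_log(config, outdir)
    conditions = tuple(config.sim.conditions) if config.sim else config.conditions

    all_trials = []
    tables: dict[str, dict[str, ChoiceTable]] = {}
    fits: dict[str, dict[str, PsychometricFit]] = {}
    summaries: dict[str, dict[str, AnimalSummary]] = {}
    for cond in conditions:
        pooled = pool_condition_days(log, cond, n_days=config.n_days,
                                     window_start=config.window[0],
                                     window_end=config.window[1])
        trials = build_trials(pooled, durations=config.durations, condition=cond)
        all_trials.extend(trials)
        by_animal: dict[str, list] = {}
        for t in trials:
            by_animal.setdefault(t.animal_id, []).append(t)
        for animal, ts in sorted(by_animal.items()):
            table = build_choice_table(ts, cond, durations=config.durations,
                                       include_repeats=config.include_repeats)
            tables.setdefault(animal, {})[cond] = table
            fits.setdefault(animal, {})[cond] = fit_psychometric(
                table, max_iter=config.thresholds.iter_cap)
            summaries.setdefault(animal, {})[cond] = summarize_activity(ts, cond)

    exclusions = apply_exclusions(fits, tables, conditions, config.thresholds)
    retained = sorted(a for a, rep in exclusions.items() if rep.retained)
    logger.info("retained %d of %d animals", len(retained), len(exclusions))

    result = PipelineResult(
        log=log, ground_truth=truth, trials=trials_to_frame(all_trials),
        tables=tables, fits=fits, summaries=summaries, exclusions=exclusions,
        retained=retained, comparisons=[], correlations=[],
        summary_table=pd.DataFrame(), outdir=outdir,
    )

    sal, drug = conditions
    if len(retained) >= 3:
        for param, tail in COMPARISON_TAILS.items():
            s = np.array([_parameter_value(result, a, sal, param) for a in retained])
            d = np.array([_parameter_value(result, a, drug, param) for a in retained])
            result.comparisons.append(
                compare_paired(s, d, parameter_name=param, tail=tail,
                               g_variant=config.g_variant))
        d50_diff = np.array([result.fits[a][drug].d50 - result.fits[a][sal].d50
                             for a in retained])
        for other in ("total_activity", "omissions"):
            o_diff = np.array([
                _parameter_value(result, a, drug, other)
                - _parameter_value(result, a, sal, other) for a in retained])
            result.correlations.append(
                correlate_differences(d50_diff, o_diff,
                                      method=config.correlation_method,
                                      pair_of_parameters=("D50", other)))

    result.summary_table = _summary_table(result, conditions)
    if outdir is not None:
        _write_bundle(result, conditions)
    if config.make_figure:
        fig_path = outdir / "psychometric.png" if outdir else None
        result.plot_data = render_psychometric_plot(result, conditions, fig_path)
    return result


def _summary_table(res: PipelineResult, conditions) -> pd.DataFrame:
    """Group mean (sd) and range per parameter and condition over retained animals."""
    rows = []
    for cond in conditions:
        for param in COMPARISON_TAILS:
            vals = np.array([_parameter_value(res, a, cond, param)
                             for a in res.retained], dtype=float)
            if len(vals) == 0:
                continue
            rows.append(dict(condition=cond, parameter=param, n=len(vals),
                             mean=vals.mean(), sd=vals.std(ddof=1) if len(vals) > 1 else 0.0,
                             min=vals.min(), max=vals.max()))
    return pd.DataFrame(rows)


def _write_bundle(res: PipelineResult, conditions) -> None:
    out = res.outdir
    res.trials.to_csv(out / "trials.csv", index=False)

    ct_rows = []
    for animal, by_cond in sorted(res.tables.items()):
        for cond, table in by_cond.items():
            p = table.p_long
            for t in table.durations:
                ct_rows.append(dict(animal_id=animal, condition=cond, duration_s=t,
                                    n_long=table.n_long[t], n_short=table.n_short[t],
                                    p_long=p[t]))
    pd.DataFrame(ct_rows).to_csv(out / "choice_tables.csv", index=False)

    fit_rows = []
    for animal, by_cond in sorted(res.fits.items()):
        for cond, f in by_cond.items():
            fit_rows.append(dict(animal_id=animal, condition=cond, d50=f.d50,
                                 epsilon=f.epsilon, slope=f.slope,
                                 t_at_max_slope=f.t_at_max_slope,
                                 midpoint_deviation=f.midpoint_deviation,
                                 n_iterations=f.n_iterations, converged=f.converged,
                                 residual_sse=f.residual_sse, valid=f.valid))
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)

    excl_rows = [dict(animal_id=a, retained=rep.retained,
                      reasons=";".join(rep.reasons))
                 for a, rep in sorted(res.exclusions.items())]
    pd.DataFrame(excl_rows).to_csv(out / "exclusions.csv", index=False)

    summ_rows = []
    for animal, by_cond in sorted(res.summaries.items()):
        for cond, s in by_cond.items():
            summ_rows.append(dict(animal_id=animal, condition=cond,
                                  total_activity=s.total_activity,
                                  omissions=s.omissions, prematures=s.prematures,
                                  pct_omission=s.pct_omission,
                                  pct_premature=s.pct_premature))
    pd.DataFrame(summ_rows).to_csv(out / "activity_summaries.csv", index=False)

    pd.DataFrame([dataclasses.asdict(c) for c in res.comparisons]).to_csv(
        out / "comparisons.csv", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in res.correlations]).to_csv(
        out / "correlations.csv", index=False)
    res.summary_table.to_csv(out / "group_summary.csv", index=False)


def render_psychometric_plot(res: PipelineResult, conditions, path=None) -> dict:
    """Two-condition mean psychometric figure.

    Plots the across-animal mean fitted curve on [0, 4] s, per-duration mean
    +/- sd of the observed choice probabilities, and the D50 of each mean
    curve.  Returns the plotted arrays so assertions can target data, not
    pixels; skips conditions without valid fits with a warning.
    """
    grid = np.linspace(0.0, 4.0, 201)
    data: dict = {"grid": grid, "conditions": {}}
    for cond in conditions:
        valid_fits = [f[cond] for f in res.fits.values()
                      if cond in f and f[cond].valid]
        if not valid_fits:
            logger.warning("no valid fits for condition %r; curve skipped", cond)
            continue
        curves = np.vstack([f.predict(grid) for f in valid_fits])
        mean_curve = curves.mean(axis=0)
        d50_marker = float(np.interp(0.5, mean_curve, grid))
        pts = {t: [] for t in next(iter(res.tables.values()))[cond].durations}
        for animal in res.retained:
            table = res.tables[animal].get(cond)
            if table is None:
                continue
            for t, p in table.p_long.items():
                if not np.isnan(p):
                    pts[t].append(p)
        durations = sorted(pts)
        p_mean = np.array([np.mean(pts[t]) if pts[t] else np.nan for t in durations])
        p_sd = np.array([np.std(pts[t], ddof=1) if len(pts[t]) > 1 else 0.0
                         for t in durations])
        data["conditions"][cond] = dict(mean_curve=mean_curve, d50=d50_marker,
                                        durations=np.array(durations),
                                        p_mean=p_mean, p_sd=p_sd,
                                        n_fits=len(valid_fits))
    if path is not None and data["conditions"]:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5.2, 3.8))
        colors = {"saline": "tab:blue", "clomipramine": "tab:green"}
        for i, (cond, d) in enumerate(data["conditions"].items()):
            c = colors.get(cond, f"C{i}")
            ax.plot(grid, d["mean_curve"], color=c, label=cond)
            ax.errorbar(d["durations"], d["p_mean"], yerr=d["p_sd"], fmt="o",
                        color=c, capsize=3, ms=4)
            ax.plot([d["d50"]], [0.5], "o", color="red", ms=6, zorder=5)
        ax.axhline(0.5, color="0.8", lw=0.8, ls="--")
        ax.set_xlabel("stimulus duration (s)")
        ax.set_ylabel("P(long response)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        data["path"] = str(path)
    return data
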