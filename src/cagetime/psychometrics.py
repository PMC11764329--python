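"""Psychometric model, nonlinear least-squares fit, slope, and exclusions.

The choice probability is modelled as a cumulative-normal (probit)
psychometric function of stimulus duration ``t``::

    P(long | t) = Phi( c * (t - D50) / epsilon ),    c = 0.6745

where ``D50`` is the bisection point (the duration answered "long" half the
time), ``epsilon`` scales timing imprecision, and ``c`` is the 75% quantile
of the standard normal so that ``t = D50 ± epsilon`` maps to P = 0.75/0.25.

Per animal and condition the two parameters are estimated by unweighted
nonlinear least squares on the five ``(t, p_long)`` points.  Discrimination
precision is reported as the *slope*: the maximum of dP/dt over the stimulus
domain [0, 4] s, which in closed form is ``c * phi(0) / epsilon`` whenever
D50 lies inside the domain.  Animals whose fits have unrealistic parameters,
hit the iteration cap, or rest on fewer than 10 timed anchor responses are
excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trials import ANCHOR_LONG, ANCHOR_SHORT, ChoiceTable

#: scaling constant of the model: the 75% quantile of the standard normal
C_CONST = 0.6745

#: stimulus domain (s) over which the maximum derivative is taken
SLOPE_DOMAIN = (0.0, 4.0)

#: optimisation box: D50 (s) and epsilon (s) bounds used to stabilise
#: degenerate choice tables; recorded in every fit report
FIT_BOUNDS = ((-4.0, 1e-6), (12.0, 10.0))

DEFAULT_MAX_ITER = 10_000

EXCLUSION_REASONS = (
    "unrealistic_D50",
    "unrealistic_epsilon",
    "iteration_cap",
    "low_anchor_visits",
    "fit_failure",
)


def psychometric_model(t, d50: float, epsilon: float):
    """P(long | t) = Phi(c (t - D50) / epsilon); strictly increasing in t."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    return stats.norm.cdf(C_CONST * (np.asarray(t, dtype=float) - d50) / epsilon)


def psychometric_derivative(t, d50: float, epsilon: float):
    """dP/dt = (c/epsilon) * phi(c (t - D50)/epsilon)."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    z = C_CONST * (np.asarray(t, dtype=float) - d50) / epsilon
    return (C_CONST / epsilon) * stats.norm.pdf(z)


@dataclass
class SlopeResult:
    slope: float
    t_at_max_slope: float
    p_at_max_slope: float
    midpoint_deviation: float  # |P(t_at_max_slope) - 0.5|


@dataclass
class PsychometricFit:
    """Fitted parameters with convergence diagnostics for one animal/condition."""

    animal_id: str
    condition: str
    d50: float
    epsilon: float
    slope: float
    t_at_max_slope: float
    midpoint_deviation: float
    n_iterations: int
    converged: bool
    residual_sse: float
    n_points: int
    c_const: float = C_CONST
    bounds: tuple = FIT_BOUNDS
    valid: bool | None = None  # set by apply_exclusions

    def predict(self, t):
        return psychometric_model(t, self.d50, self.epsilon)


@dataclass
class ExclusionThresholds:
    """Operationalisation of the 'realistically achievable parameters' rule."""

    d50_lo: float = 0.0
    d50_hi: float = 8.0     # 2x the longest stimulus duration
    eps_max: float = 4.0    # 2x the 'epsilon >> 2' anchor
    iter_cap: int = DEFAULT_MAX_ITER
    min_anchor_visits: int = 10


@dataclass
class ExclusionReport:
    animal_id: str
    reasons: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)
    thresholds: ExclusionThresholds = field(default_factory=ExclusionThresholds)

    @property
    def retained(self) -> bool:
        return not self.reasons


def compute_slope(
    d50: float,
    epsilon: float,
    domain: tuple[float, float] = SLOPE_DOMAIN,
    check_tol: float = 1e-4,
) -> SlopeResult:
    """Maximum of dP/dt over ``domain`` (closed form, verified numerically).

    The derivative peaks at t = D50; clipped to the domain this gives the
    closed form directly.  A grid + bounded scalar maximisation cross-checks
    it, and a disagreement above ``check_tol`` raises a diagnostic warning.
    """
    lo, hi = domain
    t_star = float(np.clip(d50, lo, hi))
    slope_closed = float(psychometric_derivative(t_star, d50, epsilon))

    grid = np.linspace(lo, hi, 401)
    dvals = psychometric_derivative(grid, d50, epsilon)
    t0 = grid[int(np.argmax(dvals))]
    res = optimize.minimize_scalar(
        lambda t: -psychometric_derivative(t, d50, epsilon),
        bounds=(max(lo, t0 - 0.05), min(hi, t0 + 0.05)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    slope_num = float(-res.fun)
    if abs(slope_num - slope_closed) > check_tol:
        warnings.warn(
            f"closed-form slope {slope_closed:.6g} disagrees with numeric "
            f"maximisation {slope_num:.6g} (D50={d50:.3g}, eps={epsilon:.3g})",
            RuntimeWarning,
        )
    p_at = float(psychometric_model(t_star, d50, epsilon))
    return SlopeResult(
        slope=slope_closed,
        t_at_max_slope=t_star,
        p_at_max_slope=p_at,
        midpoint_deviation=abs(p_at - 0.5),
    )


def fit_psychometric(
    table: ChoiceTable,
    init: tuple[float, float] | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    weighted: bool = False,
) -> PsychometricFit:
    """Nonlinear least-squares fit of the probit model to one choice table.

    The loss is the unweighted sum of squared deviations between observed
    ``p_long`` and the model over durations with at least one timed
    response; ``weighted=True`` scales residuals by sqrt(n_t) instead.
    Non-convergence never raises: the fit is returned with
    ``converged=False`` (and later excluded).
    """
    ts, ps, ns = table.defined_points()
    base = dict(animal_id=table.animal_id, condition=table.condition,
                n_points=len(ts))
    if len(ts) < 2:
        return PsychometricFit(
            d50=float("nan"), epsilon=float("nan"), slope=float("nan"),
            t_at_max_slope=float("nan"), midpoint_deviation=float("nan"),
            n_iterations=0, converged=False, residual_sse=float("nan"), **base,
        )
    if init is None:
        lo, hi = min(table.durations), max(table.durations)
        init = ((lo + hi) / 2.0, (hi - lo) / 4.0)
    w = np.sqrt(ns) if weighted else np.ones_like(ps)

    def resid(params):
        d50, eps = params
        return w * (psychometric_model(ts, d50, eps) - ps)

    lower, upper = FIT_BOUNDS
    res = optimize.least_squares(
        resid, x0=np.asarray(init, dtype=float),
        bounds=(np.asarray(lower), np.asarray(upper)),
        max_nfev=max_iter,
    )
    d50, eps = (float(v) for v in res.x)
    converged = bool(res.status > 0) and res.nfev <= max_iter
    if converged:
        sl = compute_slope(d50, eps)
        slope, t_star, dev = sl.slope, sl.t_at_max_slope, sl.midpoint_deviation
    else:
        slope = t_star = dev = float("nan")
    return PsychometricFit(
        d50=d50, epsilon=eps, slope=slope, t_at_max_slope=t_star,
        midpoint_deviation=dev, n_iterations=int(res.nfev), converged=converged,
        residual_sse=float(np.sum(res.fun**2) if weighted is False
                           else np.sum((psychometric_model(ts, d50, eps) - ps) ** 2)),
        **base,
    )


def _check_fit(fit: PsychometricFit, thr: ExclusionThresholds) -> list[str]:
    reasons = []
    if not fit.converged or fit.n_points < 2:
        reasons.append("fit_failure")
        return reasons
    if not (thr.d50_lo <= fit.d50 <= thr.d50_hi):
        reasons.append("unrealistic_D50")
    if fit.epsilon > thr.eps_max:
        reasons.append("unrealistic_epsilon")
    if fit.n_iterations > thr.iter_cap:
        reasons.append("iteration_cap")
    return reasons


def apply_exclusions(
    fits: dict[str, dict[str, PsychometricFit]],
    tables: dict[str, dict[str, ChoiceTable]],
    conditions: tuple[str, str],
    thresholds: ExclusionThresholds | None = None,
) -> dict[str, ExclusionReport]:
    """Decide retention per animal from both conditions' fits and tables.

    An animal is retained only if, in *both* conditions, the fit converged
    with realistic parameters within the iteration cap and the animal has at
    least ``min_anchor_visits`` timed responses at each anchor duration.
    ``fits[animal][condition]`` / ``tables[animal][condition]``; a missing
    condition excludes the animal with reason ``fit_failure``.
    """
    thr = thresholds or ExclusionThresholds()
    reports: dict[str, ExclusionReport] = {}
    for animal in sorted(set(fits) | set(tables)):
        rep = ExclusionReport(animal_id=animal, thresholds=thr)
        for cond in conditions:
            fit = fits.get(animal, {}).get(cond)
            table = tables.get(animal, {}).get(cond)
            if fit is None or table is None:
                rep.reasons.append("fit_failure")
                rep.detail[cond] = "missing condition"
                continue
            reasons = _check_fit(fit, thr)
            for anchor in (ANCHOR_SHORT, ANCHOR_LONG):
                if table.n_timed(anchor) < thr.min_anchor_visits:
                    reasons.append("low_anchor_visits")
                    break
            if reasons:
                rep.detail[cond] = {
                    "d50": fit.d50, "epsilon": fit.epsilon,
                    "n_iterations": fit.n_iterations,
                    "anchor_visits": {a: table.n_timed(a)
                                      for a in (ANCHOR_SHORT, ANCHOR_LONG)},
                }
            rep.reasons.extend(r for r in reasons if r not in rep.reasons)
        for cond in conditions:
            fit = fits.get(animal, {}).get(cond)
            if fit is not None:
                fit.valid = rep.retained and fit.converged
        reports[animal] = rep
    return reports
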