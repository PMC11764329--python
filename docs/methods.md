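# Methods

## Task and data model

The interval bisection task presents an LED stimulus of duration
t ∈ {1, 1.65, 2.5, 3.25, 4} s when an animal enters a corner chamber, each
duration with probability 0.2.  The anchors (1 s → left poke, 4 s → right
poke) are reinforced; an incorrectly answered anchor is re-presented until
answered correctly.  The raw material is a time-ordered event log — visit
starts/ends, stimulus on/off, nose pokes — attributed to chipped animals.

Trial classification follows the trial's poke pattern relative to stimulus
offset: pokes strictly before offset are *premature* and do not stop the
trial; the first poke at/after offset is the *timed* response; a trial with
no poke is an *omission*.  A trial with only premature pokes is
*premature-only* and counts toward neither timed totals nor omissions (it
did contain a poke, just an early one); this is a deliberate resolution of
an ambiguity in the task definition and is flagged here rather than hidden.
A trial ends at `visit_end` or at the next `stimulus_on`, whichever comes
first.  Total activity counts timed responses only.

Analysis is restricted to a half-open evening window [16:00, 24:00) on each
injection day — the dark-phase onset during which drinking activity is high
and acute drug exposure applies — with visits assigned to the window by
their `visit_start`; the three injection days of a condition are pooled.
The half-open convention (an event at exactly 16:00 is in; midnight is out)
avoids double counting at day boundaries and is a package choice where the
protocol wording is ambiguous.

## Psychometric model and fitting

Choice probabilities are modelled by a cumulative-normal (probit) function

P(long | t) = Φ( c (t − D50) / ε ),  c = 0.6745,

so that t = D50 ± ε maps to P = 0.75 / 0.25; c is the 75% quantile of the
standard normal.  D50 (s) is the bisection point, ε (s) indexes timing
imprecision.  Parameters are estimated per animal and condition by
**unweighted** nonlinear least squares over the durations with at least one
timed response (`scipy.optimize.least_squares`, default trust-region
reflective), matching a fit to the five (t, p̂) points rather than to raw
trials; a binomial-weight option (residuals scaled by √n_t) exists behind a
flag but is off by default.  Initialisation is D50₀ = 2.5 s (the midpoint
of the duration range) and ε₀ = 0.75 s (a quarter of the range); bounds
D50 ∈ [−4, 12], ε ∈ (0, 10] stabilise degenerate tables and are recorded in
every fit report.  Non-convergence never raises — the fit is returned
flagged and the animal is later excluded.  Repeat presentations are
included in the choice counts (each presentation is an independent draw
from the animal's curve, so including them leaves p̂ unbiased); a flag
allows excluding them for sensitivity analysis.

The **slope** is the maximum of dP/dt = (c/ε) φ(c(t−D50)/ε) over [0, 4] s.
The maximum sits at t = D50 clipped to the domain, giving the closed form
c·φ(0)/ε when D50 is interior; a grid + bounded scalar maximisation
cross-checks the closed form on every call and warns if they disagree by
more than 1e-4 (the test suite holds them to 1e-6).  The fitted value at
the point of maximum slope is stored, and its deviation from 0.5 is the
package's internal sanity metric (≤ 0.01 across parameter sweeps).

## Exclusion rules

An animal is analysed only if, in **both** conditions: the fit converged;
D50 ∈ [0, 8] s and ε ≤ 4 s (operationalising "realistically achievable
parameters" as twice the longest stimulus and twice a 2 s imprecision
anchor); the solver stayed within 10,000 iterations; and each anchor
duration has ≥ 10 timed responses.  Every exclusion is reported with its
reasons and the thresholds used.  All thresholds are configurable.

## Condition comparison

Paired differences are computed as **drug − saline** throughout (positive
Hedge's g ⟺ the parameter increased under drug).  A Shapiro–Wilk gate on
the differences (pass: p ≥ 0.05) selects the paired Student t test, else
the Wilcoxon signed-rank test; D50 is tested one-tailed (directional
hypothesis: drug increases D50), all other parameters two-tailed.  Hedge's
g defaults to mean(diff)/sd(diff) × J(n−1) with the exact gamma-function
small-sample correction J; a pooled variant (mean difference over the
average condition sd, as pingouin computes for paired designs) is available
behind a flag.  Difference-score correlations (e.g. ΔD50 vs Δactivity) use
Pearson by default with df = n − 2; Spearman is available.  No
multiple-testing correction is applied, by design.  Degenerate inputs
(constant or all-zero differences, zero-variance vectors) are returned
flagged, never raised.

## Synthetic cohort generator

The generator emulates the study conditions and writes the same CSV dialect
the reader consumes, with a ground-truth sidecar for recovery testing.

Defaults (chosen once from the observed group statistics and protocol, not
tuned): saline true D50 ~ N(2.18, 0.55²) s between animals; ε from a
truncated normal (mean 0.36 s — derived from the mean observed slope via
ε = c·φ(0)/slope — sd 0.12, floor 0.05 s); the drug effect is a pure
per-animal D50 shift ~ N(+0.24, 0.32²) s (reproducing a paired g ≈ 0.74)
with ε unchanged, plus an independent multiplicative activity drop to 0.52
of the saline visit rate.  Visits arrive as a Poisson stream at 11/h inside
the 16:00–24:00 window on three injection days per condition (saline days
consecutive, drug days alternating), giving ≈220 timed responses per animal
per condition triple.  Between-animal visit rates are lognormal with CV 0.4,
floored at 0.35× the mean — without the floor, sampling noise alone pushes
some healthy animals' drug-condition anchor counts under the 10-response
exclusion line, which contradicts the emulated cohort where no retained
animal was near the threshold.  Omissions occur per stimulus presentation
(probability 0.14) and premature pokes per presentation (0.20, uniform
timing within the stimulus, random side).  Timed latencies are stimulus
duration + exponential(0.5 s) — only the premature/timed boundary matters
downstream.  The logged stimulus-off time carries ±100 ms uniform jitter,
mirroring hardware presentation accuracy.  Repeat-until-correct applies at
the anchors (capped at 25 repeats as a numerical guard).

Degenerate constructions: `low_activity` (0.25 visits/h, guaranteeing < 10
anchor responses) and `one_sided` (true D50 = −6 s: the animal answers
"long" everywhere, a non-identifiable table whose fit pegs at the lower
parameter bound and is excluded as unrealistic).

What the generator does **not** emulate: corner preference and social
dynamics between cage mates, drinking microstructure, learning dynamics
within the training phase, any mechanistic internal-clock process, and any
drug effect on omission/premature *rates* (only the D50 shift and the
activity drop are modelled).  Passing recovery tests therefore demonstrate
that the pipeline is an unbiased reader of data satisfying the probit
choice model with these nuisance processes — not that real cage data meets
those assumptions.

Determinism: a fixed seed plus config reproduces the event log byte for
byte.  Retention counts on small cohorts are cohort-specific (anchor counts
sit near the exclusion line in the low-activity drug condition, as in the
emulated study), so the constructed 25-animal demonstration cohort is
generated at a fixed seed.

## Problem sizes used in validation

The midpoint-deviation sweep fits 100 synthetic animals with D50 ∈
[1.3, 3.6], ε ∈ [0.2, 1.4] and 200 trials per duration.  The schedule check
counts ≈10,500 first presentations.  Dense recovery uses one virtual animal,
25 virtual days of evenly spaced visits (the `regular` schedule exists
because a Poisson stream at that density would overlap visits), ≈10⁴
presentations per duration, run through the full CSV → filter → classify →
tabulate → fit path; across replicate seeds the fitted D50 has Monte-Carlo
SE ≈ 0.005 s, and the recovery tests assert agreement within 3 SE
(0.015 s).

## Known limitations

- The probit fit on five proportion points ignores per-point binomial
  variance by default (fidelity to the five-point method over statistical
  optimality); the weighted flag exists for sensitivity checks.
- Slope estimates are noisy at realistic per-duration counts and inherit
  upward bias from small-ε fits; D50 is the robust endpoint.
- `n_iterations` reports solver function evaluations, the closest available
  analogue of an iteration count for the trust-region solver.
- The event dialect assumes visits do not overlap per animal; logs from
  hardware with re-entrant antenna reads may need pre-cleaning.
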