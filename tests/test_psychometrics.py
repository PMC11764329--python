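import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cagetime.psychometrics import (C_CONST, ExclusionThresholds, apply_exclusions,
                                    compute_slope, fit_psychometric,
                                    psychometric_derivative, psychometric_model)
from cagetime.simulate import simulate_choice_counts
from cagetime.trials import ChoiceTable

DURATIONS = (1.0, 1.65, 2.5, 3.25, 4.0)


def table_from_probs(p_by_dur, n=100, animal="ratA", cond="saline"):
    n_long = {t: int(round(n * p)) for t, p in p_by_dur.items()}
    n_short = {t: n - n_long[t] for t in p_by_dur}
    return ChoiceTable(animal_id=animal, condition=cond,
                       durations=tuple(p_by_dur), n_long=n_long, n_short=n_short)


def exact_table(d50, eps, n=10**6):
    """Choice counts carrying the model probabilities to float precision."""
    n_long = {t: float(n) * float(psychometric_model(t, d50, eps)) for t in DURATIONS}
    n_short = {t: n - n_long[t] for t in DURATIONS}
    tab = ChoiceTable("ratA", "saline", DURATIONS,
                      {t: v for t, v in n_long.items()},
                      {t: v for t, v in n_short.items()})
    return tab


class TestModel:
    def test_half_probability_at_d50(self):
        assert psychometric_model(2.3, 2.3, 0.5) == pytest.approx(0.5)

    def test_quartiles_at_one_epsilon(self):
        assert psychometric_model(2.3 + 0.4, 2.3, 0.4) == pytest.approx(0.75, abs=2e-5)
        assert psychometric_model(2.3 - 0.4, 2.3, 0.4) == pytest.approx(0.25, abs=2e-5)

    def test_value_against_erf_closed_form(self):
        # Phi(0.6745 * (4 - 2.5) / 0.5) = Phi(2.0235), via erf independently
        expected = 0.5 * (1 + math.erf(0.6745 * 3 / math.sqrt(2)))
        assert psychometric_model(4.0, 2.5, 0.5) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9785, abs=5e-5)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            psychometric_model(2.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            psychometric_derivative(2.0, 2.0, -1.0)

    @settings(derandomize=True, deadline=None)
    @given(d50=st.floats(0.0, 4.0), eps=st.floats(0.05, 5.0))
    def test_monotone_increasing(self, d50, eps):
        t = np.linspace(0, 4, 50)
        p = psychometric_model(t, d50, eps)
        assert np.all(np.diff(p) >= 0)
        # strictly increasing wherever the CDF has not saturated in float64
        interior = (p[:-1] > 1e-12) & (p[1:] < 1 - 1e-12)
        assert np.all(np.diff(p)[interior] > 0)


class TestFit:
    def test_exact_probabilities_recovered_to_1e6(self):
        fit = fit_psychometric(exact_table(2.5, 0.5))
        assert fit.converged
        assert fit.d50 == pytest.approx(2.5, abs=1e-6)
        assert fit.epsilon == pytest.approx(0.5, abs=1e-6)

    def test_saturated_table_flagged_unrealistic(self):
        tab = table_from_probs({t: 1.0 for t in DURATIONS})
        fit = fit_psychometric(tab)
        thr = ExclusionThresholds()
        assert (not fit.converged) or not (thr.d50_lo <= fit.d50 <= thr.d50_hi)

    def test_too_few_points_is_fit_failure_not_exception(self):
        tab = table_from_probs({2.5: 0.6})
        fit = fit_psychometric(tab)
        assert not fit.converged and np.isnan(fit.d50)

    def test_sampled_counts_recover_truth_within_3se(self):
        # dense binomial sampling at the saline group-mean parameters
        d50, eps, n = 2.18, 0.36, 1000
        fits = [fit_psychometric(simulate_choice_counts(d50, eps, n, seed=s))
                for s in range(8)]
        est = np.array([f.d50 for f in fits])
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - d50) < 3 * max(se, 1e-3)

    def test_bias_shrinks_with_sample_size(self):
        d50, eps = 2.18, 0.36
        err = {}
        for n in (100, 1000, 10000):
            e = [abs(fit_psychometric(simulate_choice_counts(d50, eps, n, seed=s)).d50
                     - d50) for s in range(6)]
            err[n] = np.mean(e)
        assert err[10000] < err[100]

    def test_weighted_option_changes_loss_not_contract(self):
        tab = simulate_choice_counts(2.0, 0.4, 50, seed=3)
        fw = fit_psychometric(tab, weighted=True)
        assert fw.converged and 0 < fw.epsilon


class TestSlope:
    def test_closed_form_value(self):
        # c * phi(0) / eps with eps chosen to give slope 1.0 at t = D50
        res = compute_slope(2.0, 0.26908)
        assert res.slope == pytest.approx(0.6745 * 0.3989423 / 0.26908, rel=1e-6)
        assert res.slope == pytest.approx(1.0, abs=1e-4)
        assert res.t_at_max_slope == pytest.approx(2.0)

    def test_slope_halves_when_epsilon_doubles(self):
        s1 = compute_slope(2.0, 0.3).slope
        s2 = compute_slope(2.0, 0.6).slope
        assert s1 == pytest.approx(2 * s2, rel=1e-9)

    def test_d50_outside_domain_peaks_at_boundary(self):
        res = compute_slope(5.0, 0.5)
        assert res.t_at_max_slope == 4.0
        assert res.p_at_max_slope < 0.5

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(d50=st.floats(0.0, 4.0), eps=st.floats(0.05, 5.0))
    def test_closed_form_matches_numeric_maximisation(self, d50, eps):
        from scipy.optimize import minimize_scalar

        res = compute_slope(d50, eps)
        grid = np.linspace(0, 4, 20001)
        t0 = grid[np.argmax(psychometric_derivative(grid, d50, eps))]
        opt = minimize_scalar(lambda t: -psychometric_derivative(t, d50, eps),
                              bounds=(max(0.0, t0 - 0.01), min(4.0, t0 + 0.01)),
                              method="bounded", options={"xatol": 1e-12})
        assert res.slope == pytest.approx(-opt.fun, abs=1e-6)


class TestExclusions:
    def _fit(self, animal, cond, d50=2.2, eps=0.4, n_iter=20, converged=True):
        tab = exact_table(d50, max(eps, 0.05), n=50)
        fit = fit_psychometric(tab)
        fit.animal_id, fit.condition = animal, cond
        fit.d50, fit.epsilon = d50, eps
        fit.n_iterations, fit.converged = n_iter, converged
        return fit

    def _table(self, animal, cond, anchor_n=30):
        n_long = {t: anchor_n // 2 for t in DURATIONS}
        n_short = {t: anchor_n - anchor_n // 2 for t in DURATIONS}
        return ChoiceTable(animal, cond, DURATIONS, n_long, n_short)

    def test_unrealistic_d50_excluded(self):
        fits = {"r1": {"a": self._fit("r1", "a", d50=25.0), "b": self._fit("r1", "b")}}
        tabs = {"r1": {"a": self._table("r1", "a"), "b": self._table("r1", "b")}}
        rep = apply_exclusions(fits, tabs, ("a", "b"))["r1"]
        assert "unrealistic_D50" in rep.reasons and not rep.retained

    def test_low_anchor_visits_excluded(self):
        fits = {"r1": {"a": self._fit("r1", "a"), "b": self._fit("r1", "b")}}
        tabs = {"r1": {"a": self._table("r1", "a"), "b": self._table("r1", "b", anchor_n=6)}}
        rep = apply_exclusions(fits, tabs, ("a", "b"))["r1"]
        assert rep.reasons == ["low_anchor_visits"]

    def test_iteration_cap_and_epsilon_rules(self):
        fits = {"r1": {"a": self._fit("r1", "a", n_iter=10_001),
                       "b": self._fit("r1", "b", eps=6.0)}}
        tabs = {"r1": {"a": self._table("r1", "a"), "b": self._table("r1", "b")}}
        rep = apply_exclusions(fits, tabs, ("a", "b"))["r1"]
        assert {"iteration_cap", "unrealistic_epsilon"} <= set(rep.reasons)

    def test_missing_condition_is_fit_failure(self):
        fits = {"r1": {"a": self._fit("r1", "a")}}
        tabs = {"r1": {"a": self._table("r1", "a")}}
        rep = apply_exclusions(fits, tabs, ("a", "b"))["r1"]
        assert "fit_failure" in rep.reasons

    def test_healthy_animal_retained_and_fit_marked_valid(self):
        fits = {"r1": {"a": self._fit("r1", "a"), "b": self._fit("r1", "b")}}
        tabs = {"r1": {"a": self._table("r1", "a"), "b": self._table("r1", "b")}}
        rep = apply_exclusions(fits, tabs, ("a", "b"))["r1"]
        assert rep.retained and fits["r1"]["a"].valid
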