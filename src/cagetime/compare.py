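"""Saline-vs-drug condition comparisons for the retained cohort.

The battery follows a normality-gated paired design: Shapiro-Wilk on the
paired differences decides between the paired Student t test and the
Wilcoxon signed-rank test.  The bisection point D50 carries a directional
hypothesis (drug > saline) and is tested one-tailed; every other parameter
is two-tailed.  Effect sizes are Hedge's g on the paired differences with
the exact small-sample correction.  Differences are always computed as
drug - saline, so positive g means the parameter increased under drug.
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

#: parameters compared between conditions, with their test tail
COMPARISON_TAILS = {
    "D50": "one",
    "slope": "two",
    "total_activity": "two",
    "omissions": "two",
    "prematures": "two",
    "pct_omission": "two",
    "pct_premature": "two",
}


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    passed: bool
    degenerate: bool = False


@dataclass
class ConditionComparison:
    parameter_name: str
    test_used: str          # "paired_t" | "wilcoxon"
    tail: str               # "one" | "two"
    statistic: float
    df: float               # n-1 for t, NaN for Wilcoxon
    p_value: float
    hedges_g: float
    n_pairs: int
    normality: NormalityResult | None = None
    degenerate: bool = False


@dataclass
class DifferenceCorrelation:
    pair_of_parameters: tuple[str, str]
    method: str             # "pearson" | "spearman"
    r: float
    p_value: float
    n: int
    df: int
    degenerate: bool = False


def normality_gate(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk on paired differences; passes when p >= alpha.

    A constant vector is degenerate: the gate fails and the comparison falls
    through to the rank test.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"normality gate needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        return NormalityResult(float("nan"), float("nan"), passed=False, degenerate=True)
    w, p = stats.shapiro(x)
    return NormalityResult(float(w), float(p), passed=bool(p >= alpha))


def hedges_correction(df: int) -> float:
    """Exact small-sample bias correction J(df) = Gamma(df/2) / (sqrt(df/2) Gamma((df-1)/2))."""
    return float(np.exp(special.gammaln(df / 2) - np.log(np.sqrt(df / 2))
                        - special.gammaln((df - 1) / 2)))


def hedges_g(saline, drug, variant: str = "diff") -> float:
    """Hedge's g for the paired contrast, drug - saline.

    ``variant="diff"`` (default): mean difference standardised by the sd of
    the differences, corrected by J(n-1).  ``variant="pooled"``: mean
    difference over the average of the two condition sds, corrected by
    J(2(n-1)).
    """
    s = np.asarray(saline, dtype=float)
    d = np.asarray(drug, dtype=float)
    diff = d - s
    n = len(diff)
    md = diff.mean()
    if variant == "diff":
        sd = diff.std(ddof=1)
        j = hedges_correction(n - 1)
    elif variant == "pooled":
        sd = np.sqrt((s.std(ddof=1) ** 2 + d.std(ddof=1) ** 2) / 2)
        j = hedges_correction(2 * (n - 1))
    else:
        raise ValueError(f"unknown Hedge's g variant {variant!r}")
    if sd == 0:
        return 0.0 if md == 0 else float(np.sign(md)) * float("inf")
    return float(md / sd * j)


def compare_paired(
    saline,
    drug,
    parameter_name: str = "",
    tail: str = "two",
    alpha: float = 0.05,
    g_variant: str = "diff",
    force_test: str | None = None,
) -> ConditionComparison:
    """Paired condition comparison with the normality gate.

    One-tailed tests use the directional alternative drug > saline.
    ``force_test`` ("paired_t" | "wilcoxon") bypasses the gate, e.g. for
    calibration studies of one branch.
    """
    s = np.asarray(saline, dtype=float)
    d = np.asarray(drug, dtype=float)
    if s.shape != d.shape:
        raise ValueError(f"paired vectors differ in length: {s.shape} vs {d.shape}")
    n = len(s)
    if n < 3:
        raise ValueError(f"paired comparison needs n >= 3, got {n}")
    diff = d - s
    if np.allclose(diff, 0):
        # exactly null data: no evidence either way, degenerate sd handled
        return ConditionComparison(
            parameter_name=parameter_name, test_used="paired_t", tail=tail,
            statistic=0.0, df=n - 1, p_value=1.0 if tail == "two" else 0.5,
            hedges_g=0.0, n_pairs=n,
            normality=NormalityResult(float("nan"), float("nan"), False, True),
            degenerate=True,
        )
    gate = normality_gate(diff, alpha=alpha)
    if force_test is not None:
        use_t = force_test == "paired_t"
    else:
        use_t = gate.passed
    alternative = "greater" if tail == "one" else "two-sided"
    g = hedges_g(s, d, variant=g_variant)
    if use_t:
        res = stats.ttest_rel(d, s, alternative=alternative)
        return ConditionComparison(
            parameter_name=parameter_name, test_used="paired_t", tail=tail,
            statistic=float(res.statistic), df=float(n - 1),
            p_value=float(res.pvalue), hedges_g=g, n_pairs=n, normality=gate,
            degenerate=gate.degenerate,
        )
    res = stats.wilcoxon(d, s, alternative=alternative)
    return ConditionComparison(
        parameter_name=parameter_name, test_used="wilcoxon", tail=tail,
        statistic=float(res.statistic), df=float("nan"),
        p_value=float(res.pvalue), hedges_g=g, n_pairs=n, normality=gate,
        degenerate=gate.degenerate,
    )


def correlate_differences(
    x_diff,
    y_diff,
    method: str = "pearson",
    pair_of_parameters: tuple[str, str] = ("", ""),
) -> DifferenceCorrelation:
    """Correlation between two per-animal difference scores (df = n - 2)."""
    x = np.asarray(x_diff, dtype=float)
    y = np.asarray(y_diff, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vectors differ in length: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"correlation needs n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DifferenceCorrelation(
            pair_of_parameters=pair_of_parameters, method=method,
            r=float("nan"), p_value=float("nan"), n=n, df=n - 2, degenerate=True,
        )
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return DifferenceCorrelation(
        pair_of_parameters=pair_of_parameters, method=method,
        r=float(res.statistic), p_value=float(res.pvalue), n=n, df=n - 2,
    )
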