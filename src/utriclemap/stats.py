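"""Zonal count statistics: exact binomial sector tests, two-proportion
z-tests, chi-square tests, and standardized effect sizes.

Conventions follow the study design these analyses serve: all tests are
two-sided at alpha = 0.05; the binomial test is the exact minimum-
likelihood two-sided form; the z-test uses the pooled standard error with
no continuity correction; mean-difference effect sizes use bias-corrected
Hedges' g when the smaller group has n < 15 and Cohen's d otherwise;
chi-square goodness-of-fit tests carry Cohen's w = sqrt(chi2 / N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from utriclemap.simulate import (
    TYPE_EXTRASTRIOLAR,
    TYPE_INTERMEDIATE,
    TYPE_NEGATIVE,
    TYPE_STRIOLAR,
)

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One statistical test: statistic, two-sided p, optional effect size."""

    test: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    effect_measure: str = "none"
    sample_sizes: tuple[int, ...] = ()
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "effect_measure": self.effect_measure,
            "sample_sizes": list(self.sample_sizes),
            **self.detail,
        }


def binom_test(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials vs p0.

    Two-sidedness by the minimum-likelihood rule: the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    res = sps.binomtest(int(k), int(n), float(p0), alternative="two-sided")
    return TestResult(
        test="binomial",
        statistic=float(k) / n if n else float("nan"),
        p_value=float(res.pvalue),
        sample_sizes=(int(n),),
        detail={"k": int(k), "p0": float(p0)},
    )


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-sided two-proportion z-test with pooled SE, no continuity
    correction: z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2))."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is 0 or 1: z undefined")
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return TestResult(
        test="two_prop_z",
        statistic=float(z),
        p_value=float(p),
        sample_sizes=(int(n1), int(n2)),
        detail={"k1": int(k1), "k2": int(k2), "pooled_p": pooled},
    )


def cohens_w(chi2: float, n_total: int) -> float:
    """Cohen's w effect size for chi-square tests: sqrt(chi2 / N)."""
    if n_total <= 0:
        raise ValueError("N must be positive")
    return float(np.sqrt(chi2 / n_total))


def chisq_test(observed, expected=None) -> TestResult:
    """Pearson chi-square test.

    With a 2D ``observed`` table: test of independence/homogeneity
    (no Yates correction).  With 1D ``observed`` and ``expected`` (counts
    or probabilities): goodness-of-fit, with Cohen's w attached.
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if obs.ndim == 2:
        chi2, p, dof, exp = sps.chi2_contingency(obs, correction=False)
        if np.any(exp <= 0):
            raise ValueError("zero expected cell")
        n = int(obs.sum())
        return TestResult(
            test="chisq_independence",
            statistic=float(chi2),
            p_value=float(p),
            effect_size=cohens_w(chi2, n),
            effect_measure="cohens_w",
            sample_sizes=(n,),
            detail={"dof": int(dof)},
        )
    if expected is None:
        raise ValueError("1D input needs expected counts or probabilities")
    exp = np.asarray(expected, dtype=float)
    if exp.shape != obs.shape:
        raise ValueError("observed and expected shapes differ")
    n = obs.sum()
    if not np.isclose(exp.sum(), n):
        exp = exp / exp.sum() * n  # probabilities -> expected counts
    if np.any(exp <= 0):
        raise ValueError("zero expected cell")
    chi2, p = sps.chisquare(obs, f_exp=exp)
    return TestResult(
        test="chisq_gof",
        statistic=float(chi2),
        p_value=float(p),
        effect_size=cohens_w(chi2, int(n)),
        effect_measure="cohens_w",
        sample_sizes=(int(n),),
        detail={"dof": int(obs.size - 1)},
    )


def effect_size(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> tuple[float, str]:
    """Standardized mean difference with the n-based measure rule.

    Cohen's d = (m1 - m2) / s_pooled; bias-corrected Hedges'
    g = d * (1 - 3 / (4(n1 + n2) - 9)) is used when the smaller group has
    n < 15.  Returns (value, measure name).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    s_pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("zero pooled SD")
    d = (m1 - m2) / s_pooled
    if min(n1, n2) < 15:
        g = d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))
        return float(g), "hedges_g"
    return float(d), "cohens_d"


def proportion_table(cells: pd.DataFrame, type_column: str = "type") -> pd.DataFrame:
    """Counts and nearest-integer percentages per hair-cell type.

    The three marker-positive categories (extrastriolar, striolar,
    intermediate) share the percentage denominator; double-negative cells
    are reported separately with a NaN percentage.
    """
    order = [TYPE_EXTRASTRIOLAR, TYPE_STRIOLAR, TYPE_INTERMEDIATE, TYPE_NEGATIVE]
    counts = {t: int((cells[type_column] == t).sum()) for t in order}
    n_typed = sum(counts[t] for t in order[:3])
    rows = []
    for t in order:
        if t == TYPE_NEGATIVE:
            pct = float("nan")
        else:
            pct = round(100.0 * counts[t] / n_typed) if n_typed else float("nan")
        rows.append({"type": t, "count": counts[t], "percent": pct})
    out = pd.DataFrame(rows)
    out.attrs["n_typed"] = n_typed
    out.attrs["n_total"] = int(len(cells))
    return out
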