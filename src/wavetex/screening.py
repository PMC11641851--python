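"""Univariate screening: normality checks and two-sample t-tests per feature.

The univariate stage compares each wavelet-texture variable between the
responder (pCR) and non-responder groups.  Normality is assessed with the
Kolmogorov–Smirnov statistic using the Lilliefors correction (the normal's
parameters are estimated from the sample, so the classical KS null table
would be anticonservative).  Group comparisons use the two-sample t-test;
the default is Welch's unequal-variance form, which reproduces the
published worked-example p-value from summary statistics, with the pooled
(classical Student) form available.

Screening is reporting-only: it ranks and flags features but does not gate
which features enter the multivariate discriminant stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .features import FeatureTable

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ks_normality",
    "ttest_from_summary",
    "ttest_raw",
    "univariate_screen",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def ks_normality(sample) -> dict[str, float]:
    """Lilliefors-corrected one-sample KS test against a fitted normal.

    Requires n >= 4 and non-degenerate data (zero-variance samples have no
    fitted normal to test against).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("ks_normality requires n >= 4")
    if np.std(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = lilliefors(x, dist="norm")
    return {"statistic": float(stat), "p": float(p)}


def ttest_from_summary(g1: GroupSummary, g2: GroupSummary,
                       variant: str = "welch") -> TTestResult:
    """Two-sample t-test from group means, SDs and sizes.

    Welch: ``t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2)`` with Satterthwaite
    degrees of freedom.  Pooled: classical equal-variance Student form with
    ``df = n1 + n2 - 2``.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    v1, v2 = g1.sd**2, g2.sd**2
    if variant == "welch":
        if v1 == 0 and v2 == 0:
            raise ValueError("both groups have zero variance")
        se2_1, se2_2 = v1 / g1.n, v2 / g2.n
        se2 = se2_1 + se2_2
        t = (g1.mean - g2.mean) / math.sqrt(se2)
        df = se2**2 / (se2_1**2 / (g1.n - 1) + se2_2**2 / (g2.n - 1))
    else:
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / (g1.n + g2.n - 2)
        if sp2 == 0:
            raise ValueError("pooled variance is zero")
        t = (g1.mean - g2.mean) / math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
        df = g1.n + g2.n - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), variant=variant)


def ttest_raw(x1, x2, variant: str = "welch") -> TTestResult:
    """Two-sample t-test on raw samples (defers to the summary form)."""
    return ttest_from_summary(GroupSummary.from_sample(x1),
                              GroupSummary.from_sample(x2), variant=variant)


def univariate_screen(table: FeatureTable, variant: str = "welch",
                      alpha: float = 0.05, near_alpha: float = 0.15) -> pd.DataFrame:
    """Per-feature two-sample comparison between the two label groups.

    Returns a DataFrame sorted by p-value with columns ``mean_pos``,
    ``sd_pos``, ``mean_neg``, ``sd_neg``, ``t``, ``df``, ``p``, ``tier``
    and Bonferroni-adjusted ``p_bonferroni`` (an optional extra, not part
    of the core screening convention).  ``tier`` is ``"significant"``
    (p <= ``alpha``), ``"near"`` (p <= ``near_alpha``), ``""`` otherwise,
    or ``"degenerate"`` for untestable zero-variance features.
    """
    y = table.labels
    n_pos, n_neg = table.class_counts()
    if n_pos < 2 or n_neg < 2:
        raise ValueError("both classes need >= 2 subjects for screening")
    m = len(table.features)
    rows = []
    for name in table.features:
        x = table.data[name].to_numpy(dtype=float)
        x1, x2 = x[y == 1], x[y == 0]
        g1, g2 = GroupSummary.from_sample(x1), GroupSummary.from_sample(x2)
        row = {
            "feature": name,
            "mean_pos": g1.mean, "sd_pos": g1.sd,
            "mean_neg": g2.mean, "sd_neg": g2.sd,
        }
        try:
            res = ttest_from_summary(g1, g2, variant=variant)
            row.update(t=res.t, df=res.df, p=res.p)
            if res.p <= alpha:
                row["tier"] = "significant"
            elif res.p <= near_alpha:
                row["tier"] = "near"
            else:
                row["tier"] = ""
        except ValueError:
            row.update(t=np.nan, df=np.nan, p=np.nan, tier="degenerate")
        rows.append(row)
    df = pd.DataFrame(rows).set_index("feature")
    df["p_bonferroni"] = np.minimum(df["p"] * m, 1.0)
    return df.sort_values("p", na_position="last")
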