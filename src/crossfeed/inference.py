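"""Predictions and group comparisons for exchange-ratio experiments.

Links a measured fold-change in one strain's exchange ratio (release rate
per consumption) to the predicted relative change in the partner's — and
the community's — steady-state growth rate, and provides the
variance-test-gated two-sample t-test used to compare exchange ratios or
growth rates between genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FoldChangeEstimate",
    "GroupComparison",
    "predict_partner_growth_change",
    "fold_change_ci",
    "compare_groups",
]


def predict_partner_growth_change(fold: float) -> float:
    """Relative change in the partner's steady-state growth rate when one
    strain's exchange ratio changes ``fold``-fold.

    The community steady-state growth rate is the geometric mean of the two
    strains' exchange ratios, so scaling one ratio by ``fold`` with the
    partner's ratio fixed scales the growth rate by sqrt(fold); the relative
    change is sqrt(fold) − 1 (e.g. fold 1.6 → +0.2649, i.e. about +26%).
    """
    if not fold > 0:
        raise ValueError("fold must be > 0")
    return float(np.sqrt(fold) - 1.0)


@dataclass(frozen=True)
class FoldChangeEstimate:
    """Fold-change between two replicate groups with a confidence interval."""

    point: float
    ci: tuple[float, float]
    level: float

    def predicted_partner_change(self) -> tuple[float, tuple[float, float]]:
        """Propagate to the predicted partner growth-rate change.

        sqrt is monotone, so applying the prediction to the CI endpoints
        yields a valid interval for the predicted change.
        """
        lo, hi = self.ci
        return (
            predict_partner_growth_change(self.point),
            (predict_partner_growth_change(lo), predict_partner_growth_change(hi)),
        )


def fold_change_ci(
    mutant_values: Sequence[float],
    ancestor_values: Sequence[float],
    level: float = 0.95,
) -> FoldChangeEstimate:
    """Fold-change of mutant over ancestor replicate measurements.

    Point estimate: ratio of group means.  Interval: Welch t-interval on
    the difference of log-means, exponentiated — appropriate for positive,
    roughly multiplicative measurement error.  Zero-variance groups give a
    degenerate interval equal to the point estimate.
    """
    m = np.asarray(mutant_values, float)
    a = np.asarray(ancestor_values, float)
    if len(m) < 2 or len(a) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.any(m <= 0) or np.any(a <= 0):
        raise ValueError("replicate values must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    point = float(m.mean() / a.mean())
    lm, la = np.log(m), np.log(a)
    diff = lm.mean() - la.mean()
    v1, v2 = lm.var(ddof=1) / len(m), la.var(ddof=1) / len(a)
    se = np.sqrt(v1 + v2)
    if se == 0:
        return FoldChangeEstimate(point, (point, point), level)
    # Welch–Satterthwaite degrees of freedom
    df = (v1 + v2) ** 2 / (v1**2 / (len(m) - 1) + v2**2 / (len(a) - 1))
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    lo, hi = np.exp(diff - tcrit * se), np.exp(diff + tcrit * se)
    return FoldChangeEstimate(point, (float(lo), float(hi)), level)


class GroupComparison(NamedTuple):
    p_value: float
    method: str  # "pooled" or "welch"
    variance_p: float


def compare_groups(
    x: Sequence[float], y: Sequence[float], alpha_var: float = 0.05
) -> GroupComparison:
    """Two-tailed two-sample t-test, pooled or Welch as an F-test decides.

    A two-sided F-test of variance equality at ``alpha_var`` gates the
    choice: if equality is not rejected, the classic pooled-variance t-test
    runs; otherwise Welch's unequal-variance t-test.  Returns the t-test
    p-value, which branch ran, and the F-test p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")

    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        # no within-group variability: identical means carry no evidence of
        # difference; different means are trivially separated
        p = 1.0 if x.mean() == y.mean() else 0.0
        return GroupComparison(p, "pooled", 1.0)
    F = vx / vy if vy > 0 else np.inf
    if np.isinf(F):
        p_var = 0.0
    else:
        cdf = stats.f.cdf(F, len(x) - 1, len(y) - 1)
        p_var = float(2 * min(cdf, 1 - cdf))
    if p_var < alpha_var:
        res = stats.ttest_ind(x, y, equal_var=False)
        return GroupComparison(float(res.pvalue), "welch", p_var)
    res = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(float(res.pvalue), "pooled", p_var)
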