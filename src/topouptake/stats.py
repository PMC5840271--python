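"""Time-series statistics for diagram coordinates and aggregate measures.

Two tests drive the analysis:

* Kruskal–Wallis on a coordinate grouped by hour — a rank-based screen
  for whether the coordinate changes over the study period at all;
* linear trend comparison — an ordinary-least-squares model
  ``value ~ hour + set + hour:set`` fitted to two pooled point sets, with
  a two-sided t-test on the interaction coefficient (the difference of
  the two slopes).

p-values are reported raw and categorized: not significant (p >= 0.05),
significant (0.01 <= p < 0.05), highly significant (p < 0.01).

Three qualitative properties summarize a method (a coordinate under a
normalization, or an aggregate measure):

(i)   it separates the two study groups' uptake trends directly;
(ii)  within a group, it separates high-region from low-region trends;
(iii) it separates the groups indirectly, by (ii) holding in exactly one
      group — a differential heterogeneity signature.

Diagram points are pooled across subjects within a group/hour cell and
treated as independent observations; within-subject correlation is
knowingly ignored (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TrendFit",
    "TrendComparison",
    "PropertyReport",
    "kruskal_wallis",
    "fit_linear_trend",
    "compare_trends",
    "significance_category",
    "evaluate_properties",
]

NOT_SIGNIFICANT = "ns"
SIGNIFICANT = "significant"
HIGHLY_SIGNIFICANT = "highly_significant"
DEGENERATE = "degenerate"


@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_se: float
    n: int

    @property
    def residual_df(self) -> int:
        return self.n - 2


@dataclass
class TrendComparison:
    slope_a: float
    slope_b: float
    slope_diff: float
    t_stat: float
    p_value: float
    category: str
    degenerate: bool = False


@dataclass
class PropertyReport:
    """Which of the three evaluation properties a method satisfies."""

    method: str
    property_i: bool  # between-group, all-region points
    property_i_any_region: bool  # between-group, any of all/high/low
    property_ii_group1: bool
    property_ii_group2: bool
    property_iii: bool
    p_values: dict = field(default_factory=dict)


def significance_category(p: float) -> str:
    """Categorize a p-value; boundary values fall in the less-significant class."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p >= 0.05:
        return NOT_SIGNIFICANT
    if p >= 0.01:
        return SIGNIFICANT
    return HIGHLY_SIGNIFICANT


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across >= 2 groups.

    Returns (nan, nan) for the degenerate all-identical case, where the
    rank statistic is undefined even after tie correction.
    """
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(s.size == 0 for s in samples):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return float("nan"), float("nan")
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def fit_linear_trend(points: np.ndarray) -> TrendFit:
    """OLS fit of value on hour for (hour, value) pairs."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (hour, value) pairs")
    hours, values = points[:, 0], points[:, 1]
    if np.unique(hours).size < 2:
        raise ValueError("trend fit needs at least 2 distinct hours")
    res = sps.linregress(hours, values)
    n = points.shape[0]
    se = float(res.stderr) if n >= 3 else float("nan")
    return TrendFit(slope=float(res.slope), intercept=float(res.intercept), slope_se=se, n=n)


def compare_trends(set_a: np.ndarray, set_b: np.ndarray) -> TrendComparison:
    """Compare the linear time trends of two point sets.

    Fits the pooled model value ~ hour + set + hour:set by OLS (set coded
    1 for ``set_a``) and tests the interaction coefficient — the slope
    difference slope_a - slope_b — with a two-sided t-test on the pooled
    residual variance.  Exact fits (zero residual variance) are flagged
    degenerate: the slope difference is still reported, the p-value is nan.
    """
    set_a = np.asarray(set_a, dtype=float)
    set_b = np.asarray(set_b, dtype=float)
    fit_a = fit_linear_trend(set_a)
    fit_b = fit_linear_trend(set_b)
    slope_diff = fit_a.slope - fit_b.slope

    hours = np.concatenate([set_a[:, 0], set_b[:, 0]])
    values = np.concatenate([set_a[:, 1], set_b[:, 1]])
    indicator = np.concatenate([np.ones(len(set_a)), np.zeros(len(set_b))])
    X = sm.add_constant(np.column_stack([hours, indicator, hours * indicator]))
    model = sm.OLS(values, X).fit()

    tss = float(np.sum((values - values.mean()) ** 2))
    if model.df_resid <= 0 or model.ssr <= 1e-12 * max(1.0, tss):
        return TrendComparison(
            slope_a=fit_a.slope,
            slope_b=fit_b.slope,
            slope_diff=slope_diff,
            t_stat=float("nan"),
            p_value=float("nan"),
            category=DEGENERATE,
            degenerate=True,
        )
    t_stat = float(model.tvalues[3])
    p = float(model.pvalues[3])
    return TrendComparison(
        slope_a=fit_a.slope,
        slope_b=fit_b.slope,
        slope_diff=slope_diff,
        t_stat=t_stat,
        p_value=p,
        category=significance_category(p),
    )


def _is_significant(comp: TrendComparison | None) -> bool:
    return comp is not None and not comp.degenerate and comp.category != NOT_SIGNIFICANT


def evaluate_properties(
    method: str,
    between_group: dict[str, TrendComparison],
    within_group: dict[str, TrendComparison],
) -> PropertyReport:
    """Assess the three evaluation properties from a method's trend comparisons.

    ``between_group`` maps region ("all"/"high"/"low") to the group-1 vs
    group-2 comparison; ``within_group`` maps group id ("1"/"2") to that
    group's high vs low comparison.  Property (i) is read on the
    all-region comparison (the any-region readout is also reported);
    property (iii) requires (ii) in exactly one group.
    """
    missing = [r for r in ("all",) if r not in between_group]
    missing += [g for g in ("1", "2") if g not in within_group]
    if missing:
        raise ValueError(f"missing trend comparisons for: {missing}")

    prop_i = _is_significant(between_group.get("all"))
    prop_i_any = any(_is_significant(c) for c in between_group.values())
    ii_1 = _is_significant(within_group["1"])
    ii_2 = _is_significant(within_group["2"])
    prop_iii = ii_1 != ii_2

    p_values = {f"between_{r}": c.p_value for r, c in between_group.items()}
    p_values.update({f"within_group{g}": c.p_value for g, c in within_group.items()})
    return PropertyReport(
        method=method,
        property_i=prop_i,
        property_i_any_region=prop_i_any,
        property_ii_group1=ii_1,
        property_ii_group2=ii_2,
        property_iii=prop_iii,
        p_values=p_values,
    )
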