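"""Descriptive series, trend classification and sensitivity checks.

Trend categories follow the doubling/halving-over-25-years convention:
an annual growth rate of 100*(2^(1/25) - 1) = 2.81 %/yr doubles abundance
over 25 years, and 100*(0.5^(1/25) - 1) = -2.73 %/yr halves it.  Trends
that are not statistically significant are "no change" regardless of
their point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError

#: Printed category thresholds on the annual growth rate (% per year).
STRONG_INCREASE = 2.81
MODERATE_INCREASE = 1.16
MODERATE_DECREASE = -1.14
STRONG_DECREASE = -2.73

CATEGORY_LABELS = (
    "strong increase",
    "moderate increase",
    "no change",
    "moderate decrease",
    "strong decrease",
)


@dataclass(frozen=True)
class TrendCategory:
    """Classification of one (AGR, p-value) pair.

    ``note`` flags a significant trend whose AGR sits inside the
    moderate band, which is still labelled "no change".
    """

    label: str
    note: str = ""
    alpha: float = 0.05


def classify_trend(
    agr: float,
    p_value: float,
    *,
    alpha: float = 0.05,
    strong_increase: float = STRONG_INCREASE,
    moderate_increase: float = MODERATE_INCREASE,
    moderate_decrease: float = MODERATE_DECREASE,
    strong_decrease: float = STRONG_DECREASE,
) -> TrendCategory:
    """Label a trend from its annual growth rate and significance.

    Insignificant trends (p > alpha) are "no change".  Significant trends:
    AGR >= 2.81 strong increase; 1.16 <= AGR < 2.81 moderate increase;
    -2.73 < AGR <= -1.14 moderate decrease; AGR <= -2.73 strong decrease.
    A significant AGR inside (-1.14, 1.16) is labelled "no change" with a
    significant-but-small note.  Exactly one label applies to any input.
    """
    if not math.isfinite(agr):
        raise UsageError("AGR must be finite")
    if not 0.0 <= p_value <= 1.0:
        raise UsageError("p-value must lie in [0, 1]")
    if p_value > alpha:
        return TrendCategory("no change", alpha=alpha)
    if agr >= strong_increase:
        return TrendCategory("strong increase", alpha=alpha)
    if agr >= moderate_increase:
        return TrendCategory("moderate increase", alpha=alpha)
    if agr <= strong_decrease:
        return TrendCategory("strong decrease", alpha=alpha)
    if agr <= moderate_decrease:
        return TrendCategory("moderate decrease", alpha=alpha)
    return TrendCategory(
        "no change", note="significant trend with small growth rate", alpha=alpha
    )


def doubling_threshold(horizon_years: float, *, halving: bool = False) -> float:
    """AGR (%/yr) that doubles (or halves) abundance over ``horizon_years``.

    Satisfies (1 + AGR/100)^horizon = 2 (resp. 0.5) exactly.
    """
    if horizon_years <= 0:
        raise UsageError("horizon must be >= 1 year")
    factor = 0.5 if halving else 2.0
    return 100.0 * (factor ** (1.0 / horizon_years) - 1.0)


def geometric_mean_series(
    totals: pd.DataFrame, *, by: str = "year", shift: float = 1.0
) -> pd.Series:
    """Shifted geometric mean abundance per year.

    value_t = exp(mean(ln(x + shift))) - shift over the sample totals of
    year t.  The shift (default 1) keeps years with zero counts finite;
    an unshifted geometric mean collapses to zero whenever any sample
    lacks the group.  Years with no samples are absent, not zero.  The
    result never exceeds the arithmetic mean (AM-GM on shifted values).
    """
    if "count" not in totals.columns or by not in totals.columns:
        raise UsageError(f"totals need 'count' and {by!r} columns")
    x = totals["count"].to_numpy(dtype=float)
    if (x < 0).any():
        raise UsageError("counts must be non-negative")
    logs = np.log(x + shift)
    out = (
        pd.Series(logs, index=totals[by].to_numpy())
        .groupby(level=0)
        .mean()
        .pipe(lambda s: np.exp(s) - shift)
    )
    out.index.name = by
    return out


def sensitivity_correlation(
    trends_a: pd.Series, trends_b: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of paired slope estimates from two filter settings.

    Aligns the two series on their shared units (e.g. families present under
    both the 3-year and 10-year minimum-coverage rules) and returns (r, p).
    Fewer than 3 finite shared pairs raises :class:`UsageError`.
    """
    joined = pd.concat(
        {"a": trends_a, "b": trends_b}, axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise UsageError(
            f"need >= 3 shared units with finite slopes, got {len(joined)}"
        )
    r, p = stats.pearsonr(joined["a"], joined["b"])
    return float(r), float(p)
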