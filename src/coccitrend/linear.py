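"""Simple-linear-regression trends in captures per trap, with percent-change
summaries over the full series and fixed dynamical phases.

Percent change over a window is computed from the fitted line's endpoints:
``100 * (yhat(end) - yhat(start)) / yhat(start)``; percent change per year
divides by the inclusive year count of the window (31 for 1993-2023, 8 for
2016-2023).  The window phases are fixed inputs tied to the invasion history
of the community, not estimated breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The four fixed dynamical phases: establishment of the dominant exotic
#: (I), soybean-aphid invasion and outbreak (II), stabilization under
#: widespread aphid management (III), and the recent inflection (IV).
@dataclass(frozen=True)
class PhaseDefinition:
    label: str
    start_year: int
    end_year: int  # inclusive

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


STUDY_PHASES: tuple[PhaseDefinition, ...] = (
    PhaseDefinition("I", 1993, 2000),
    PhaseDefinition("II", 2001, 2005),
    PhaseDefinition("III", 2006, 2015),
    PhaseDefinition("IV", 2016, 2023),
)


@dataclass(frozen=True)
class TrendFit:
    """OLS line through (year, captures-per-trap) points with window summaries.

    ``pct_change_total`` is undefined (None, flagged) when the fitted value
    at the window start is non-positive.
    """

    label: str
    slope: float            # captures/trap/year
    intercept: float
    slope_se: float
    p_value: float
    window: tuple[int, int]  # inclusive year range
    n_points: int
    mean_rate: float        # mean captures per trap over the window's points
    pct_change_total: float | None
    pct_change_per_year: float | None
    significant: bool       # two-sided, alpha = 0.05
    pct_defined: bool

    def predicted(self, year) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(year, float)


def percent_change_per_year(pct_change_total: float, window: tuple[int, int]) -> float:
    """Total percent change divided by the window's inclusive year count.

    E.g. -76.6% over 1993-2023 (31 years) -> -2.47.../yr, reported as -2.5
    at one decimal place; -62.9% over 2016-2023 (8 years) -> -7.9/yr.
    """
    start, end = window
    n_years = end - start + 1
    if n_years < 1:
        raise ValueError("window must contain at least one year")
    return pct_change_total / n_years


def fit_slr(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    label: str = "overall",
    window: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> TrendFit:
    """Ordinary least-squares line through (year, captures_per_trap) points.

    Requires >= 3 points over >= 2 distinct years; the slope p-value is the
    two-sided t-test.  ``window`` defaults to the data's year range; fitted
    endpoints of that window define the percent-change summaries.
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(float)
        y = points.iloc[:, 1].to_numpy(float)
    else:
        arr = np.asarray(points, float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate design: all years identical")

    res = stats.linregress(x, y)
    if window is None:
        window = (int(np.min(x)), int(np.max(x)))
    start, end = window
    y0 = res.intercept + res.slope * start
    y1 = res.intercept + res.slope * end
    if y0 > 0:
        pct_total = 100.0 * (y1 - y0) / y0
        pct_year = percent_change_per_year(pct_total, window)
        defined = True
    else:
        pct_total = pct_year = None
        defined = False
    return TrendFit(
        label=label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        p_value=float(res.pvalue),
        window=(start, end),
        n_points=len(x),
        mean_rate=float(np.mean(y)),
        pct_change_total=pct_total,
        pct_change_per_year=pct_year,
        significant=bool(res.pvalue < alpha),
        pct_defined=defined,
    )


def phase_analysis(
    series: pd.DataFrame,
    phases: Sequence[PhaseDefinition] = STUDY_PHASES,
    alpha: float = 0.05,
) -> list[TrendFit]:
    """Whole-series SLR plus one SLR per dynamical phase.

    ``series`` needs columns ``year``, ``response``, ``effort``; the fitted
    response is captures per trap (response/effort), units with zero effort
    dropped.  A phase covering fewer than 3 yearly values is skipped with a
    warning.  Slope-derived percent changes are populated for every fit;
    the ``significant`` flag marks which ones are reportable.
    """
    df = series[series["effort"] > 0]
    pts = pd.DataFrame({"year": df["year"], "rate": df["response"] / df["effort"]})
    fits = [fit_slr(pts, label="overall", alpha=alpha)]
    for ph in phases:
        sub = pts[(pts["year"] >= ph.start_year) & (pts["year"] <= ph.end_year)]
        if sub["year"].nunique() < 3:
            warnings.warn(
                f"phase {ph.label} ({ph.start_year}-{ph.end_year}) has fewer than "
                "3 yearly values; skipped"
            )
            continue
        fits.append(
            fit_slr(sub, label=ph.label, window=(ph.start_year, ph.end_year), alpha=alpha)
        )
    return fits


def trend_table(fits: Sequence[TrendFit], group: str) -> pd.DataFrame:
    """Summary table: one row per fit with 1-dp reported percent changes."""
    rows = []
    for f in fits:
        rows.append(
            {
                "group": group,
                "window": f"{f.window[0]}-{f.window[1]}",
                "label": f.label,
                "n_points": f.n_points,
                "mean_rate": f.mean_rate,
                "slope": f.slope,
                "p_value": f.p_value,
                "significant": f.significant,
                "pct_change_total": None if f.pct_change_total is None else round(f.pct_change_total, 1),
                "pct_change_per_year": None if f.pct_change_per_year is None else round(f.pct_change_per_year, 1),
            }
        )
    return pd.DataFrame(rows)
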