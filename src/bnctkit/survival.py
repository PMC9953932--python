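"""Kaplan–Meier estimation, log-rank testing and percent increased lifespan.

Per-subject times-to-event (days post-implantation; death or euthanasia
counted as the event, censoring flag 0 otherwise) are grouped by treatment
arm.  The Kaplan–Meier product-limit estimator gives each arm's survival
curve; the median survival time (MST) is the first time at which the curve
reaches 0.5 or below, with a Brookmeyer–Crowley-style CI obtained by
inverting the pointwise confidence band.  Treatment effect is quantified by

    %ILS = (MST_treated - MST_untreated) * 100 / MST_untreated

and pairwise significance by the two-group log-rank test (chi-square with
one degree of freedom; unadjusted for multiplicity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times

__all__ = [
    "KMEstimate",
    "km_fit",
    "logrank",
    "pct_ils",
    "survival_report",
]

EVENT_COLUMNS = ["subject", "arm", "time_days", "event"]


@dataclass
class KMEstimate:
    """Kaplan–Meier fit of one cohort."""

    timeline: np.ndarray
    survival: np.ndarray  # S(t) at each timeline point, step function
    median: float  # inf when the curve never reaches 0.5
    median_ci: Tuple[float, float]
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return math.isfinite(self.median)


def _check_times_events(times: np.ndarray, events: np.ndarray) -> None:
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")


def km_fit(times: Sequence[float], events: Optional[Sequence[int]] = None) -> KMEstimate:
    """Product-limit estimator; all-event data when ``events`` is omitted.

    The median is the first time t with S(t) <= 0.5; with every subject
    censored it is undefined and reported as ``inf`` (flagged by
    :attr:`KMEstimate.median_defined`).
    """
    t = np.asarray(times, dtype=float)
    e = np.ones_like(t, dtype=int) if events is None else np.asarray(events, dtype=int)
    _check_times_events(t, e)
    if e.sum() == 0:
        raise ValueError("at least one event is required")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMEstimate(
        timeline=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank(
    times_a: Sequence[float],
    times_b: Sequence[float],
    events_a: Optional[Sequence[int]] = None,
    events_b: Optional[Sequence[int]] = None,
) -> Tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, two-sided p).

    Ties are handled by simultaneous risk-set accounting at each distinct
    event time.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.ones_like(ta, dtype=int) if events_a is None else np.asarray(events_a, dtype=int)
    eb = np.ones_like(tb, dtype=int) if events_b is None else np.asarray(events_b, dtype=int)
    _check_times_events(ta, ea)
    _check_times_events(tb, eb)
    if len(ta) < 2 or len(tb) < 2:
        raise ValueError("each arm needs at least 2 subjects")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either arm")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def pct_ils(mst_treated: float, mst_untreated: float) -> float:
    """Percent increased lifespan relative to the untreated arm.

    (MST_treated − MST_untreated) × 100 / MST_untreated, unrounded; reports
    round to one decimal.
    """
    if mst_untreated <= 0:
        raise ValueError("untreated MST must be positive")
    if mst_treated < 0:
        raise ValueError("treated MST must be non-negative")
    return (mst_treated - mst_untreated) * 100.0 / mst_untreated


def survival_report(df: pd.DataFrame, reference: str = "Untreated") -> pd.DataFrame:
    """Arm-level table: n, events, MST with 95% CI, %ILS and log-rank p.

    ``df`` has columns ``subject, arm, time_days, event``.  %ILS and the
    pairwise (unadjusted) log-rank p-value are computed against the
    ``reference`` arm; the reference row carries NaN for both.  Arm order
    follows first appearance; values are invariant to row order.
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    arms = list(dict.fromkeys(df["arm"]))
    if reference not in arms:
        raise ValueError(f"reference arm {reference!r} not present")

    def arm_data(name: str) -> Tuple[np.ndarray, np.ndarray]:
        sub = df[df["arm"] == name]
        return sub["time_days"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=int)

    ref_t, ref_e = arm_data(reference)
    ref_fit = km_fit(ref_t, ref_e)
    rows = []
    for name in sorted(arms, key=lambda a: (a != reference, arms.index(a))):
        t, e = arm_data(name)
        fit = km_fit(t, e)
        if name == reference:
            ils = math.nan
            p = math.nan
        else:
            ils = round(pct_ils(fit.median, ref_fit.median), 1)
            _, p = logrank(t, ref_t, e, ref_e)
        rows.append(
            {
                "arm": name,
                "n": fit.n,
                "events": fit.n_events,
                "mst_days": fit.median,
                "mst_ci_low": fit.median_ci[0],
                "mst_ci_high": fit.median_ci[1],
                "pct_ils": ils,
                "logrank_p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)
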