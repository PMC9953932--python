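"""Boron biodistribution summaries, tumor ratios and uptake comparisons.

Per-animal organ boron concentrations (μg B/g, ICP-AES) are summarized to
group mean ± SD; the tumor-to-brain (T/Br) and tumor-to-blood (T/Bl) ratios
are ratios of the unrounded group means.  Cellular uptake is normalized to
μg B per 10⁹ cells and compared between compounds with a two-sample
Student's t-test (pooled variance; Welch available behind a flag).

The weight-based unit μg B/g is numerically equivalent to parts-per-million
(ppm); no conversion is performed.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ORGANS",
    "summarize",
    "tumor_ratios",
    "ratio_table",
    "normalize_uptake",
    "compare_uptake",
]

ORGANS = (
    "tumor",
    "brain",
    "blood",
    "heart",
    "lung",
    "liver",
    "kidney",
    "spleen",
    "skin",
    "muscle",
)

MEASUREMENT_COLUMNS = ["subject", "compound", "route", "time_h", "organ", "boron_ug_per_g"]
GROUP_KEYS = ["compound", "route", "time_h", "organ"]


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if df.empty:
        raise ValueError("no measurements")
    bad_organs = set(df["organ"]) - set(ORGANS)
    if bad_organs:
        raise ValueError(f"unknown organs: {sorted(bad_organs)}")
    if (df["boron_ug_per_g"] < 0).any():
        raise ValueError("boron concentrations must be non-negative")
    if (df["time_h"] < 0).any():
        raise ValueError("time_h must be non-negative")


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Group mean and sample SD (n−1) per compound/route/time/organ.

    A single-animal group gets sd = 0.
    """
    _validate(df)
    out = (
        df.groupby(GROUP_KEYS, sort=False)["boron_ug_per_g"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def tumor_ratios(
    tumor_mean: float, brain_mean: float, blood_mean: float
) -> Tuple[float, float]:
    """(T/Br, T/Bl): tumor mean over brain mean and over blood mean.

    Computed from unrounded group means; display rounding is the caller's
    concern.
    """
    if brain_mean <= 0 or blood_mean <= 0:
        raise ValueError("brain and blood means must be positive")
    if tumor_mean < 0:
        raise ValueError("tumor mean must be non-negative")
    return tumor_mean / brain_mean, tumor_mean / blood_mean


def ratio_table(summary: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Wide per-group table: tumor/brain/blood means ± SD plus T/Br, T/Bl.

    One row per (compound, route, time_h); concentrations and ratios are
    rounded to ``decimals`` for display, with the ratios computed from the
    unrounded means.  Groups missing any of tumor/brain/blood are skipped.
    """
    rows = []
    for (compound, route, time_h), grp in summary.groupby(
        ["compound", "route", "time_h"], sort=False
    ):
        by_organ = grp.set_index("organ")
        if not {"tumor", "brain", "blood"} <= set(by_organ.index):
            continue
        t_br, t_bl = tumor_ratios(
            by_organ.loc["tumor", "mean"],
            by_organ.loc["brain", "mean"],
            by_organ.loc["blood", "mean"],
        )
        row = {"compound": compound, "route": route, "time_h": time_h,
               "n": int(by_organ.loc["tumor", "n"])}
        for organ in ("tumor", "brain", "blood"):
            row[organ] = round(by_organ.loc[organ, "mean"], decimals)
            row[f"{organ}_sd"] = round(by_organ.loc[organ, "sd"], decimals)
        row["t_br"] = round(t_br, decimals)
        row["t_bl"] = round(t_bl, decimals)
        rows.append(row)
    if not rows:
        raise ValueError("no group contains tumor, brain and blood measurements")
    return pd.DataFrame(rows)


def normalize_uptake(boron_ug: float, n_cells: float) -> float:
    """Cellular uptake normalized to μg B per 10⁹ cells."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if boron_ug < 0:
        raise ValueError("boron_ug must be non-negative")
    return boron_ug / n_cells * 1e9


def compare_uptake(
    group_a: Iterable[float],
    group_b: Iterable[float],
    welch: bool = False,
) -> Tuple[float, float]:
    """Two-sample t-test on normalized uptakes: (t statistic, two-sided p).

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        # Degenerate but well-defined: identical constant groups differ by 0.
        return 0.0, 1.0
    if not welch and np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
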