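"""Relative gene expression by the 2^-ΔΔCT method.

For each subject, qPCR cycle thresholds of a target gene and a reference
gene are measured in tumor and in normal (calibrator) tissue:

    ΔCT_tumor  = CT_target,tumor  - CT_ref,tumor
    ΔCT_normal = CT_target,normal - CT_ref,normal
    ΔΔCT       = ΔCT_tumor - ΔCT_normal
    fold       = 2 ** (-ΔΔCT)

Ideal doubling per cycle is assumed (no amplification-efficiency
correction).  Cohort summaries default to the arithmetic mean of the
per-subject folds with a nearest-integer headline; a geometric mean is
available since fold-changes are ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Sequence, Union

import pandas as pd

__all__ = [
    "ExpressionSample",
    "FoldSummary",
    "fold_change",
    "summarize_folds",
    "cohort_fold_summary",
    "folds_from_table",
]

CT_MAX = 45.0


@dataclass(frozen=True)
class ExpressionSample:
    """CT quadruple (target/reference × tumor/normal) for one subject."""

    subject: str
    ct_target_tumor: float
    ct_ref_tumor: float
    ct_target_normal: float
    ct_ref_normal: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_tumor",
            "ct_ref_tumor",
            "ct_target_normal",
            "ct_ref_normal",
        ):
            ct = getattr(self, name)
            if not 0.0 < ct <= CT_MAX:
                raise ValueError(f"{name} = {ct} outside (0, {CT_MAX}]")


def fold_change(sample: ExpressionSample) -> float:
    """2^-ΔΔCT fold-change of the target in tumor relative to normal tissue."""
    ddct = (sample.ct_target_tumor - sample.ct_ref_tumor) - (
        sample.ct_target_normal - sample.ct_ref_normal
    )
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class FoldSummary:
    folds: Sequence[float]
    mean: float
    geometric_mean: float
    headline: int  # nearest-integer fold for the arithmetic or chosen mean


def summarize_folds(
    folds: Iterable[float],
    method: Literal["arithmetic", "geometric"] = "arithmetic",
) -> FoldSummary:
    """Cohort fold summary from per-subject fold-changes."""
    vals = [float(f) for f in folds]
    if not vals:
        raise ValueError("no folds")
    if any(f <= 0 for f in vals):
        raise ValueError("folds must be positive")
    mean = sum(vals) / len(vals)
    gmean = math.exp(sum(math.log(f) for f in vals) / len(vals))
    headline = round(mean if method == "arithmetic" else gmean)
    return FoldSummary(folds=tuple(vals), mean=mean, geometric_mean=gmean, headline=headline)


def cohort_fold_summary(
    samples: Union[Iterable[ExpressionSample], Iterable[float]],
    method: Literal["arithmetic", "geometric"] = "arithmetic",
) -> FoldSummary:
    """Summary over a cohort of CT quadruples (or precomputed folds)."""
    items = list(samples)
    if items and isinstance(items[0], ExpressionSample):
        folds = [fold_change(s) for s in items]  # type: ignore[arg-type]
    else:
        folds = [float(f) for f in items]  # type: ignore[arg-type]
    return summarize_folds(folds, method=method)


def folds_from_table(
    df: pd.DataFrame, target: str, reference: str
) -> List[ExpressionSample]:
    """Build per-subject samples from a long CT table.

    Expected columns: ``subject, gene, tissue, ct`` with tissue in
    {tumor, normal} and gene naming the target and reference assays.
    """
    for col in ("subject", "gene", "tissue", "ct"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    samples = []
    for subject, grp in df.groupby("subject", sort=False):
        cts: Dict[tuple, float] = {}
        for _, row in grp.iterrows():
            cts[(row["gene"], row["tissue"])] = float(row["ct"])
        try:
            samples.append(
                ExpressionSample(
                    subject=str(subject),
                    ct_target_tumor=cts[(target, "tumor")],
                    ct_ref_tumor=cts[(reference, "tumor")],
                    ct_target_normal=cts[(target, "normal")],
                    ct_ref_normal=cts[(reference, "normal")],
                )
            )
        except KeyError as exc:
            raise ValueError(f"subject {subject!r} is missing CT for {exc.args[0]}") from None
    return samples
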