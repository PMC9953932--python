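"""Linear-quadratic survival fitting and CBE / beam-RBE estimation.

Clonogenic surviving fractions follow the linear-quadratic (LQ) model

    SF(D) = exp(-alpha * D - beta * D**2)

fitted here by (optionally weighted) least squares on ln SF with the
non-negativity constraint alpha, beta >= 0.  The reference X-ray curve
fixes the photon iso-effect dose at a chosen survival level (SF = 0.1 by
convention).  For a neutron irradiation with absorbed components
(D_B, D_N, D_H, D_γ) at its own iso-effect point, the photon-equivalent
equation

    lq_iso = CBE * D_B + RBE_beam * (D_N + D_H) + D_γ

is inverted to estimate the beam RBE (boron-free condition, gamma credited
at weight one) and the compound biological effectiveness of each boron
carrier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .dosimetry import DoseComponents

__all__ = [
    "LQParams",
    "EffectivenessEstimates",
    "colony_sf",
    "fit_lq",
    "dose_at_sf",
    "survival_at",
    "curve_iso_dose",
    "estimate_rbe_beam",
    "estimate_cbe",
    "analyze_clonogenic",
    "bootstrap_effectiveness",
]

CLONOGENIC_COLUMNS = [
    "condition",
    "replicate",
    "dose_gy",
    "d_b_gy",
    "d_n_gy",
    "d_h_gy",
    "d_gamma_gy",
    "colonies_treated",
    "colonies_control",
]


@dataclass(frozen=True)
class LQParams:
    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


def colony_sf(
    treated_colonies: float,
    control_colonies: float,
    zero_policy: Literal["error", "floor"] = "error",
) -> float:
    """Surviving fraction = treated colonies / control colonies.

    Values above 1 warn and clip to 1.  A zero treated count cannot enter a
    log-scale fit; by default it raises, with ``zero_policy='floor'`` it is
    replaced by half a colony (0.5 / control).
    """
    if control_colonies <= 0:
        raise ValueError("control colony count must be positive")
    if treated_colonies < 0:
        raise ValueError("treated colony count must be non-negative")
    if treated_colonies == 0:
        if zero_policy == "floor":
            return 0.5 / control_colonies
        raise ValueError(
            "zero treated colonies gives SF = 0; use zero_policy='floor' to "
            "substitute half a colony"
        )
    sf = treated_colonies / control_colonies
    if sf > 1.0:
        warnings.warn(f"surviving fraction {sf:.3g} > 1 clipped to 1", stacklevel=2)
        sf = 1.0
    return sf


def fit_lq(
    dose: np.ndarray,
    sf: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> LQParams:
    """Fit SF = exp(-aD - bD²) by non-negative least squares on ln SF.

    ``weights`` (e.g. colony counts) multiply the squared residuals.
    Requires at least 3 points and at least 2 distinct positive doses.
    """
    dose = np.asarray(dose, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if dose.shape != sf.shape or dose.ndim != 1:
        raise ValueError("dose and sf must be 1-D arrays of equal length")
    if len(dose) < 3:
        raise ValueError("at least 3 points are required to fit the LQ model")
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    if np.any((sf <= 0) | (sf > 1)):
        raise ValueError("surviving fractions must lie in (0, 1]")
    if len(np.unique(dose[dose > 0])) < 2:
        raise ValueError("at least 2 distinct positive doses are required")
    design = np.column_stack([dose, dose**2])
    y = -np.log(sf)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        design = design * w[:, None]
        y = y * w
    coef, _ = nnls(design, y)
    return LQParams(alpha=float(coef[0]), beta=float(coef[1]))


def survival_at(params: LQParams, dose: float) -> float:
    """LQ surviving fraction at ``dose`` (Gy)."""
    return math.exp(-params.alpha * dose - params.beta * dose**2)


def dose_at_sf(params: LQParams, sf_level: float = 0.1) -> float:
    """Dose (Gy) at which the fitted LQ curve reaches ``sf_level``.

    Positive root of beta·D² + alpha·D + ln(sf_level) = 0.
    """
    if not 0.0 < sf_level < 1.0:
        raise ValueError("sf_level must lie in (0, 1)")
    if params.alpha == 0 and params.beta == 0:
        raise ValueError("alpha = beta = 0: the curve never reaches sf_level")
    kill = -math.log(sf_level)  # > 0
    # stable form of the positive quadratic root (no cancellation as beta -> 0)
    disc = params.alpha**2 + 4.0 * params.beta * kill
    return 2.0 * kill / (params.alpha + math.sqrt(disc))


def curve_iso_dose(
    dose: np.ndarray,
    sf: np.ndarray,
    sf_level: float = 0.1,
    method: Literal["lq", "loglinear"] = "lq",
    smooth_nonmonotone: bool = True,
) -> float:
    """Iso-effect absorbed dose of a measured survival curve.

    ``method='lq'`` fits the LQ model to the curve and inverts it (the
    default; allows mild extrapolation through the model).  With
    ``method='loglinear'`` ln SF is linearly interpolated between measured
    points; the level must then be bracketed by the observations, and a
    non-monotone curve is warned about and pre-smoothed by (antitonic)
    isotonic regression when ``smooth_nonmonotone`` is true.
    """
    dose = np.asarray(dose, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if method == "lq":
        return dose_at_sf(fit_lq(dose, sf), sf_level)
    if method != "loglinear":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(dose)
    d = dose[order]
    log_sf = np.log(sf[order])
    if np.any(np.diff(log_sf) > 0):
        warnings.warn("survival curve is not monotone decreasing", stacklevel=2)
        if smooth_nonmonotone:
            from sklearn.isotonic import IsotonicRegression

            log_sf = IsotonicRegression(increasing=False).fit_transform(d, log_sf)
        else:
            raise ValueError("non-monotone curve and smoothing disabled")
    target = math.log(sf_level)
    if not (log_sf.min() <= target <= log_sf.max()):
        raise ValueError(
            f"sf_level {sf_level} is outside the observed range; extrapolation "
            "is disabled for log-linear interpolation"
        )
    # np.interp needs increasing x; ln SF decreases with dose.
    return float(np.interp(target, log_sf[::-1], d[::-1]))


def estimate_rbe_beam(lq_iso: float, beam_iso_components: DoseComponents) -> float:
    """Beam RBE from the boron-free iso-effect condition.

    The gamma dose is credited at weight one and subtracted from the photon
    requirement: RBE_beam = (lq_iso - D_γ) / (D_N + D_H).
    """
    if beam_iso_components.d_b != 0:
        raise ValueError("beam-only components must have d_b = 0")
    denom = beam_iso_components.d_n + beam_iso_components.d_h
    if denom <= 0:
        raise ValueError("d_n + d_h must be positive for the beam-only condition")
    numer = lq_iso - beam_iso_components.d_gamma
    if numer <= 0:
        raise ValueError("gamma dose exceeds the photon iso-effect dose")
    return numer / denom


def estimate_cbe(
    lq_iso: float,
    compound_iso_components: DoseComponents,
    rbe_beam: float,
) -> float:
    """CBE by inverting the photon-equivalent equation at the iso-effect point.

    CBE = (lq_iso - RBE_beam·(D_N + D_H) - D_γ) / D_B.
    """
    c = compound_iso_components
    if c.d_b <= 0:
        raise ValueError("d_b must be positive to estimate a CBE")
    numer = lq_iso - rbe_beam * (c.d_n + c.d_h) - c.d_gamma
    if numer <= 0:
        raise ValueError(
            "non-boron photon-equivalent dose exceeds the photon iso-effect "
            "dose; inputs are inconsistent"
        )
    return numer / c.d_b


@dataclass
class EffectivenessEstimates:
    """Fitted LQ parameters, iso-effect doses, beam RBE and per-compound CBE."""

    lq: LQParams
    lq_iso: float
    sf_level: float
    iso_doses: Dict[str, float]
    rbe_beam: float
    cbe_by_compound: Dict[str, float]
    lq_by_condition: Dict[str, LQParams] = field(default_factory=dict)


def _condition_fractions(group: pd.DataFrame) -> np.ndarray:
    """Component fractions (b, n, h, gamma) of the absorbed dose, pooled."""
    total = group["dose_gy"].sum()
    if total <= 0:
        raise ValueError("condition has no positive absorbed dose")
    frac = (
        np.array(
            [
                group["d_b_gy"].sum(),
                group["d_n_gy"].sum(),
                group["d_h_gy"].sum(),
                group["d_gamma_gy"].sum(),
            ]
        )
        / total
    )
    if not math.isclose(frac.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("dose components do not sum to the absorbed dose")
    return frac


def analyze_clonogenic(
    df: pd.DataFrame,
    sf_level: float = 0.1,
    xray_label: str = "X-ray",
    beam_label: str = "Neutron only",
    zero_policy: Literal["error", "floor"] = "error",
    weighted: bool = False,
) -> EffectivenessEstimates:
    """Full clonogenic analysis of a long-format colony-count table.

    Expected columns: ``condition, replicate, dose_gy, d_b_gy, d_n_gy,
    d_h_gy, d_gamma_gy, colonies_treated, colonies_control``.  The X-ray
    condition defines the photon LQ reference; the beam-only condition
    (zero boron) yields RBE_beam; every remaining condition yields a CBE.
    Component doses at each condition's iso-effect point are obtained by
    scaling the condition's pooled component fractions to the estimated
    iso-dose.
    """
    missing = [c for c in CLONOGENIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for label in (xray_label, beam_label):
        if label not in set(df["condition"]):
            raise ValueError(f"condition {label!r} not present in the data")

    sf = df.apply(
        lambda r: colony_sf(r["colonies_treated"], r["colonies_control"], zero_policy),
        axis=1,
    ).to_numpy()
    work = df.assign(sf=sf)
    weights_of = (
        (lambda g: g["colonies_treated"].to_numpy()) if weighted else (lambda g: None)
    )

    xray = work[work["condition"] == xray_label]
    lq = fit_lq(xray["dose_gy"].to_numpy(), xray["sf"].to_numpy(), weights_of(xray))
    lq_iso = dose_at_sf(lq, sf_level)

    iso_doses: Dict[str, float] = {}
    lq_by_condition: Dict[str, LQParams] = {xray_label: lq}
    fractions: Dict[str, np.ndarray] = {}
    for label, group in work.groupby("condition", sort=False):
        if label == xray_label:
            continue
        params = fit_lq(group["dose_gy"].to_numpy(), group["sf"].to_numpy(), weights_of(group))
        lq_by_condition[label] = params
        iso_doses[label] = dose_at_sf(params, sf_level)
        fractions[label] = _condition_fractions(group)

    def components_at_iso(label: str) -> DoseComponents:
        f = fractions[label] * iso_doses[label]
        return DoseComponents(d_b=f[0], d_n=f[1], d_h=f[2], d_gamma=f[3])

    beam_comps = components_at_iso(beam_label)
    if beam_comps.d_b > 1e-12 * iso_doses[beam_label]:
        raise ValueError(f"beam condition {beam_label!r} carries a boron dose")
    beam_comps = DoseComponents(0.0, beam_comps.d_n, beam_comps.d_h, beam_comps.d_gamma)
    rbe_beam = estimate_rbe_beam(lq_iso, beam_comps)

    cbe: Dict[str, float] = {}
    for label in iso_doses:
        if label == beam_label:
            continue
        cbe[label] = estimate_cbe(lq_iso, components_at_iso(label), rbe_beam)

    return EffectivenessEstimates(
        lq=lq,
        lq_iso=lq_iso,
        sf_level=sf_level,
        iso_doses=iso_doses,
        rbe_beam=rbe_beam,
        cbe_by_compound=cbe,
        lq_by_condition=lq_by_condition,
    )


def bootstrap_effectiveness(
    df: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    sf_level: float = 0.1,
    xray_label: str = "X-ray",
    beam_label: str = "Neutron only",
    ci: float = 0.95,
) -> Dict[str, Dict[str, tuple]]:
    """Percentile bootstrap CIs for iso-doses, RBE_beam and CBEs.

    Parametric bootstrap on the counting noise: treated and control colony
    counts are redrawn Poisson around the observed counts, the full
    analysis is re-run, and percentile intervals are formed.  Replicates in
    which the analysis fails (e.g. a resampled curve too flat to invert)
    are skipped and reported.
    """
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 50 * (1 - ci), 50 * (1 + ci)
    samples: Dict[str, list] = {}
    failures = 0
    for _ in range(n_boot):
        boot = df.copy()
        boot["colonies_treated"] = rng.poisson(df["colonies_treated"].to_numpy())
        boot["colonies_control"] = np.maximum(
            rng.poisson(df["colonies_control"].to_numpy()), 1
        )
        try:
            est = analyze_clonogenic(
                boot, sf_level, xray_label, beam_label, zero_policy="floor"
            )
        except ValueError:
            failures += 1
            continue
        samples.setdefault("lq_iso", []).append(est.lq_iso)
        samples.setdefault("rbe_beam", []).append(est.rbe_beam)
        for k, v in est.iso_doses.items():
            samples.setdefault(f"iso:{k}", []).append(v)
        for k, v in est.cbe_by_compound.items():
            samples.setdefault(f"cbe:{k}", []).append(v)
    out: Dict[str, Dict[str, tuple]] = {"_meta": {"n_boot": n_boot, "failures": failures}}
    for key, values in samples.items():
        arr = np.asarray(values)
        out[key] = {
            "ci": (float(np.percentile(arr, lo_q)), float(np.percentile(arr, hi_q))),
            "median": float(np.median(arr)),
        }
    return out
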