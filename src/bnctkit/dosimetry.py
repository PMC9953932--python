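"""Four-component BNCT dosimetry.

The absorbed dose delivered during boron neutron capture therapy is the sum
of four components:

* ``D_B`` — the boron dose from the ¹⁰B(n,α)⁷Li capture reaction, proportional
  to the tissue ¹⁰B concentration and the thermal neutron fluence,
* ``D_N`` — the nitrogen dose from ¹⁴N(n,p)¹⁴C, proportional to the tissue
  nitrogen weight fraction and the thermal fluence,
* ``D_H`` — the hydrogen recoil dose from elastic scattering of epithermal
  and fast neutrons,
* ``D_γ`` — the gamma dose (beam contamination plus capture gammas).

The boron and nitrogen components are computed from thermal-neutron kerma
coefficients; the hydrogen and gamma components depend on the beam spectrum
and are taken as pre-computed inputs.  The photon-equivalent (Gy-Eq) dose
weights each component by its biological effectiveness: the compound
biological effectiveness (CBE) for boron and the beam RBE for the nitrogen
and hydrogen recoil components, with gamma at weight one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "KermaConstants",
    "BeamExposure",
    "TissueComposition",
    "DoseComponents",
    "RBEWeights",
    "CEDParams",
    "MissingCBEError",
    "boron_dose",
    "nitrogen_dose",
    "total_absorbed",
    "photon_equivalent",
    "ced_effective_boron",
    "DoseArm",
    "TissueSpec",
    "build_dose_table",
]


class MissingCBEError(ValueError):
    """Raised when a photon-equivalent dose needs a CBE that is unavailable."""


@dataclass(frozen=True)
class KermaConstants:
    """Thermal-neutron kerma coefficients.

    ``boron_coeff`` is in Gy·cm² per (μg ¹⁰B/g); ``nitrogen_coeff`` in
    Gy·cm² per weight-% nitrogen.  Defaults are the standard values used
    for reactor-based BNCT dosimetry.
    """

    boron_coeff: float = 7.43e-14
    nitrogen_coeff: float = 6.78e-14

    def __post_init__(self) -> None:
        if self.boron_coeff <= 0 or self.nitrogen_coeff <= 0:
            raise ValueError("kerma coefficients must be strictly positive")


@dataclass(frozen=True)
class BeamExposure:
    """One irradiation: thermal fluence plus the spectrum-dependent doses.

    ``hydrogen_dose`` and ``gamma_dose`` are accepted as pre-computed Gy
    because they require a spectral model that is outside this package.
    """

    thermal_fluence: float  # neutrons / cm^2
    hydrogen_dose: float = 0.0  # Gy
    gamma_dose: float = 0.0  # Gy

    def __post_init__(self) -> None:
        if self.thermal_fluence < 0 or self.hydrogen_dose < 0 or self.gamma_dose < 0:
            raise ValueError("beam exposure values must be non-negative")


@dataclass(frozen=True)
class TissueComposition:
    nitrogen_pct: float  # weight-%
    boron_conc: float = 0.0  # μg ¹⁰B per g tissue

    def __post_init__(self) -> None:
        if not 0.0 <= self.nitrogen_pct <= 100.0:
            raise ValueError("nitrogen_pct must lie in [0, 100]")
        if self.boron_conc < 0:
            raise ValueError("boron_conc must be non-negative")


@dataclass(frozen=True)
class DoseComponents:
    """The four absorbed-dose parts (Gy) for one tissue under one irradiation."""

    d_b: float
    d_n: float
    d_h: float
    d_gamma: float

    def __post_init__(self) -> None:
        for name in ("d_b", "d_n", "d_h", "d_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.d_b + self.d_n + self.d_h + self.d_gamma


@dataclass(frozen=True)
class RBEWeights:
    """Biological-effectiveness weights for the photon-equivalent dose.

    ``cbe`` may be ``None`` to represent a compound/tissue pair whose CBE
    could not be estimated; any computation that actually needs it then
    fails loudly instead of silently defaulting.
    """

    cbe: Optional[float]
    rbe_n: float
    rbe_h: float

    def __post_init__(self) -> None:
        if self.cbe is not None and self.cbe <= 0:
            raise ValueError("cbe must be positive when given")
        if self.rbe_n <= 0 or self.rbe_h <= 0:
            raise ValueError("rbe_n and rbe_h must be positive")


@dataclass(frozen=True)
class CEDParams:
    """Effective-boron correction for convection-enhanced delivery (CED).

    Boron infused directly into the tumor by CED is heterogeneously
    distributed, and only a fraction of the measured gross concentration
    contributes to the capture dose.  The default fraction is 0.268.
    """

    contribution_fraction: float = 0.268

    def __post_init__(self) -> None:
        if not 0.0 < self.contribution_fraction <= 1.0:
            raise ValueError("contribution_fraction must lie in (0, 1]")


def boron_dose(
    boron_conc: float,
    thermal_fluence: float,
    constants: KermaConstants = KermaConstants(),
) -> float:
    """Boron capture dose: kerma coefficient × concentration × fluence (Gy)."""
    if boron_conc < 0 or thermal_fluence < 0:
        raise ValueError("boron_conc and thermal_fluence must be non-negative")
    return constants.boron_coeff * boron_conc * thermal_fluence


def nitrogen_dose(
    nitrogen_pct: float,
    thermal_fluence: float,
    constants: KermaConstants = KermaConstants(),
) -> float:
    """Nitrogen capture dose: kerma coefficient × weight-% N × fluence (Gy)."""
    if thermal_fluence < 0:
        raise ValueError("thermal_fluence must be non-negative")
    if not 0.0 <= nitrogen_pct <= 100.0:
        raise ValueError("nitrogen_pct must lie in [0, 100]")
    return constants.nitrogen_coeff * nitrogen_pct * thermal_fluence


def total_absorbed(components: DoseComponents) -> float:
    """Total absorbed dose D_B + D_N + D_H + D_γ (Gy)."""
    return components.total


def photon_equivalent(components: DoseComponents, weights: RBEWeights) -> float:
    """Photon-equivalent dose CBE·D_B + RBE_N·D_N + RBE_H·D_H + D_γ (Gy-Eq).

    Raises :class:`MissingCBEError` if the boron component is non-zero but
    no CBE is available.
    """
    if components.d_b > 0 and weights.cbe is None:
        raise MissingCBEError("CBE is required when the boron dose is non-zero")
    cbe = weights.cbe if weights.cbe is not None else 0.0
    return (
        cbe * components.d_b
        + weights.rbe_n * components.d_n
        + weights.rbe_h * components.d_h
        + components.d_gamma
    )


def ced_effective_boron(boron_conc: float, params: CEDParams = CEDParams()) -> float:
    """Effective boron concentration credited for CED administration (μg/g)."""
    if boron_conc < 0:
        raise ValueError("boron_conc must be non-negative")
    return boron_conc * params.contribution_fraction


@dataclass(frozen=True)
class TissueSpec:
    """Per-tissue inputs for one arm of a dose table.

    ``cbe`` is the compound/tissue CBE (``None`` = not estimable, the table
    cell is flagged missing).  ``depth_correction`` is an optional
    multiplicative factor applied to every dose component of this tissue,
    standing in for depth/position corrections derived elsewhere.
    """

    composition: TissueComposition
    cbe: Optional[float] = None
    depth_correction: float = 1.0

    def __post_init__(self) -> None:
        if self.depth_correction <= 0:
            raise ValueError("depth_correction must be positive")


@dataclass(frozen=True)
class DoseArm:
    """One treatment arm: a beam exposure applied to a set of tissues."""

    name: str
    exposure: BeamExposure
    tissues: Mapping[str, TissueSpec]
    rbe_n: float = 1.0
    rbe_h: float = 1.0
    ced: Optional[CEDParams] = None
    ced_tissues: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError(f"arm {self.name!r} defines no tissues")
        unknown = set(self.ced_tissues) - set(self.tissues)
        if unknown:
            raise ValueError(f"ced_tissues not in arm {self.name!r}: {sorted(unknown)}")


def arm_components(arm: DoseArm, tissue_name: str) -> DoseComponents:
    """Dose components for one tissue of one arm."""
    spec = arm.tissues[tissue_name]
    boron = spec.composition.boron_conc
    if arm.ced is not None and tissue_name in arm.ced_tissues:
        boron = ced_effective_boron(boron, arm.ced)
    c = spec.depth_correction
    return DoseComponents(
        d_b=c * boron_dose(boron, arm.exposure.thermal_fluence),
        d_n=c * nitrogen_dose(spec.composition.nitrogen_pct, arm.exposure.thermal_fluence),
        d_h=c * arm.exposure.hydrogen_dose,
        d_gamma=c * arm.exposure.gamma_dose,
    )


def build_dose_table(arms: Sequence[DoseArm], decimals: int = 1) -> pd.DataFrame:
    """Absorbed and photon-equivalent doses per tissue per arm.

    Returns a tidy frame with columns ``arm, tissue, d_b, d_n, d_h, d_gamma,
    absorbed_gy, photon_eq_gyeq, cbe_missing``.  A tissue whose CBE is
    unavailable while it carries a boron dose gets ``photon_eq_gyeq = NaN``
    and ``cbe_missing = True`` (the '-' cell of a printed dose table).
    Display columns ``absorbed_gy`` / ``photon_eq_gyeq`` are rounded to
    ``decimals``; the component columns are left unrounded.
    """
    if not arms:
        raise ValueError("no arms given")
    names = [a.name for a in arms]
    if len(set(names)) != len(names):
        raise ValueError("arm names must be unique")
    rows = []
    for arm in arms:
        for tissue_name, spec in arm.tissues.items():
            comps = arm_components(arm, tissue_name)
            weights = RBEWeights(cbe=spec.cbe, rbe_n=arm.rbe_n, rbe_h=arm.rbe_h)
            try:
                photon = photon_equivalent(comps, weights)
                missing = False
            except MissingCBEError:
                photon = math.nan
                missing = True
            rows.append(
                {
                    "arm": arm.name,
                    "tissue": tissue_name,
                    "d_b": comps.d_b,
                    "d_n": comps.d_n,
                    "d_h": comps.d_h,
                    "d_gamma": comps.d_gamma,
                    "absorbed_gy": round(comps.total, decimals),
                    "photon_eq_gyeq": round(photon, decimals) if not missing else math.nan,
                    "cbe_missing": missing,
                }
            )
    return pd.DataFrame(rows)
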