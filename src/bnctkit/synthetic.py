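"""Synthetic experiment generator for every input the pipeline consumes.

The generator emulates the four data-producing experiments of a small-animal
BNCT study — clonogenic survival assays, organ boron biodistribution,
qPCR expression, and a survival study — with planted ground truth, so that
every downstream estimator can be tested end-to-end without any real data.
Each generator has a zero-noise mode in which the downstream estimator
recovers the planted parameters exactly.

Noise families: Poisson colony counts, zero-truncated normal boron
concentrations, normal CT noise, and log-logistic survival times.  All
randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClonogenicCompound",
    "ClonogenicConfig",
    "BiodistGroup",
    "BiodistConfig",
    "UptakeConfig",
    "ExpressionConfig",
    "SurvivalArm",
    "SurvivalConfig",
    "GeneratorConfig",
    "default_config",
    "gen_clonogenic",
    "gen_biodistribution",
    "gen_uptake",
    "gen_expression",
    "gen_survival",
    "default_dose_config",
    "write_fixtures",
    "dump_config",
    "load_config",
]


# --------------------------------------------------------------------------
# clonogenic assay


@dataclass(frozen=True)
class ClonogenicCompound:
    """Planted truth for one boron-carrier irradiation condition.

    ``iso_gy`` is the absorbed dose at which the condition reaches the
    iso-effect survival level; together with the planted CBE it fixes the
    boron share of the condition's dose rate.
    """

    label: str
    cbe: float
    iso_gy: float


@dataclass(frozen=True)
class ClonogenicConfig:
    """Design of the synthetic clonogenic experiment.

    The X-ray reference curve is an LQ model with ``alpha`` and a beta
    calibrated so that SF = ``sf_level`` at ``lq_iso_gy``.  Neutron
    conditions share the irradiation durations; each condition's dose rate
    is scaled so its curve crosses the iso-effect level at the middle
    duration (separate irradiation setups cannot share a single fluence
    rate when their effectiveness differs several-fold).  The non-boron
    beam dose splits into a gamma fraction (weight 1) and a recoil fraction
    (weight ``rbe_beam``), the recoil part further into nitrogen and
    hydrogen shares (biologically equivalent, both at the beam RBE).
    """

    alpha: float = 0.2  # 1/Gy
    lq_iso_gy: float = 6.45
    sf_level: float = 0.1
    rbe_beam: float = 3.0
    gamma_fraction: float = 0.45  # of the non-boron beam dose
    nitrogen_share: float = 0.25  # of the recoil (n+h) dose
    durations_min: Tuple[float, ...] = (10.0, 20.0, 30.0)
    xray_doses_gy: Tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    control_colonies: int = 200
    replicates: int = 3
    xray_label: str = "X-ray"
    beam_label: str = "Neutron only"
    compounds: Tuple[ClonogenicCompound, ...] = (
        ClonogenicCompound("DPA-BSTPG", cbe=8.43, iso_gy=0.88),
        ClonogenicCompound("BPA", cbe=3.80, iso_gy=1.90),
        ClonogenicCompound("BSH", cbe=2.41, iso_gy=2.80),
    )
    noise: bool = True

    @property
    def beta(self) -> float:
        """Beta calibrated so the X-ray curve hits sf_level at lq_iso_gy."""
        kill = -math.log(self.sf_level)
        return (kill - self.alpha * self.lq_iso_gy) / self.lq_iso_gy**2

    @property
    def beam_weight(self) -> float:
        """Average photon-equivalent weight of the non-boron beam dose."""
        return self.rbe_beam * (1.0 - self.gamma_fraction) + self.gamma_fraction

    @property
    def beam_iso_gy(self) -> float:
        """Absorbed beam-only dose at the iso-effect level (implied)."""
        return self.lq_iso_gy / self.beam_weight

    def boron_fraction(self, compound: ClonogenicCompound) -> float:
        """Boron share of the absorbed dose implied by (cbe, iso_gy)."""
        lo = self.lq_iso_gy / compound.cbe
        hi = self.beam_iso_gy
        if not lo < compound.iso_gy < hi:
            raise ValueError(
                f"{compound.label}: iso_gy must lie in ({lo:.3f}, {hi:.3f}) Gy "
                f"for CBE {compound.cbe} under this beam model"
            )
        return (self.lq_iso_gy / compound.iso_gy - self.beam_weight) / (
            compound.cbe - self.beam_weight
        )


def _condition_rates(
    cfg: ClonogenicConfig, boron_fraction: float, iso_gy: float
) -> Tuple[float, float, float, float]:
    """Per-minute (d_b, d_n, d_h, d_gamma) rates for one condition."""
    mid = cfg.durations_min[len(cfg.durations_min) // 2]
    rate = iso_gy / mid
    b = boron_fraction * rate
    rest = rate - b
    gamma = cfg.gamma_fraction * rest
    recoil = rest - gamma
    return b, cfg.nitrogen_share * recoil, (1 - cfg.nitrogen_share) * recoil, gamma


def gen_clonogenic(cfg: ClonogenicConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format colony-count table for the X-ray and neutron conditions.

    Expected counts are ``control_colonies × SF_true`` with SF_true from the
    LQ model in photon-equivalent dose; with ``noise`` both treated and
    control counts are Poisson draws, otherwise the exact expectations are
    emitted (as floats).
    """
    alpha, beta = cfg.alpha, cfg.beta

    def sf_true(deq: float) -> float:
        return math.exp(-alpha * deq - beta * deq**2)

    rows = []

    def emit(condition: str, dose: float, comps: Tuple[float, float, float, float], deq: float) -> None:
        expected = cfg.control_colonies * sf_true(deq)
        for rep in range(1, cfg.replicates + 1):
            if cfg.noise:
                treated = int(rng.poisson(expected))
                control = max(int(rng.poisson(cfg.control_colonies)), 1)
            else:
                treated, control = expected, float(cfg.control_colonies)
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "dose_gy": dose,
                    "d_b_gy": comps[0],
                    "d_n_gy": comps[1],
                    "d_h_gy": comps[2],
                    "d_gamma_gy": comps[3],
                    "colonies_treated": treated,
                    "colonies_control": control,
                }
            )

    for dose in cfg.xray_doses_gy:
        emit(cfg.xray_label, dose, (0.0, 0.0, 0.0, dose), dose)

    conditions = [(cfg.beam_label, None, cfg.beam_iso_gy)] + [
        (c.label, c, c.iso_gy) for c in cfg.compounds
    ]
    for label, compound, iso in conditions:
        x = 0.0 if compound is None else cfg.boron_fraction(compound)
        rates = _condition_rates(cfg, x, iso)
        cbe = 0.0 if compound is None else compound.cbe
        for t in cfg.durations_min:
            comps = tuple(r * t for r in rates)
            deq = (
                cbe * comps[0]
                + cfg.rbe_beam * (comps[1] + comps[2])
                + comps[3]
            )
            emit(label, sum(comps), comps, deq)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# biodistribution and cellular uptake


@dataclass(frozen=True)
class BiodistGroup:
    compound: str
    route: str  # iv | ced | combination
    time_h: float
    n: int
    organs: Mapping[str, Tuple[float, float]]  # organ -> (mean, sd), μg B/g


@dataclass(frozen=True)
class BiodistConfig:
    groups: Tuple[BiodistGroup, ...]


@dataclass(frozen=True)
class UptakeConfig:
    """Cell-line uptake study: (mean, sd) in μg B per 10⁹ cells."""

    lines: Mapping[str, Mapping[str, Tuple[float, float]]]
    replicates: int = 3
    n_cells: float = 1e6


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal draws truncated at zero (concentrations cannot be negative)."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def gen_biodistribution(cfg: BiodistConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-animal organ boron concentrations in long format."""
    rows = []
    subject_id = 0
    for grp in cfg.groups:
        subjects = [f"{grp.compound}-{grp.time_h:g}h-{subject_id + i + 1}" for i in range(grp.n)]
        subject_id += grp.n
        for organ, (mean, sd) in grp.organs.items():
            draws = _truncated_normal(mean, sd, grp.n, rng)
            for subj, value in zip(subjects, draws):
                rows.append(
                    {
                        "subject": subj,
                        "compound": grp.compound,
                        "route": grp.route,
                        "time_h": grp.time_h,
                        "organ": organ,
                        "boron_ug_per_g": float(value),
                    }
                )
    return pd.DataFrame(rows)


def gen_uptake(cfg: UptakeConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cellular uptake table: raw boron mass and cell count per replicate."""
    rows = []
    for line, compounds in cfg.lines.items():
        for compound, (mean, sd) in compounds.items():
            draws = _truncated_normal(mean, sd, cfg.replicates, rng)
            for rep, uptake in enumerate(draws, start=1):
                rows.append(
                    {
                        "cell_line": line,
                        "compound": compound,
                        "replicate": rep,
                        # uptake is μg B per 1e9 cells; convert to raw mass
                        "boron_ug": float(uptake) * cfg.n_cells / 1e9,
                        "n_cells": cfg.n_cells,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionConfig:
    """Planted per-subject fold-changes turned into CT quadruples.

    CTs are constructed so the 2^-ΔΔCT analysis recovers each planted fold
    exactly at zero noise: reference CTs sit at ``ref_ct``, the normal-tissue
    target CT at ``ref_ct + normal_delta_ct``, and the tumor target CT is
    offset by −log2(fold).  ``noise_sd`` (cycles) is added independently to each CT.
    """

    folds: Tuple[float, ...] = (13.95, 23.07, 11.09)
    ref_ct: float = 20.0
    normal_delta_ct: float = 4.0
    noise_sd: float = 0.0
    target_gene: str = "PBR"
    reference_gene: str = "ACTB"


def gen_expression(cfg: ExpressionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Long CT table (subject, gene, tissue, ct)."""
    rows = []
    for i, fold in enumerate(cfg.folds, start=1):
        if fold <= 0:
            raise ValueError("planted folds must be positive")
        subject = f"rat{i}"
        ct_target_normal = cfg.ref_ct + cfg.normal_delta_ct
        ct_target_tumor = ct_target_normal - math.log2(fold)
        quad = {
            (cfg.target_gene, "tumor"): ct_target_tumor,
            (cfg.reference_gene, "tumor"): cfg.ref_ct,
            (cfg.target_gene, "normal"): ct_target_normal,
            (cfg.reference_gene, "normal"): cfg.ref_ct,
        }
        for (gene, tissue), ct in quad.items():
            if cfg.noise_sd > 0:
                ct += rng.normal(0.0, cfg.noise_sd)
            rows.append({"subject": subject, "gene": gene, "tissue": tissue, "ct": ct})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalArm:
    label: str
    median_days: float
    n: int


@dataclass(frozen=True)
class SurvivalConfig:
    """Per-arm log-logistic survival times scaled to the configured medians.

    The log-logistic shape controls dispersion (``inf`` = every subject dies
    exactly at the arm median); the default is calibrated so small-cohort
    median CIs are of the order of 10–20% of the median, as typical for
    tightly staged orthotopic glioma models.  All subjects are events.
    """

    arms: Tuple[SurvivalArm, ...] = (
        SurvivalArm("Untreated", 21.0, 6),
        SurvivalArm("Neutron only", 23.0, 5),
        SurvivalArm("DPA-BSTPG-BNCT", 28.0, 6),
        SurvivalArm("BPA-BNCT", 31.5, 5),
        SurvivalArm("Combination BNCT", 33.5, 6),
    )
    shape: float = 19.0


def gen_survival(cfg: SurvivalConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject event table (subject, arm, time_days, event)."""
    if cfg.shape <= 0:
        raise ValueError("shape must be positive")
    rows = []
    for arm in cfg.arms:
        if arm.median_days <= 0 or arm.n < 1:
            raise ValueError(f"invalid arm {arm.label!r}")
        u = rng.uniform(size=arm.n)
        if math.isinf(cfg.shape):
            times = np.full(arm.n, arm.median_days)
        else:
            times = arm.median_days * (u / (1.0 - u)) ** (1.0 / cfg.shape)
        for i, t in enumerate(times, start=1):
            rows.append(
                {
                    "subject": f"{arm.label}-{i}",
                    "arm": arm.label,
                    "time_days": float(t),
                    "event": 1,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# bundled configuration


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    clonogenic: ClonogenicConfig = field(default_factory=ClonogenicConfig)
    biodistribution: BiodistConfig = field(default_factory=lambda: default_biodist_config())
    uptake: UptakeConfig = field(default_factory=lambda: default_uptake_config())
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)


def default_biodist_config() -> BiodistConfig:
    """Tumor/brain/blood biodistribution design of the rat glioma study."""
    tbb = lambda t, br, bl: {"tumor": t, "brain": br, "blood": bl}
    return BiodistConfig(
        groups=(
            BiodistGroup("DPA-BSTPG", "ced", 2.5, 6, tbb((45.0, 18.8), (0.8, 0.8), (0.4, 0.2))),
            BiodistGroup("DPA-BSTPG", "ced", 12.0, 4, tbb((32.5, 13.1), (0.8, 0.8), (0.3, 0.1))),
            BiodistGroup("DPA-BSTPG", "ced", 24.0, 4, tbb((23.7, 13.5), (1.0, 1.4), (0.4, 0.1))),
            BiodistGroup("BPA", "iv", 2.5, 4, tbb((20.6, 2.2), (5.5, 0.6), (7.7, 0.5))),
            BiodistGroup("BPA", "iv", 12.0, 4, tbb((9.1, 3.3), (2.5, 0.6), (2.9, 0.4))),
            BiodistGroup("BPA", "iv", 24.0, 4, tbb((8.2, 0.8), (2.3, 0.3), (2.9, 0.4))),
            BiodistGroup("Combination", "combination", 2.5, 4, tbb((61.8, 20.4), (5.1, 0.7), (7.3, 0.5))),
        )
    )


def default_uptake_config() -> UptakeConfig:
    """In vitro uptake design: three glioma lines × three boron carriers."""
    return UptakeConfig(
        lines={
            "F98": {"DPA-BSTPG": (60.3, 3.8), "BPA": (11.9, 0.5), "BSH": (3.0, 0.2)},
            "C6": {"DPA-BSTPG": (26.0, 2.4), "BPA": (6.5, 0.2), "BSH": (3.2, 0.1)},
            "9L": {"DPA-BSTPG": (24.0, 4.0), "BPA": (24.3, 1.7), "BSH": (5.3, 0.4)},
        }
    )


def default_config(seed: int = 0) -> GeneratorConfig:
    """The study-condition defaults used throughout the test suite."""
    return GeneratorConfig(seed=seed)


def default_dose_config() -> dict:
    """Synthetic beam/tissue configuration for the in vivo dose table.

    The thermal fluence and the hydrogen/gamma doses are a synthetic beam
    fixture (the study's physical beam parameters are not part of this
    package); tissue boron concentrations come from the biodistribution
    design, nitrogen weight fractions are textbook soft-tissue values, and
    the DPA-BSTPG brain CBE is deliberately missing (not estimable).
    """
    beam = {"thermal_fluence": 1.2e12, "d_h": 0.15, "d_gamma": 0.45}
    no_beam = {"thermal_fluence": 0.0, "d_h": 0.0, "d_gamma": 0.0}
    return {
        "arms": [
            {
                "name": "Untreated",
                "beam": no_beam,
                "weights": {"rbe_n": 3.0, "rbe_h": 3.0},
                "tissue": {
                    "brain": {"nitrogen_pct": 2.2, "boron_conc": 0.0},
                    "tumor": {"nitrogen_pct": 3.5, "boron_conc": 0.0},
                },
            },
            {
                "name": "Neutron only",
                "beam": beam,
                "weights": {"rbe_n": 3.0, "rbe_h": 3.0},
                "tissue": {
                    "brain": {"nitrogen_pct": 2.2, "boron_conc": 0.0},
                    "tumor": {"nitrogen_pct": 3.5, "boron_conc": 0.0},
                },
            },
            {
                "name": "DPA-BSTPG-BNCT",
                "beam": beam,
                "weights": {"rbe_n": 3.0, "rbe_h": 3.0},
                "ced": {"contribution_fraction": 0.268},
                "tissue": {
                    "brain": {"nitrogen_pct": 2.2, "boron_conc": 0.8, "cbe": None, "ced": True},
                    "tumor": {"nitrogen_pct": 3.5, "boron_conc": 45.0, "cbe": 8.43, "ced": True},
                },
            },
            {
                "name": "BPA-BNCT",
                "beam": beam,
                "weights": {"rbe_n": 3.0, "rbe_h": 3.0},
                "tissue": {
                    "brain": {"nitrogen_pct": 2.2, "boron_conc": 5.5, "cbe": 1.35},
                    "tumor": {"nitrogen_pct": 3.5, "boron_conc": 20.6, "cbe": 3.80},
                },
            },
        ]
    }


# --------------------------------------------------------------------------
# fixture writing and config round-trip


def write_fixtures(config: GeneratorConfig, outdir: Path) -> Dict[str, Path]:
    """Write every pipeline input to ``outdir``; returns name -> path.

    Sub-generators draw from independent streams spawned from the single
    seed, so each file is reproducible on its own.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]
    tables = {
        "clonogenic": gen_clonogenic(config.clonogenic, rngs[0]),
        "biodistribution": gen_biodistribution(config.biodistribution, rngs[1]),
        "uptake": gen_uptake(config.uptake, rngs[2]),
        "expression_ct": gen_expression(config.expression, rngs[3]),
        "survival": gen_survival(config.survival, rngs[4]),
    }
    paths: Dict[str, Path] = {}
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    dose_path = outdir / "dose_config.json"
    dose_path.write_text(json.dumps(default_dose_config(), indent=2, sort_keys=True) + "\n")
    paths["dose_config"] = dose_path
    return paths


def dump_config(config: GeneratorConfig, path: Path) -> None:
    """Serialize a generator configuration to JSON."""
    Path(path).write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True, default=list) + "\n"
    )


def _tupled(obj):
    if isinstance(obj, list):
        return tuple(_tupled(x) for x in obj)
    return obj


def load_config(path: Path) -> GeneratorConfig:
    """Load a generator configuration from JSON written by :func:`dump_config`."""
    raw = json.loads(Path(path).read_text())
    clon = dict(raw["clonogenic"])
    clon["durations_min"] = tuple(clon["durations_min"])
    clon["xray_doses_gy"] = tuple(clon["xray_doses_gy"])
    clon["compounds"] = tuple(ClonogenicCompound(**c) for c in clon["compounds"])
    biod = BiodistConfig(
        groups=tuple(
            BiodistGroup(
                compound=g["compound"],
                route=g["route"],
                time_h=g["time_h"],
                n=g["n"],
                organs={k: tuple(v) for k, v in g["organs"].items()},
            )
            for g in raw["biodistribution"]["groups"]
        )
    )
    upt = UptakeConfig(
        lines={
            line: {comp: tuple(v) for comp, v in comps.items()}
            for line, comps in raw["uptake"]["lines"].items()
        },
        replicates=raw["uptake"]["replicates"],
        n_cells=raw["uptake"]["n_cells"],
    )
    expr = dict(raw["expression"])
    expr["folds"] = tuple(expr["folds"])
    surv = SurvivalConfig(
        arms=tuple(SurvivalArm(**a) for a in raw["survival"]["arms"]),
        shape=raw["survival"]["shape"],
    )
    return GeneratorConfig(
        seed=raw["seed"],
        clonogenic=ClonogenicConfig(**clon),
        biodistribution=biod,
        uptake=upt,
        expression=ExpressionConfig(**expr),
        survival=surv,
    )
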