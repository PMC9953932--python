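# Methods

This note records the models, assumptions, parameter choices and numerical
conventions behind `bnctkit`, in the spirit of a statistical methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dosimetry

The absorbed dose in a neutron field is decomposed into boron capture
(`D_B`), nitrogen capture (`D_N`), hydrogen recoil (`D_H`) and gamma
(`D_γ`) components. The two thermal-capture terms are linear kerma
products: `D_B = 7.43e-14 × c_B × Φ_th` and `D_N = 6.78e-14 × c_N × Φ_th`,
with `c_B` in μg ¹⁰B/g, `c_N` in weight-% and `Φ_th` the thermal fluence in
1/cm². `D_H` and `D_γ` require a beam spectral model, which is out of scope
here; they are accepted as pre-computed Gy in the beam configuration. An
optional per-tissue multiplicative `depth_correction` (default 1.0) stands
in for depth/position corrections computed elsewhere.

The photon-equivalent dose is `CBE·D_B + RBE_N·D_N + RBE_H·D_H + D_γ`
(Gy-Eq). A CBE is compound- *and* tissue-specific; when it is not
estimable (a TSPO-targeted compound in normal brain, for instance) it is
represented as missing, and any computation that needs it raises instead of
defaulting — dose tables carry an explicit flagged empty cell. Boron
delivered by convection-enhanced delivery is credited at an effective
contribution fraction, default 0.268, reflecting the heterogeneous
intratumoral distribution of infused compound. Report tables round Gy and
Gy-Eq values to one decimal; component columns stay unrounded.

The beam fixture shipped with the synthetic configuration (thermal fluence
1.2e12 /cm², `D_H` 0.15 Gy, `D_γ` 0.45 Gy, tumor nitrogen 3.5 wt-%, brain
2.2 wt-%) is a synthetic stand-in chosen to give order-of-magnitude
realistic single-fraction reactor doses (~1 Gy non-boron absorbed dose); it
is not a measured beam.

## Clonogenic analysis

Surviving fractions are treated/control colony-count ratios; values above 1
warn and clip. A zero treated count cannot enter a log-scale fit, so it is
an error by default, with an explicit `floor` policy (half a colony,
0.5/control) for noisy data. The LQ model is fitted by least squares on
`ln SF = −αD − βD²` with `α, β ≥ 0` enforced by non-negative least squares
(an active-set solver, exact at the noiseless limit); weighting by colony
counts is available but off by default since the fitting literature for
clonogenic assays most commonly uses unweighted log-scale fits. The
iso-effect dose solves `βD² + αD + ln s = 0` through the numerically stable
positive-root form `2·(−ln s)/(α + √(α² − 4β ln s))`, which degrades
gracefully to `−ln s/α` as β → 0. For measured (non-X-ray) curves the
default iso-effect strategy is a per-curve LQ fit plus inversion; log-linear
interpolation between observed points is available, requires bracketing,
and pre-smooths non-monotone curves by antitonic regression after a
warning.

The beam RBE is estimated from the boron-free condition with the gamma dose
credited at weight one: `RBE_beam = (D_X − D_γ)/(D_N + D_H)` where `D_X` is
the X-ray iso-dose. This is the only reading consistent with the
photon-equivalent equation. The same `RBE_beam` is used for both the
nitrogen and hydrogen components. Each carrier's CBE follows by inverting
the photon-equivalent equation at the carrier's iso-effect point; a
non-positive numerator (non-boron dose already exceeding the photon
requirement) is flagged as inconsistent input rather than returning a
negative CBE. Component doses at an estimated iso-point are obtained by
scaling the condition's pooled component fractions — exact when the
component mix is constant along the curve, as it is for a fixed irradiation
geometry.

Uncertainty is quantified by a parametric bootstrap on the counting noise:
treated and control counts are redrawn Poisson around the observed counts,
the full analysis re-runs, and percentile intervals are reported
(B configurable, 1000 by default in the CLI; resamples that fail to invert
are skipped and counted).

## Biodistribution and uptake

Group summaries use the sample SD (n−1); single-animal groups get SD 0.
T/Br and T/Bl are ratios of unrounded group means — not means of per-animal
ratios — because the summary-table convention defines them from the group
values; display rounding is one decimal for both concentrations and ratios.
Uptake is `boron mass / cell count × 10⁹`. Group comparisons default to the
pooled-variance Student's t-test (two-sided, α = 0.05), with Welch's
correction behind a flag; identical constant groups return (t = 0, p = 1)
as the only sensible degenerate answer.

## Expression

2^-ΔΔCT with a single reference gene and the normal tissue as calibrator;
amplification efficiency is assumed ideal (doubling per cycle). CT values
are validated into (0, 45]. Cohort summaries default to the arithmetic mean
of per-subject folds with a nearest-integer headline; because fold-changes
are ratios, a geometric-mean option is provided, and both values are
reported by the CLI. The averaging convention for the headline is a
deliberate choice, documented rather than hidden.

## Survival

Kaplan–Meier product-limit estimation per arm (via `lifelines`), with death
or euthanasia counted as the event and no censoring in the default design.
The median convention is the first time with S(t) ≤ 0.5, which handles the
even-n plateau; the median CI inverts the pointwise confidence band
(Brookmeyer–Crowley style). The two-group log-rank test handles ties by
simultaneous risk-set accounting, with a chi-square(1) two-sided p-value;
pairwise comparisons against the reference arm are unadjusted for
multiplicity. %ILS is exactly linear in the treated median.

## Synthetic-data generator

The generator emulates the statistical structure of each experiment with
planted ground truth. Noise families — Poisson colony counts,
zero-truncated normal organ concentrations, normal CT noise, log-logistic
survival times — are plausibility choices, each configurable. All
randomness derives from one integer seed through spawned `SeedSequence`
streams; fixed seed gives byte-identical fixture files. Every generator has
a zero-noise mode in which the downstream estimator recovers the planted
parameters exactly; that exactness is the backbone of the test suite.

**Clonogenic design.** The X-ray reference uses α = 0.2 /Gy with β
calibrated so SF = 0.1 at 6.45 Gy (β ≈ 0.0243 /Gy²), a realistic α/β ≈ 8 Gy
for a glioma line. The non-boron beam dose is split 45% gamma / 55% recoil,
and the recoil part 25% nitrogen / 75% hydrogen (the two are biologically
equivalent under a shared beam RBE of 3.0). Planted carrier truths are
CBE 8.43 (DPA-BSTPG), 3.80 (BPA) and 2.41 (BSH), with planted iso-effect
absorbed doses 0.88, 1.90 and 2.80 Gy. Two structural constraints shaped
the iso-dose choices. First, the photon-equivalent model bounds any
carrier's iso-dose below by `6.45/CBE` and above by the beam-only iso-dose
(`6.45/(3 − 2·gamma_fraction)`): a BPA iso-dose below 1.697 Gy is
algebraically impossible at CBE 3.80, so the planted values sit inside the
feasible band while preserving the qualitative ordering
DPA-BSTPG < BPA < BSH < beam-only. Second, the gamma fraction 0.45 widens
the BSH/beam-only separation (BSH's CBE of 2.41 is close to the beam's
average weight, so a smaller gamma fraction would leave the two curves
nearly indistinguishable under noise). Each condition's dose rate is scaled
so its curve crosses the iso-effect level at the middle of the three
irradiation durations (10/20/30 min): a single shared fluence rate cannot
place all four crossings inside one duration design when effectiveness
ratios span a factor of seven. Counts are Poisson around
`200 × SF` with 200 control colonies and 3 replicates per point.

**Biodistribution.** Per-animal draws are zero-truncated normal at the
configured group means ± SD (tumor/brain/blood per compound, route and
timepoint; n = 4–6 per group), matching the design of a rat glioma
biodistribution study. Truncation matters only for near-zero brain/blood
levels after CED.

**Expression.** Reference CTs sit at 20 cycles, the normal-tissue target CT
4 cycles above the reference, and the tumor target CT offset by −log2 of the
planted fold (defaults 13.95, 23.07, 11.09); optional N(0, sd) noise is
added per CT.

**Survival.** Log-logistic times scaled so the distribution median equals
each arm's configured value (defaults 21.0 / 23.0 / 28.0 / 31.5 / 33.5
days). The five-arm design totals 28 animals split 6/5/6/5/6 — a documented
assumption, since only the total is specified. The shape parameter defaults
to 19, calibrated a priori so that the asymptotic SE of a six-animal median
(`SE ≈ 2m/(shape·√n)`) yields 95% CIs of roughly 15–20% of the median,
matching the narrow interval widths such tightly staged orthotopic models
report. The degenerate `shape = inf` limit puts every subject exactly at
the arm median, which the report tests exploit.

## Problem sizes

The recovery experiments use 50 seeded replicates of the full clonogenic
design (5 conditions, 16 dose points, 3 replicates each) and 200 seeded
replicates of the 28-animal survival design; both complete in seconds. The
bootstrap default is B = 1000 resamples.

## What the synthetic tests do and do not show

Passing recovery tests demonstrates that the estimators are consistent and
approximately unbiased *under the generator's assumptions*: Poisson-only
counting noise, a constant component mix per condition, exactly LQ-shaped
survival, ideal qPCR doubling, and log-logistic event times with no
censoring. Real assays add plating-efficiency drift, inter-experiment
batch effects, boron microdistribution effects that make the effective CBE
dose-dependent, qPCR efficiency below 2, and censoring — none of which the
generator emulates. The synthetic beam fixture likewise means dose-table
outputs are structurally, not physically, validated.

## Known limitations

- No neutron transport or treatment planning: fluence and the `D_H`/`D_γ`
  components are inputs, never derived.
- CBE estimation assumes the photon-equivalent equation is exactly
  invertible at the iso-effect point; strongly non-LQ survival shapes would
  bias the inversion.
- The median-CI method reproduces the *kind* of interval such studies print,
  not any specific software's convention.
- No multiplicity correction across pairwise log-rank tests, by design.
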