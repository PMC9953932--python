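# bnctkit

Quantitative analysis tools for preclinical **boron neutron capture therapy
(BNCT)** studies: four-component neutron dosimetry, linear-quadratic
clonogenic analysis with compound biological effectiveness (CBE) and beam
RBE estimation, boron biodistribution summaries, 2^-ΔΔCT relative gene
expression, and Kaplan–Meier / %ILS survival analysis — plus a seeded
synthetic-data generator that emulates every experiment, so the whole chain
is testable end to end.

## Who this is for

Radiobiology groups running small-animal or in vitro BNCT experiments with
novel boron carriers (e.g. TSPO-targeted compounds alongside the clinical
carriers BPA and BSH) who need a reproducible path from raw measurement
tables — colony counts, ICP-AES organ boron concentrations, qPCR cycle
thresholds, survival times — to the standard derived quantities.

## The models

**Dosimetry.** The absorbed dose is the sum of four components,
`D = D_B + D_N + D_H + D_γ`, with the thermal-neutron capture terms computed
from kerma coefficients:

```
D_B = 7.43e-14 (Gy·cm²/μg ¹⁰B/g) × c_B (μg ¹⁰B/g) × Φ_th (1/cm²)
D_N = 6.78e-14 (Gy·cm²/wt-%)     × c_N (wt-%)      × Φ_th (1/cm²)
```

The photon-equivalent dose weights each component by its biological
effectiveness: `D_eq = CBE·D_B + RBE_N·D_N + RBE_H·D_H + D_γ` (Gy-Eq).
Boron delivered by convection-enhanced delivery (CED) is credited at an
effective contribution fraction (default 0.268).

**Radiobiology.** Clonogenic survival follows the LQ model
`SF(D) = exp(−αD − βD²)`, fitted by non-negative least squares on ln SF.
With the X-ray curve's iso-effect dose `D_X` at SF = 0.1, the boron-free
neutron condition gives the beam RBE,
`RBE_beam = (D_X − D_γ)/(D_N + D_H)`, and each boron carrier's CBE follows
by inverting the photon-equivalent equation at its own iso-effect point:
`CBE = (D_X − RBE_beam·(D_N + D_H) − D_γ)/D_B`.

**Biodistribution & expression.** Organ boron is summarized to mean ± SD per
group with tumor-to-brain (T/Br) and tumor-to-blood (T/Bl) ratios of the
unrounded group means; cellular uptake is normalized to μg B per 10⁹ cells
and compared by Student's t-test. Gene expression uses the 2^-ΔΔCT method
with a reference gene and normal-tissue calibrator.

**Survival.** Kaplan–Meier product-limit curves per treatment arm, median
survival time (MST, first t with S(t) ≤ 0.5) with a Brookmeyer–Crowley-style
CI, pairwise log-rank tests, and percent increased lifespan
`%ILS = (MST_arm − MST_untreated) × 100 / MST_untreated`.

## Worked example

```python
import numpy as np
from bnctkit.synthetic import default_config, gen_clonogenic
from bnctkit.radiobiology import analyze_clonogenic
from bnctkit.survival import pct_ils

cfg = default_config(seed=1)
counts = gen_clonogenic(cfg.clonogenic, np.random.default_rng(1))
est = analyze_clonogenic(counts, zero_policy="floor")
print(f"alpha = {est.lq.alpha:.3f} /Gy, beta = {est.lq.beta:.4f} /Gy^2")
print(f"X-ray iso-dose at SF=0.1: {est.lq_iso:.2f} Gy")
print(f"RBE-beam: {est.rbe_beam:.2f}")
for k in ("DPA-BSTPG", "BPA", "BSH"):
    print(f"CBE[{k}] = {est.cbe_by_compound[k]:.2f} (iso {est.iso_doses[k]:.2f} Gy)")
print(f"%ILS BPA-BNCT: {pct_ils(31.5, 21.0):.1f}")
```

Output:

```
alpha = 0.194 /Gy, beta = 0.0259 /Gy^2
X-ray iso-dose at SF=0.1: 6.40 Gy
RBE-beam: 2.88
CBE[DPA-BSTPG] = 8.58 (iso 0.86 Gy)
CBE[BPA] = 3.75 (iso 1.91 Gy)
CBE[BSH] = 2.52 (iso 2.72 Gy)
%ILS BPA-BNCT: 50.0
```

One seeded Poisson-noise clonogenic experiment recovers the planted ground
truth (CBE 8.43 / 3.80 / 2.41, RBE-beam 3.0, photon iso-dose 6.45 Gy)
within a few percent; the iso-doses show the expected ordering — the
TSPO-targeted compound needs the smallest absorbed dose for the same cell
kill. The %ILS value is the lifespan gain of an arm with a 31.5-day median
over a 21-day untreated median.

The same pipeline runs from the shell:

```bash
bnct run-all --simulate --seed 42 --outdir out/
# or stage by stage:
bnct simulate --seed 42 --outdir fixtures/
bnct cbe --survival fixtures/clonogenic.csv --out effectiveness.json
bnct biodist --measurements fixtures/biodistribution.csv --out table1.csv
bnct expr --ct fixtures/expression_ct.csv --out expression.json
bnct survival --events fixtures/survival.csv --out survival_report.csv
bnct dose --config fixtures/dose_config.json --out dose_table.csv
```

`run-all` writes a markdown report with all analysis sections plus CSV
sidecars and a hash manifest; reruns with the same seed are byte-identical.

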