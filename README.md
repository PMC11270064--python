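# hyperna — acute hypernatremia in single human ventricular cardiomyocytes

Clinical data on what acute hypernatremia (serum Na⁺ above ~145 mmol/L,
extreme above ~190 mmol/L) does to the heart are scarce and inconsistent,
and direct measurements on human cardiomyocytes do not exist. This
package reproduces, in silico, the electrophysiology of a single human
ventricular cardiomyocyte exposed acutely to elevated extracellular NaCl,
using two ORd-family ventricular ionic models side by side: a
re-implemented **ToR–ORd** endocardial model and a second, synthetic
ORd-2011-backbone model standing in for the **BPS2020** slot of the
comparison (see `docs/methods.md` — its numbers are its own).

Hypernatremia at fractional level *x* (0.10 / 0.20 / 0.50) is applied as
three coupled perturbations:

* **milieu** — [Na⁺]ₑ → (1+x)[Na⁺]ₑ and [Cl⁻]ₑ → [Cl⁻]ₑ + x[Na⁺]ₑ
  (equimolar NaCl addition);
* **ion-current scaling** — experimental hyperosmosis data interpolated
  linearly from (0, 1): f_IKr = 1 − 0.8x, f_IKs = 1 − x,
  f_INaCa = 1 + 0.7667x, f_INaK = 1 − 2.2222x (anchors 0.6/0.5 at
  x = 0.5 and 1.23/0.6 at x = 0.3); ICaL and IK1 unscaled by default;
* **osmotic shrinkage** — with osmolarity the plain ion sum and a 32 %
  osmotically inactive volume fraction q, the relative cell volume is
  v = q + (1−q)·osm₀/osm(x); all intracellular compartment volumes scale
  by v (membrane capacitance fixed) and every intracellular concentration
  is stepped at onset by the factor osm(x)/osm₀ = (1−q)/(v−q), the water
  lost leaving its solutes behind (≈ ×1.47 at x = 0.5, i.e. the "+47 %"
  concentration effect).

Cells are paced with 1-ms, 2×-threshold pulses at 50/75/100 per minute
for 10 simulated minutes (stiff LSODA, rtol 1e-7); biomarkers — RMP,
APA, APD50/APD90, (dVm/dt)max, threshold current Ith, EK/ENa, Ca²⁺
transient peak/diastole — come from the last complete beat of the final
five seconds.

## Worked example

The parameterization layer alone (instant):

```python
>>> from hyperna import scaling_factors, volume_fraction, OsmoticVolumeModel
>>> from hyperna.models import get_model
>>> bps = get_model("bps2020").baseline_milieu
>>> scaling_factors(0.50)
ScalingFactors(f_ICaL=1.0, f_IKr=0.6, f_IKs=0.5, f_IK1=1.0,
               f_INaCa=1.383..., f_INaK=0.333...)
>>> round(100 * volume_fraction(0.50, OsmoticVolumeModel(), bps), 2)
78.28
```

`python analysis/01_parameterization.py` prints the full table; the row
for the second model's milieu at 50 % hypernatremia reads

```
  model  level  f_IKr  f_IKs  f_INaCa  f_INaK  na_e   cl_e  vcell_pct  conc_gain_pct
bps2020    0.5   0.60    0.5    1.383   0.333 216.0  226.8      78.28          46.92
```

i.e. IKr down 40 %, IKs halved, the Na⁺/K⁺ pump at a third of its
amplitude, the cell at 78.28 % of its volume, and conserved intracellular
solutes concentrated by 46.9 %.

A full condition (about a minute of compute):

```python
>>> from hyperna.runner import run_condition
>>> base = run_condition("torord", 0.0, 50.0)
>>> hyper = run_condition("torord", 0.50, 50.0)
>>> round(base.biomarkers.rmp - hyper.biomarkers.rmp, 1)   # hyperpolarization, mV
9.6
>>> round(100 * (hyper.biomarkers.apd90 / base.biomarkers.apd90 - 1))
47
>>> round(hyper.biomarkers.na_i_diastolic, 1)              # mmol/L (50 % level)
22.7
```

The resting potential hyperpolarizes by ~10 mV (tracking EK after the
K⁺-concentrating osmotic step), the action potential prolongs, and
diastolic [Na⁺]i roughly doubles — reduced pump plus concentrated
cytosol. The numbered scripts under `analysis/` walk the whole study:
parameterization, the biomarker grid over models × rates × levels, the
75/min ionic concentrations, the ICaL-scaling scenarios (×0.72 / ×1.45)
and the shrinkage-vs-scaling ablations; each writes its table under
`results/`.

There is also a small CLI (`hyperna grid`, `hyperna cell`,
`hyperna ablation`, `hyperna ical-scan`) for running conditions from the
shell; everything is deterministic.

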