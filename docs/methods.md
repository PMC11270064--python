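# Methods

## The perturbation model

Acute hypernatremia is parameterized as an equimolar elevation of
extracellular NaCl by a fraction `level` (0.10 / 0.20 / 0.50 for mild /
severe / extreme). Three coupled consequences are applied to a ventricular
cell model:

1. **Milieu.** `[Na+]e' = (1+level)·[Na+]e`, `[Cl-]e' = [Cl-]e +
   level·[Na+]e`; `[K+]e` and `[Ca2+]e` are untouched. For the model
   without an explicit extracellular Cl⁻ parameter, the baseline `[Cl-]e`
   is computed from the extracellular charge of Na⁺, K⁺ and Ca²⁺.
2. **Ion-current scaling.** Experimental hyperosmosis data anchor a
   straight line through (0, 1) for each affected current: IKr 0.6 and
   IKs 0.5 at the 50 % level; INaCa 1.23 and INaK 0.6 at the 30 % level.
   Factors at any level are read off these lines (interpolation or
   extrapolation; a factor extrapolating to ≤ 0 is rejected — INaK hits
   zero at level 0.75). ICaL and IK1 stay at 1 in the default scenario;
   the contradictory ICaL data motivate the alternative factors 0.72 and
   1.45 exposed as scenarios.
3. **Osmotic shrinkage.** Osmolarity is the plain sum of the four
   extracellular ion concentrations (each species once); this is the
   unique simple definition that reproduces all published relative-volume
   values to two decimals. With an osmotically inactive volume fraction
   q = 0.32, the relative cell volume after an acute exposure is
   `v(level) = q + (1−q)·osm(0)/osm(level)`. All intracellular
   compartment volumes (myoplasm, network and junctional SR, subspace)
   scale by `v`; the membrane capacitance and capacitive area never
   change. Shrinkage is a step — no water-flux kinetics — matching the
   acute-exposure framing (experimentally complete within 2–3 minutes).

**Concentration step at onset.** Water leaving the cell concentrates the
solutes left behind: every intracellular concentration state (Na⁺, K⁺,
free Ca²⁺ in all compartments) is multiplied at onset by the
active-volume factor `osm(level)/osm(0) = (1−q)/(v−q)` (≈ 1.47 at the
50 % level, hence the "47 % increase" of a conserved solute). This step
is essential, not cosmetic: the quasi-steady [K⁺]i relaxes over tens of
minutes, so after 10 minutes of pacing the ~10 mV hyperpolarization of
EK — and with it the RMP shift, the INa availability gain and the
threshold-current rise — exists only if the step is applied. Without it
the same 10-minute protocol leaves RMP essentially unchanged and [K⁺]i
drifts slightly *down* (the reduced Na⁺/K⁺ pump imports less K⁺). For
this reason the step is the default, and the package's own test of
"step vs no step" insensitivity documents the large difference rather
than hiding it. Buffer maximal concentrations are left unscaled (the
source models treat them as fixed parameters).

## Cell models

Both models are flat-state ODE systems `dy/dt = f(t, y, p)` behind one
interface; `p` carries the milieu, the six scaling factors, the relative
volume and the stimulus. At the identity condition the right-hand side
is bitwise the unperturbed model. Scaling factors multiply maximal
amplitudes only (conductances / permeabilities / maximal turnover), so a
pinned-state current scales exactly by its factor; where INaCa and ICaL
split into bulk and subspace components, one factor multiplies both.

**ToR–ORd (endocardial).** Re-implemented from the published
Tomek–Rodriguez 2019/2020 model description: Grandi-form INa with
CaMKII-phosphorylated gates, raised INaL and Ito, GHK-driving-force ICaL
with Davies activity coefficients split 80/20 between subspace and
myoplasm, instantaneous-rectification IK1, Ca²⁺-activated and background
Cl⁻ currents (fixed [Cl⁻]i = 24 mmol/L), rescaled SERCA/release fluxes,
INaCa split 65/35 bulk/subspace. One documented departure: the
rapid-delayed-rectifier (IKr) is carried by the parent ORd-2011
Hodgkin–Huxley formulation (two activation time scales plus
instantaneous inward rectification) rather than the five-state Markov
scheme of the release, and its conductance (GKr = 0.0653 mS/µF) was set
once so the baseline endocardial APD90 at 1 Hz matches the published
~276 ms; all hypernatremia responses remain emergent. Re-derived
baseline behaviour: RMP −88.9 mV, (dVm/dt)max ≈ 300 V/s, diastolic
[Na⁺]i 12.1 mmol/L at 1 Hz and 12.5 mmol/L after 10 min at 75/min.

**BPS2020 slot — synthetic stand-in.** The published
Bartolucci–Passini–Severi 2020 equation set could not be obtained, so
its slot is filled by a clearly-labelled synthetic stand-in
(`bps2020_synthetic.py`): the O'Hara–Rudy 2011 endocardial equation set
— the common ancestor both published models update — operated with the
BPS2020 milieu (144 / 5.4 / 2.7 mmol/L, charge-balance Cl⁻, no Cl⁻
current). It preserves the qualitative contrasts the comparison turns
on (several-fold smaller Ito, larger IKs, lower [Na⁺]i load than
ToR–ORd) but its quantitative biomarkers are its own; results for this
slot must be read as "ORd-family second model", not as the published
BPS2020 numbers.

**Initial states.** Published default initial conditions (ORd backbone)
or published quasi-steady concentrations with gates at their closed-form
steady state for the initial potential (ToR–ORd). The 10-minute pacing
protocol is the arbiter: quasi-steadiness of APD90 and diastolic [Na⁺]i
(< 0.5 % beat-to-beat) is checked on every run.

## Protocol

Pacing follows the study design: 1-ms current pulses, rates 50/75/100
per minute, 10 simulated minutes, analysis on the final five seconds
(the last ⌈5 s / CL⌉ complete beats). The stimulus is inward and is
assigned to the K⁺ balance, as in the source models. The threshold
current Ith is the minimal 1-ms pulse magnitude driving Vm above 0 mV
within 50 ms of pulse onset, found by bisection to 0.5 % relative
bracket width from the condition's quasi-steady diastolic state; an
invalid initial bracket (both ends fire, or neither) is a reported
error, not a silent retry. Threshold and pacing amplitude are solved
self-consistently: pace at a provisional 2× threshold, re-measure Ith at
the final diastolic state, re-pace once at twice the re-measured value.
The "≈2×" of the study is taken as exactly 2.0.

Integration is adaptive stiff LSODA restarted at every stimulus edge,
relative tolerance 1e-7, absolute tolerances 1e-9 (myoplasmic/subspace
Ca²⁺), 1e-8 (SR Ca²⁺), 1e-7 (gates and other concentrations), 1e-5 mV
(Vm). Output resolution is ≤ 0.05 ms for the first 60 ms of each
captured beat and ≤ 1 ms elsewhere; biomarkers are verified insensitive
to doubling it. Everything is deterministic — there is no random number
generation anywhere in the package.

## Biomarkers

Per beat: RMP = pre-stimulus diastolic Vm (labelled RMP as in the study,
although the cell is paced); APA = peak − RMP; (dVm/dt)max = maximum of
the stimulus-corrected derivative, where the pulse's additive
contribution (its amplitude, in V/s) is subtracted over the pulse window
— at 2× threshold the upstroke completes *inside* the 1-ms pulse, so
truncating at pulse offset (the obvious alternative) would measure the
upstroke tail and invert the hypernatremia effect; APD50/APD90 = time
from the (dVm/dt)max instant to the repolarizing crossing of
RMP + 0.5·APA / RMP + 0.1·APA (linear interpolation); Ca²⁺ transient
peak and pre-stimulus diastole in µmol/L; EK and ENa by the Nernst
equation from the final diastolic intracellular concentrations and the
condition milieu at 310 K. Reported values come from the last complete
beat; percent changes always compare identical rates.

## Fixtures and oracles

The piecewise-linear AP-train fixture has closed-form biomarkers
(trapezoid geometry chosen so APD90 is exact by construction) and backs
the extraction tests, including time-shift and supersampling invariance.
The analytic toy cell (K⁺ leak, Na⁺ leak, optional pump, fast
regenerative inward current, 3 state variables) has a chord-conductance
resting potential in closed form and a threshold monotone in the
regenerative conductance; the bisection search is validated against an
exhaustive amplitude-grid oracle on it. The toy also runs the whole
condition→threshold→biomarker pipeline in milliseconds, with monotone
RMP/Ith trends under the same perturbation layer. These fixtures emulate
protocol mechanics only — none of the ionic, Ca²⁺-handling or rate
dependence of real cells — so passing fixture tests validates the
machinery, not the physiology.

## Problem sizes

The acceptance computations use the full study protocol: 500 beats
(50/min) or 750 beats (75/min) per condition, two pacing passes per
condition for the self-consistent amplitude, ~12–18 bisection probes of
50 ms per threshold. The test suite's trend scans sample levels
0/0.2/0.5 at 75 and 100 per minute (all four study levels at 50 per
minute) and skip the second self-consistency pass, whose effect on
biomarkers is far below the trend spacing. Conservation checks run on
single beats; the silenced-membrane conservation test integrates 10 s.

## Known limitations

* The BPS2020 slot is a synthetic stand-in (above); its panel-level
  percent changes differ from the published BPS2020 model's, most
  visibly in APD90 (+30 % rather than +46 % at the 50 % level — the
  stand-in lacks the large IKs whose halving drives much of that
  prolongation) and in the Ca²⁺ transient scale at [Ca2+]e = 2.7 mmol/L.
* The ToR–ORd reconstruction's IKr substitution shifts how repolarization
  is distributed across currents; its APD90 prolongation under the 50 %
  condition (+47 %) overshoots the published ToR–ORd's (+30 %) even
  though baseline AP, Ith trends, RMP shifts and the [Na⁺]i trajectory
  (12.5 → 24.1 mmol/L at 75/min) land on the published values.
* Chronic hypernatremia, tissue-level conduction, stretch-activated
  channels, T-tubule sealing and contractile mechanics are out of scope.
* The quasi-steady state at 10 min is not a true steady state for
  [K⁺]i/[Na⁺]i; results are protocol-defined quantities, as in the study
  design.
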