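# Methods

`cabpbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of cabozantinib, a receptor tyrosine kinase inhibitor whose
plasma profile combines three unusual features: extreme plasma protein
binding (99.7%), a very long terminal phase, and multiple secondary peaks
attributed to enterohepatic recirculation (EHC). The package couples a
perfusion-limited multi-organ circulation with a segmented gastrointestinal
lumen, saturable CYP3A4 metabolism in liver and gut wall, saturable MRP2
canalicular efflux feeding a meal-triggered gallbladder, a rifampin
CYP3A4-induction scenario, and hepatic-impairment physiology scaling.

## Model structure

**Circulation.** Venous blood → lung → arterial blood → organs. Adipose,
bone, brain, heart, kidney, muscle, skin and a lumped "rest" organ return to
the venous pool; gut, spleen, pancreas and stomach drain into the portal
stream, which joins the hepatic arterial inflow at the liver. Each organ is
a single well-stirred compartment exchanging with blood at its perfusion
rate (optionally `min(Q, PS)` for a permeability-limited organ with a
user-supplied PS). The blood concentration leaving an organ is
`A/(V·Kp/B:P)`, with tissue:plasma coefficients `Kp` from the
Rodgers & Rowland scheme and the blood:plasma ratio
`B:P = (1−hct) + hct·kp_rbc·fu`. For a 99.7%-bound drug the red-cell
partition `kp_rbc` defaults to 0 (drug confined to plasma within blood).
Venous plasma concentration — the reported output — is the venous blood
concentration divided by B:P.

**Partitioning.** The weak-base/neutral branch of the Rodgers & Rowland
equations (extracellular water, ionization-weighted intracellular water,
neutral-lipid/phospholipid partitioning, extracellular albumin binding) is
used for pKa < 7; cabozantinib (monoprotic base, pKa 6.32) falls in this
branch. The moderate-to-strong base branch (acidic-phospholipid
association calibrated from blood-cell partitioning) is implemented for
pKa ≥ 7 but requires a measured blood-cell partition. Tissue composition
ships as a packaged CSV with a provenance column; pancreas and stomach
reuse gut values and the lumped rest organ reuses muscle (not tabulated in
the source compilations).

**Protein binding.** The printed unbound fraction "0.24" is read as
*percent* (fu = 0.0024), consistent with 99.7% binding; this reading is a
deliberate, documented interpretation and the value is configurable.
Binding scaling uses `fu' = 1/(1 + s·(1−fu)/fu)` where `s` multiplies the
binding-protein concentration at constant affinity.

**Intracellular driving concentrations.** Saturable processes (CYP3A4,
MRP2) are driven by the unbound intracellular concentration, taken as
`C_tissue/Kpu = fu·C_tissue/Kp` — i.e. unbound tissue water is assumed in
equilibrium with unbound plasma. This is an assumption; other conventions
(e.g. explicit intracellular sub-compartments) would rescale the enzyme
amounts, which is why the hepatic CYP3A4 concentration is the designated
calibration knob (below).

**GI tract.** Stomach plus seven intestinal segments (duodenum, upper/lower
jejunum, upper/lower ileum, caecum, colon), each with lumen volume,
absorptive area, pH and a first-order transit time; the terminal segment
routes to fecal elimination. Solid and dissolved drug transit at
`1/transit_time`; dissolved drug is absorbed transcellularly at
`P·A·min(C, S_lumen)` into the portal inflow. Dissolution follows the
empirical Weibull profile `F(t) = 1 − 2^{−(t/t50)^shape}` implemented as a
time-varying first-order hazard applied to the undissolved amount, so
transit can carry solids downstream while the aggregate dissolved fraction
tracks the fitted curve. Two numerical guards apply:

* the hazard is capped at 2.5 h⁻¹ — the Weibull hazard diverges at late
  times for shape > 1 (an artifact of the empirical form, prominent for
  the shape-5 capsule), while physically the rate is bounded by surface
  area and agitation; the cap preserves the early-dissolution advantage of
  faster formulations, which drives the observed formulation ordering of
  early absorbed fraction (solution > tablet > capsule);
* dissolution pauses when a segment reaches its saturation concentration
  (precipitation-free clamp), and only drug at or below saturation
  permeates; any supersaturated excess transits until capacity frees up.

The saturation concentration is the Henderson–Hasselbalch aqueous
solubility of the base, anchored at the printed reference value
(7.72×10⁻³ mg/mL at pH 6.5), multiplied by a luminal solubilization factor
(default 200) representing bile-salt micellar solubilization — biorelevant
solubilities of lipophilic bases are typically orders of magnitude above
aqueous. At this default the clamp rarely binds at clinical doses and
absorption is permeability-limited (small-intestinal absorption rate
constants ≈ 0.2–1 h⁻¹ from the declining mucosal-area profile), which is
what the fitted Weibull parameters presuppose. The oral solution enters
the stomach pre-dissolved; its configurable solubility scale (< 1, default
0.5) lowers the saturation cap for that arm, mimicking the suspension-like
behavior inferred for the clinical "solution".

**EHC.** Hepatic MRP2 efflux (Michaelis–Menten,
`kcat·E·Cu/(Km+Cu)` with `E` = reference concentration × liver volume)
delivers drug to bile. While the gallbladder fills, 10% of bile bypasses it
continuously into the duodenum and 90% is stored. Each meal event commits
45% of the stored amount to an ejecting pool that drains exponentially with
the 41.44 min emptying half-time into the duodenum; for the 241 min refill
time after a meal the contracted gallbladder cannot fill and all bile
bypasses it. Bile-origin drug is tracked as a separate dissolved pool in
the lumen so the fraction-absorbed bookkeeping refers strictly to the
administered dose (bounded by 1) while recycled drug still competes for
the same absorption and saturation capacity.

Meal times are a config default: with a fasted 8 am dose the defaults are
5 h (lunch), 11 h (dinner) and 24 h (next breakfast), repeating daily —
three events per 24 h and no event before the first meal. The 24 h meal
reproduces the characteristic secondary plasma peak about one day
post-dose directly; with an earlier first meal (e.g. 4 h) the first bump is
masked by the tail of dose absorption and appears only as a shoulder.

**Elimination.** Exactly three routes: saturable CYP3A4 metabolism in liver
and gut wall, and fecal excretion of unabsorbed or biliary-secreted drug.
The parent compound has no renal clearance.

## Parameters, units, calibration

Internal units are hours, µmol and µmol/L; ng/mL appears only at I/O
boundaries (1 µmol/L = MW ng/mL). Rate constants from in-vitro sources are
stored on their printed scale (1/min) and converted once at assembly.

The drug profile (MW 501.50 g/mol, pKa 6.32, logP 4.40, fu 0.0024,
solubility 7.72×10⁻³ mg/mL at pH 6.5, CYP3A4 Km 0.97 µmol/L and
kcat 0.67 min⁻¹, MRP2 Km 10 µmol/L and kcat 2111.11 min⁻¹, MRP2 reference
concentration 0.09 µmol/L liver, transcellular permeability
1.70×10⁻⁴ cm/min, Weibull tablet 36.00 min/1.29 and capsule 45.00 min/5.00,
EHC constants) ships as the packaged default configuration. Baseline
physiology is a standard ICRP-type 73 kg adult (cardiac output 390 L/h,
organ flows summing to it by construction).

Hepatic CYP3A4 tissue concentration is not a printed observable and depends
on the driving-concentration convention; it was calibrated once so that the
base model's oral plasma clearance matches the clinical CL/F implied by the
published single-dose 140 mg exposure (≈ 2.3 L/h), giving 8.5 µmol/L. It is
the designated tuning knob for metabolic capacity. The gut-wall
concentration (0.6 µmol/L) is a literature-scale mucosal estimate. With
these values the model's elimination is ≈ 70% metabolic / 30% fecal at
baseline, and biliary recirculation raises single-dose exposure ≈ 1.6-fold
over a no-recirculation counterfactual over 6 days.

## Scenarios

**Rifampin DDI.** The perpetrator is a one-compartment oral model (600 mg
daily; ka 1.7 h⁻¹, CL 12 L/h, V 55 L, fu 0.17) whose unbound concentration
drives `fold = 1 + Emax·Cu/(EC50+Cu)` (Emax 9, EC50 0.34 µmol/L) in a
synthesis-rate turnover model for liver (kdeg 0.0193 h⁻¹) and gut
(0.0301 h⁻¹) CYP3A4. These induction constants are literature defaults
from the published rifampin PBPK model, external to the cabozantinib
analysis. Competitive inhibition by rifampin is omitted (induction
dominates). With a 9-day lead-in the hepatic enzyme is ≈ 4.2-fold induced
at the victim dose — matching the ≈ 4.3-fold clearance increase reported
clinically — and the single-dose 140 mg capsule AUC ratio evaluates to
≈ 0.36 over a 600 h observation window.

**Hepatic impairment.** Grades apply the standard physiological changes:
hematocrit (0.39 mild / 0.37 moderate vs 0.47), portal flow ×0.40/×0.36,
renal flow ×0.88/×0.65, hepatic arterial flow ×1.30/×2.30, other organs
except brain ×1.75/×2.25, liver volume ×0.81/×0.65 (enzyme and transporter
amounts scale with it), CYP3A4 activity ×1.00/×0.40, plasma-protein factor
0.85/1.25. Cardiac output is recomputed as the sum of the scaled flows.
The protein factor follows the clinical narrative — factors above 1 raise
the unbound fraction (higher distribution volume and clearance, lower
Cmax), factors below 1 lower it — and is therefore applied internally as a
binding-protein concentration scale of 1/factor. (Published values for the
moderate factor vary between 1.25 and 1.30; the packaged default is 1.25.) Both impaired grades raise simulated exposure
over control (≈ +28% mild, +12% moderate for AUC to 504 h); the published
magnitudes (+64%/+50%) depend on the original platform's internal
physiology and fitted context and are not reproduced quantitatively.

**Sensitivity.** `local_sensitivity` returns the normalized central
difference `(ΔY/Y)/(Δp/p)` for any dotted-path parameter against AUC or
Cmax.

## Synthetic data

The clinical profiles used by the original analysis were digitized from
literature figures and are not redistributable. The generator therefore
emulates their statistical structure: single oral doses over the 20–140 mg
range; uniform anthropometrics with allometric scaling (volumes ∝ W,
flows ∝ W^0.75); lognormal inter-individual multipliers (median 1) with
default CVs of 0.35 on CYP3A4 kcat, 0.45 on MRP2 kcat, 0.30 on intestinal
permeability and 0.30 on the emptying half-time; multiplicative lognormal
residual noise (constant CV — concentrations stay positive); LLOQ
censoring by dropping; and a ground-truth sidecar table per study. The
generated profiles show the EHC secondary peaks, including a local maximum
after the first post-dose meal and peaks ≈ 24–26 h post-dose.

What passing tests on these data do *not* show: the generator shares the
simulator's structural assumptions, so recovery tests demonstrate
self-consistency of the estimation pipeline, not correctness of the
structural model against real patients; residual noise in real digitized
data is neither lognormal nor independent; and real meal times vary between
subjects, which smears secondary peaks that are sharp here.

## Numerics

LSODA (stiff-capable) integration restarted at every discrete event — dose,
meal (gallbladder commitment is a state jump), gallbladder refill-end and
perpetrator dose — so event logic stays exact; each segment is integrated
through to its boundary and the boundary state seeds the next segment.
Default tolerances rtol 1e-9 / atol 1e-12 (µmol scale); the output grid is
0.1 h plus event times. Global mass balance (all drug compartments plus
cumulative eliminated vs cumulative administered) holds to ~1e-14 relative
at the defaults and is asserted ≤ 1e-6 across scenarios; halving
tolerances changes AUC by < 0.1%. Multi-scenario tests and fits use
relaxed settings (rtol 1e-7…1e-5) that preserve these properties. The
dissolution clock references the most recent oral dose (a fresh Weibull
clock per dose; residual solids from a previous daily dose are ≥ 99%
dissolved or transited by the next dose). Saturable rates clamp negative
round-off states to zero. Tie-breaks: Cmax takes the earliest maximum;
fold-deviation bounds are inclusive; observed values ≤ 0 are excluded from
error statistics with the exclusion count reported.

Steady state for the average steady-state concentration requires ≥ 5
simulated intervals and a successive-interval AUC change < 1%; with the
model's long terminal phase the 60 mg daily tablet meets this after ≈ 40
doses (Css ≈ 940 ng/mL vs 1197.44 ng/mL reported).

Problem sizes used by the shipped tests and analysis drivers — single-dose
horizons of 96–600 h, impairment comparisons to 504 h, 40 daily doses for
steady state, populations of 1–8 individuals with 20 recovery seeds — were
chosen as the smallest sizes at which the respective quantities are stable;
the full 100-individual population simulation is available through
`simulate_population`/`--population 100` unchanged.

## Known limitations

* Rodgers & Rowland partitioning with logP 4.40 yields a large adipose Kp
  (≈ 44) and hence a very large Vss; the simulated terminal half-life
  (≈ 340 h) overestimates the ≈ 120 h observed clinically. Exposure
  metrics driven by clearance (AUC, Css, DDI ratios) are insensitive to
  this, but late single-dose concentrations run high.
* The gut model is a first-order transit simplification with effective
  areas; it does not reproduce the source platform's gut model, and the
  formulation contrasts are directional rather than quantitative.
* Metabolites are not modelled (insufficient data in the source); the
  fecal route lumps unabsorbed and biliary-secreted parent drug.
* The perpetrator model is deliberately minimal (no autoinduction of
  rifampin's own clearance, no inhibition component).
* Impairment scaling reproduces directions, not the published magnitudes
  (see above).
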