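# Methods

## The model

`abekin` implements a structured kinetic model of batch
acetone–butanol–ethanol (ABE) fermentation by solventogenic
*Clostridium*.  The metabolic network is the classical two-phase ABE
scheme: glucose is taken up through the PTS system and converted via
glycolysis to pyruvate, pyruvate–ferredoxin oxidoreductase (PFOR) feeds
acetyl-CoA, and acetyl-CoA is the branch point toward acetate, ethanol,
biomass, and the C4 branch (acetoacetyl-CoA → butyryl-CoA → butyrate /
butanol).  Acetone is formed by decarboxylation of acetoacetate produced
when the CoA-transferase re-assimilates acetate or butyrate.  The model
balances 16 species — glucose (G), fructose-6-phosphate (F6P),
glyceraldehyde-3-phosphate (G3P), pyruvate (Pyr), lactate (Lac),
acetyl-CoA (ACoA), biomass (X), acetate (Ac), ethanol (EtOH),
acetoacetyl-CoA (AACoA), acetoacetate (AcAc), butyryl-CoA (BCoA),
butyrate (Buty), acetone (An), butanol (BuOH) and NADH — over 19 lumped
reactions:

    dC/dt = v · r(C) · X

with `v` the 16×19 stoichiometric matrix, `r` the vector of specific
rates (h⁻¹, per unit biomass) and `X` the biomass concentration (mM; no
dry-weight conversion is attempted — the reference inoculum is 0.20 mM).

The distinguishing feature is that NADH is a *dynamic state* and an
explicit co-substrate of the three NAD⁺-regenerating reductive steps:
acetaldehyde dehydrogenase (r11, → ethanol), β-hydroxybutyryl-CoA
dehydrogenase (r14, acetoacetyl-CoA → butyryl-CoA) and butyraldehyde
dehydrogenase (r19, → butanol).  These three follow ping-pong
bi-substrate kinetics

    r = V·S1·S2 / (K1·S1 + K2·S2 + S1·S2),

with r19 additionally carrying competitive butanol inhibition
(the S1·S2 term is scaled by 1 + [BuOH]/Ki).  Because butanol formation
consumes reducing power while glycolysis produces it, the
acidogenic-to-solventogenic transition emerges from the redox balance
itself; no on–off switching functions are needed.  Single-substrate
steps are Michaelis–Menten; the two CoA-transferase legs (r8, r15) are
products of two independent Michaelis–Menten factors; glucose uptake
(r1) carries both substrate and butanol inhibition; cell death (r13) is
a constant specific rate.

## Transcription choices (and why)

The published rate-law table and balance matrix leave three genuinely
open readings; `abekin` resolves them as follows.

**Glucose-uptake denominator (r1).**  Implemented, in the single
function `glucose_uptake_rate`, as

    r1 = V1·G / ( k1A·(1 + G/k1C) + G·(1 + BuOH/k1B) )

with k1A = 11.54 mM (Michaelis), k1C = 2.56 mM (substrate inhibition)
and k1B = 89.50 mM (butanol inhibition).  The alternative pairing
(butanol Ki = 2.56 mM) would cap simulated butanol near 110 mM at any
glucose load, contradicting the model's own high-glucose response
surface (butanol > 150 mM), and would make butanol inhibition of uptake
~40× stronger than the two other butanol-inhibition constants fitted in
the same study (K12B = 144.58 mM on growth, K19C = 105.51 mM on r19).

**Stoichiometric matrix.**  Carbon coefficients are ±1 throughout
(lumped reactions absorb molecularities into their fitted constants).
The rows for F6P through acetone follow the printed matrix, which
matches the network topology exactly.  Three printed rows are internally
impossible (butanol produced by PFOR; NADH consumed nowhere) or violate
basic constraints (glucose produced by cell death; butyrate never
produced), and were reconciled against the network diagram: glucose is
only consumed (−1 at r1), butyrate is produced by phosphotransbutyrylase
/butyrate kinase (+1 at r18), butanol only by r19.

**NADH row.**  Follows the study's own cofactor accounting: glycolysis
yields 2 NADH per glucose (+2 at r3; the lumped network carries one G3P
per glucose), the ferredoxin cycle yields additional NADH at PFOR of
which part is diverted to NADPH (+1 at r6), and each lumped reductive
step consumes 2 (−2 at r11, r14, r19; butanol therefore costs 4 NADH
from butyryl-CoA synthesis onward).  Alternative integer couplings (±1
everywhere; no PFOR credit; ±2 credits with ±2 debits) make NADH either
never or always limiting and reproduce the published phase-resolved
sensitivities and NADH response surfaces strictly worse.

## Parameters

All kinetic constants come from the two packaged fits (`packaged_fixture
("fit_A"/"fit_B")`): maximum specific rates V (h⁻¹) and up to three
constants kA/kB/kC (mM) per reaction, 47 constants entering the rate
laws in total.  The table's kC = 2.56 entries for r16 and r18 do not
appear in any printed rate law; they are stored for fidelity but unused
(a log message notes this).  Fit B as printed lacks V16 and V18 and is
therefore not simulable without user-supplied values; it is stored with
the omission-tolerant schema.  Default fitting bounds are
[θ₀/100, 100·θ₀] around the starting values.

Initial conditions for the reference batch (fit A): glucose 70.6,
biomass 0.20, acetate 40.12, butyrate 2.12, acetone 2.58, butanol
4.46 mM.  The calibration experiments did not measure the intracellular
pools, so F6P, G3P, Pyr, Lac, ACoA, EtOH, AACoA, AcAc and BCoA start at
10⁻³ mM (small but nonzero to keep the stiff start smooth).  Initial
NADH is likewise unreported; the package default is 8.49 mM, the upper
bound of the physiological range cited for clostridia
(0.039–8.49 mM).  The choice matters: at 2 mM the simulated glucose is
exhausted near 14 h and the 15-h "solventogenic phase" of the published
sensitivity analysis has no remaining flux to be sensitive to, while at
8.49 mM depletion occurs past 15 h and the reported solventogenic
sensitivities are reproduced.  Both the pools and NADH are plain config
(`state_vector`, or the `--init` CSV of the CLI).

## Numerics

* Stiff integration: LSODA, rtol 10⁻⁸, atol 10⁻¹⁰ mM (constants span
  4·10⁻⁴ to ~500 mM).  Halving both tolerances moves no reported
  concentration by more than 0.1 % (tested).
* Negative excursions: the solver may step a pool slightly negative;
  rates clamp the state at 0 on evaluation (keeping the RHS smooth and
  the balance exact for admissible states), the reported trajectory is
  clamped at 0, and an excursion beyond a tolerance-scaled bound
  (10⁻⁶ mM at the default tolerances) is a hard error.
* r17's 1 + kB/[Buty] factor is evaluated in polynomial form
  (V·S²/(kA·S + kA·kB + S²)), which is exact and smooth at zero
  butyrate.
* Ping-pong rates take the 0/0 limit as 0 (co-substrate depletion halts
  the reaction).
* Estimation: scipy `least_squares` (trust-region reflective) on
  √w-weighted residuals; W is diagonal per species, wᵢ =
  1/max_t|Cᵢᵐᵉᵃˢ|², constant over time.  Finite-difference Jacobian
  steps are fixed at 10⁻³ relative so they dominate the ODE-solver noise
  floor in the residuals.  Missing cells are skipped, never imputed.
  Multi-start (log-uniform in the bounds, seeded) is available for
  rugged subsets.
* Sensitivity: the finite relative response S = (C(θ*) − C(θ))/C(θ) at
  time τ, one parameter perturbed per run; rankings score each
  parameter by max(|S(+f)|, |S(−f)|) with alphabetical tie-break;
  percentages are 100·S.  Undefined (division by zero) when the base
  concentration vanishes — the implementation raises then.
* Sweeps: each grid cell overrides initial glucose/NADH/acetate on the
  reference state and simulates 60 h; NADH is an initial condition by
  default because the cofactor is a balanced state (`clamp_nadh` holds
  it constant for the buffered-pool reading).  Selectivity Bn/An is
  undefined (NaN/flag) when acetone ≤ 10⁻⁶ mM.  Extremum location
  breaks ties toward the lowest axis values in axis order.

## Synthetic data

`generate_synthetic_dataset` emulates the *statistical shape* of the
calibration data the estimation module expects: 13 samples over 0–60 h
of the six measured species (G, X, Ac, Buty, An, BuOH), with
multiplicative noise C·(1 + cv·z) plus an additive floor, clamped at 0,
from a seeded generator.  It does not emulate instrument-specific error
structure, autocorrelated sampling error, replicate-to-replicate batch
variability, or missingness patterns of real HPLC/OD data — so passing
recovery tests demonstrate identifiability under the stated noise model,
not performance on any particular laboratory dataset.  Practical
identifiability is asserted (and tested) only for the {V1, V10, V14}
subset; the full 47-parameter problem is ill-conditioned, which is why
`fit_parameters` fits user-chosen subsets.

## What the acceptance numbers show

`scripts/acceptance.py` recomputes nine headline quantities of the
simulation study.  With the transcription above, the butanol plateaus
over NADH (t3 ≈ 62.7 vs 60 mM; t4 ≈ 79.1 vs 77 mM) and the
solventogenic/acidogenic butanol sensitivities (t6 ≈ 13.9 vs 15 %;
t7 ≈ 29.7 vs 28 %) reproduce the published values.  The selectivity
extrema, the acidogenic acetone sensitivity, and the high-glucose
production ceilings do not (t1 ≈ 5.0 vs 3.6; t2 ≈ 1.3 vs 2.1;
t5 ≈ 8.5 vs 26 %; t8 ≈ 250 vs 160 mM; t9 ≈ 55 vs 140 mM): they sit on
opposite sides of the NADH supply/demand balance, and no self-consistent
integer reading of the cofactor row reproduces both groups at once.
The qualitative structure is reproduced throughout — the selectivity
dip-and-recover profile along glucose at physiological NADH, the
saturating butanol-vs-NADH curves whose plateau rises with glucose, and
the dominance of glucose uptake (V1) in the acidogenic rankings.

## Known limitations

* pH dynamics, hydrogen production, gas stripping, fed-batch/continuous
  operation and NADPH accounting are outside the model's scope.
* Biomass is a single lumped state; no maintenance term beyond the
  first-order death rate.
* The transcription ambiguities above mean absolute numbers (especially
  selectivity levels) should be read as model-family results, not exact
  reproductions.
* Problem sizes in the test-suite (coarser sweep grids than the
  headline 51×33 surface, 10 noisy-recovery replicates) were chosen to
  keep the default run comfortably interactive; the acceptance script
  uses the full grids.
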