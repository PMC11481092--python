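# Methods

This note documents the models behind `flowopt`: what the virtual rig
does and does not emulate, how it was calibrated, how the optimizer is
put together, and where the genuinely open design choices were made.

## 1. The virtual rig

### Step 1 — packed-bed hydrogenation

The liquid-phase reduction of 4-nitrophenol over a packed catalyst bed is
modelled as a single first-order step in the nitro compound:

    τ₁    = V_bed / Q₁
    k_eff = A₁ · m_cat · exp(−Ea₁ / R T₁) / (1 + K_inh · C₁)
    X     = 1 − exp(−k_eff · a · τ₁)

Assumptions: hydrogen at 7 bar is always in excess, so the gas side is
never rate-limiting and does not appear in the rate law; plug flow in the
bed; catalyst activity `a` enters multiplicatively and affects only this
step.  The weak inhibition term `1 + K_inh·C₁` makes feed concentration
the least influential variable, reproducing the observed behaviour
without invoking a mechanistic adsorption model.  The small amount of
water formed by the reduction is not tracked: the step-2 water inventory
is owned by the solvent (see §1.2), which keeps reservoir experiments
made from step-1 outlet and from commercial material exactly comparable.

### Step 2 — plug-flow amidation

Acylation competes with anhydride hydrolysis by the trace water that wet
2-MeTHF carries, and with a slow second acylation of the product:

    d[2]/dt = −k₂[2][3]
    d[3]/dt = −k₂[2][3] − k_h[3][w] − k_da[4][3]
    d[4]/dt =  k₂[2][3] − k_da[4][3]
    d[5]/dt =  k_da[4][3]
    d[w]/dt = −k_h[3][w]
    d[AcOH]/dt = k₂[2][3] + 2 k_h[3][w] + k_da[4][3]

4-nitrophenol is inert in this step (the control experiment with a 50:50
reservoir of 1:2 gives the same yield as pure 2).  The final conversion
of 2 is set by whether the anhydride excess outlasts the water, which is
why equivalents dominate this step and why, beyond completion, the yield
plateaus over a wide range of residence times.  Both k₂ and k_h follow
Arrhenius laws; their activation energies are deliberately close
(30 vs 20 kJ/mol, hydrolysis referenced to 373.15 K), so the competition
is only weakly temperature-sensitive and the amidation temperature ends
up the least important variable of the telescoped campaign — as the
length-scale ranking then shows.  The double-acylation constant is small
enough that the 4′-acetoxyacetanilide by-product stays below 0.5 % of
the fed aminophenol everywhere inside the bounds.

### Telescoping

The telescoped rig runs step 1, removes the gas phase through an ideal
separator (liquid unchanged), mixes the outlet with the anhydride stream
by flow-weighted averaging (Q₃ = Q₁ / ratio), and runs step 2 with
τ₂ = V_R2 / (Q₁ + Q₃).  The overall yield is moles of product out per
mole of nitrophenol fed, so dilution by the second stream is accounted
for.  Both feed solutions carry the same solvent water content.

### Catalyst deactivation

Activity decays as `exp(−k_slow · t)` with k_slow = ln(1/0.96)/28 h⁻¹,
i.e. 4 % over a standard 14-experiment campaign (2 h per experiment) —
inside the <5 % band that monitoring is meant to confirm.  Two discrete
events exist: an abrupt failure (activity × 0.7, default off, scheduled
by experiment index to emulate sudden late-campaign deactivation) and a
shutdown/restart (+5 % relative, capped at full activity).  Monitoring
runs — the design-space midpoint, every fourth optimization experiment —
age the catalyst like any experiment but never train the surrogate.

### Measurement

HPLC yields receive additive Gaussian noise (σ = 0.01 absolute by
default, clipped to [0, 1]).  With probability p_fault = 0.02 a sample is
a blank: the gas–liquid separation failed, both yields read below 0.02
and a blank flag is set, emulating the fault an operator would catch on
the chromatogram.

### Numerical choices

Single evaluations integrate the step-2 system with an adaptive
stiff-capable solver (LSODA, rtol 1e-7, atol 1e-9).  Dense-grid sweeps
use a vectorized fixed-step RK4 with per-system time scaling (900 steps
per residence time), validated in the suite against the adaptive solver
to 1e-5 absolute in every species; concentrations are clamped to be
nonnegative.  Step-1 conversions are closed-form and exact.

### Calibration

Three constants are free; everything else is fixed by the qualitative
behaviour above.  Calibration is a deterministic sequence of 1-D
bracketing searches on noise-free grid maxima, each monotone in its knob:

1. hydrogenation pre-exponential A₁ → step-1 grid maximum = 0.65;
2. amidation pre-exponential A₂ → step-2 maximum on the intermediate
   mixture (the step-1 optimum outlet, ≈65:35 of 2:1) = 0.97;
3. telescoped anhydride stock concentration → overall maximum = 0.85.

Residual tolerance is ±0.005 yield.  The shipped `paper` preset is the
frozen output of this procedure; the suite re-verifies all three grid
targets on every run.  Whether the 85 % telescoped optimum is limited by
step-1 conversion or step-2 selectivity is not constrained by the
targets; under the shipped calibration it is a mix (X₁ ≈ 0.94 at the
optimum corner, step-2 conversion ≈ 0.90).

## 2. The optimizer

Inputs are unit-scaled to [0,1]ⁿ; objectives are standardized per fit.
The surrogate is a GP with Matérn-5/2 ARD kernel, amplitude and
length-scale hyperparameters (bounds [0.01, 100] in unit space) and a
fitted noise variance floored at 1e-8, maximizing the log marginal
likelihood from 5 seeded log-uniform restarts.  Small campaigns (7–30
points) need exactly this kind of regularized, reproducible fit.
Prediction uses dense Cholesky algebra at the fitted hyperparameters and
is cross-checked against an independent posterior implementation.

Acquisition is expected improvement with an exploration offset ξ in
standardized units.  The schedule is geometric and cyclic: ξ starts at
0.05, shrinks ×0.7 after any experiment that improves the best observed
yield by more than 0.005, grows ×1.5 otherwise, within [0.005, 0.5] — and
a stagnation step that would exceed the ceiling wraps ξ back to the
floor.  The wrap is a deliberate design choice: a pure ratchet parks a
stagnating campaign at maximum exploration for its entire remaining
budget, and on a noiseless concave test surface that costs the final
0.5 % of yield; cycling turns sustained stagnation into alternating
exploration bursts and exploitation phases.  The published description of
the adaptive-EI optimizer names the behaviour but not the update rule, so
this schedule is this package's own documented stand-in.

Proposals maximize EI by 64 seeded local searches (32 uniform starts, 32
Gaussian perturbations of the incumbent, σ = 0.1), tie-broken toward the
lexicographically smallest unit-scaled point; a numerically flat
acquisition falls back to the maximum-posterior-sd point and is flagged.
Termination: budget; a plateau (no best-yield improvement beyond 0.005
over the last 5 optimization experiments, never during the Latin
hypercube); or, optionally, a maximum posterior sd below a set threshold
over a 1024-point seeded sample.  Default budgets are 25 for single-step
campaigns and 18 for telescoped ones.  `experiments_to_optimum` is the
first optimization experiment whose measured yield is within one
percentage point of the campaign's final best — the published counts are
"found after N experiments" without a stated closeness, so the tolerance
is made explicit here.

Anomaly handling: an experiment is discounted and repeated (up to three
times) when its measurement carries the blank flag, or when its yield is
below 0.02 while the surrogate confidently expected more than 0.10.
Rejected and monitoring records are excluded from every fit; this hygiene
is asserted on each iteration.

## 3. Green metrics

Mass flows are steady-state rates.  Feed streams are converted to
per-material g/h using stock concentrations and molar masses (139.11,
109.13, 102.09, 151.16 g/mol for species 1–4; solvent density
0.854 g/mL); the solvent rate is the stream mass rate minus dissolved
solutes, and hydrogen enters at the preset gas rate (stoichiometric plus
excess, kept below 1 % of total mass).  PMI is total input mass over
product mass; the 20 %-solvent scenario counts only a fifth of the
solvent as consumed.  Work-up, isolation and transport masses are outside
the boundary.  The published comparison table is reproduced from its own
printed row inputs (total mass, product mass, solvent percentage), since
printed solvent percentages are rounded to integers the arithmetic
agrees within ±3 %.

## 4. What the rig does not emulate

No mass-transfer or dispersion physics (Taylor flow, bed hydrodynamics),
no hydrogen partial-pressure dependence, no separator membrane model, no
oxidative degradation of the aminophenol, no adsorption/desorption
catalyst chemistry.  Within-bounds behaviour is calibrated to three
scalar optima and a set of qualitative trends; agreement of campaign
statistics with the published counts therefore shows that the optimizer
is efficient on a surface with the right shape and noise, not that the
kinetic constants are those of the physical system.  Variable bounds and
reactor constants in the presets are documented working assumptions, and
the published mass-flow table is internally inconsistent with a
minimal-flow optimum on any monotone rig, so campaign-derived mass flows
are reported alongside, not instead of, the published-inputs table.

## 5. Problem sizes

Dense grids use 41 points per axis for the 3-variable spaces and 21 (15
inside calibration loops) for the 4-variable telescoped space; campaign
statistics use 20 seeded repeats at σ = 0.01, p_fault = 0.  These sizes
give grid maxima stable to well under the ±0.5-point calibration band
and medians stable across seed batches.
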