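# Methods

This note records the models behind `flowopt`, the parameters that matter,
the choices made where the design was genuinely open, and what the
simulator does and does not capture about a physical rig.

## The optimization loop

The search kernel is the complex method: k vertices inside the bounded
condition box (temperature, residence time, reagent equivalents), with the
worst vertex reflected through the centroid of the remaining ones.

Defaults: k = dimension + 1 = 4 vertices; reflection factor α = 1.3;
out-of-bounds coordinates clipped to 1 % of the range inside the violated
bound; up to 3 halving retreats toward the centroid when a reflection
remains the worst vertex, then a uniform re-draw of that vertex; stop when
the relative spread of vertex scores falls below 1 % or after 40
evaluations.  All randomness flows through one `numpy` Generator seeded
explicitly; with the spread tolerance set to zero and a fixed budget, runs
are bit-reproducible.

Two properties of the stopping rule are worth knowing.  First, a score
spread of 1 % resolves position only to about √0.01 = 10 % of range on a
unit-curvature surface, so checks that demand 2 %-of-range accuracy run in
the fixed-budget configuration (spread tolerance 0, 100 evaluations).
Second, with detector noise contributing roughly 0.5–1 % of the score, the
spread rarely crosses the 1 % threshold early: campaigns typically spend
their full 40-evaluation budget.  A budget of 40 was chosen so the
stopping rule, not the cap, normally ends a campaign; historical rigs that
stopped after ~9 experiments were budget-capped, and with this algorithm
9 evaluations are not enough to localize a 3-D optimum to a few degrees
(the suite documents that tension as a deliberately failing check).

The optimizer never averages repeated measurements; smoothing is the
process-control layer's job (steady-state window means).

## Evaluation functions

Scores are a product of normalized factors,

E = c^(w_c) · (τ_min/τ)^(w_τ) · (x_min/x)^(w_x) · (1 − γ (T−T_lo)/(T_hi−T_lo))^(w_T),

with c = p/(p+s) the IR peak-ratio conversion estimate.  The multiplicative
form was chosen because it preserves the published term inventories, the
monotonicities the published optima imply (E increasing in c, decreasing in
τ, x and T where the respective terms are active), dimensionlessness, and
the bound E ∈ [0, 1] with E = 1 exactly when every active factor is
maximal.  Default exponents are 1 and the energy slope is γ = 0.3 (a 30 %
score penalty at the hottest admissible temperature).  Normalization
constants come from the campaign's parameter space, making scores
comparable across campaigns.  The published reports do not disclose their
exact algebraic forms; this family is a declared surrogate validated by
the calibration-and-recovery tests.

## Reactor model

A single effective mechanism generates every campaign's response surface:

- A + B → P, second order, rate constant k₁(T) = A₁·exp(−Ea₁/RT);
- P → Q, first order, k₂(T) = A₂·exp(−Ea₂/RT);

integrated over one residence time in an ideal 20 mL plug-flow coil.  The
substrate A follows its closed-form second-order solution; P is propagated
with an exponential integrating-factor rule per substep (unconditionally
stable for arbitrarily stiff degradation), and the high-accuracy scalar
path uses an adaptive stiff integrator at rtol 1e-10, checked against the
closed form to 1e-6.  The series degradation exists so that interior
optima in temperature and residence time are representable at all: with
formation alone, any conversion-seeking objective pins T and τ to their
upper bounds.

The IR readout is Beer–Lambert: p = ε_p·[P], s = ε_s·[A], plus additive
Gaussian noise with σ = 0.5 % of the clean full-scale absorbance
(ε_p · feed concentration).  Feed concentrations are back-calculated from
published production rates where available (tramadol from its volumetric
yield, the bupropion steps from their g/h rates) and default to 0.5 M
otherwise.  Molar masses are always computed from molecular formulas with
standard atomic weights.

## Calibration

`calibrate()` makes the published optimum the simulator's ground truth.
At the target point it imposes the target yield and first-order optimality
of E in every coordinate interior to its range (log-slope of c equal to
the penalty exponent), with the correct inequality at coordinates on a
bound.  The unknowns are the Damköhler numbers θ = k₁a₀τ*, κ = k₂τ*, the
band-coefficient ratio ρ = ε_s/ε_p, and the activation-energy pair.  The
system is solved exactly per coordinate status; the temperature condition
then yields Ea₂/Ea₁ in closed form; remaining free parameters are scanned;
and every candidate is verified against the brute-force oracle — the
argmax of noiseless E on a 41³ grid must land within one grid cell of the
target in each representable coordinate.  Ea₂ is capped at 400 kJ/mol with
Ea₁ re-solved so the stationarity product is preserved exactly; the
fitted kinetics are effective parameters of a lumped pathway, not claimed
to be chemically real.

The ratio ρ matters because at high conversion the plain peak ratio
saturates (c → 1 regardless of τ): a stronger substrate band keeps the
signal informative near complete conversion, which is what makes interior
residence-time optima reachable for the high-yield campaigns.

Three published coordinates are provably not representable by this
mechanism, and the calibration reports them (diagnostics
`infeasible_coords`) rather than approximating silently:

1. **Stoichiometry interior optimum without a consumption term** (second
   lidocaine step, 3.9 equiv inside 1.0–4.0): c is structurally monotone
   increasing in reagent excess, so with no penalty on x the argmax sits at
   the adjacent 4.0 bound, 0.1 equiv from the published value.
2. **Interior residence time at a stoichiometric-cap yield** (bupropion
   bromination, τ = 9.7 min at 95 % yield with 0.95 equiv): a yield at the
   cap saturates c, so the throughput term drives τ to its lower bound.
   The log-slope-1 stationarity would require c to still be rising
   proportionally to τ, impossible within ~1.5 % of the cap.
3. **Interior residence time under a conversion-only objective at high
   yield** (bupropion alkylation, τ = 20 min at 80 % yield): a peak of c
   in τ requires the degradation exposure rate to match the substrate
   decay rate (~1.3 per residence time here), but an 80 % yield bounds the
   total degradation log-loss to ~0.14.  The equation system has no root,
   which the solver detects constructively before relaxing τ.

All yields, all bound coordinates and all other interior coordinates meet
the grid-cell criterion for all five campaigns.

## Process control

Experiments advance a simulated clock: a 5 min solvent flush, then
sampling every 0.5 min while the outlet approaches the new steady state
first-order with time constant τ (the residence time).  Steady state is
declared when a rolling window — spanning at least one time constant, with
the configured 5-sample window as a floor — keeps both bands within
`rel_tol·|mean| + abs_tol`, where the deadband `abs_tol` defaults to 6
detector sigmas, and a trend test bounds the remaining first-order offset
inside the band (the half-window mean drift, amplified by the analytic
lag factor, must also fit).  The experiment reading is the window mean; a
transient exceeding 6τ raises a stalled-experiment error.  Nine-experiment
campaigns take ~5–6.5 simulated hours, within twice the historical three
hours — adequate for an order-of-magnitude model of rig cadence.

The telescoped timeline models the intermediate band as a cascade of the
stage-1 residence-time lag and the junction-holdup lag; the second stage's
feeds start when that band first crosses 50 % of its plateau, and the
product band then rises through the stage-2 lag.  Feed outages zero the
affected stream: during the outage the evaporator-outlet composition is
enriched by (main flow)/(main − outage flow) and washes through the holdup
first-order; the fluctuation duration is the time spent outside the 1 %
band.  The holdup volume is sized (by root-finding on the simulated
response) so a 3 min outage yields an 8 min fluctuation — a declared
calibration to the observed anecdote, stated as such.

## Telescoped mass balance

Streams carry volumetric flow, per-species molar concentrations and the
solvent pool as mole fractions, with ideal volume additivity (solute
volume neglected); mixing and evaporation conserve species moles exactly
(to 1e-12 in the tests).  The bisulfite workup passes the organic phase
through and drops the quenched excess halogen; the evaporator removes 87 %
of the DCM moles.

The original feed flows are not public.  `build_process` keeps what was
published — stage 2 at (90 °C, 20 min, 3.0 equiv) with the amine reservoir
at 1.928 M, stage 1 at (44 °C, 9.7 min) with equivalents raised to 1.0 —
and solves the remaining free quantities (stage-2 inlet concentration,
amine/evaporator/NMP flows, stage-1 feed concentration) so the steady
production equals 2.88 g/h.  After that single declared calibration,
`telescoped_rate` recomputes the rate purely by forward mass balance, and
the amine-alignment consistency (required feed concentration = 1.928 M at
3.0 equiv) emerges rather than being imposed.

## What the simulator does not capture

Axial dispersion, heat transfer, solids handling, liquid–liquid
equilibrium in the workup, vapor–liquid equilibrium in the evaporator
(fixed removal fraction instead), multi-wavelength spectra and chemometric
peak fitting, and any solvent effect on kinetics.  Passing tests therefore
demonstrate that the control and optimization layers behave correctly
against a self-consistent nonlinear response surface with realistic noise —
not that the fitted kinetics describe the real chemistry.

## Problem sizes

Default test and acceptance workloads: 41³ grid oracles per calibration,
20-seed recovery ensembles at 40 evaluations each, 10 h telescoped
timelines sampled every 0.5 min.  These sizes make the full suite and the
acceptance script each complete in a few minutes on one CPU while keeping
every stochastic check a median over 20 independent campaigns.
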