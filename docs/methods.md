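# Methods

## Model structure

The model describes cytosolic redox homeostasis as a balance between a
lumped reactive-oxygen pool (ROS, proxying H₂O₂) and its glutathione/NADPH
antioxidant system, driven by three extracellular nutrients — glucose,
glutamine and cystine — that are treated as piecewise-constant inputs
(instantaneous medium changes, no mixing kinetics).  Ten concentrations are
integrated: intracellular cystine, cysteine, glutamate, NADPH, GSH, GSSG,
ROS, calcium, reduced (active) tyrosine phosphatase and phosphorylated
(active) tyrosine kinase.  Three moieties are conserved algebraically and
never integrated separately: NADP⁺ = NADP_total − NADPH, oxidized
phosphatase = PPTase_total − PPTase_red, unphosphorylated kinase =
TK_total − TK_phos.

Kinetic conventions:

- mass action everywhere except nutrient transport, which saturates
  hyperbolically in the extracellular nutrient, and ROS autoinhibition,
  a decreasing Hill factor K^n₁/(K^n₁ + ROS^n₁) multiplying all ROS
  production (lumping enzyme saturation and oxidative self-limitation of
  mitochondrial metabolism);
- cystine import through the SLC7A11/xCT antiporter consumes one
  intracellular glutamate per cystine (strict 1:1 antiport), and its rate
  is proportional to transporter abundance and glutamate;
- removal of one ROS consumes two GSH (third-order: k·ROS·GSH²); GSH and
  GSSG share one first-order degradation constant;
- NADPH regeneration is split between a glucose (oxPPP) route and a
  glutamate (TCA-associated) route, biased by the dimensionless switch
  s ∈ [−1, 1] (+1: fully glucose-dependent);
- ROS production is an additive partition (basal + glucose-driven +
  glutamate-driven) multiplied by calcium, active kinase and the
  autoinhibition factor;
- signaling: phosphatase is re-reduced by GSH and oxidatively inactivated
  by ROS; kinase is phosphorylated at a constant rate and dephosphorylated
  by active phosphatase; calcium has basal and ROS-stimulated influx and
  first-order efflux.

Units are µM and minutes throughout; fluxes are µM/min.  (Literature GSH
values quoted in mM are converted at reporting only.)

Feedback-loop perturbations are multiplicative knockdowns of the loop
coupling constants: the cystine-NADPH loop scales cystine reduction and its
NADPH cost together; the ROS-GSH loop scales GSH oxidation and
GSH-dependent ROS removal together; the positive loops scale the
ROS-stimulated calcium influx and the ROS-phosphatase oxidation. A factor
of 1 reproduces the unperturbed model bitwise; 0 severs the loop.

## Calibration

Rate constants are estimated from a steady-state constraint table rather
than fitted to time series.  Stage 1 computes every constant whose reaction
flux is tabulated, by dividing the flux by the product of the participating
concentrations and fixed saturation factors.  Stage 2 assumes each ODE
balance vanishes at the tabulated state and solves every equation left with
exactly one unknown constant, iterating until the system closes; the
iteration order is discovered automatically, and an equation retaining two
or more unknowns raises an explicit closure error.  Because every flux is
linear in its constant, the recovery is exact to floating point, giving the
central property `calibrate(steady state of P) = P` for any admissible
parameter set.

Signaling-loop constants can be constrained in two modes.  With tabulated
fluxes they are recovered exactly like metabolic constants.  Without them
(the realistic case: absolute signaling fluxes are rarely measured), fold
activations across the redox catastrophe fix the calcium-loop ratios, and
the steady-state balances fix the forward/reverse ratios of the phosphatase
and kinase cycles; one absolute timescale per loop (calcium export rate,
phosphatase oxidation rate constant, kinase phosphorylation rate) completes
the set and is documented in the default table.

Saturation constants, conserved totals, the ROS-partition fractions, the
Hill exponent and the SLC7A11 level are inputs ("fixed" rows of the table),
not calibration outputs.  SLC7A11 abundance in molarity is obtained from
proteomic ppm via a reference protein of known molarity (actin),
`estimate_slc7a11_concentration`, giving the 0–10 µM range from which the
default (5 µM, a high-expressing cell) is taken.

Fluxes reported per cell or per mg protein convert to µM/min with a default
cell volume of 3 pl and protein content of 300 mg/ml.

## The default configuration

The shipped table (`data/default_constraints.csv`) encodes a
self-consistent glucose-addicted reference cell at 10 mM glucose, 2 mM
glutamine, 200 µM cystine: GSH 3 mM with GSH:GSSG = 100:1, NADPH 0.96 of a
1 µM NADP(H) pool, ROS 10 nM, glutathione redox-cycle flux 100 µM/min, de
novo GSH synthesis 30 µM/min (pool half-life ≈ 1.2 h), cystine uptake
30 µM/min, NADPH regeneration 96% glucose-routed (s = 0.95), ROS production
dominated by the glutamate/anaplerosis partition (75%), and signaling pools
of 100 nM poised for strong activation (kinase 2.2-fold from basal to
saturated, phosphatase mostly oxidizable).  These magnitudes were chosen
once, as a realistic configuration reproducing the reported redox
phenotypes of glucose-addicted lines, and are not asserted to equal any
published cell line's measured fluxes.

Measured behavior of the calibrated model (also recomputed by
`scripts/acceptance.py`):

- saddle-node points of the glucose bifurcation at ≈11.9 µM (loss of the
  antioxidant state) and ≈151 µM (loss of the oxidized state); between
  them the redox fate is history-dependent, and glucose add-back after a
  collapse reverses it only above the upper fold (200 µM reverts, 25 µM
  does not);
- high-branch GSH stays above 2 mM down to ≈100 µM glucose;
- full glucose withdrawal triggers the catastrophe at ≈48 min with a
  NADPH→GSH 90%-decline gap of ≈17 min; deprivation to 12 µM (just below
  the fold) stretches the gap to ≈86 min;
- GSH collapses when the total NADP(H) pool is cut to ≤0.1 µM but not at
  0.2 µM, and enlarging the pool from 1.0 to 1.3 µM prevents the
  deprivation-induced catastrophe;
- cystine dilution to 1/4–1/8 of reference rescues the catastrophe at zero
  glucose (the fold moves below zero), whereas cystine+glutamine
  co-dilution cannot push the fold below ≈5 µM glucose — dilute glutamine
  starves both the glutamate NADPH route and GSH synthesis.

One reported property is *not* met by this configuration and its check is
left failing deliberately: NADPH's 90% depletion after full deprivation
takes ≈34 min here versus the reported ≤10 min.  The glutamate-route NADPH
regeneration required for the pool-enlargement rescue and the fold position
buffers the early NADPH crash; making the crash faster (weakening that
route) breaks those two properties in exchange.  We chose the rescue and
fold fidelity and record the trade-off here.

Approximate literature values are asserted in the acceptance tests at
±20%, the precision with which they are reported ("≈" figures).

## Numerics

- Integration: LSODA with the analytic Jacobian (hand-derived, verified
  against finite differences in the tests), rtol 1e-8, atol 1e-12 µM;
  integration restarts at every schedule switch so discontinuous inputs
  never cross a solver step.  The system is stiff: ROS turnover is
  ~2000/min while glutathione-pool turnover is ~1e-2/min.
- Steady states: Powell root finding on log-transformed concentrations
  (positivity and conditioning across ≥6 decades), multi-started from a
  Latin-hypercube subsample of a log-spaced lattice (deterministic seed),
  the endpoints of long integrations from strongly reduced and strongly
  oxidized extremes, and log-midpoint seeds between coexisting attractors
  (which reliably land on the separating saddle).  Duplicates are merged at
  1e-5 relative distance in log space; stability is the sign of the largest
  real part of the analytic Jacobian's eigenvalues.
- Bifurcation scans warm-start each grid point from its neighbor's fixed
  points, re-seed with the full multi-start periodically and whenever a
  branch is lost, and refine fold points by bisection on the stable-state
  count (default axis tolerance 0.1 µM).
- The catastrophe time is the argmax of dROS/dt evaluated from the analytic
  right-hand side along the trajectory (no finite-difference sensitivity to
  the sampling grid).  A trajectory with max dROS/dt below 1% of its ROS
  scale per hour, or that does not *end* at least twofold above its
  pre-perturbation ROS, reports "no catastrophe": the end-state gate keeps
  brief relaxation spikes of rescued trajectories from registering as
  collapses, mirroring the twofold criterion used to call single cells
  responsive.
- Finite perturbations near the fold: stepping from 10 mM glucose to a
  value within ~4 µM above the lower fold can escape the shallow basin of
  the still-existing antioxidant state and collapse anyway.  This is a
  genuine property of large perturbations near a saddle-node, not solver
  error; consistency checks between catastrophe occurrence and the
  bifurcation diagram therefore probe deprivation targets clearly below
  the fold and clearly above this band.

## Synthetic single-cell data

The generator emulates ratiometric H₂O₂-probe time-lapse experiments.  Each
cell draws lognormal multiplicative jitter (default CV 10%) on a
configurable parameter subset — transporter abundance (SLC7A11), basal ROS
production and NADP(H) pool size, the axes along which real cells plausibly
differ — with an independent, cell-id-keyed random stream; a configurable
fraction of deliberate non-responders receives an enlarged NADP(H) pool
that places it outside the catastrophe-committed region.  Cells are
simulated under the nutrient protocol from their own pre-perturbation
steady state, the ROS course is normalized to baseline (probe ratio treated
as linear in ROS over its operating range; probe kinetics and saturation
are not modeled), multiplicative lognormal measurement noise (default CV
5%) is applied, and traces are sampled every 15 min.  The generator records
ground truth (committed or not, true catastrophe time) from the noiseless
trajectory.

Statistics on such traces follow the conventions of the imaging analyses
they emulate: cells are *responsive* if the ratio reaches twofold within
90 min of the perturbation (75 min windows for the hysteresis summaries);
dose-response curves use the per-dose median over cells, excluding
non-responders at the lowest doses; the Hill exponent's 95% CI comes from
bootstrap resampling of cells within doses (default 1000 resamples, fixed
seed); hysteresis is summarized as the percent responsive per deprivation
level versus the percent irreversible (still ≥2-fold at the end of the
add-back window) among previously responsive cells.

What passing these tests does and does not show: the synthetic population
reproduces the statistical *structure* of single-cell ROS data (all-or-none
heterogeneous switching, ultrasensitive dose response, hysteresis) with
known ground truth, so the statistics are validated as estimators.  It does
not validate the model against real traces: real cells have correlated
parameter variation, slow adaptation (glycogen buffering, AMPK signaling),
probe saturation, and death-associated signal loss, none of which are
generated.

Feedback-loop dependence of bistability: severing the cystine-NADPH,
ROS-GSH or phosphatase-kinase loop abolishes the bistable window in this
configuration, while severing the ROS-calcium loop only narrows it (the
upper fold drops): the calcium gain was deliberately kept weak to place the
upper fold near 150 µM, so calcium acts as a modulator of the oxidized
state's range rather than a prerequisite for bistability.  Dynamic
rescues share the finite-perturbation caveat above: at 1/8 cystine dilution
the deprivation trajectory settles onto the surviving antioxidant state,
while at 1/4 dilution that state exists but the transient can escape its
basin.

## Known limitations

- No gene regulation, AMPK adaptation, intracellular glucose/glycogen
  reservoir, or trans-sulfuration cysteine source; no spatial or
  mitochondrial compartmentalization.  These are the main reasons measured
  NADPH/GSH declines in real cells lag the model's.
- The default constants form one self-consistent glucose-addicted
  configuration; they are produced by the calibration module from the
  shipped table and are not the (unpublished) constants of any specific
  study.
- Oscillatory attractors, if produced by exotic parameter sets, are
  reported as instability of fixed points but not continued as limit
  cycles.
- The calcium module is a two-parameter linear balance; calcium "fold
  activation" inputs beyond the bistable switch's needs are not modeled
  mechanistically.
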