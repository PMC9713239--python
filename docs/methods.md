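# Methods

`kneeplan` implements a probabilistic pre-operative planning chain for
ligament-balanced total knee arthroplasty (TKA):

1. quantify subject-specific uncertainty in ligament properties by Bayesian
   sampling against *native safe zones*;
2. optimize the planned implant position so that, under surgical placement
   error and that property uncertainty, the probability of a
   ligament-balanced outcome (the *global success probability*, GSP) is
   maximal;
3. rank the ligament properties that limit the GSP with a
   moment-independent sensitivity measure.

This note records the models, defaults and numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The knee model

The knee is a rigid-body model with ten tension-only line-element ligament
bundles (deepMCL, supMCL, LCL, ALL, PFL, two ACL bundles, two PCL bundles,
posterior capsule) spanning femur and tibia.  At each prescribed flexion
angle, the five secondary tibiofemoral degrees of freedom — M/L, A/P, P/D
translation (mm) and V/V, I/E rotation (deg) — settle into the configuration
of minimal total elastic energy.  This quasi-static treatment mirrors
force-dependent kinematics, which is itself a quasi-static equilibrium of
the passive structures; patellofemoral mechanics and muscle loads are out of
scope.

**Ligament law.** Force is zero in slack (ε ≤ 0), quadratic in the toe
region (0 < ε ≤ 2ε_l, f = k ε²/4ε_l) and linear above (f = k(ε − ε_l)),
continuous and C¹ at the transition.  Each bundle carries two subject
parameters: linear stiffness k (N, force per unit strain) and reference
strain ε_r, which fixes the slack length via l0 = L_ref/(1 + ε_r) with
L_ref measured at the reference pose (20° flexion, zero secondary
displacement).  The toe half-width is ε_l = 0.03 for every bundle, a
standard value for line-element ligament models; it is configurable in
`SolverSettings`.  Strains are dimensionless internally (0.06 ≡ 6%).

**Contact.** Each femoral condyle is a sphere articulating in a shallow
spherical dish on the tibia (radial clearance 8 mm medially, 15 mm
laterally).  The dishes stand in for tibial conformity — menisci and plateau
concavity natively, insert conformity after TKA — and give the joint
physiological anterior/posterior and rotational stability through contact.
Penetration is penalized quadratically at 10⁴ N/mm.  An earlier flat-plateau
variant left A/P bistable once the cruciates were removed (a drawer-lax
joint with a discontinuous equilibrium map), which is neither realistic for
a conforming insert nor learnable by a surrogate; the dished surfaces
resolve both.

**Loads and regularization.** A 100 N compressive preload acts along P/D so
the one-sided contact has a unique resting configuration, and a weak
soft-tissue envelope (1 N/mm on translations, 2 N·mm/deg² on rotations,
centred at the aligned pose) regularizes directions that ligaments and
contact leave unconstrained when slack.  Both are far softer than any
engaged ligament and do not visibly alter engaged kinematics.

**Implant placement.** The 12 pose DOFs (6 femoral: M/L, A/P, P/D, F/E,
V/V, I/E; 6 tibial: M/L, A/P, P/D, slope, V/V, I/E) transform the articular
surfaces rigidly relative to their bones — intrinsic rotation order
F/E→V/V→I/E (femur) and slope→V/V→I/E (tibia) — with the zero vector the
mechanically aligned reference.  Ligament attachments stay with the bones.
A posterior-stabilized implant is assumed: the four cruciate bundles are
removed post-TKA, and no cam-post mechanism is modelled, so post-TKA A/P
stability arises from contact and the retained ligaments only (a documented
limitation).  The cruciates' property entries remain in the 50-vector
because family correlations involve them.

**Solver.** A damped (Levenberg) Gauss–Newton method minimizes the energy
with an analytic gradient and a PSD Hessian approximation (material term
f′/l0 · J Jᵀ plus the geometric string-swing term f/len; rotation-curvature
terms are dropped).  Convergence tolerance is 10⁻⁴ mm/deg on the step,
with backtracking and per-row adaptive damping; converged rows drop out of
the batch.  Squats are solved sequentially over the flexion schedule (seven
angles evenly spaced on [20°, 120°]) with warm starting; independent point
evaluations (surrogate labelling) start cold from the aligned pose.  The
solver never returns silent NaNs: non-converged rows are flagged and either
raised (squat simulation) or discarded with a count (labelling).

## The synthetic subject

MRI-segmented geometry is not available, so subjects are generated.
Attachment sites start from plausible anatomic coordinates with the femoral
sites deliberately close to the flexion axis (near-isometry, as in the
native knee), receive seeded jitter (±1.5 mm tangentially, smaller
off-axis), and condylar half-separation and radius are jittered ±1.5 mm.
Stiffnesses are drawn in the mid-range of the sampling table.  Reference
strains are then calibrated by a damped fixed-point iteration so each
bundle's peak strain over the nominal native squat hits a target drawn from
U(0.012, 0.025) (posterior capsule: U(0.052, 0.058), peaking at low flexion
where it is tightest).  The generator retries with fresh jitter until the
audit passes: all peak strains inside (−2%, 6%), and the medial, lateral
and central groups engaged at every flexion angle.  The resulting subjects
show physiological behaviour — near-isometric collaterals, ACL engaging in
early flexion, PCL in deep flexion, capsule slackening with flexion.

What this does not emulate: real attachment footprints (areas, not points),
mesh-based contact geometry, muscle loading, and inter-subject anatomical
covariance.  Tests passing on these subjects demonstrate the statistical
machinery under a mechanically plausible forward model, not clinical
validity.

## Native safe zones and set families

Three safe zones define physiological plausibility of a property vector for
the native knee, all evaluated on the simulated squat:

* **damage** (SZ_D): every bundle's *peak* strain within (−2%, 6%);
* **damage & stability** (SZ_D&S): additionally each of the medial
  ({deepMCL, supMCL}), lateral ({LCL, ALL, PFL}) and central ({ACL, PCL})
  groups has group-max strain > 0 at every scheduled angle (engagement is
  strict, damage non-strict, following the usual wording "greater than 0%"
  / "not exceed 6%");
* **damage & kinematics** (SZ_D&K): the damage indicator combined with an
  independent-Gaussian likelihood of measured secondary kinematics, with
  standard deviations 0.5 mm/° for M/L, A/P, I/E and 1.0 mm/° for P/D, V/V.

The central-group engagement requirement is implemented as the maximum over
both cruciates jointly (configurable via the group table).

Set families are sampled by transitional MCMC from the uniform prior on the
50-parameter sampling box.  Indicator zones cannot be tempered directly, so
stages use the soft log-target `loglik − λ·(squared violation)`; during
tempering the effective penalty is β·λ with λ = 10⁶ per unit strain², and
after β reaches 1 further stages temper λ itself upward (chosen by the same
weight-CoV criterion, so the ladder is geometric) with importance
resampling, until the chains satisfy the exact indicator.  Stage increments
target a weight coefficient of variation of 0.5; proposals are Gaussian
with covariance (0.2)² times the weighted sample covariance; five
Metropolis moves per chain per stage; a tempering-increment floor prevents
stalling on pure indicators.  These hyperparameters are the package's own
choices (the method's original hyperparameters are unreported) and are all
exposed in `TmcmcConfig`.  Every returned family is audited by re-running a
subsample (≥200 sets) through the knee model; membership below 95% rejects
the family with diagnostics.

On synthetic subjects the SZ_D&K posterior conditioned on the subject's own
squat kinematics brackets the true reference strains (90% interval covering
≥8/10 bundles at family size 500), and the reference-strain /
attachment-offset correlation of the collaterals is stronger under SZ_D&K
than under SZ_D — measuring kinematics ties the two together.

## Post-TKA surrogate

Planning needs millions of strain evaluations (4,096 Monte Carlo samples ×
7 angles × 64 offspring × ~400 generations ≈ 7.3·10⁸ per optimization), so
a neural surrogate replaces the equilibrium solve.  Training samples pair
property rows drawn from the set family with implant poses from an
unscrambled Sobol sequence over [−8, 8] mm/deg per DOF and flexion from
[20°, 120°] (the sequence is fast-forwarded past its origin point), each
labelled by the knee model; non-converged labels are discarded and counted.
Data are split 90/10 train/validation with the validation count rounded to
the nearest integer.

The network is fully connected with Softplus activations
(a(x) = log(eˣ + 1), evaluated overflow-safely), trained with Adam on the
mean-squared error of standardized outputs, with early stopping on the
validation loss.  Rather than regressing strains directly, the post-TKA
surrogate predicts the five secondary equilibrium DOFs and reconstructs the
six retained-bundle strains in closed form from the predicted
configuration, after a fixed four damped Gauss–Newton refinement iterations
of the true energy.  Predicting kinematics avoids the 1/l0 amplification
that makes short-bundle (deepMCL) strains hard to regress to 3% absolute
accuracy, and the refinement is roughly an order of magnitude cheaper than
a cold solve.  The native variant keeps the printed 51-input (50 parameters
+ flexion) plain regression form.  The post-TKA network input is 26
retained-ligament parameters + 12 pose DOFs + flexion = 39; the original
study's corresponding input count (45) has no obvious derivation from its
parameter table, so the package defines its own.

A surrogate is usable for planning only if the 90th percentile of the
held-out absolute strain error is below 3% strain for every strain output,
measured on the full prediction path.  At the default test scale (4,096
samples, two hidden layers of 96) the gate passes with maxima around 2%
strain; a failed gate is a soft error — the report flags the surrogate
unusable and planning falls back to the direct model.  Hidden widths
default to the large published-style stack (128‑256‑512‑256‑128‑64) for
full-scale runs and are configurable.

## Planning

Surgical imprecision presets carry per-DOF standard deviations for
conventional surgery, patient-specific guides, two robot-assisted systems,
and the 90%-success precision benchmark (`pr90`); entries the literature
does not report are NaN, and drawing from an incomplete preset is an error
directing the user to `ras` (the complete robot column) or `pr90`.

A fixed base sample set S_MCS(x=0) of n_MCS = 4,096 (256 at test scale)
per-DOF-normal pose perturbations is drawn once and paired, once, with
family rows drawn uniformly with replacement; the pairing stays fixed so
the objective is deterministic across optimizer iterations.  Candidate mean
poses shift the base set additively, S_MCS(x) = S_MCS(x=0) + x.  The
objective sums, over samples and angles, squared strain excess above 6%
(u1, over the six retained bundles) and squared negative lateral/medial
group-max strains (u2), scaled by 10/n_MCS, plus the regularization
0.005·Σxᵢ² that keeps the plan near mechanical alignment; strains enter as
fractions.  The GSP is the fraction of samples whose squat is balanced
(no strain above 6% anywhere and medial and lateral groups engaged at every
angle).

The optimizer is a real-coded genetic algorithm on [−8, 8]¹²: binary
tournament selection, simulated binary crossover (η = 15), polynomial
mutation (η = 20, rate 1/12), (μ+λ) survivor selection with population =
offspring = 64 (32 at test scale), 400 generations full scale, 30 at test
scale, fully seeded.  The first generation always contains the mechanical
alignment pose.  Evaluations are counted and audited against the closed
form n_MCS × angles × offspring × generations.

## Sensitivity analysis

For each of 750 property sets (full scale; 50 at test scale) from the
SZ_D&S family, the same optimization is repeated with properties held
fixed, propagating pose uncertainty only through 256 (test: 32) Sobol
points mapped through the per-DOF normal inverse CDF — the first point is
the all-zero median perturbation.  Per-set outputs are the optimized mean
pose DOFs and the GSP.

The delta moment-independent measure conditions each input on
max(8, ⌊√n⌋) equal-count quantile classes and accumulates
½·Σ w_m ∫|f_Y − f_{Y|m}| dy with Gaussian KDEs (Scott's rule) on a common
grid.  A permutation-based bias correction (the same estimator applied to a
seeded permutation of the input column, subtracted and clipped to [0, 1])
removes the finite-sample offset that otherwise makes independent inputs
score ≈0.1; without it the analytic null cases fail at these sample sizes.
Degenerate conditional slices fall back to a narrow-normal density; a
constant output yields all-zero deltas with a warning.  The top-10
criticality table splits into 3 most / 3 mid / 4 least critical.
Convergence of the ranking is scored by the rank penalty: each ground-truth
top-10 member of rank r missing from an evaluated top-10 adds 10/r, with
the ground truth defined on all collected samples, and subsampling curves
report mean ± spread over repeated draws (default 50).

## Problem sizes and determinism

Default test-scale sizes: family 300 (TMCMC chains = family size),
surrogate 4,096 labelled samples, n_MCS 256, GA 30×32, SA 50 sets × 32 QMC
points; these finish in a few minutes on one core while exercising every
stage at meaningful statistical resolution, and all full-scale values
(10,000-set families, 4,096×7 MCS, 64×400 GA, 750 SA sets, 256 QMC) remain
configurable.  Every stochastic stage derives a logged sub-seed from the
global seed; repeated runs are byte-identical in their artifacts.

## Known limitations

* The knee model is a stand-in: spherical contact, point attachments, no
  muscles, no cam-post, single-strand bundles (except the cruciates'
  two bundles).  Absolute GSP values are subject- and model-specific and
  not comparable to any published cohort.
* The 5-DOF equilibrium ignores patellofemoral mechanics entirely.
* Equilibrium under extreme joint-line distraction (condyle lift-off) can
  still switch modes discontinuously; such poses lie far outside the
  balanced region but inflate surrogate validation errors slightly.
* The delta estimator's class count and KDE rule are pinned for
  reproducibility, not optimality; rankings at n = 50 sets are coarse
  screening, not stable estimates (the convergence curve quantifies this).
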