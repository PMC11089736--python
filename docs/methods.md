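# Methods

`cardiotwin` personalizes a segmental left-ventricle (LV) model from LV
cavity volume and regional longitudinal strain, and asks which model
parameters such data can actually constrain.  This note documents the
models, the statistics, and the numerical and design choices behind the
package.

## The personalization problem

A digital twin (DT) is an instance of a mechanistic heart model whose
parameters are estimated from one patient's measurements.  Mechanistic
models of LV mechanical discoordination carry hundreds of parameters
(hemodynamics, vessels, valves, pericardium, activation timing, and 14
myocardial tissue properties per wall segment), while the data — one
end-diastolic volume, one ejection fraction, and 18 segmental strain
traces — constrain only a subset.  Estimating unidentifiable parameters
produces irreproducible twins: repeated optimizations land in different
places while fitting the data equally well.  The pipeline therefore
reduces the parameter subset until repeated estimations agree, and only
then interprets the twin.

## Parameter registry

The registry enumerates the model family's parameters with category,
wall, scope (global / regional / global-offset), reference value, a
screening range used by sensitivity analysis and quasi-Monte-Carlo
sampling, and extended swarm boundaries (screening range widened by 25%
per side, floored just above zero for positive quantities).  The
homogeneous-wall model has 100 parameters; subdividing the LV into
`n_seg` segments replicates the 14 LV tissue types per segment and adds
one mechanical activation delay per extra segment
(`100 + 14*n_seg - 28 + (n_seg - 2)`; 160 at 6 segments, 340 at 18).
Global-offset (GO) parameters add one LV-wide handle per regional
tissue type (174 at 6 segments).  Tissue GO parameters act as
multipliers on the segmental values (neutral at 1); the activation
delay GO is additive in milliseconds (neutral at 0), since a delay is
an offset, not a scale.

Reference values and ranges are versioned package defaults chosen to
span a wide spectrum of cardiovascular abnormality (e.g. active stress
20–160 kPa, passive stiffness exponent 5–40, activation delay 0–150
ms); each entry carries a provenance flag distinguishing parameter
names established in the lumped-parameter modeling literature from
package placeholders.  The counting arithmetic and all pipeline
behavior are independent of the specific numbers.

The 6-to-18 segment expansion triplicates each of the six LV walls in
the apex-to-base dimension, following the 18-segment longitudinal
strain convention.  The reduced subset used for 18-segment estimation
(cardiac output, atrioventricular delay, global activation duration,
plus regional delay, wall area, zero-passive-stress length and
stiffness coefficient) expands to 75 parameters.

## Bundled forward model

The package ships a deliberately lightweight phenomenological LV model
behind a narrow contract (parameters in, strain/stress/volume traces
out) so a full closed-loop cardiovascular model can be substituted.  It
is not a reduced-order approximation of any particular published
model; it is designed to reproduce the *structure* of the
personalization problem — shared-tension segmental coupling, activation
timing, exponential passive and gated active stress — at ~1–2 ms per
cycle evaluation.

* **Volume template.**  One cycle on a fixed 2 ms grid: isovolumic
  contraction, raised-cosine ejection of stroke volume
  `SV = q0 * tCycle`, isovolumic relaxation, raised-cosine filling.
  Aortic valve opening sits at `0.05 * tCycle + dTauAv`; ejection lasts
  `0.30 * tCycle`.  End-diastolic volume is the cavity volume of the
  midwall sphere spanned by the summed reference wall area
  (≈ 132 mL at the 140 cm² reference).
* **Common-tension equilibrium.**  At every instant a single wall
  tension `T(t)` satisfies the patch constraint
  `sum_i AmRef_i * L_i / 2.0 = sum_i AmRef_i * a(t)`, where `a(t)` is
  the relative area template derived from the volume waveform
  (end-diastolic sarcomere stretch 1.10) and each segment's sarcomere
  length `L_i` inverts its tension–length law
  `T = SfPas*(exp(k1*(L/Ls0Pas - 1)) - 1) + act_i(t)*SfAct*(L - 1)`.
  Only relative `AmRef` weights enter the equilibrium.
* **Activation.**  A raised-cosine pulse per segment starting at its
  mechanical activation delay `dT`; rise time `2800*TR/vMax` ms,
  plateau to `0.6*ADO_LV + 30*LDAD` ms after onset, decay time
  `480*TD/LDCI` ms, wrapped periodically across cycle boundaries.  The
  parameter-to-waveform couplings are monotone so that each parameter
  keeps its physiological role (faster `vMax` → faster force
  development; larger `LDAD` → later relaxation; larger `LDCI` → faster
  relaxation), but the specific constants are package choices.
* **Outputs.**  Fiber strain is referenced to mitral valve closure
  (`t = 0`), in percent, shortening negative.  Per-segment wall stress
  equals the common tension, so stress–strain loop areas differ between
  segments only through their strain trajectories — exactly the
  mechanism that makes early-activated septal segments perform less
  work under late-activated lateral loading.

**Numerics.**  The scalar tension equation is solved per time point by
a safeguarded Newton iteration in `u = log(T + C)` (the passive branch
is nearly linear in `u`), falling back to bisection on a guaranteed
bracket whenever a Newton step fails to keep halving the constraint
gap; the segmental law inverts by globally convergent Newton on the
exponent `m = k1*(L/Ls0Pas - 1)`, where the residual
`P*e^m + B*m - R` is convex and strictly increasing.  A compiled
(numba) per-column kernel with warm starts across time is the default;
a vectorized NumPy implementation of the same algorithm serves as
reference, and the two are cross-checked in the test suite to ~1e-11.
The relative patch residual is below 1e-12 at every accepted time step.
Parameter sets for which the template is infeasible (stroke volume
exceeding the cavity, negative valve times) or the solver fails its
1e-8 residual bound return `success=False` rather than raising; failed
evaluations are excluded from screening and sampling statistics, which
mirrors how wide screening ranges behave in mechanistic cardiac models
generally (only a fraction of the hypercube is physiological).

## Outputs of interest

Per segment, 12 strain indices (peak and peak systolic strain,
post-systolic shortening, pre-ejection and ejection stretch, mean
systolic/ejection strain, times to 10/50/90% shortening and 10/50%
re-lengthening) and 4 strain-rate indices (peak and mean over the
systolic and ejection windows), plus EDV and SV globally.  Systole is
[mitral closure, aortic closure]; ejection is [aortic opening,
closure].  Timing indices of traces that never shorten (or never
re-lengthen) are NaN sentinels, and a NaN output voids the containing
Morris trajectory — silent zeros would bias `mu*` low.  Ejection
stretch accumulates only positive strain increments; pre-ejection
stretch is the maximum positive excursion before ejection.  These
window and sentinel conventions are package definitions, documented
rather than asserted as anyone else's.

## Goodness of fit

`chi2 = (chi2_VED + chi2_EF + chi2_eps + chi2_epsdot) / (2 + 2*n_seg)`
with measurement uncertainties `0.13*V_ED,mea`, `0.14*EF_mea`, 2%
strain and 20%/s strain rate.  Only strain from mitral valve closure
until 10% global re-lengthening + 50 ms enters, excluding late
diastole.  Simulated fiber strain is scaled by the ratio of measured to
simulated global strain peak (the global signal is the segment
average), then linearly interpolated onto the measurement grid; strain
rate is a central difference on that grid, computed after resampling.
`n_dp` counts window samples only.  Whether EF enters in percent or as
a fraction is immaterial (the term is ratio-normalized); the package
uses percent.  The identifiability variant adds a cycle-time deviation
(`sigma = 50 ms`) with doubled weight over `4 + 2*n_seg`.

## Sensitivity screening

Morris elementary effects on the normalized screening hypercube,
8-level grid, step `Delta = z/(2(z-1))`; steps that would exit [0,1]
are taken in the feasible direction (standard Morris practice), which
with `Delta > 1/2` means each level has exactly one feasible direction
and all grid points remain equally likely.  A failed evaluation voids
its whole trajectory.  `mu*` is normalized per output by the
across-parameter mean; a parameter is kept iff its normalized `mu*` is
at least 1 for some output.  Convergence is leave-one-out stability of
that classification, checked from 1000 successful trajectories onward
in batches of 100; at the 3000-trajectory budget the decision falls to
a bootstrap percentile CI (1000 resamples; a parameter is non-important
for an output only when the entire 95% CI lies below the mean).
Desk-scale demonstrations use 50–200 trajectories on low-dimensional
subsets; the defaults encode the full-scale settings.

## Identifiability (diaphony) and reproducibility (ICC)

A scrambled Sobol sample of the subset's screening ranges (cycle time
added as an extra dimension so one simulation set serves all patients)
is scored per patient on sixteen components: the identifiability cost,
its volume, EF and cycle-time terms, and the per-segment strain and
strain-rate terms.  For each component the best `N_best = 2*n_par`
samples are kept (ties broken by sample index; failures excluded), and
the diaphony `d = |mean exp(i*2*pi*x_p)|` of each parameter's
normalized values over the selection measures how strongly that
component pins the parameter.  Groups are ranked by their maximum
diaphony over patients, components and (for regional groups) segments.
The desk-scale default is 2^12–2^16 samples with a recorded scramble
seed; the full-scale analyses this emulates used millions.

Reproducibility uses the one-way random-effects ICC of the n x m matrix
of estimates (subjects x repeats); regional groups pool (patient,
segment) pairs as subjects, global parameters use patients.  Parameters
whose all-positive range spans more than a decade are log-transformed
first (the mean squares are scale-sensitive); the transform is recorded
per group.  The subset is accepted when `ICC_min > 0.75`, strictly.

## Estimation and the reduction loop

Each estimation run seeds 60 particles (20 swarms of 3) from the best
of 1000 constrained uniform Monte-Carlo draws — the default
restrictions bound the activation-delay spread (≤ 130 ms), mean
contractility (40–150 kPa) and mean stiffness (k1 ≤ 32), preventing
unphysiological starts; the thresholds are package defaults exposed in
configuration.  Constriction-type updates (inertia 0.729, cognitive =
social = 1.49445), velocities clamped to 25% of the extended range,
infinite cost outside the extended boundaries, random swarm regrouping
every 20 iterations.  Termination combines two readings of "normalized
particle energy below 1e-4": no parameter of any particle may move more
than 1% of its Monte-Carlo range width in one iteration *and* the
mean-square normalized displacement must be below 1e-4; enforcing both
is conservative.  Five independent repeats (fresh Monte-Carlo pools,
seeds spawned from one sequence so serial and parallel execution agree)
supply the ICC observations.

The reduction loop alternates: repeated estimation → ICC gate →
diaphony ranking → removal.  Removal counts are 10/5/3 per iteration
while more than 30 / 16–30 / 11–15 groups remain; at 10 or fewer
groups one group is removed per iteration, choosing between the
lowest-diaphony and lowest-ICC candidates by whichever causes the
smallest maximal chi-square increase over the cohort (candidates are
evaluated with single-repeat estimations at desk scale).  The
dual-candidate comparison is active only in the ≤ 10-group regime.  A
removed regional group returns as one global-offset parameter; removed
globals are fixed at reference — no parameter silently disappears, and
the spec floor of one group guarantees termination.  Diaphony is
recomputed each iteration on the current subset's space.

## Virtual cohort

Virtual patients define the study conditions: cardiac output 55–95
mL/s and cycle time 750–950 ms per patient; the LBBB archetype imposes
a graded activation delay from the anterior septum to the posterolateral
wall (total septal-to-lateral delay 90–130 ms, intermediate walls at
fractions 0.15/0.35/0.60/0.80 of the path); the MI archetype depresses
contractility (x0.25–0.45) and shortening velocity (x0.5–0.8) and
raises stiffness (k1 x1.6–2.4, SfPas x1.5–2.5) in a contiguous
three-wall lesion (anteroseptal, anterior, inferolateral), with narrow-QRS
activation scatter ≤ 15 ms; LBBB-MI combines both.  Measurements are
exported at 60 Hz with additive Gaussian noise per strain sample
(sigma 2%) and one volume perturbation per patient (relative sigmas
0.13/0.14) — the cost function's uncertainty scales reinterpreted as
noise scales.  A noise level of 0 gives the noise-free twins used for
recovery experiments.

What the generator does *not* emulate: speckle-tracking drift and
segment dropout, inter-vendor strain differences, beat-to-beat
variability, atrial and right-ventricular mechanics, pericardial
constraint, and real measurement-model mismatch (virtual measurements
come from the same model family that is being fitted).  Passing
recovery and reduction tests on this cohort therefore demonstrates the
statistical machinery — not clinical validity on real echocardiograms.

## Myocardial work

Segmental work is the signed shoelace area of the closed (strain
fraction, stress) loop times segmental wall volume (kPa·mL = mJ);
shortening at high tension with re-lengthening at low tension is
counterclockwise, hence positive.  Wall volumes come from the
registry's per-segment `VWall`.  Normalized work divides by the summed
work of all segments; the septal-to-lateral imbalance subtracts the six
septal (anteroseptal + inferoseptal) from the six posterolateral
(inferolateral + anterolateral) normalized-work sums; the anterior and
inferior walls are the excluded "other" six.  Homogeneous twins give an
imbalance of exactly zero by symmetry; LBBB-archetype twins give
positive values (lateral overload), and lesions confined to the lateral
wall flip the sign.  Group-comparison statistics across cohorts are out
of scope; the tooling emits per-twin tables for external analysis.

## Problem sizes and determinism

Desk-scale runs used throughout the tests and the acceptance script:
6-segment schemes for screening/identifiability, 24 particles (8
swarms), Monte-Carlo pools of 150, 300–600 swarm iterations, 2^12 Sobol
samples, 3–5 repeats, 3-patient cohorts.  These sizes were chosen so a
full pipeline pass completes on a single core in minutes while leaving
every algorithmic path (convergence checks, bootstrap CI, dual-candidate
removal, GO demotion) exercised; the configuration objects default to
the full-scale settings.  All randomness flows through explicit
`numpy.random.Generator` seeds; simulations are bitwise deterministic
for fixed parameters on one platform.

## Known limitations

* The forward model's valve timing is template-driven, so
  atrioventricular delay shifts valves rather than emerging from
  pressure crossings; global activation duration is weakly identifiable
  once strain amplitude is rescaled to measurements, and the reduction
  loop routinely (and correctly) removes it on synthetic cohorts.
* How the global activation-duration parameter enters activation
  kinetics is a package choice; detailed constitutive behavior
  (force–velocity, length-dependent activation dynamics) is collapsed
  into monotone pulse-shape couplings.
* The ICC uses the one-way form only; two-way and consistency forms are
  out of scope.
* With very small cohorts and few repeats (3 x 3 at desk scale) the ICC
  is a noisy statistic: on some seeds the gate accepts while a
  non-identifiable parameter's small-sample ICC happens to exceed 0.75.
  Larger cohorts and the default five repeats stabilize the gate.
* Diaphony detects marginal clustering of best samples; jointly
  identifiable but marginally flat combinations (ridges) can evade it,
  which is why the reproducibility gate, not diaphony, is the
  acceptance criterion.
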