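# Methods

This note records the models, conventions and numerical choices behind
`crtpredict`, and what the synthetic data do and do not establish.

## Anatomy

The ventricles are a truncated two-ellipsoid pair: the LV a thick shell
between concentric ellipsoids centred at the origin (endocardial radii
30 × 30 × 55 mm, wall 9 mm), the RV a thinner shell (wall 5 mm) around an
ellipsoid shifted toward +x and clipped against the LV epicardium, so the
shared septal wall belongs to the LV.  Truncation is at the base plane
z = 0; the long axis points down (−z); +x is the patient's right, +y
anterior.  These dimensions describe a dilated cardiomyopathy heart at
desk scale; real CT/MRI segmentation is out of scope and the idealization
preserves exactly the structure the downstream mathematics consumes: wall
identity (LV free wall / septum / RV free wall), transmural layer
(endo/mid/epi by thirds of the normalized depth), and the AHA 17-segment
map (basal/mid rings in 60° sectors, apical ring in 90° sectors, apex cap
below the cavity; the two septal sectors face the RV).  Septal wall
identity follows the AHA convention (segments 2, 3, 8, 9, 14).

Meshing: interior nodes on a regular lattice at the requested edge length
(default 4 mm, the heart-mesh resolution of the study this emulates) plus
Fibonacci-sampled boundary points on each surface at matching density,
Delaunay-tetrahedralized and filtered to elements whose centroid lies in
the myocardium; the largest connected component is kept.  The meshed
volume matches a Monte-Carlo evaluation of the analytic shell volume to
≪1%.  Construction is fully deterministic.

Fibers follow the rule-based linear-helix family: the helix angle
interpolates from +60° (endo) to −60° (epi) across the transmural depth,
vectors lie in the local wall tangent plane of the interpolated ellipsoid
(tangency is exact by construction); apex-cap elements with an undefined
longitudinal direction are flagged and given circumferential fibers.  The
full Laplace–Dirichlet construction is a possible extension; for an
ellipsoidal wall the analytic normals make it unnecessary.

Lesions are assigned at (segment, layer) granularity — the resolution of
an expert's imaging report, not voxels.  Scar is inexcitable and excluded
from the propagation domain and from MTV; fibrosis conducts at 1% of
normal conductivity (10% speed).

Torso electrodes are fixed synthetic landmarks placed at plausible
positions well outside the ventricular bounding box (the source study does
not state how its electrode positions were defined); limb electrodes far
away, V1–V6 on an anterior arc.

## Activation model

First-arrival (Eikonal) activation with the speed tensor
`D = v_f² f fᵀ + v_t² (I − f fᵀ)`; the homogeneous point-source solution
is the elliptical norm `T(x) = sqrt(xᵀ D⁻¹ x)`.  Speeds derive from a
global dimensionless conductivity scale g through `v = v0 √(g·s)` with
local scale s (1 normal, 0.01 fibrosis), so the 4:1 conductivity
anisotropy yields the 2:1 velocity ratio.  `v0 = 0.6 mm/ms` anchors the
physiologic range; personalization rescales it per patient.

The solver is two-stage:

1. **Graph stage.** Dijkstra on the tetrahedral edge graph, each edge
   costed at the Riemannian travel time `sqrt(eᵀ D⁻¹ e)` of its *slowest*
   incident element.  The slowest-element rule makes the graph time a true
   upper bound on the continuum time (an edge skirting a thin fibrotic
   layer cannot tunnel through it) — necessary both for physical fidelity
   of slow lesion tails and because stage 2 only ever lowers times.
   Multi-source onset conditions (e.g. Purkinje junction times) enter
   through per-source virtual nodes, so any number of sources costs one
   shortest-path sweep.  An optional order-2 graph adds second-ring edges
   in tissue-homogeneous scar-free neighbourhoods.
2. **Factored local refinement.** Plain linear local solvers suffer both
   angular metrication error and wavefront-curvature error near point
   sources; measurements on a 2 mm slab showed no practical edge-graph
   neighbourhood reaches 3% accuracy under 2:1 anisotropy.  Instead, each
   node's time is re-expressed against a local reference solution
   `T0(x) = min_k [onset_k + sqrt((x−s_k)ᵀ D⁻¹ (x−s_k))]` over the
   dominant sources of the four local nodes, and the *ratio* τ = T/T0 is
   interpolated linearly over the upwind face of each tetrahedron; the
   entry point minimizing `τ·T0 + travel` is located by sampled search
   with local grid refinement.  Active-set Jacobi sweeps run to a
   convergence tolerance expressed as an equivalent path length
   (6·10⁻³ mm), which keeps the exact 1/c time-scaling of the solution
   under a c² conductivity rescale bit-true.  On the homogeneous 2 mm
   slab the refined solution matches the closed form to <0.04% and planar
   fronts along/across fibers to <1%.

Degenerate inputs: sources on scar are discarded (an error if none
survive); scar-isolated nodes keep +∞ with a warning; times are floored at
the earliest onset.

Geodesic distances (`DLvRv`, `DLvInfarct`, `DLvLATZ`) use the isotropic
unit-speed graph metric with scar *included* — they mimic ruler
measurements on images, not conduction — and deliberately skip the
refinement stage so they coincide exactly with a shortest-path oracle; an
exclude-scar flag exists but is off by default.  The late-activation zone
is the last 10% of the activation span (fraction 0.9, an exposed
parameter; the source study names no cutoff), restricted to the LV.

## Purkinje surrogate and pacing

Only the right bundle conducts in LBBB: a trunk of ~40 mm grows from a
basal septal origin along the RV endocardial surface graph toward the RV
apex, then branches as a deterministic seeded fractal (defaults: 6
generations, 8 mm branches, ±20°) constrained to the surface.  Terminal
tips project to mesh nodes as Purkinje–myocardial junctions; onset = tree
path length / 3 mm/ms.  Coupling is one-way (tree → myocardium); tips on
scar are discarded.  Only the trunk length and conduction velocity are
anchored by the literature; the arborization parameters are declared
defaults.  BiV pacing stimulates the RV endocardial apex node and an LV
posterolateral epicardial node directly, with zero inter-lead delay; if
the requested LV position falls on scar the nearest non-scar candidate
substitutes.

## Forward ECG and QRS duration

Each non-scar element contributes an equivalent dipole
`p(t) = −A′(t − T_e) ∇T_e · vol_e`, with `∇T_e` from linear shape
functions and `A` a logistic upstroke (rest −85 mV, plateau +25 mV,
τ = 0.4 ms; depolarization only — no repolarization is simulated because
only the QRS is analysed).  Electrode potentials sum the
infinite-homogeneous-medium kernel `p·r/(4π|r|³)`; torso and lung
conductivity inhomogeneities are out of scope, which preserves QRS timing
and normalized morphology (all the pipeline consumes) at a fraction of
the cost.  Standard Wilson/Goldberger lead algebra guarantees
I + III = II and aVR + aVL + aVF = 0 to rounding.  Sampling step 0.5 ms;
window [AT_min − 5, AT_max + 10] ms.

QRS boundaries per lead are the first/last crossings of 5% of that lead's
peak absolute amplitude, located with sub-sample linear interpolation
(the interpolation makes the personalization objective continuous in g).
`QRSd` is the maximum per-lead duration; the mean over leads is also
returned and is the personalization target.  The 5% threshold rule is this
package's operational convention; a "Q-peak to S-peak" reading would end
earlier on slow low-amplitude tails (see Limitations).

## Personalization

Mean simulated QRSd is monotone decreasing in g, so the fit is bracketed
root finding (Brent on log g, bounds g ∈ [0.1, 10]) rather than
minimization of the equivalent flat quadratic — any bounded scalar scheme
with the same recovery behaviour would do.  A global g multiplies every
edge time by 1/√g, so the propagation graph is built once and rescaled
per evaluation (Purkinje onsets held fixed; they are not fitted); only
the ECG projection is recomputed, via a cached forward operator.
Accepted discrepancy 0.5 ms (= the sampling step; threshold-crossing
discontinuities can leave a residual of that order).  Out-of-range targets
return the nearer boundary with a non-convergence flag.  LBBB and BiV are
fitted independently.  Self-consistency recovery over 20 synthetic
patients with g* log-uniform in [0.25, 4]: median error ~10⁻⁵, maximum
<1%.

## Biomarkers

As defined in the README; conventions worth recording:

* `AT_RVLV` counts the septum with the LV (the septum activates with the
  left chamber in LBBB physiology); sign positive = LV later.
* `mAT_STLV` node means are volume-weighted (lumped nodal volumes); an
  unweighted mode exists for sensitivity checks.  Undefined at TAT = 0
  (NaN, not 0).
* Activated-volume curves count an element once its mean nodal time has
  passed; scar is excluded from numerators and totals; the integral uses
  the trapezoid rule on a 1 ms grid (halving the step changes smooth maps
  by <1%).
* Missing values are NaN markers (no lesion → `DLvInfarct` = NaN), so the
  downstream missing-feature exclusion rule is genuinely exercised.

## Synthetic cohorts

*Statistical mode* draws a latent responder label at 40% prevalence and
every feature from group-conditional distributions whose defaults are the
published responder/nonresponder summary statistics (EF 23±5 vs 29±6%,
BMI 27±5 vs 30±5, QRSd 192±20 vs 190±26 ms, DLvInfarct 45±28 vs
28±27 mm, simulated TAT 269±109 vs 246±130 ms, …), truncated at
physiologic bounds (e.g. EF at the ≤35% inclusion limit).  Outcomes come
from group-conditional truncated normals arranged so EF10 labels equal the
latent group.  Features are independent within group — the real cohort's
covariance is unpublished — except derived columns (InfarctV/MTV, TAT/MTV,
the Δ block), which are computed from the drawn values.  The
echo-dyssynchrony block (IVD, ΔTs, SD12) shares a 40% missingness mask,
matching its 34-of-57 availability.  A `planted` list restricts
group-conditional effects to a subset, with everything else drawn from
the pooled mixture; `model_effect_spec` plants effects only on
model-derived features, isolating their contribution for the
hybrid-versus-clinical comparison.

*In-silico mode* runs the full pipeline per patient: anatomy scaled ±8%,
random lesion maps (prevalence 0.6; 2–5 contiguous segments × 1–3 layers;
scar or fibrosis), apex/posterolateral leads, seeded Purkinje tree, and
conductivity personalized per mode to paired QRSd targets — LBBB
~N(190, 23) ms and BiV = LBBB × (1 + δ) with δ ~ N(−0.25, 0.17) truncated
to [−0.60, −0.05], from the published simulated pacing effect (pacing
always narrows).  Simulated feature columns come from the actual physics;
clinical columns are sampled; consequently the simulated block is *not*
statistically linked to the latent response label in this mode (no
mechanism exists to plant causality through the physics).

What passing tests on these cohorts show: that the pipeline's statistics,
selection, cross-validation and leakage behaviour are correct, and that
model-derived features lift classification when they truly carry signal.
What they cannot show: real-world predictive performance — the published
patient-level headline numbers (AUC 0.82 etc.) are not reproducible
without the undeposited cohort, and no attempt is made to match them.

## Machine-learning pipeline

Preprocessing drops feature columns with any missing value (no
imputation), zero-variance columns, and one member of every pair with
|Pearson r| > 0.85 — the kept member decided by a declared priority
(clinical before model-derived provenances, alphabetical within); the
study this follows does not state its drop order.  Z-scoring happens
inside the cross-validation loop (per-fold scaler), never globally.
Selectors rank on training folds only: RF permutation importance (200
trees, 5 repeats), univariate tests (Welch t for continuous, uncorrected
χ² for categorical — p-values are used as ranks, not inferences), or
|weights| of an L1 logistic fit (C = 1, escalated ×10 only if all weights
vanish; not a hyperparameter search).  Classifiers: logistic regression,
LDA, linear SVM (decision-function scores), random forest.  No
hyperparameter search anywhere.  LOO pools the n held-out scores into one
ROC; 5-fold × R repeats reports AUC mean ± SD over folds × repeats (the
published SD's exact denominator is ambiguous; folds × repeats is this
package's convention).  Binary metrics are reported at the Youden-J cutoff
of pooled out-of-fold scores (the published cutoff rule is unstated).
PCA-logistic refits PCA inside the loop; with full rank it reproduces the
plain L2-logistic AUC (orthogonal invariance of the L2 penalty).  2-means
runs on the first two PCs, best of 10 restarts.

## Problem sizes and determinism

Default meshes (4 mm) have ~4.7 k nodes / 22 k tetrahedra; a full
activation solve takes seconds and an in-silico patient (two
personalized modes) tens of seconds, so the deep integration test uses 10
patients and the personalization-recovery check 5 anatomies × 4
conductivities at 5 mm.  Every stochastic path takes an explicit seed and
is bit-reproducible; anatomy construction is deterministic outright.

## Known limitations

* The idealized anatomy has no valves, atria, outflow tracts or
  patient-specific wall-thickness variation; torso/lung heterogeneity is
  absent from the ECG, so absolute lead amplitudes are not meaningful
  (normalized morphology and timing are).
* The QRS threshold convention keeps QRSd close to TAT in both pacing
  modes (TAT/QRSd ≈ 1.1).  The emulated study reads QRSd peak-to-peak and
  its LBBB maps carry long low-amplitude tails (TAT/QRSd ≈ 1.4 in LBBB
  vs ≈ 1.0 under BiV); consequently the mean relative TAT reduction under
  BiV here is about −26% at default conditions versus the published
  −45 ± 18%.  The direction and per-patient consistency hold.
* Eikonal activation ignores wavefront curvature effects, source-sink
  mismatch and repolarization; fibrosis is a homogeneous slow continuum,
  not micro-structural.
* In-silico cohorts cannot encode a causal link between simulated
  features and outcome; only the statistical mode can plant effects.
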