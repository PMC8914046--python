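# Methods

This note records the models, numerical choices and known limitations of
rvstrain, in the spirit of a software methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Mesh model and geometric primitives

A frame is a closed, consistently oriented triangular mesh of the RV
endocardium with vertices in millimetres. A cardiac cycle is a
*topology-constant* series: every frame shares the vertex count and the
exact face list, so a surface point expressed in barycentric coordinates on
a face is a material point trackable through the cycle. Surface area is the
triangle-area sum (mm²); cavity volume is the absolute signed-tetrahedron
sum about the origin (divergence theorem), reported in mL. End-diastole and
end-systole are the global maximum and minimum of the volume curve; ties are
broken to the earliest frame. Inconsistent winding is repaired by trimesh's
flood-fill normal fix when possible; open surfaces are rejected with the
boundary edges listed. The OBJ reader accepts `v`/`vn`/`vt`/`f` records
(only `v`/`f` used), fan-triangulates polygonal faces from their first
vertex, preserves vertex order exactly, and reports parse errors with file
and 1-based line number. Real speckle-tracking exports may leave the
tricuspid/pulmonary orifices open; such surfaces must be capped upstream,
since volumes and area strain are defined here only for closed meshes.

## Long axis

With a base-ring hint (annulus points), the base centre is their centroid
and the apex is the vertex farthest from it. Without a hint, the long axis
is the first principal axis of the vertex cloud; of the two axial end caps,
the one whose extreme-vertex slab has the smaller axial-spread-to-radial-
extent ratio is taken as the base (exported RV surfaces are capped by the
near-planar annulus, while the apex is pointed). Nearly isotropic vertex
clouds (principal-value gap < 5%) are rejected with a request for a hint.

## Contours and strains

*Latitudes.* 15 planes orthogonal to the axis at fractions k/16 of the
apex→base-centre distance (endpoints excluded) cut the ED mesh; each
crossing is walked face-to-face into closed loops, and each loop point is
stored as (face, barycentric) on a crossed edge. If a plane yields several
loops, the longest is kept.

*Longitudes.* 45 base seeds are placed on the basal rim — vertices within
the top 2% of the axial extent (widened adaptively up to 25% when the rim
is sparse or the axis is tilted), with cap-interior vertices removed by a
radial cut at 80% of the slab's maximal in-plane radius — at equal 8°
azimuthal increments. The azimuth origin is anchored at the lowest-index rim
vertex: an arbitrary but deterministic choice that is intrinsic to the mesh,
which makes the whole construction (and therefore GLS) rigid-motion
invariant; anchoring on a world axis would not be. Each longitude is the
edge-graph shortest path apex → nearest mid-level-latitude vertex in the
seed's angular sector → seed, an approximation of an apex-to-base geodesic
through mid-cavity. Graph paths rather than exact polyhedral geodesics are
deliberate: strains are length *ratios* between frames of one material
polyline, so the discretisation largely cancels.

*Material tracking.* Contours are constructed once, on the ED frame, and
re-evaluated on every other frame through their fixed barycentric
coordinates. Re-slicing each frame is explicitly rejected: it would measure
surface motion relative to a moving coordinate system rather than material
shortening.

*Strains.* GCS and GLS are means of per-contour fractional shortenings
(ED→ES) times 100; GAS is the fractional total-surface-area reduction; all
reported positive for shortening, matching clinical reporting conventions
(a raw sum over contours would scale with contour count and is not used).
If ES coincides with ED (flat volume curve) all strains are zero and a
warning is issued.

Verified invariants (see the test suite): similarity identities under
uniform scaling, including (1−GAS/100) = (1−GCS/100)(1−GLS/100); rigid-
motion invariance; sub-1-point changes under mesh-resolution doubling;
agreement with an independent shortest-path oracle and with a ray-casting
volume oracle.

## Synthetic mesh cycles

The base shape is a half-ellipsoid (default semi-axes 30 × 25 × 70 mm,
ED volume ≈ 110 mL, a typical RV cavity size) closed by a flat basal disk,
with an optional inward crescent term emulating the concave septal wall
(default 0 — realism is secondary to having analytic ground truth). The
cycle scales the in-plane axes by s_c(t) and the long axis by s_l(t) with a
cosine profile whose trough is at mid-cycle; with an even frame count
(default 20) the mid-cycle frame carries exactly the end-systolic scales
(defaults s_c = 0.90, s_l = 0.85, in the range of normal RV deformation).
Ground truth on the continuous surface: GCS = (1−s_c)·100 exactly
(horizontal planar curves scale uniformly in-plane), EF = (1−s_c²s_l)·100
exactly (affine determinant), GLS and GAS by quadrature of meridian lengths
and the first fundamental form at 10× mesh resolution. Per-vertex Gaussian
jitter (default 0 mm, so truth stays exact; set a few tenths of a mm to
emulate tracking noise) is applied per frame from a seeded generator.

What the generator does *not* emulate: speckle noise and dropout, valve
orifices, trabeculation, frame-rate-dependent temporal blur, and the
irregular RV crescent geometry beyond the single bulge term. Passing tests
therefore validate the geometry engine's correctness, not its robustness to
poor image quality.

## Synthetic cohorts

Covariates are drawn from a Gaussian copula. Continuous marginals are
skew-normal, fitted so the quartiles match published median/IQR summaries of
a mixed cardiac-disease cohort (n = 341); when a variable's quartile
asymmetry exceeds what the skew-normal family can express (ratio ≈ 1.34,
e.g. strongly right-skewed ventricular volume indices), the shape parameter
saturates and the fit preserves the median and IQR width exactly, which are
the quantities the calibration checks measure. Binary covariates are
Bernoulli at the published prevalences. Values are clipped to loose
physiologic bounds.

Only five pairwise rank correlations are published (RVEF–GCS 0.90, RVEF–GLS
0.87, RVEF–GAS 0.93, LVEF–LVGLS 0.92, LVEF–RVEF 0.64). A matrix with those
entries and zeros elsewhere is not positive semidefinite, so the default
correlation structure is a two-factor loading model — an RV-function factor
and an LV-function factor with inter-factor correlation chosen to hit
LVEF–RVEF — which reproduces every published pair exactly and is PSD by
construction; all remaining pairs are left at the implied (mostly zero)
values, since the true joint distribution is unknowable from marginal
summaries. Spearman targets are converted to copula (Pearson) correlations
via 2·sin(πρ/6). User-supplied non-PSD matrices are rejected with a
nearest-PSD suggestion.

Event times are exponential with hazard log-linear in configured covariates
centred at their medians, plus optional step terms (a multiplicative hazard
below a cutoff), administratively censored at a horizon (default 40 months).
The default plants only the published per-unit RVEF effect (HR 0.93): the
published univariate hazard ratios of RVEF/GCS/GLS/GAS are *marginal* fits
of strongly collinear predictors and cannot all hold jointly as conditional
coefficients, so recovery experiments plant them one at a time. The default
baseline hazard (0.030/month, ≈30% censoring at the horizon) gives
parameter-recovery experiments good power; it is intentionally more
event-rich than the source cohort's 14% event fraction. Event types are
drawn from the published split among events (HF hospitalization 30/49,
ventricular tachyarrhythmia 5/49, cardiac death 14/49). An exponential
baseline suffices because the Cox partial likelihood is invariant to the
baseline's shape.

## Outcome statistics

The composite endpoint takes the *severity-maximal* label (HF
hospitalization < sustained ventricular tachyarrhythmia < cardiac death)
and the *first* qualifying event time — the standard time-to-first-event
convention; subjects without events are censored at last follow-up. The
secondary endpoint counts HF hospitalization only. Kaplan–Meier and the
two-group log-rank test are delegated to lifelines; median follow-up uses
the reverse Kaplan–Meier method. Cox models use Efron tie handling, Wald
CIs on the log hazard ratio, and Harrell's C over comparable pairs; no
multiple-testing correction is applied (nominal p-values). Nested models on
identical records are compared by 2·Δlog-likelihood against χ² with the
parameter-count difference. NNT is 1/|risk difference| for binary contrasts
and 1/(2·AUC−1) for continuous markers (the AUC-based effect-size
formulation; published NNT values computed with unreported variants are not
treated as exact reproduction targets). The 18-segment image-quality score
sums 0/0.5/1 per segment and categorizes: good ≥ 16, fair [13, 16),
poor [10, 13), extremely poor < 10 (exclusion).

## Survival tree

Splits are found by exhaustive search: every candidate variable, every
midpoint between consecutive sorted unique values (or a user grid), scored
by the two-sample log-rank χ² between `x < c` and `x ≥ c`; ties prefer the
smaller cutoff, then earlier variable order. Stopping: max depth 3, minimum
leaf 30, minimum χ² 3.84 (the 0.05 critical value at 1 df) — chosen to
yield compact 4-leaf trees from cohorts of a few hundred subjects; no
pruning or cross-validation, and no surrogate splits (complete-case data
assumed). Leaves are labelled by event rate normalized between the extreme
leaves (lowest third low, highest third high, otherwise intermediate), so a
four-leaf tree can carry two high-risk leaves, one intermediate and one low.
Subjects at a cutoff route to the `≥` child. The estimator
`LogRankSurvivalTree` follows scikit-learn conventions (get_params/
set_params/clone; `tree_`, `predict`, `apply`).

## Problem sizes and determinism

Simulation-based checks use: coefficient recovery at n = 2000 over 100
replicates per marker; tree-cutoff recovery at n = 1000 over 50 replicates
on a 0.5-unit cutoff grid; null-calibration of log-rank (n = 200) and
nested-LRT (n = 150) at 1000 replicates; generator calibration at n = 10⁵.
These sizes give Monte Carlo error comfortably below the tolerances being
checked. All replicate streams derive from single master seeds via numpy
`SeedSequence` hashing; reruns with the same seed are bit-reproducible. A
95%-CI coverage check over 100 replicates has a binomial standard error of
≈2 percentage points; the acceptance threshold (≥93%) leaves about one such
standard error of slack, so occasional failures of any fixed 100-seed block
are expected even for a perfectly calibrated estimator — the estimator's
calibration itself (empirical-SD/model-SE ≈ 1.01) is the verified property.

## Known limitations

- Contour placement on real exports depends on the proprietary base-point
  rule of the originating software; the azimuthal seeding here is a
  deterministic stand-in, so absolute GLS values may differ slightly from
  vendor values while remaining internally consistent.
- Geodesics are edge-graph paths; absolute longitude lengths overestimate
  true surface geodesics by a mesh-dependent factor that cancels only
  approximately in strain ratios (observed < 1.5 points against quadrature
  truth at default resolution).
- No competing-risks modelling, time-varying covariates, or frailty terms;
  the event hierarchy resolves multiple events per subject instead.
- The cohort generator's joint covariate law beyond the published pairs is
  an assumption (two-factor copula), and its hazard is a single-index
  exponential model; both are designed for verifiability, not epidemiologic
  realism.
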