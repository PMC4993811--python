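# Methods

This note documents the models, conventions and numerical choices behind
braincohort, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Coordinate conventions and transforms

All world coordinates are RAS+ millimetres; streamline points and ROI
centers are stored in world mm, never voxel indices. TRK files, whose
on-disk convention is voxel-ordered, are converted to world RAS mm on load
through their header transform, so every dialect meets the library in the
same frame.

Affine registrations are 4×4 homogeneous matrices (last row exactly
(0,0,0,1), linear block invertible with |det| > 1e-12). Composition is
matrix multiplication applied right-to-left; chaining checks that the
source/target space names line up. Warp fields are dense per-voxel
displacement vectors in mm on their own grid. Applying a warp adds the
*trilinearly* interpolated displacement; points outside the warp grid are a
hard error rather than extrapolated, because silent extrapolation would
quietly corrupt ROI propagation at the cohort edge.

The local Jacobian determinant of a warp — det(I + ∂d/∂x) — is estimated by
central differences with a step of one voxel spacing per axis, matching the
field's own resolution. For a field encoding a global affine this recovers
|det A| to ~1e-12 away from boundaries (the tests assert 1e-4); the one-voxel
margin requirement is enforced.

## Sphere ROIs

A sphere is (subject, space, center mm, radius mm). Propagation to another
subject maps the center exactly and scales the radius by the cube root of
the volume-change determinant — |det| of the linear block for an affine, the
local Jacobian determinant at the center for a warp. A sphere maps to an
ellipsoid under a non-rigid transform, so *some* convention is required;
volumetric (cube-root) scaling is the isotropic equivalent: rigid transforms
leave the radius untouched, uniform scale s multiplies it by s, and the rule
is invertible. Propagated spheres carry an `auto_propagated` flag because in
practice they approximate a manual placement and await per-subject
adjustment; no snapping to image features is attempted.

Voxel membership for `mean_in_sphere` is voxel-center-within-radius with no
partial-volume weighting. The discretisation error of this choice is
quantified rather than hidden: the tests check that the counted volume is
within 5% of 4/3 π r³ at r = 10 mm with 1 mm voxels and that the error
decreases monotonically as voxels shrink (2 → 1 → 0.5 mm).

Streamline-vs-sphere crossing densifies each polyline so no step exceeds
radius/2 before the vertex-in-sphere test. This bounds the geometric miss
band without an exact segment–sphere solver in the hot path; an analytic
segment–sphere oracle in the tests confirms agreement away from a ±0.3 mm
boundary band.

## Logic bundles

Bundle expressions are boolean trees over crossing predicates. The grammar
(`~` > `&` > `|`, parentheses, identifier leaves) is a plain-text surface
for what is conceptually a GUI operation; NOT is complement *within the
supplied universe* (typically whole-brain tractography), which is the only
sensible reading of "fibers that don't cross C" on a finite fiber set.

Label-map crossing assigns each densified point (step = half the minimum
voxel spacing, so no traversed voxel can be skipped) to its *nearest* voxel,
rounding half away from zero — labels are categorical and are never
interpolated. Evaluation memoizes leaf results per call; the tests assert
that caching is observationally invisible and that the usual algebra laws
(idempotence, commutativity, absorption, double negation, De Morgan) hold
with exact id-set equality against a brute-force per-streamline evaluator.

## Descriptors

Structure volume = matching-voxel count × |det| of the voxel-to-world linear
block; an absent structure yields 0 with a warning rather than an error,
since real cohorts contain genuinely unsegmentable structures and the
flag-and-continue policy keeps cohort loops running. Mean scalar along a
bundle is the mean of per-streamline means (two-level averaging), not a pool
over all points: this stops long, densely-sampled fibers from dominating the
bundle summary. Scalar sampling along streamlines is trilinear; points
outside the scalar grid are skipped and counted, and a streamline entirely
outside contributes a missing value. "Fiber count" counts streamlines (the
reconstruction unit), not estimated axons, and is named accordingly.

`capture_descriptor` maps a descriptor over a sample with no cross-subject
coupling; missing subjects are flagged (NaN + counted), never dropped, and
the stored variable records a JSON provenance snapshot sufficient to re-run
the capture.

## Cohort database

A single SQLite file (stdlib sqlite3; transactional, concurrent readers) is
the shared data model: variables written by descriptors are
indistinguishable from imported ones. Missing values are SQL NULL — never a
sentinel number. Nominal variables store integer level codes plus a
level→label table; CSV import infers numeric/nominal from dtype unless
hinted.

Samples store both their membership and the definition that produced it
(filter conditions + missing policy, explicit list, set-operation tree, or
(parent, n, seed) for random subsamples), and `reevaluate_sample` re-derives
membership from the definition — on unchanged data the two must agree
exactly. Filters are conjunctions only; disjunction is expressed as sample
union, keeping the filter language minimal. Random subsampling is uniform
without replacement from a named, persisted seed: reproducibility is chosen
over true randomness because exploratory sessions must be replayable.

## Statistics

One OLS core serves both the linear-model and ANOVA views; fitted values and
residuals are identical between them by construction. The design matrix is
intercept + treatment-coded dummies (reference = first *sorted* level, a
deterministic convention) + elementwise-product interaction columns, built
by hand and fitted through statsmodels OLS; tests cross-check the
coefficients against the normal equations and the ANOVA table against both
a from-scratch nested-model partial-F computation and statsmodels'
independent Type-II implementation.

Per-term F tests use Type-II sums of squares: each term is adjusted for all
terms that do not contain it, with the denominator mean square from the full
model. Type-II is order-invariant for main effects, which suits a workflow
where regressors are added and removed exploratorily. Degenerate cases are
explicit: a constant outcome reports SS 0 / F 0 (sums of squares below
1e-12·‖y‖² are clamped to zero); rank deficiency raises a collinearity error
naming aliased columns (pivoted QR); an exclusion that empties a nominal
level raises a degenerate-design error instead of silently re-coding.

Missingness is listwise within a model and pairwise for correlations, always
with counts (`n_used`, `n_missing_excluded`, `n_outlier_excluded`,
per-pair n) reported. Outlier handling is an explicit refit
(`refit_excluding`) that composes (excluding {a} then {b} equals {a,b}) and
leaves the original result untouched. Correlation p-values are raw by
default — the exploratory stance shows unfiltered links — with an optional
Benjamini–Hochberg flag to make the adjustment decision explicit. A pair
with fewer than 3 complete observations is reported undefined, not
fabricated.

## Synthetic cohort: what it emulates and what it does not

The generator realises a three-group design (term, preterm-control,
preterm-intervention; 20/group by default) on a 36³ grid of 2 mm voxels.
Structures are ellipsoids (two lateral nuclei, a mid-callosal body,
ventricles) with per-subject lognormal shape jitter (σ = 0.03) and 0.5 mm
center jitter; bundles are quadratic Bezier arcs between the nuclei through
the callosal body, each streamline offset rigidly by N(0, 2 mm) plus 0.2 mm
per-point roughness. Because containment and crossing have closed forms,
every streamline's ground-truth membership is known analytically, and the
tests require ≥ 99% agreement between analytic labels and the evaluated
predicates for streamlines clear of the boundary band.

Injected effects (defaults, all recorded in the manifest):

| effect | value |
| --- | --- |
| mid-callosal volume multiplier | 1.0 / 0.8 / 0.9 per group |
| ventricle volume multiplier | 1.0 / 1.3 / 1.15 |
| FA shift | 0 / −0.05 / −0.02 (noise SD 0.02) |
| streamline count | 60 / 42 / 50 |
| visuomotor score (vmi) | 110 / 100 / 105, within-group SD 10 → 1.0 SD shift |
| transfer time | 18 ms + 2 ms × latent arc-length factor, noise SD 0.25 ms |
| planted outliers | 4 subjects of the untreated preterm group |

The transfer-time variable is coupled to each subject's arc geometry through
a latent standard-normal factor that scales the arc's control height (±30%
per SD), giving a within-group length–transfer-time correlation near 0.97.
Planted outliers have canonical anatomy (latent factor 0) but a transfer
time shifted by 20 noiseless-slope SDs — anatomically unremarkable subjects
with a pathologically slow interhemispheric transfer. Including them the
correlation collapses (|r| ≈ 0.1–0.3); excluding them it returns above 0.9.
This is the outlier-exclusion workflow the stats layer is designed around,
with known truth.

Per-subject randomness uses independent child seeds per (subject, modality),
so simulating only the label maps for a Monte-Carlo loop draws exactly the
same clinical values as a full simulation, and no subject's draw shifts
another's.

What passing these tests shows: the pipeline recovers effects it is told
exist, at the stated sizes, under well-behaved Gaussian noise and exactly
known geometry. What it does not show: robustness to registration failure,
segmentation artifacts, bias fields, non-Gaussian clinical distributions,
or anatomically realistic fiber configurations — none of which the
generator attempts to emulate (no k-space, no bias fields, no fMRI time
series).

## Problem sizes

The Monte-Carlo acceptance surface uses 100 synthetic cohorts of 3 × 20
subjects (label maps only, plus clinical tables) for the volume-ratio and
clinical-shift recovery, and a single full cohort realisation for the
outlier-flip demonstration; the whole acceptance script completes in about
a minute on one CPU. Detection is assessed on the injected pairwise
contrast (term vs untreated preterm) at α = 0.05, where the design's
theoretical power at d = 1.0, n = 20/group is ≈ 0.87.

## Known limitations

- Volumes are never resampled when changing space; only their affine is
  composed. Requests that would require resampling (a volume through a
  warp) are refused.
- Nonlinear inverse warps are out of scope; affine transforms invert
  exactly.
- Legacy ASCII VTK polydata is read-only; TRK/TCK are the write formats.
- Endpoint-only ("terminates in") predicates are not implemented; crossing
  is tested along the whole trajectory.
- Single-summary descriptors only — no along-tract profiles.
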