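# braincohort

Headless analysis library + CLI for cohort neuroimaging studies that mix
spatial data (structural/diffusion MRI derivatives) with clinical and
behavioral tables. It covers the computational path from per-subject files
on disk to group statistics:

- **Coordinate spaces** — apply, compose and invert precomputed affine
  registrations and dense displacement (warp) fields on points and
  tractography streamlines; local Jacobian determinants for volume-change
  estimates. Everything lives in world RAS+ millimetres.
- **Imaging I/O** — NIfTI-1 volumes and integer label maps, TRK/TCK
  streamlines (legacy ASCII VTK polydata read-only), plain-text 4×4
  affines, 4D NIfTI warps; a YAML-configured *project reader* resolves
  (data type, subject id, coordinate space) to a loaded, transformed
  object, and missing files surface as a typed missing-data signal instead
  of a crash.
- **Sphere ROIs** — place a spherical region in one subject, propagate it
  across the cohort through the registrations (radius scales with the cube
  root of the local volume-change determinant), sample mean scalar values
  inside it, and select the streamlines that cross it.
- **Logic bundles** — define fiber bundles by boolean expressions over
  crossing predicates, e.g. the fibers that go through structure `A` or
  ROI `B` but don't cross `C`: `(A | B) & ~C`. `~` binds tightest, then
  `&`, then `|`; `NOT` is complement within the supplied whole-brain
  streamline universe.
- **Descriptors** — turn geometry into per-subject scalars: structure
  volumes from label maps, bundle streamline counts / mean lengths / mean
  scalar along the bundle, linear distances; captured values are stored as
  cohort variables with full provenance.
- **Cohort database** — a single SQLite file shared by every stage: typed
  variables (numeric / nominal with level labels), per-subject values with
  explicit missingness, named samples (filters, explicit lists, set
  operations, seeded random subsamples — each re-derivable from its stored
  definition), sphere ROIs, bundle definitions, saved scenarios with
  annotations, and an append-only session log.
- **Statistics** — statsmodels-style `CohortModel.fit()` → results object
  with OLS coefficients, treatment-coded dummies for nominal variables,
  pairwise interactions, Type-II per-term F tests, residual diagnostics
  (Shapiro–Wilk W, residual-vs-fitted pairs keyed by subject id), pairwise-
  complete Pearson correlation matrices, and explicit outlier-exclusion
  refits that never mutate the original result.
- **Synthetic cohort** — a generator that emulates a three-group
  developmental study (term, preterm control, preterm with early-care
  intervention; 20 subjects per group by default) with ellipsoid
  structures, Bezier-arc bundles, FA-like scalar maps, registrations and a
  clinical table, all with known injected effects, so the entire pipeline
  is testable offline.

## Worked example

Generate a synthetic cohort, import its clinical table, capture the
mid-callosal structure volume as a new variable, and test the group effect:

```python
from braincohort.synth import CohortConfig, generate_cohort
from braincohort.cohortdb import CohortDB
from braincohort.descriptors import DescriptorSpec, capture_descriptor
from braincohort.imaging import list_subjects
from braincohort.stats import CohortModel, ModelSpec

layout, manifest = generate_cohort(CohortConfig(seed=1), "demo")
db = CohortDB("demo/cohort.sqlite")
db.import_table("demo/clinical.csv", type_hints={"group": {"type": "nominal"}})

spec = DescriptorSpec("callosum_volume", "structure-volume",
                      {"labelmap": "labels", "labels": [3]})
capture_descriptor(spec, layout, list_subjects(layout), db=db)

fit = CohortModel.from_db(db, ModelSpec("callosum_volume", ("group",))).fit()
print(fit.summary())
```

prints

```
Outcome: callosum_volume
n used = 60  (missing excluded = 0, outliers excluded = 0)
R-squared = 0.7360

Coefficients (treatment coding, reference = first sorted level):
                      coef  std_err     t         p
Intercept            785.6    11.18 70.28 4.539e-57
group[T.preterm_kmc] 111.2    15.81 7.034 2.794e-09
group[T.term]        198.8    15.81 12.57 4.434e-18

Type-II ANOVA:
            sum_sq  df     F         p
term
group    3.971e+05   2 79.44 3.295e-17
Residual 1.425e+05  57   NaN       NaN
```

The reference level is the untreated preterm group (first sorted label), so
its mean mid-callosal volume is 785.6 mm³ and the term group's is
785.6 + 198.8 = 984.4 mm³ — a recovered volume ratio of 0.798 against the
generator's injected 0.8, detected at p ≈ 3·10⁻¹⁷.

The same pipeline is available from the shell:

```sh
braincohort --seed 1 synth generate --out demo
braincohort --db demo/cohort.sqlite import table demo/clinical.csv
braincohort --project demo/project.yaml --db demo/cohort.sqlite \
    descriptor run --spec volspec.yaml
braincohort --db demo/cohort.sqlite stats anova \
    --outcome callosum_volume --regressors group
```

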