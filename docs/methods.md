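# Methods

## Scope and assumptions

The package post-processes niche-model output and landmark data; it does not
fit niche models (no Maxent, no climate-layer handling) and does not
digitize landmarks. The study extent it is designed for is small (a few
degrees), so all raster and point geometry is planar; no great-circle terms
or reprojection are applied. Sexual dimorphism in the landmark data is
assumed negligible and is not modeled.

## Raster conventions

Grids are ESRI ASCII (`.asc`) with values in [0, 1] (logistic-style
suitability); nodata is NaN in memory. Point-in-cell membership uses
half-open intervals `[edge, edge + cell_size)` from the lower-left origin,
so a point exactly on a cell's lower-left corner belongs to that cell and
the grid's upper and right outer edges are out of extent. The
minimum-training-presence threshold uses an inclusive comparison (≥) so a
species' own training localities are never classified unsuitable by their
own model. Exact floating-point ties in the dominance map are reported as a
distinct `tie` category rather than assigned arbitrarily. Contact zones are
axis-aligned lon/lat boxes (half-open on their upper edges); they must be
pairwise disjoint.

## The modified binomial exclusion test

For a contact zone with `n = n_a + n_b` unique localities, the null
proportion `p₀ = a_away / (a_away + b_away)` is estimated from unique
localities inside potential sympatry but outside every zone, and the
expected counts are `n·p₀` and `n·(1 − p₀)` (they conserve `n` exactly).
The two-sided exact p-value follows the minimum-likelihood rule: sum
`Binomial(n, p₀)` probabilities over every outcome whose probability is ≤
that of the observed count, with a relative tolerance of 1e-7 in the
comparison to avoid float-equality artifacts. Which species counts as the
"success" is immaterial — the rule is invariant under `(k, p₀) → (n−k,
1−p₀)`, and the runner asserts this on every zone instead of choosing a
focal species. A zone with `n = 0` reports expectations 0 and p = 1. No
multiple-testing correction is applied across zones, and no spatial
autocorrelation correction is applied among localities. The release
assessment is deliberately descriptive (per-stratum n/mean/min/max of
own-model suitability, plus counts of localities in rival-dominant cells):
it supports inspection, not a hypothesis test.

## Procrustes superimposition

Full Procrustes GPA: each configuration is centered and scaled to unit
centroid size, rotated to the current consensus by the SVD solution with
reflections disallowed (determinant forced positive — specimens are
digitized in one orientation, so an improper fit indicates a data error),
and the consensus is re-estimated as the landmark-wise mean rescaled to unit
centroid size. Iteration stops when the consensus moves less than 1e-10
(root-sum-square) or after 100 iterations; both rotation and consensus
steps are coordinate-wise optimal, so the Procrustes objective is
non-increasing and this is asserted at every iteration. Shape variables are
the aligned coordinates treated as the linearized tangent space at the
consensus; no explicit orthogonal projection is added, which is the
small-variation regime skull data occupy. The initial consensus is the
first specimen; the final orientation of shape space is therefore arbitrary
up to a common rotation, which no downstream statistic depends on.

## Allometry

A pooled ordinary least-squares regression of each of the 2k shape
variables on centroid size, across all specimens and groups jointly
(per-group regression can be run by fitting `AllometryRegression` to a
subset, but pooled is the default and the pipeline's choice).
`percent_predicted` is 100 × (predicted sum of squares / total shape sum of
squares). Residuals are returned with the mean shape re-added so corrected
shapes remain interpretable as shapes. Residuals are exactly orthogonal to
the centered size predictor; refitting on them gives zero slopes.

## Displacement statistics

Distances are plain Euclidean norms between mean shapes in the common
GPA/tangent frame; group means are **not** re-superimposed pairwise, so the
distances of the common alignment are preserved ("no distortion").
Between-group PCA takes the eigenvectors of the covariance of the
unweighted group means (each group counts once), yielding at most
(groups − 1) axes; specimens are projected onto them and axis variance is
reported against total specimen variance. The permutation mean test
shuffles the two groups' specimens across labels with group sizes
preserved; `exact=True` enumerates all distinct assignments instead (used
for small-sample validation). The displacement test statistic is
`d_diff = d_sym − d_allo`; its null relabels sympatric/allopatric *within
each species independently* — specimens never cross species — preserving
group sizes. This is implemented as permutation without replacement, the
reading most consistent with "random assignment of context within species";
a with-replacement variant was considered and rejected as it breaks the
group-size conditioning. All resampling p-values use the add-one
(Davison–Hinkley) convention `p = (b + 1)/(B + 1)`, so p ∈ [1/(B+1), 1] and
is reproducible bit-for-bit under a fixed seed. Defaults: 10,000
permutations for pairwise distance tests, 1,000 resamples for the
displacement test; both configurable. The size ANOVA uses the standard
one-way F test with Tukey HSD contrasts (studentized-range adjustment);
groups with fewer than 2 usable observations are dropped from the Tukey
table with a warning, and NaN measurements (e.g. missing body mass) are
dropped per measure.

## Synthetic data

The generators define the study conditions under which the engines are
validated:

* **Surfaces** — a Gaussian kernel `exp(−d²/bandwidth²)` around each
  species' optimum: smooth, bounded in (0, 1], and with overlap controlled
  by the optimum offset. Defaults place a 70×60 grid of 0.1° cells over the
  lon −53…−47, lat −34…−27 window with optima offset along the coast and
  bandwidth 1.2°. Real niche-model output has spatial autocorrelation
  structure and anisotropy this kernel does not emulate.
* **Localities** — 29 and 45 points for the two species, drawn at cell
  centers without replacement with probability proportional to suitability.
  Cell-center placement makes point-in-cell classification exact;
  without-replacement sampling makes "unique localities" true by
  construction. Real records cluster along roads and rivers; none of that
  sampling bias is emulated.
* **Landmarks** — 30 landmarks on an elliptical outline (unit centroid
  size), four groups of 22/17/24/22 (85 specimens), centroid sizes from a
  normal law (mean 9.7, sd 0.7) truncated at 0, a common allometric vector
  (default magnitude 0.005 per unit size), isotropic per-coordinate
  landmark noise (sd 0.01), and a sympatric displacement of magnitude
  `delta` (default 0.03) added to one species. Default direction vectors
  are drawn once from the config seed and projected to be translation-free
  and orthogonal to the mean shape, so injected magnitudes are recovered
  exactly by alignment. Noise and shift magnitudes were chosen so simulated
  group mean-shape distances land in the low-10⁻² range typical of
  congeneric skull comparisons; real landmark error is correlated across
  landmarks and anisotropic, which isotropic noise does not capture.
  Nuisance rotation/translation/scale transforms are recorded per specimen
  for ground-truth tests.

Because the original specimen landmarks are unpublished, the morphometric
engine is validated by property, not by value: nuisance-transform removal,
objective monotonicity, allometric-vector recovery, BG-PCA isometry and
subspace recovery, agreement of the permutation test with exhaustive
enumeration, and type-I/power calibration of the displacement bootstrap on
synthetic replicates. Passing these shows the machinery is correct under
the generator's assumptions; it does not certify behavior under real-data
pathologies (digitization error structure, outliers, unbalanced missing
metadata).

## Numerical choices and degenerate inputs

Zero-centroid-size configurations are rejected with the specimen named
(and regenerated up to 10 times inside the simulator). Zero size variance
makes the allometry regression impossible; the error advises using raw
aligned shapes. An all-constant ANOVA input is defined as F = 0, p = 1.
Resampling comparisons use a 1e-12 absolute cushion when counting
`D* ≥ D_obs` so exact ties (e.g. the identity permutation) are counted.
Calibration sizes in the acceptance suite: 1,000 null replicates (99
permutations each) for the permutation test, 500 null replicate datasets
(199 resamples each) and 200 power replicates (499 resamples each) for the
displacement bootstrap — resolutions sufficient for the α = 0.05 and
p ≤ 0.01 criteria they check.

## Pipelines and reproducibility

One global seed fans out to stage seeds via
`SeedSequence(seed).spawn(...)`, each child reduced mod 2³¹ and recorded in
the report, so any stage can be rerun in isolation. Reports are JSON with a
provenance block (config echo, seed, stage seeds, timestamp); the report
digest excludes the timestamp, and reruns with identical config and seed are
digest-identical. The exclusion pipeline accepts zone counts directly, so a
published worked example can be fed in without rasters.
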