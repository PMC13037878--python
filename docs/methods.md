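# Methods

## The measurement model

Each scan is a node × frame matrix of parcellated BOLD signals. After
censoring and frame equating, the scan's network is the matrix of Fisher-z
transformed Pearson correlations between node timeseries with the diagonal
set to zero. Negative z values are replaced by zero before segregation is
computed; the replacement is a value substitution, not an edge removal, so
the within- and between-system denominators W and B remain the structural
pair counts. System segregation is `(Z̄_w − Z̄_b) / Z̄_w` with
`Z̄_w = ΣZ_w / W`, `Z̄_b = ΣZ_b / B`. The statistic is scale invariant, at
most 1 (attained iff `Z̄_b = 0`), undefined when `Z̄_w ≤ 0` (rejected with a
diagnostic), and nodes without a system label are excluded entirely.

Frame equating defaults to truncation (keep the first `target_frames` kept
frames) because it involves no randomness; uniform random subsampling is
available and both record their method in scan metadata.

## Functional systems

Communities are detected on the thresholded group-average young-adult
matrix. Thresholding at density `d` keeps the `round(d·E)` strongest
positive edges (`E = n(n−1)/2`), rounding half away from zero, with ties at
the cutoff broken toward the lexicographically smaller edge index — this
makes retained edge sets nested across densities and the whole sweep
deterministic. Two objectives sit behind one interface:

- **map_equation** (default): Infomap search (igraph), with the two-level
  map-equation codelength computed in-package to select the best of
  `n_restarts` (default 20) seeded restarts;
- **modularity**: weighted Newman modularity maximized by Leiden search,
  selected the same way. This objective admits an exhaustive-search oracle
  on small graphs, which the test suite uses.

Consensus labels start from the reference-density partition (default 7%,
sweep 0.5–20% in 0.5% steps). Communities smaller than `min_size` (default
4 nodes) are dissolved; each dissolved member joins the surviving community
holding the plurality of its retained edge weight at the reference density,
ties resolving to the community with the member's strongest single edge and
residual ties to unassigned. The published adjustment procedure is specified
only at the level of "small communities are merged/reassigned across
densities"; this plurality rule is this package's own concrete, testable
reconstruction, and it is intentionally simple. Isolated nodes are always
unassigned (label −1).

## Harmonization

`CovBat` operates on scan × edge vectors (upper triangle, `i < j`).
Location/scale mode is parametric ComBat: each edge is standardized against
a covariate-adjusted grand mean and pooled variance, per-batch location and
scale are estimated with empirical-Bayes shrinkage (normal prior on
locations, inverse-gamma on scales), and protected covariates (age, sex by
default; species where present) are restored after adjustment. CovBat mode
additionally harmonizes the location/scale of principal-component scores of
the ComBat residuals for the components explaining `pc_variance` (default
0.90) of residual variance, aligning batch covariance.

With shrinkage disabled (`empirical_bayes=False`) the covariate-adjusted
batch means of the output are equalized exactly (an algebraic identity of
the method-of-moments estimates); with shrinkage on, a small residual
difference of order the shrinkage pull remains — this is inherent to
empirical Bayes, not an implementation artifact. The pipeline harmonizes raw
z edges (before negative-zeroing), with batch = acquisition site.

## Aging trajectories and the cross-species model

Per-scan metrics are modeled with linear models: response ~ age + sex, with
a REML random intercept per subject whenever any subject has repeated scans,
reducing exactly to OLS otherwise. Sex is a centered ±0.5 covariate.
Inference is by Wald F (squared coefficient ratio); with repeats the
denominator df are containment-style (`n_obs − rank(X) − n_subjects + 1`),
chosen over a Satterthwaite approximation for simplicity and transparency —
in the balanced, low-noise regimes tested the two are close, and with no
repeats the OLS df are exact.

For cross-species comparison, mouse ages are mapped to human-equivalent
years by the affine map through two anchor pairs (defaults: 3 mo ↔ 18 y,
20 mo ↔ 70 y, configurable for alternate mappings); the common-scale age is
z-scored within the combined sample and species is coded ±0.5, so the model
`response ~ age + species + age×species + sex` yields per-species
standardized slopes `β_age ∓ β_int/2` (reported from a refit on the z-scored
response) and swapping species labels flips only the species and interaction
signs.

The 2 × 2 factorial ANOVA ships in two flavors: between-subjects (classical
two-way decomposition via OLS, type-II sums of squares) and fully
within-subject repeated measures, where each effect in a 2 × 2 design
reduces exactly to a one-sample F(1, n−1) on the per-subject contrast; the
seed-target specificity test is this repeated design applied to the four
seed × target-set cell means per subject (seeds excluded from target sets).

## Distance stratification

Between-system edges are labeled short- or long-range against half the
maximum Euclidean centroid-to-centroid distance of the species'
parcellation, computed over **all** node pairs, so the threshold is a
property of the anatomy alone. Boundary ties (distance exactly at the
threshold) are labeled long. Distances stay in native species units;
cross-species comparisons always use per-species thresholds. Centroid
(not voxel-pair) distances are the adopted convention.

## The synthetic cohort generator

The generator is the package's study condition: everything downstream is
validated against what it plants. Node centroids form mirrored
left/right-hemisphere clusters, one spatial cluster per system (system
centers on a circle of radius `spatial_scale`, jitter 0.15·scale, left
cluster strictly lateral at 0.35·scale and mirrored through the midline), so
systems are spatially contiguous and homotopic pairs exist. The population
correlation of a node pair is

```
[ r_w  if same system else  r_b0 + r_b1 · age_norm ] · exp(−d/λ) + site_offset
```

clipped to ±0.99, with `age_norm` the age scaled to [0, 1] over the design's
range. Non-positive-definite targets are repaired by the smallest diagonal
loading from {1e−8 … 1e−2} (logged) and rejected beyond that. Scans are
exact zero-mean multivariate normal draws (Cholesky), one per
subject × session; follow-up sessions age subjects forward by
`session_age_step`. Sex alternates across subjects and carries no planted
effect (a null covariate); sites rotate in blocks of two so site is not
collinear with sex; non-reference sites receive the additive `site_shift`.

Preset conditions (chosen once for realism and testability — the source
observations report no effect sizes in correlation units):

| parameter | mouse-like | human-like |
|---|---|---|
| ages | 3–20 mo | 18–88 y |
| within r | 0.55 | 0.45 |
| between r at youngest age | 0.15 | 0.18 |
| between r rise over adulthood | +0.10 | +0.16 |
| distance decay scale λ | 6 mm | 200 mm |
| spatial scale | 4 mm | 30 mm |
| nodes / systems | 40 / 4 | 40 / 4 |
| frames per scan | 200 | 200 |

These choices reproduce the qualitative cross-species pattern: mice get
higher segregation, a shallower decline on the common age scale, stronger
distance dependence (λ comparable to the brain's extent), and a lower
proportion of long-range between-system edges.

**Generator-implied estimands.** The population segregation at an age is
computed directly from the planted covariance. Because measured Fisher-z
edges carry sampling noise of roughly `1/√(t−3)` and negatives are zeroed,
the *measured* expectation of a near-zero edge is the censored-normal mean
`μΦ(μ/σ) + σφ(μ/σ)`; `expected_measured_segregation` applies this closed
form so that recovery tests compare fitted slopes against the estimand a
linear model actually targets at the design's frame count (the population
least-squares slope of expected segregation over the cohort's ages).

**What the synthetic conditions do not emulate:** hemodynamics, motion and
scanner noise spectra, spatial smoothness, subject-level trait variance in
coupling (between-subject variance here is purely sampling noise),
non-Gaussian signals, and any resemblance to the deposited datasets'
effect sizes. Passing tests therefore demonstrate correctness of the
computations and calibration of the inference under a known generative
model — not performance on real data.

## Numerical conventions

- Edges are canonically the upper triangle with 0-based indices, `i < j`.
- Correlations are clipped to ±(1 − 1e−7) before `atanh` (logged when hit).
- Scans with too few kept frames or zero-variance nodes are rejected with
  diagnostics naming the scan/node; the pipeline drops them and records the
  reduced cohort.
- All randomness flows from explicit integer seeds; the pipeline fans a
  global seed out to stages by CRC32 of the stage name, and restart seeds
  derive from `numpy.random.SeedSequence`. Deterministic outputs are
  byte-identical across reruns.
- Problem sizes in the shipped simulations (40-node parcellations, 50–100
  subjects per species, 20-replicate Monte-Carlo) are the package's default
  study scale; they were chosen so every distributional claim in the test
  suite rests on at least 20 independent replicates.

## Known limitations

- The consensus rule is a reconstruction (see above), not a transcription of
  the published multi-density adjustment.
- Only two-level (non-hierarchical) community structure; no overlapping
  communities.
- Harmonization is not longitudinal-aware; repeated scans of a subject are
  treated as independent rows by `CovBat` (the trajectory models, not the
  harmonizer, absorb subject identity).
- Mixed-model df are containment-style, not Satterthwaite; p-values in
  heavily unbalanced longitudinal designs will be mildly conservative.
- Nonlinear (spline) age trajectories are out of scope; the linear slope is
  the estimand throughout.
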