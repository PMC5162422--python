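# Methods

## The analysis model

The pipeline treats each olive-oil sample as a frequency-domain 1D ¹H NMR
trace dominated by triacylglycerol (TAG) signals. The statistical unit is
the individual tree (plant): each tree contributes one oil per harvest year,
so a two-harvest cohort is a *paired* design in which tree-level composition
offsets are shared across the years while the harvest effect shifts each
cultivar's mean profile.

The analysis chain is:

1. **Bucketing.** The spectrum is segmented into rectangular buckets of
   fixed width (default 0.04 ppm) over a working region (default
   10.00–0.50 ppm), excluding solvent windows (default 7.6–6.9 ppm, the
   residual CHCl₃ signal and its ¹³C satellites). Each bucket value is the
   trapezoidal integral of the intensity over the bucket span; the bucket is
   labelled by its central chemical shift at two decimals. The grid is
   anchored at the upper region edge and steps downward; a trailing bucket
   truncated at the lower edge is kept; buckets *fully contained* in an
   exclusion window are dropped. Under the defaults this yields exactly 221
   bucket variables (238 anchored buckets minus the 17 contained in
   7.60–6.90 ppm). Other boundary conventions are conceivable; this one is
   fixed because it tiles the region exactly and the resulting count is the
   conventional one for this scheme.
2. **Total-sum normalization.** Each sample row is rescaled to a fixed sum
   (default 100), removing global concentration/acquisition scale. Only
   relative intensities matter downstream.
3. **Pareto scaling.** Each bucket column is mean-centered and divided by
   the square root of its standard deviation (denominator n − 1
   everywhere in the package). This compresses the dynamic range between the
   huge methylene signals and the small diagnostic ones without the noise
   amplification of full unit-variance scaling. A useful identity for
   testing: the variance of a Pareto-scaled column equals the original
   column's SD. Zero-variance columns are set to zero with a warning.
4. **Outlier screen.** Hotelling T² on the first k PCA scores (default
   k = 2) with the F-distribution control limit
   T²_crit = k(n² − 1)/(n(n − k)) · F_{1−α}(k, n − k), default α = 0.05,
   applied once before modelling (no iterative refitting). This is the
   conventional score-plot ellipse; it is a pragmatic screen, not a claim
   that any particular historical analysis used the same rule.

## Latent-variable models

- **PCA** is computed by SVD of the column-centered matrix; explained
  variance fractions are σᵢ²/Σσ². Loadings are oriented so the
  largest-magnitude entry of each vector is positive (sign convention only).
- **PLS-DA** uses NIPALS with per-component deflation of both the data and
  the class-indicator response (tolerance 1e-10, ≤ 500 iterations,
  deterministic start at the response column of maximal variance). Classes
  are encoded as a 0/1 indicator with columns in sorted class order; a
  two-class problem uses the single first-class column. Multi-class
  contrasts use PLS-DA; OPLS-DA is reserved for binary contrasts (the
  two-harvest comparisons).
- **OPLS-DA** (binary response) removes structured response-orthogonal
  variation sequentially: at each round the component of the X loading
  orthogonal to the predictive weight is split off as an orthogonal
  component and deflated; the single predictive component is then fitted on
  the filtered matrix. With zero orthogonal components the model is exactly
  one-component PLS-DA. Variance fractions (predictive and each orthogonal
  component) are reported relative to the centered training matrix.
- **Q²** is 1 − PRESS/TSS with PRESS accumulated over held-out folds of a
  k-fold cross-validation (default 7), folds formed as contiguous blocks of
  a seeded shuffle, and TSS the total response sum of squares about the
  global mean. With folds = n this is exactly leave-one-out. Models center
  internally per training fold; the optional `rescale="pareto"` argument
  additionally re-estimates Pareto parameters inside each training fold so
  no scaling information leaks from held-out samples.
- **Permutation test.** The response rows are permuted n_perm times
  (default 400) and Q² recomputed each time;
  p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1), so the smallest attainable
  p with 100 permutations is 1/101.
- **S-line.** Per-bucket covariance and correlation with the predictive
  score; zero-variance buckets report a missing correlation.
- **Model order** is user-supplied; `select_ncomp_by_q2` optionally stops
  when adding a component no longer raises Q².

## Cluster-quality metrics

In a k-dimensional PCA score space with class labels:

- **Scatter matrices.** S_w = Σ_c Σ_{i∈c} (x_i − m_c)(x_i − m_c)ᵀ and
  S_b = Σ_c n_c (m_c − m)(m_c − m)ᵀ, kept as raw sums: the criterion below
  is invariant to any common normalization, and raw sums make oracle
  comparisons exact.
- **J₂ = |S_w + S_b| / |S_w|**, computed via log-determinants. J₂ ≥ 1
  always, J₂ = 1 iff all class means coincide, and J₂ is invariant under
  any invertible linear map of the score space (the determinant factors
  cancel) — so it is unaffected by how the retained components are scaled.
  A condition-number guard (10¹²) rejects near-singular S_w with advice to
  retain fewer PCs or pass a ridge.
- **Group Mahalanobis distance** between two classes uses the pooled
  within-class covariance of the two classes with divisor n_a + n_b − 2.
  The pooling choice is recorded in output metadata; it is scale-invariant
  and reduces to the Euclidean distance of the means under identity
  covariance. A ridge of 1e-8 × mean diagonal is applied once if the
  pooled covariance is singular, then the operation errors.
- **Component selection.** Either a fixed k or the smallest k reaching a
  cumulative explained-variance threshold (default 0.99). Reports always
  carry the variance actually covered, because distances computed at
  different covered-variance levels are not comparable.
- `year_contrast` applies both metrics to each class's two-harvest split in
  a shared score space — the package's summary of how much each cultivar
  moved between years. The per-class J₂ is computed on the class subset's
  own two-group partition; a whole-partition J₂ over all classes at once is
  also available in `quality_report`. Both modes exist because "J₂ per
  class across two years" is genuinely ambiguous between them.

## Paired plant-level distances

All pairs of (year-1 sample, year-2 sample) of one cultivar are compared by
the Mahalanobis distance in the retained score space, whitened by the pooled
covariance of the cultivar's matched two-year samples (recorded in
`covariance_meta`; the choice of covariance is a convention, and alternatives
such as per-year covariances would change the absolute scale but not the
qualitative contrasts). The matrix diagonal — each tree against itself next
year — is the *plant–plant* set; the full matrix (by default including the
own pair; an `exclude_own_pair` switch exists) is the *plant–cultivar* set.
Distances are square roots of the squared form and hence already
nonnegative; no modulus is needed. Summaries report min/median/mean/SD/max
(SD missing for singletons); kernel-density curves use a Gaussian kernel on
a 512-point grid spanning [min − 3h, max + 3h] with Silverman's rule
h = 0.9·min(s, IQR/1.34)·n^{−1/5} by default.

When tree effects are real and shared across years, the plant–plant
distances are systematically smaller than the plant–cultivar distances
(each tree is closer to itself next year than to its cultivar at large);
with no tree effects the two sets draw from the same distribution and their
means agree.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the full physics of an oil spectrum.

- **Lineshape.** Each TAG component contributes Lorentzian lines at the
  canonical acyl-chain shifts (olefinic ≈ 5.3–5.4, glycerol backbone
  4.1–5.26, bis-allylic 2.74/2.78, allylic ≈ 2.0, chain methylenes
  1.30/1.26, terminal CH₃ ≈ 0.9 ppm), with area weights proportional to
  proton counts and half-width 0.01 ppm — narrower than the 0.04 ppm bucket,
  so bucketing is meaningful. The default grid is 10.2→0.3 ppm, 16,384
  points, descending (conventional NMR plotting order).
- **Composition model.** A cultivar's base profile is a point on the acyl
  simplex (oleic/linoleic/linolenic/saturated summing to 1; the glycerol
  backbone is fixed at 1/3, one backbone per three chains). A realized
  sample profile is base + year effect (second harvest only) + tree effect,
  clipped at zero and renormalized. Tree effects are zero-mean Gaussians
  drawn once per tree and reused in both harvests — the paired structure.
- **Tree-to-tree variability** is component-proportional: SD =
  `plant_effect_sd` (default 0.012) times a fixed profile (oleic 1.0,
  linoleic 0.5, linolenic 0.1, saturated 0.67). A uniform absolute SD would
  imply > 100% CV on linolenic (base fractions ≈ 0.01) and constant
  clipping at zero; the proportional profile keeps every component's
  variability realistic.
- **Defaults as study conditions.** Four cultivars named after the Apulian
  ones they are stylized on: the Coratina-like class oleic-rich, the
  Peranzana-like class PUFA-rich, the other two saturated-rich. Year
  effects are sum-zero shifts acting mainly on the saturated/oleic balance,
  with magnitudes relative to tree variability ordered
  coratina < peranzana < cimadimola < ogliarola (≈ 1 : 1.9 : 2.3 : 2.8),
  mirroring the relative between-year cluster movements such field studies
  report — so recovery tests have a planted, known ordering. No real
  quantitative per-cultivar fatty-acid tables back these numbers; they are
  stylized and fully user-overridable.
- **Noise and alignment.** Additive Gaussian noise per point
  (`noise_sd` = 0.005 intensity units against peak heights of 10²–10³,
  i.e. the very high SNR of concentrated oil at 16 scans) and per-spectrum
  line-position jitter (`shift_jitter_sd` = 0.0005 ppm ≈ 0.2 Hz, residual
  scatter after internal-reference alignment). These levels keep the
  99%-cumulative-variance rule at ~9–11 retained PCs on a 160-sample
  cohort, proportionate to the ~20 PCs such a rule retains on
  hundreds-of-samples datasets; much larger idiosyncratic variance would
  make covariance estimation in the retained space the binding constraint
  rather than the planted effects.
- **What it does not emulate:** FID-domain effects (apodization, phasing,
  baseline), minor components (polyphenols, sterols, squalene), peak-shape
  asymmetry, ¹³C satellites, or correlated (pink) noise. Passing tests
  therefore demonstrate that the *analysis chain* recovers planted
  composition structure under realistic noise — not that it is robust to
  every artifact of real instrument data.

## Numerical choices and degenerate inputs

- SD denominator n − 1 package-wide; NIPALS tolerance 1e-10, ≤ 500
  iterations; PCA rank guard at σ₁ × 1e-12.
- Bucket-grid arithmetic uses an absolute tolerance of 1e-9 ppm on boundary
  comparisons so grids anchored at decimal edges are not misclassified by
  floating-point representation.
- Covariance solves go through Cholesky; on failure a single ridge of
  1e-8 × mean diagonal is attempted before erroring.
- Empty distance sets, singleton classes in scatter computations,
  zero-variance sets passed to the KDE, nonpositive row sums in
  normalization, and folds that empty a class all raise labelled errors
  naming the offending sample/class where possible.
- Determinism: all stochastic operations take either an integer seed or an
  explicit generator; identical designs (including seed) reproduce cohorts
  bit-for-bit, and the pipeline writes byte-identical numeric outputs for
  identical configurations.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script experiments run on cohorts of
4 cultivars × 12–20 trees × 2 harvests (96–160 spectra) on the default
16,384-point grid, with 10–20 replicate seeds for the ranking and
paired-distance experiments; oracle comparisons use 100 random instances
with n ≤ 30 samples in ≤ 3 dimensions. These sizes were chosen as the
smallest at which the planted effects are comfortably identifiable.

## Known limitations

- OPLS-DA is binary-only by design; multi-class year contrasts should be
  decomposed into pairwise models.
- The outlier rule, the Mahalanobis pooling convention, and the paired-set
  covariance are documented conventions; other choices are defensible and
  would shift absolute values (not the qualitative orderings the tests
  check).
- Bucket-boundary conventions differ between software packages; counts
  other than 221 are possible under other anchoring rules.
- The generator's effect sizes are stylized; absolute distances and J₂
  values from synthetic cohorts should not be compared with values from
  real datasets, only their orderings and invariances.
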