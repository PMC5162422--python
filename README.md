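# olivenmr

A tested Python pipeline for ¹H NMR metabolomic profiling of single-tree
olive-oil cohorts. It addresses a recurring question in food chemometrics:
**how stable is a cultivar's oil composition across harvest years, measured
at the level of individual trees?** Each tree yields one oil per harvest;
the spectra report the triacylglycerol acyl signals (oleic, linoleic,
linolenic, saturated chains), and the analysis quantifies how far each
cultivar's cluster moves between two harvests — and how far each single
tree's oil moves relative to its cultivar.

The package is aimed at NMR metabolomics practitioners who need the full
chain from frequency-domain spectra to cluster-quality numbers, plus a
synthetic cohort generator so every stage is testable without instrument
data.

## What it computes

- **Bucketing and pretreatment.** Spectra are segmented into rectangular
  buckets of fixed 0.04 ppm width over 10.00–0.50 ppm, excluding the
  residual-chloroform window 7.6–6.9 ppm (221 bucket variables), then
  total-sum normalized per sample and Pareto scaled per bucket
  (x → (x − x̄)/√s). A Hotelling T² screen on the first PCA scores flags
  outlying samples once, before modelling.
- **Latent-variable models.** PCA by SVD; multi-class PLS-DA by NIPALS on a
  class-indicator response; binary OPLS-DA that filters response-orthogonal
  variation into separate components. Validation by R²X/R²Y, Q² from 7-fold
  cross-validation, and a response permutation test
  (p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1)); S-line
  covariance/correlation loadings for interpretation.
- **Cluster quality.** Within/between-class scatter S_w, S_b in PCA score
  space, the criterion **J₂ = |S_w + S_b| / |S_w|** (≥ 1; large = tight,
  well-separated clusters), and group Mahalanobis distances
  d = √((m_a − m_b)ᵀ C⁻¹ (m_a − m_b)) with pooled within-class C, under
  either a fixed component count or a cumulative-variance rule (e.g. 99%).
- **Paired plant-level distances.** Pairwise Mahalanobis distances between
  the two harvest cohorts, split into a *plant–plant* set (each tree vs
  itself next year) and a *plant–cultivar* set (each tree vs every
  same-cultivar oil of the next harvest), with distribution summaries and
  Gaussian kernel-density curves.
- **Synthetic cohorts.** Lorentzian-line spectra with cultivar-specific acyl
  profiles, per-cultivar harvest-year shifts, tree-level random effects
  shared across the two years (the paired structure), peak-position jitter
  and additive noise.

## Worked example

```python
from olivenmr import (default_design, generate_cohort, fit_pca,
                      select_ncomp_by_cumvar, year_contrast)
from olivenmr.preprocessing import (build_bucket_table, normalize_total_sum,
                                    pareto_scale)
from olivenmr.paired import paired_distance_sets, summarize

design = default_design(plants_per_cultivar=20, seed=7)
cohort = generate_cohort(design)           # 4 cultivars x 20 trees x 2 harvests
table = pareto_scale(normalize_total_sum(
    build_bucket_table(cohort.spectra, cohort.metadata)))
pca = fit_pca(table.values, 40)
k = select_ncomp_by_cumvar(pca, 0.99)      # 99% cumulative-variance rule
print(year_contrast(pca.scores[:, :k],
                    table.metadata["cultivar"].tolist(),
                    table.metadata["harvest"].tolist()))
```

prints (160 × 221 bucket matrix, 9 PCs retained for 99% variance):

```
     class  n  mahalanobis   j2
cimadimola 40         2.86 3.15
  coratina 40         1.39 1.51
 ogliarola 40         3.51 4.24
 peranzana 40         3.16 3.63
```

The between-year Mahalanobis distance and J₂ are smallest for the
Coratina-like class: its oil profile moved least between the two harvests,
exactly the ordering planted in the generator defaults. The paired analysis
for that cultivar,

```python
sets = paired_distance_sets(pca.scores[:, :k], table.metadata, "coratina")
s = summarize(sets.plant_plant)
print(f"median={s.median:.2f} mean={s.mean:.2f} sd={s.standard_deviation:.2f}")
# median=3.86 mean=3.77 sd=0.59
```

summarizes how far each single tree's oil moved between the years, in
covariance-whitened score-space units; comparing it with the plant–cultivar
set shows whether trees retain an individual signature across harvests.

## Command line

```sh
olivenmr simulate --out spectra/ --seed 1          # write spectra + metadata
olivenmr bucket spectra/*.txt --metadata spectra/metadata.csv --out table.csv
olivenmr preprocess table.csv --normalize 100 --scale pareto \
    --outliers t2:0.05:2 --out scaled.csv
olivenmr fit scaled.csv plsda --ncomp 6 --cv 7 --permutations 400 --out model/
olivenmr quality scaled.csv --pcs 2,3,4 --cumvar 0.99 --out quality.csv
olivenmr paired scaled.csv --cultivar coratina --cumvar 0.99 --out paired/
olivenmr run --out run1/ --seed 0                  # full pipeline + manifest
```

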