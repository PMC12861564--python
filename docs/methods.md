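# Methods

`gliotype` reimplements a multimodal radiomic subtyping analysis as a
tested pipeline.  This note records the models, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## Hierarchical multi-kernel learning

**Kernel bank.** For each modality the features are z-scored per feature
(kernel bandwidth pooling across features requires a common scale) and a
grid of neighborhood-adaptive Gaussian kernels is built:

    K(i,j) = exp( -d(i,j)^2 / (2 eps_ij^2) ),
    eps_ij = sigma * (mu_ik + mu_jk) / 2,

where `d` is Euclidean distance and `mu_ik` is sample *i*'s mean distance
to its *k* nearest neighbors (self excluded; distance ties broken by
sample order).  Defaults: sigma in {1.0, 1.25, ..., 2.5} and k in
{10, 15, 20, 25, 30} — 35 kernels per modality, the standard grid for
multiple-kernel similarity learning at cohort sizes of a few hundred.

**Stage 1 (per-modality similarity).** Alternating exact minimization of

    J(S, w, L) = sum_ij [ beta S_ij^2 - W_ij S_ij + (gamma/2) D_ij S_ij ]
                 + rho n sum_l w_l log w_l,

with `W = sum_l w_l K_l`, `D_ij = ||L_i - L_j||^2`, rows of `S` on the
probability simplex, and `L` the bottom-k eigenvectors of the Laplacian of
`(S + S')/2`.  The three block updates — row-wise simplex projection,
eigendecomposition, softmax — are each exact minimizers, so the objective
is non-increasing (tests assert this to 1e-8).  Defaults `beta = 0.2`,
`gamma = n/k`, `rho = 0.1` balance the three terms for kernels whose
entries live in [0, 1]; `gamma = n/k` scales the rank penalty to the
embedding distances, whose magnitude shrinks like k/n.  The returned
similarity is the symmetrized final iterate: the spectral steps downstream
(fusion weights, embedding) require symmetry, and symmetrization preserves
the row-normalized mass.

**Stage 2 (modality fusion).** The modality weights `beta_m` are the
leading eigenvector (nonnegative by Perron-Frobenius, normalized to the
simplex) of `diag(q) R diag(q)`, where `R` holds RV coefficients between
the double-centered per-modality similarities and `q_m` is each modality's
own cluster quality — the Newman modularity of its k-way spectral
partition.  The modularity factor matters: with only two modalities any
pairwise agreement measure is symmetric in its arguments, so agreement
alone can never rank an informative modality above a noise one; modularity
is an asymmetric per-view quantity that does (a clean two-block similarity
scores ~0.5, an unstructured graph ~0).  The fused matrix is the weighted
sum of the raw similarities.

**Clustering.** The learned similarities are sparse (simplex projection),
so before the spectral embedding the fused matrix is smoothed by one
two-hop diffusion step (`P P'` on the row-normalized similarity) and a
small uniform teleport term (1% of the mean entry) keeps the graph
connected; without these, near-disconnected intra-cluster fragments can
outrank the between-cluster eigenvectors.  K-means (best inertia of 100
restarts, seeded) runs on the row-normalized top-k eigenvectors of the
symmetrically normalized matrix.

## Choosing the number of subtypes

`k* = argmax_k CPI(k) + Gap(k)` over k = 2..8, ties toward smaller k.

* **CPI** refits the full hMKL pipeline on a 70% training split (20
  repeats), projects held-out samples into the training spectral embedding
  via their kernel-weighted, k-NN-sparsified cross-similarity to training
  samples (renormalized to the unit sphere the embedding lives on), and
  scores `1 - WSS/TSS` of the held-out points around the training-cluster
  centroids.  The sparsification step is load-bearing: a dense Gaussian
  cross-kernel in a noise-dominated feature space is nearly uniform and
  carries no cluster information.
* **Gap** follows Tibshirani's formulation: uniform reference draws over
  the per-feature range box of the concatenated standardized features,
  with K-means dispersion in both arms and the sqrt(1 + 1/B) standard
  error.  K-means (rather than a re-run of the similarity pipeline) keeps
  the reference arm cheap and deterministic; Gap here acts as the
  regularizing term of the sum, while CPI carries most of the
  discrimination when many noise features are present.
* **DBI / CH** are confirmatory indices computed on the concatenated
  standardized features at each candidate k (scikit-learn closed forms,
  hand-verified in the tests).

Known limitation: CPI's penalty for over-splitting is weak — compact
sub-clusters still predict held-out dispersion well — so on k=3 cohorts
the argmax occasionally lands one above the truth.  The k=2 regime the
package defaults to is robust across seeds.

## Label transfer

External-cohort labels come from the published SNF cross-diffusion: full
and k-NN transition matrices per modality (affinities from the same
adaptive Gaussian construction, sigma = 0.5, K = 20), t = 20 cross-view
update rounds, symmetrized average, then label propagation `Y <- P Y`
with training rows clamped (tolerance 1e-8, max 1000 iterations).
Features are matched to the cross-cohort intersection and z-scored per
cohort before joint affinity computation; per-cohort scaling absorbs
site-level location/scale differences, while genuine batch-effect
correction is out of scope.

## Between-subtype statistics

* Chi-square: Pearson for r x c, Yates continuity correction for 2 x 2 —
  the correction is required to reproduce the printed two-cohort
  statistics and is verified to +/-0.005 against all eight of them.
* Mann-Whitney U: tie-corrected normal approximation with continuity
  correction; exact enumeration is the oracle in tests.
* Survival: Kaplan-Meier / log-rank via lifelines; Cox proportional
  hazards via the Breslow partial likelihood (statsmodels PHReg) with the
  published covariate coding (age >= 52, volume >= 91 cm^3, grade 3/4 vs
  2, male vs female, high- vs low-risk subtype) and Wald CIs.
* Pathway activity: per sample, OLS of the expression vector on all
  pathway weight columns jointly (intercept included); the slope t-values
  are the activity scores, positive = activated.  Implemented by normal
  equations with the residual variance floored at 1e-12 of the response
  variance so an exact fit returns a numerically dominant t rather than
  0/0.  Group comparison is a two-sided Welch t-test per pathway; a
  `--contrast` mode fits the same model once to a per-gene statistic
  vector instead.
* Radiomic enrichment: per-feature cohort z-scores; over-call above the
  pooled 75th percentile, under-call below the 25th (linear-interpolation
  percentiles); upper-tail hypergeometric p per (feature, cluster,
  direction); one BH family across all tests; significance additionally
  requires the altered fraction >= 2/3 inside the cluster and < 1/3 in at
  least one other cluster.  Note a structural consequence of pooled
  quartile thresholds: only ~25% of samples can be altered in a given
  direction, so the 2/3 in-cluster criterion is attainable only for
  clusters holding under ~37.5% of the cohort — the recovery experiments
  therefore plant signals in a minority cluster.

## IDH genotype prediction

**Kernel PLS.** Gaussian kernel `exp(-||x - x'||^2 / (2 sigma^2))`,
double-centered in feature space; NIPALS-style component extraction with
projector deflation; dual regression coefficients
`alpha = U (T' K U)^{-1} T' y`; test kernels centered with the training
means.  With a linear kernel the predictions coincide with linear PLS to
1e-8 (tested against scikit-learn), and at c = n-1 the model interpolates
the training response.

**Genetic algorithm.** Generational GA over (log sigma in [-2, 4],
components in 1..15): tournament selection (size 3), uniform crossover
(p = 0.7), Gaussian mutation on log sigma (sd 0.5) and +/-2 random-walk
mutation on the component count (p = 0.3 each), elitism of one.  Fitness
is mean 5-fold stratified cross-validated AUC; a failed evaluation scores
0.  The component count is co-optimized by default and can be fixed.

**Evaluation.** Stratified 80/20 resampling; per split the eight-metric
battery (AUC by the rank formulation, Se, Sp, ACC, Youden, F-measure,
G-means, MCC; undefined denominators return 0 with a flag).  KPLS scores
are Platt-calibrated to [0, 1] before the 0.5 decision threshold.
Comparators: random forest (500 trees, sqrt(p) features), L1 logistic
regression (100-value path, tenfold CV by deviance), 1-NN, and Gaussian
naive Bayes.  Model comparison is one-way ANOVA followed by Dunnett's
many-to-one test against GA-KPLS (scipy implementation; a Monte-Carlo
max-|t| null is the oracle in tests).  The GA is run once on the full
training table and the tuned kernel refitted per resample; re-running the
GA inside every split would multiply cost ~100-fold without changing the
comparison.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not images: no scanner effects, no texture computation, no spatial
correlation beyond an equicorrelated factor (rho = 0.3) inside each
informative block.

* **Subtype signal.** A one-hot block design assigns each subtype a
  disjoint informative feature group shifted by delta (default 3, in
  within-subtype SD units) against the others, giving equal, deterministic
  pairwise separation.  With two modalities each receives delta/sqrt(2),
  so the sequences jointly carry the full separation; for k > 2 each
  modality additionally merges one subtype pair (T1CE the last pair,
  T2FLAIR the first), making fusion necessary for full resolution — the
  multimodal premise made literal.
* **Clinical structure.** Default sizes 246 (training) and 144 (test);
  subtype proportions 153/93; per-subtype IDH, MGMT, gender and grade
  frequencies taken from the published two-cohort composition; log-normal
  tumor volumes matched to the reported mean +/- SD per subtype;
  exponential survival with per-subtype hazards (defaults 1/400 and 1/800
  per day, hazard ratio 2) under administrative censoring at five years.
* **IDH signal.** Two latent standard-normal coordinates per sample are
  embedded (with noise, SD 0.3) as two feature columns per modality; the
  mutation probability's logit is shifted linearly in u1 (`linear`) or in
  the negative squared radius centered at the chi-square(2) median
  (`radial`).  The radial mode is linearly inseparable by construction:
  it is the designed condition under which the kernel classifier's
  advantage over the linear comparator is demonstrated.
* **Expression.** A sparse signed weight matrix (500 genes, 14 pathways,
  35 nonzero weights per pathway) generates expression as
  `weights . (baseline + group activation) + Gaussian noise`.

Passing the recovery experiments therefore shows the pipeline recovers
planted structure of realistic size and shape; it does not validate
radiomic feature extraction, scanner harmonization, or behavior under the
heavier-tailed, batch-affected distributions of real feature tables.

## Problem sizes used in the shipped experiments

The recovery experiments run at n = 200 (subtype recovery and cluster
number), n = 144 (transfer, pathway scoring), n = 2000 (Cox recovery),
n = 120 (enrichment), and n = 240 with 100 resampling splits (classifier
ordering); these sizes give stable pass/fail behavior across seeds while
keeping the full suite runnable on a laptop core.  All randomness flows
from a single seed per run.
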