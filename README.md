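# gliotype

Phenotypic subtyping of glioma from multimodal MRI radiomics, for
researchers who have per-sequence radiomic feature tables (e.g. T1CE and
T2FLAIR extractions) plus clinical annotations and want to (a) discover
unsupervised patient subtypes by fusing the two sequences, (b) carry those
subtypes to an external cohort, (c) characterize them statistically
(survival, genotype frequencies, pathway activity, feature enrichment),
and (d) predict IDH genotype with a kernel classifier tuned by a genetic
algorithm.  A synthetic-cohort generator with known ground truth makes
every stage testable without patient data.

## The method

**Subtyping (hMKL).** Per modality *m*, a bank of neighborhood-adaptive
Gaussian kernels K_l (bandwidth grid x k-NN grid on z-scored features) is
combined into a learned similarity S_m by alternating minimization of a
CIMLR-type objective

    min_{S, w, L}  sum_ij [ beta S_ij^2 - (sum_l w_l K_l)_ij S_ij
                            + (gamma/2) ||L_i - L_j||^2 S_ij ]
                   + rho n sum_l w_l log w_l

with rows of S on the simplex and L the bottom-k Laplacian eigenvectors
(the rank-k constraint that makes S cluster-shaped).  Modality weights
beta_m then come from the leading eigenvector of a quality-weighted RV
agreement matrix between the S_m, and K-means on the spectral embedding of
S = sum_m beta_m S_m yields the subtype labels.  The cluster number
maximizes CPI(k) + Gap(k).  External cohorts receive labels by SNF
cross-diffusion and clamped label propagation.

**IDH prediction (GA-KPLS).** Kernel PLS extracts latent components from a
double-centered Gaussian kernel; a generational GA tunes the bandwidth
sigma (and the component count) by cross-validated AUC.  Random forest,
L1 logistic regression, 1-NN and naive Bayes serve as comparators over
stratified 80/20 resampling, scored by AUC, Se, Sp, ACC, Youden,
F-measure, G-means and MCC, with Dunnett's test for the many-to-one
comparison.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from gliotype import (SimCohortSpec, simulate_cohort, SubtypeModel,
                      RunConfig, km_logrank)
from sklearn.metrics import adjusted_rand_score

spec = SimCohortSpec(n_samples=200, k_true=2, delta=3.0, seed=20240101)
t1ce, t2flair, clinical, truth = simulate_cohort(spec)

model = SubtypeModel([t1ce, t2flair], RunConfig(seed=20240101))
res = model.fit(k=2)
print(res.summary())
print("ARI vs truth:", round(adjusted_rand_score(truth, res.labels_), 3))

surv = km_logrank(clinical.frame["os_days"], clinical.frame["event"],
                  res.labels_)
print(f"log-rank chi2 = {surv.chi2:.1f}, p = {surv.p:.2g}")
```

Output:

```
Multimodal subtype model (hMKL)
======================================
samples: 200   modalities: 2   k: 2
cluster sizes: 1: 124, 2: 76
modality weights (beta): T1CE=0.501, T2FLAIR=0.499
T1CE: converged=True, top kernels (sigma=2.5, k=30), (sigma=2.5, k=25), (sigma=2.5, k=20)
T2FLAIR: converged=True, top kernels (sigma=2.5, k=30), (sigma=2.5, k=25), (sigma=2.5, k=20)
ARI vs truth: 1.0
log-rank chi2 = 28.5, p = 9.1e-08
```

The two simulated sequences carry complementary halves of the subtype
signal, so the fused model recovers the planted 124/76 partition exactly
(ARI 1.0), and the subtype split separates survival strongly — the
generator plants a two-fold hazard difference between subtypes.

A thin CLI wraps the same stages:

```bash
gliotype simulate --seed 1 --out cohort/
gliotype cluster cohort/t1ce.csv cohort/t2flair.csv --k 2 --out subtypes.csv
gliotype select-k cohort/t1ce.csv cohort/t2flair.csv --out kreport.csv
```

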