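"""Between-subtype statistics.

Contingency tests, rank tests, survival analyses, pathway-activity
scoring, and radiomic-feature enrichment, mirroring the comparisons run
after subtyping: chi-square (Yates-corrected for 2x2) on categorical
factors, Mann-Whitney U on continuous ones, Kaplan-Meier / log-rank and
Cox proportional hazards for survival, a per-sample multivariate linear
model on pathway weight matrices for pathway activity, and hypergeometric
enrichment of quartile-altered features within clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, FeatureTable

logger = logging.getLogger("gliotype")


# ---------------------------------------------------------------------------
# contingency and rank tests


def chi_square_test(
    table: np.ndarray, yates_2x2: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table; Yates correction on 2x2.

    Zero rows/columns are dropped (with a warning) and df adjusted.
    Returns (chi2, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0:
        raise ValueError("contingency table must have positive total")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("chi_square_test: dropping zero rows/columns")
        t = t[np.ix_(keep_r, keep_c)]
    correction = yates_2x2 and t.shape == (2, 2)
    chi2, p, df, _ = stats.chi2_contingency(t, correction=correction)
    if df == 0:
        return 0.0, 0, 1.0
    return float(chi2), int(df), float(p)


def mann_whitney(
    x, y, continuity: bool = True
) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns (U for sample x, signed Z, two-sided p).  If every value is
    tied across both samples, Z = 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (nt * (nt - 1))
    var = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    if var <= 0:
        return float(u1), 0.0, 1.0
    cc = 0.5 if continuity else 0.0
    diff = u1 - mu
    z = (diff - np.sign(diff) * cc) / np.sqrt(var) if diff != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# survival


@dataclass
class KMLogrankResult:
    curves: dict  # group -> KaplanMeierFitter
    chi2: float
    p: float


def km_logrank(os_days, event, group) -> KMLogrankResult:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    os_days = np.asarray(os_days, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    curves = {}
    for g in np.unique(group):
        m = group == g
        if event[m].sum() == 0:
            logger.warning("km_logrank: group %s has no events", g)
        kmf = KaplanMeierFitter()
        kmf.fit(os_days[m], event[m], label=str(g))
        curves[g] = kmf
    res = multivariate_logrank_test(os_days, group, event)
    return KMLogrankResult(curves, float(res.test_statistic), float(res.p_value))


def cox_fit(
    clinical: ClinicalTable,
    subtype_labels: np.ndarray,
    age_cut: float = 52.0,
    volume_cut: float = 91.0,
) -> pd.DataFrame:
    """Cox regression of overall survival on subtype and clinical covariates.

    Covariates follow the published coding: high-risk subtype vs low-risk,
    age >= ``age_cut`` years, male vs female, WHO grade 3 and 4 vs grade 2,
    and tumor volume >= ``volume_cut`` cm^3.  Ties are handled by the
    Breslow partial likelihood; Wald CIs.  Label 1 is taken as high-risk.
    """
    f = clinical.frame
    labels = np.asarray(subtype_labels)
    design = pd.DataFrame({
        "high_risk": (labels == 1).astype(float),
        "age_ge_cut": (f["age_years"].to_numpy(float) >= age_cut).astype(float),
        "male": (f["gender"].to_numpy() == "male").astype(float),
        "grade_3": (f["grade"].to_numpy(int) == 3).astype(float),
        "grade_4": (f["grade"].to_numpy(int) == 4).astype(float),
        "volume_ge_cut":
            (f["tumor_volume_cm3"].to_numpy(float) >= volume_cut).astype(float),
    }, index=f.index)
    constant = design.nunique() <= 1
    if constant.any():
        raise ValueError(
            f"constant covariates: {list(design.columns[constant])}")
    n_events = int(f["event"].sum())
    if n_events < design.shape[1]:
        raise ValueError("fewer events than covariates")
    model = PHReg(f["os_days"].to_numpy(float), design.to_numpy(),
                  status=f["event"].to_numpy(int), ties="breslow")
    res = model.fit()
    b = res.params
    se = res.bse
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "b": b, "se": se, "z": z, "p": p,
        "hr": np.exp(b),
        "hr_lo": np.exp(b - 1.959964 * se),
        "hr_hi": np.exp(b + 1.959964 * se),
    }, index=design.columns)


def subtype_volume_correlation(
    labels: np.ndarray, volumes: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Point-biserial correlation between binary subtype and volume,
    with a Fisher-z 95% CI."""
    labels = np.asarray(labels, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.std(labels) == 0 or np.std(volumes) == 0:
        raise ValueError("zero variance in labels or volumes")
    r, _ = stats.pearsonr(labels, volumes)
    n = len(labels)
    zr = np.arctanh(r)
    half = 1.959964 / np.sqrt(n - 3)
    return float(r), (float(np.tanh(zr - half)), float(np.tanh(zr + half)))


# ---------------------------------------------------------------------------
# pathway activity


@dataclass
class PathwayScoreSet:
    """Per-sample pathway scores: the fitted slope t-values of the
    multivariate linear model of expression on pathway weights.  Positive
    means activation, negative inhibition."""

    scores: pd.DataFrame  # samples x pathways


def pathway_scores_mlm(
    expression: pd.DataFrame, weights: pd.DataFrame
) -> PathwayScoreSet:
    """Per-sample OLS of the gene-expression vector on all pathway weight
    columns jointly (with intercept); score = each slope's t-value."""
    genes = [g for g in weights.index if g in set(expression.columns)]
    if len(genes) < weights.shape[1] + 2:
        raise ValueError("need at least n_pathways + 2 shared genes")
    w = weights.loc[genes]
    if np.linalg.matrix_rank(w.to_numpy()) < w.shape[1]:
        raise ValueError("rank-deficient pathway weight matrix")
    x = add_constant(w.to_numpy())
    e = expression[genes].to_numpy(dtype=float)
    n_genes, n_coef = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    betas = xtx_inv @ x.T @ e.T                   # (coef, samples)
    resid = e.T - x @ betas
    dof = n_genes - n_coef
    s2 = (resid ** 2).sum(axis=0) / dof
    # floor the residual variance so an exact fit yields a huge (not NaN)
    # t for the driving pathway and ~0 for the rest
    var_y = np.maximum(e.var(axis=1), 1e-300)
    s2 = np.maximum(s2, 1e-12 * var_y)
    se = np.sqrt(np.outer(np.diag(xtx_inv), s2))
    t = (betas / se)[1:]                          # drop intercept
    scores = pd.DataFrame(t.T, index=expression.index, columns=w.columns)
    return PathwayScoreSet(scores)


def pathway_scores_contrast(
    contrast: pd.Series, weights: pd.DataFrame
) -> pd.Series:
    """Fit the multivariate linear model once to a per-gene statistic
    vector (e.g. differential-expression t-values) instead of per sample."""
    genes = [g for g in weights.index if g in set(contrast.index)]
    w = weights.loc[genes]
    x = add_constant(w.to_numpy())
    fit = OLS(contrast[genes].to_numpy(dtype=float), x).fit()
    return pd.Series(fit.tvalues[1:], index=w.columns, name="t")


def pathway_group_compare(
    scores: PathwayScoreSet, groups: np.ndarray, high_label=1
) -> pd.DataFrame:
    """Welch t-test per pathway between two groups of per-sample scores.

    Positive t means higher activity in the ``high_label`` group.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    other = uniq[uniq != high_label][0]
    a = scores.scores[groups == high_label]
    b = scores.scores[groups == other]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return pd.DataFrame({"t": t, "p": p}, index=scores.scores.columns)


# ---------------------------------------------------------------------------
# radiomic enrichment


@dataclass
class EnrichmentRecord:
    feature: str
    cluster: int
    direction: str           # "over" | "under"
    altered_in_cluster: int
    cluster_size: int
    altered_overall: int
    cohort_size: int
    p: float
    q: float = np.nan
    significant: bool = False
    passes_fraction_filter: bool = False

    def __post_init__(self) -> None:
        if self.altered_in_cluster > min(self.cluster_size,
                                         self.altered_overall):
            raise ValueError("inconsistent enrichment counts")


def radiomic_enrichment(
    features: FeatureTable,
    labels: np.ndarray,
    fdr_level: float = 0.05,
    lower_q: float = 25.0,
    upper_q: float = 75.0,
    min_in_fraction: float = 2.0 / 3.0,
    max_out_fraction: float = 1.0 / 3.0,
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of quartile-altered features per cluster.

    Per feature (on pooled per-feature z-scores): samples above the cohort
    75th percentile are over-calls, below the 25th under-calls.  Per
    (feature, cluster, direction) the upper-tail hypergeometric p tests
    whether the cluster holds more altered samples than chance; BH-FDR is
    applied across all tests in one family.  A record is significant iff
    q < ``fdr_level`` AND the altered fraction is >= 2/3 in the cluster
    AND < 1/3 in at least one other cluster.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    z = features.standardized().values
    n = z.shape[0]
    records: list[EnrichmentRecord] = []
    lo = np.percentile(z, lower_q, axis=0)
    hi = np.percentile(z, upper_q, axis=0)
    for direction, altered in (("over", z > hi), ("under", z < lo)):
        total_altered = altered.sum(axis=0)
        for c in clusters:
            in_c = labels == c
            size = int(in_c.sum())
            in_counts = altered[in_c].sum(axis=0)
            out_fracs = {
                oc: altered[labels == oc].mean(axis=0)
                for oc in clusters if oc != c
            }
            for j, name in enumerate(features.feature_names):
                k_in = int(in_counts[j])
                k_tot = int(total_altered[j])
                p = float(stats.hypergeom.sf(k_in - 1, n, k_tot, size))
                frac_ok = (
                    k_in / size >= min_in_fraction
                    and any(f[j] < max_out_fraction for f in out_fracs.values())
                )
                records.append(EnrichmentRecord(
                    name, int(c), direction, k_in, size, k_tot, n, p,
                    passes_fraction_filter=bool(frac_ok),
                ))
    pvals = np.array([r.p for r in records])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(records, qvals):
        r.q = float(q)
        r.significant = bool(q < fdr_level and r.passes_fraction_filter)
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
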