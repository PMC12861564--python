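"""IDH-genotype prediction: GA-optimized kernel PLS and comparators.

Kernel partial least squares (KPLS) regresses the binary genotype on latent
components extracted from a double-centered Gaussian kernel by NIPALS-style
iteration with deflation; samples that are not linearly separable in input
space can become separable in the kernel feature space.  A generational
genetic algorithm tunes the kernel bandwidth (and optionally the number of
components) against cross-validated AUC.  Four standard classifiers act as
comparators, an eight-metric battery scores every resample split, and
Dunnett's many-to-one test compares the comparators against GA-KPLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

logger = logging.getLogger("gliotype")

METRIC_NAMES = ("auc", "se", "sp", "acc", "youden", "f_measure", "mcc",
                "g_means")


# ---------------------------------------------------------------------------
# kernels and KPLS


def gaussian_kernel(x: np.ndarray, x2: np.ndarray | None = None,
                    sigma: float = 1.0) -> np.ndarray:
    """K(i,j) = exp(-||x_i - x'_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    x2 = x if x2 is None else np.asarray(x2, dtype=float)
    if x.shape[1] != x2.shape[1]:
        raise ValueError("feature dimensions must match")
    d2 = ((x[:, None, :] - x2[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


@dataclass
class KPLSModel:
    """Fitted kernel-PLS regression on a centered training kernel."""

    sigma: float
    n_components: int
    x_train: np.ndarray
    t_scores: np.ndarray        # n x c orthonormal score vectors
    u_scores: np.ndarray
    k_train: np.ndarray         # raw (uncentered) training kernel
    y_mean: float
    alpha: np.ndarray           # dual coefficients for prediction
    threshold: float = 0.5

    @property
    def n_train(self) -> int:
        return self.x_train.shape[0]


def _center_train_kernel(k: np.ndarray) -> np.ndarray:
    n = k.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    return h @ k @ h


def _center_test_kernel(k_test: np.ndarray, k_train: np.ndarray) -> np.ndarray:
    n = k_train.shape[0]
    ones_n = np.ones((n, n)) / n
    m = k_test.shape[0]
    ones_mn = np.ones((m, n)) / n
    return (k_test - ones_mn @ k_train) @ (np.eye(n) - ones_n)


def kpls_fit(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    sigma: float = 1.0,
    kernel: str = "gaussian",
) -> KPLSModel:
    """Kernel PLS by NIPALS-style extraction with deflation.

    The kernel is double-centered in feature space; per component the score
    vector t is extracted from the deflated kernel and the response, both
    are deflated by the projector (I - t t'), and the dual regression
    coefficients are alpha = U (T' K U)^-1 T' y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if n_components >= n:
        raise ValueError("n_components must be < n_train")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    k_raw = (x @ x.T) if kernel == "linear" else gaussian_kernel(x, None, sigma)
    kc = _center_train_kernel(k_raw)
    y_mean = y.mean()
    yc = (y - y_mean)[:, None]
    k_def = kc.copy()
    y_def = yc.copy()
    t_list, u_list = [], []
    for _ in range(n_components):
        u = y_def[:, 0:1]
        norm_u = np.linalg.norm(u)
        if norm_u < 1e-12:
            break
        t = k_def @ u
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            break
        t = t / nt
        c = y_def.T @ t
        u = y_def @ c
        nu = np.linalg.norm(u)
        if nu > 1e-12:
            u = u / nu
        t_list.append(t[:, 0])
        u_list.append(u[:, 0])
        proj = np.eye(n) - t @ t.T
        k_def = proj @ k_def @ proj
        y_def = y_def - t @ (t.T @ y_def)
    t_mat = np.array(t_list).T
    u_mat = np.array(u_list).T
    core = t_mat.T @ kc @ u_mat
    alpha = u_mat @ np.linalg.solve(core, t_mat.T @ yc)
    return KPLSModel(sigma, t_mat.shape[1], x, t_mat, u_mat, k_raw,
                     float(y_mean), alpha[:, 0])


def kpls_predict(model: KPLSModel, x_test: np.ndarray,
                 kernel: str = "gaussian") -> np.ndarray:
    """Continuous scores for test samples (same centering as training)."""
    x_test = np.asarray(x_test, dtype=float)
    if kernel == "linear":
        k_test = x_test @ model.x_train.T
    else:
        k_test = gaussian_kernel(x_test, model.x_train, model.sigma)
    kt = _center_test_kernel(k_test, model.k_train)
    return kt @ model.alpha + model.y_mean


def kpls_fitted(model: KPLSModel) -> np.ndarray:
    """Training-sample scores of a fitted KPLS model."""
    kc = _center_train_kernel(model.k_train)
    return kc @ model.alpha + model.y_mean


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GAResult:
    sigma: float
    n_components: int
    fitness: float
    history: list[float] = field(default_factory=list)


def _cv_auc(x, y, sigma, n_components, n_folds=5, seed=0) -> float:
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=seed % (2**31))
    aucs = []
    for tr, te in skf.split(x, y):
        if len(np.unique(y[tr])) < 2:
            return 0.0
        c = min(n_components, len(tr) - 1)
        try:
            m = kpls_fit(x[tr], y[tr], c, sigma)
            s = kpls_predict(m, x[te])
        except Exception:
            return 0.0
        aucs.append(rank_auc(y[te], s))
    return float(np.mean(aucs))


def ga_optimize(
    x: np.ndarray,
    y: np.ndarray,
    log_sigma_range: tuple[float, float] = (-2.0, 4.0),
    c_range: tuple[int, int] = (1, 15),
    population: int = 20,
    generations: int = 50,
    seed: int = 20240101,
    tournament: int = 3,
    p_crossover: float = 0.7,
    p_mutation: float = 0.3,
    optimize_components: bool = True,
    n_folds: int = 5,
) -> GAResult:
    """Generational GA over (log sigma, n_components).

    Tournament selection, uniform crossover, Gaussian mutation on log
    sigma and integer random-walk mutation on the component count; the
    fitness of an individual is its mean ``n_folds``-fold cross-validated
    AUC on the training data.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    lo, hi = log_sigma_range
    c_lo, c_hi = c_range
    c_hi = min(c_hi, x.shape[0] - 2)

    def random_ind():
        c = int(rng.integers(c_lo, c_hi + 1)) if optimize_components \
            else (c_lo + c_hi) // 2
        return [rng.uniform(lo, hi), c]

    def fitness(ind):
        return _cv_auc(x, y, float(np.exp(ind[0])), int(ind[1]),
                       n_folds=n_folds, seed=seed)

    pop = [random_ind() for _ in range(population)]
    fits = [fitness(ind) for ind in pop]
    best_idx = int(np.argmax(fits))
    best, best_fit = list(pop[best_idx]), fits[best_idx]
    history = [best_fit]
    if population == 1:
        return GAResult(float(np.exp(best[0])), int(best[1]), best_fit, history)
    for _ in range(generations):
        new_pop = [list(best)]  # elitism
        while len(new_pop) < population:
            contenders = rng.integers(0, population, tournament)
            p1 = pop[contenders[np.argmax([fits[i] for i in contenders])]]
            contenders = rng.integers(0, population, tournament)
            p2 = pop[contenders[np.argmax([fits[i] for i in contenders])]]
            child = list(p1)
            if rng.random() < p_crossover:
                child = [p1[j] if rng.random() < 0.5 else p2[j]
                         for j in range(2)]
            if rng.random() < p_mutation:
                child[0] = float(np.clip(child[0] + rng.normal(0, 0.5),
                                         lo, hi))
            if optimize_components and rng.random() < p_mutation:
                child[1] = int(np.clip(child[1] + rng.integers(-2, 3),
                                       c_lo, c_hi))
            new_pop.append(child)
        pop = new_pop
        fits = [fitness(ind) for ind in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = list(pop[gen_best]), fits[gen_best]
        history.append(best_fit)
    return GAResult(float(np.exp(best[0])), int(best[1]), best_fit, history)


# ---------------------------------------------------------------------------
# comparator classifiers

COMPARATORS = ("random_forest", "l1_logistic", "knn", "naive_bayes")


def comparator_fit_predict(
    method: str,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    seed: int = 0,
    knn_k: int = 1,
) -> np.ndarray:
    """Fit one comparator and return continuous test scores.

    Contracts: ``l1_logistic`` follows a 100-value L1 path with tenfold CV;
    ``random_forest`` uses 500 trees with sqrt(p) features per split;
    ``knn`` is a k=1 majority vote; ``naive_bayes`` uses Gaussian
    class-conditional densities.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    rs = seed % (2**31)
    if method == "random_forest":
        clf = RandomForestClassifier(n_estimators=500, max_features="sqrt",
                                     random_state=rs)
    elif method == "l1_logistic":
        cv = min(10, int(np.bincount(y_train.astype(int)).min()))
        clf = LogisticRegressionCV(penalty="l1", solver="liblinear", Cs=100,
                                   cv=max(cv, 2), scoring="neg_log_loss",
                                   max_iter=2000, random_state=rs)
    elif method == "knn":
        clf = KNeighborsClassifier(n_neighbors=knn_k)
    elif method == "naive_bayes":
        clf = GaussianNB()
    else:
        raise ValueError(f"unknown comparator: {method}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(x_train, y_train)
    return clf.predict_proba(x_test)[:, 1]


# ---------------------------------------------------------------------------
# metrics


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties get 0.5 credit."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return 0.5
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ClassifierReport:
    """Confusion counts, score vector, and the eight derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    metrics: dict
    flags: list[str] = field(default_factory=list)


def compute_metrics(y_true, scores, threshold: float = 0.5) -> ClassifierReport:
    """Eight-metric battery from scores thresholded at ``threshold``.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), ACC, Youden = Se+Sp-1,
    F = 2*Prec*Se/(Prec+Se), G-means = sqrt(Se*Sp),
    MCC = (TP*TN - FP*FN)/sqrt(...), AUC by the rank formulation.
    Undefined denominators yield 0 with a flag.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    se = ratio(tp, tp + fn, "se")
    sp = ratio(tn, tn + fp, "sp")
    acc = (tp + tn) / max(len(y_true), 1)
    prec = ratio(tp, tp + fp, "precision")
    f = ratio(2 * prec * se, prec + se, "f_measure")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ratio(tp * tn - fp * fn, np.sqrt(denom) if denom else 0, "mcc")
    report = ClassifierReport(tp, fp, fn, tn, {
        "auc": rank_auc(y_true, scores),
        "se": se,
        "sp": sp,
        "acc": acc,
        "youden": se + sp - 1.0,
        "f_measure": f,
        "mcc": mcc,
        "g_means": float(np.sqrt(max(se * sp, 0.0))),
    }, flags)
    return report


def _sigmoid_calibrate(scores_train, y_train, scores_test) -> np.ndarray:
    """Logistic (Platt) calibration of continuous KPLS outputs to [0,1]."""
    lr = LogisticRegression(max_iter=1000)
    lr.fit(np.asarray(scores_train).reshape(-1, 1), y_train)
    return lr.predict_proba(np.asarray(scores_test).reshape(-1, 1))[:, 1]


# ---------------------------------------------------------------------------
# resampling and model comparison


def resample_evaluate(
    x: np.ndarray,
    y: np.ndarray,
    models: dict,
    n_iter: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 20240101,
) -> dict[str, pd.DataFrame]:
    """Stratified repeated-split evaluation of several models.

    ``models`` maps a name to a callable
    ``(x_tr, y_tr, x_te, seed) -> test scores``; per iteration each model
    is refitted on the training 80% and scored on the held-out 20%, and
    the eight metrics are recorded.  Failed iterations are redrawn.
    Returns name -> (n_iter x metrics) DataFrame.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    results: dict[str, list] = {name: [] for name in models}
    splitter = StratifiedShuffleSplit(n_splits=4 * n_iter,
                                      train_size=train_fraction,
                                      random_state=seed % (2**31))
    done = 0
    for tr, te in splitter.split(x, y):
        if done >= n_iter:
            break
        iter_rows = {}
        try:
            for name, fn in models.items():
                scores = fn(x[tr], y[tr], x[te], seed + done)
                iter_rows[name] = compute_metrics(y[te], scores).metrics
        except Exception as exc:
            logger.info("resample_evaluate: iteration redrawn (%s)", exc)
            continue
        for name, met in iter_rows.items():
            results[name].append(met)
        done += 1
    if done < n_iter:
        logger.warning("resample_evaluate: only %d/%d iterations", done, n_iter)
    return {name: pd.DataFrame(rows) for name, rows in results.items()}


def dunnett_compare(
    metric_distributions: dict[str, np.ndarray],
    reference: str = "GA-KPLS",
) -> pd.DataFrame:
    """One-way ANOVA + Dunnett many-to-one comparison against a reference.

    Returns per comparison the mean difference (model - reference) and the
    multiplicity-adjusted p-value; the ANOVA F and p are attached as
    DataFrame attrs.
    """
    if reference not in metric_distributions:
        raise ValueError(f"reference {reference!r} missing")
    names = [n for n in metric_distributions if n != reference]
    groups = [np.asarray(metric_distributions[n], dtype=float) for n in names]
    ref = np.asarray(metric_distributions[reference], dtype=float)
    if all(np.ptp(g) == 0 for g in groups + [ref]):
        raise ValueError("zero residual variance: all groups constant")
    f_stat, f_p = stats.f_oneway(ref, *groups)
    res = stats.dunnett(*groups, control=ref)
    out = pd.DataFrame({
        "mean_difference": [g.mean() - ref.mean() for g in groups],
        "statistic": res.statistic,
        "p_adjusted": res.pvalue,
    }, index=names)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    return out


# ---------------------------------------------------------------------------
# Model / Results interface


class IDHClassifierModel:
    """GA-KPLS genotype classifier with comparator models.

    Parameters
    ----------
    x : ndarray (n, p)
        Stability-selected radiomic features.
    y : ndarray (n,)
        Binary genotype (1 = mutant).
    """

    def __init__(self, x: np.ndarray, y: np.ndarray,
                 comparators: tuple[str, ...] = COMPARATORS):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.comparators = comparators

    def fit(
        self,
        n_iter: int = 1000,
        seed: int = 20240101,
        ga_population: int = 20,
        ga_generations: int = 50,
        optimize_components: bool = True,
    ) -> "IDHClassifierResults":
        """GA-tune the kernel once on the full data, then resample."""
        ga = ga_optimize(self.x, self.y, population=ga_population,
                         generations=ga_generations, seed=seed,
                         optimize_components=optimize_components)

        def gakpls(x_tr, y_tr, x_te, s):
            m = kpls_fit(x_tr, y_tr,
                         min(ga.n_components, x_tr.shape[0] - 1), ga.sigma)
            raw_te = kpls_predict(m, x_te)
            raw_tr = kpls_fitted(m)
            return _sigmoid_calibrate(raw_tr, y_tr, raw_te)

        models = {"GA-KPLS": gakpls}
        for name in self.comparators:
            models[name] = (
                lambda x_tr, y_tr, x_te, s, _m=name:
                comparator_fit_predict(_m, x_tr, y_tr, x_te, seed=s))
        dists = resample_evaluate(self.x, self.y, models, n_iter=n_iter,
                                  seed=seed)
        return IDHClassifierResults(self, ga, dists)


@dataclass
class IDHClassifierResults:
    model: IDHClassifierModel
    ga: GAResult
    distributions: dict[str, pd.DataFrame]

    def metric_table(self) -> pd.DataFrame:
        """Mean of each metric over resampling iterations, per model."""
        return pd.DataFrame({name: df.mean() for name, df
                             in self.distributions.items()}).T

    def dunnett(self, metric: str = "auc") -> pd.DataFrame:
        return dunnett_compare(
            {n: df[metric].to_numpy() for n, df in self.distributions.items()},
            reference="GA-KPLS")

    def representative_split(self, metric: str = "mcc") -> tuple[int, float]:
        """Iteration whose GA-KPLS metric is closest to the resampling mean."""
        vals = self.distributions["GA-KPLS"][metric].to_numpy()
        idx = int(np.argmin(np.abs(vals - vals.mean())))
        return idx, float(vals[idx])

    def summary(self) -> str:
        tab = self.metric_table()
        lines = [
            "IDH genotype prediction (GA-KPLS vs comparators)",
            "=" * 50,
            f"n = {len(self.model.y)}, positives = {int(self.model.y.sum())}",
            f"GA optimum: sigma = {self.ga.sigma:.4g}, "
            f"components = {self.ga.n_components}, "
            f"CV AUC = {self.ga.fitness:.3f}",
            "",
            tab.round(3).to_string(),
        ]
        try:
            dn = self.dunnett("auc")
            lines += ["", "Dunnett vs GA-KPLS (AUC): ",
                      dn.round(4).to_string()]
        except ValueError:
            pass
        return "\n".join(lines)
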