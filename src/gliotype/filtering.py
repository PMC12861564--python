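"""Feature-reduction procedures.

Three screens used at different stages of the subtyping analysis:

* coefficient-of-variation filter (unsupervised, per modality, applied to
  the raw loaded values before any standardization);
* Kruskal-Wallis H screen across subtypes with Benjamini-Hochberg FDR;
* stability selection by L1-penalized logistic regression over repeated
  stratified splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedShuffleSplit
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable


@dataclass
class CVFilterReport:
    table: pd.DataFrame  # feature, cv_percent, retained

    @property
    def retained(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "feature"])


def cv_filter(
    table: FeatureTable, cutoff_percent: float = 30.0
) -> tuple[FeatureTable, CVFilterReport]:
    """Drop features whose coefficient of variation is below the cutoff.

    CV = 100 * sample SD / |mean|.  A zero mean with positive SD is treated
    as infinite CV (retained); a constant feature has CV 0 (removed for any
    positive cutoff).
    """
    x = table.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / np.abs(mean)
    cv = np.where((mean == 0) & (sd > 0), np.inf, cv)
    cv = np.where(sd == 0, 0.0, cv)
    keep = cv >= cutoff_percent
    report = CVFilterReport(pd.DataFrame({
        "feature": table.feature_names,
        "cv_percent": cv,
        "retained": keep,
    }))
    kept = [f for f, k in zip(table.feature_names, keep) if k]
    return table.select_features(kept), report


def kruskal_wallis_screen(
    table: FeatureTable,
    labels: np.ndarray,
    fdr_level: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature Kruskal-Wallis H across subtype groups, BH-adjusted.

    Returns the selected feature names (q < fdr_level) and a report frame
    with tie-corrected H, raw p, and BH q per feature.  A feature constant
    across all samples gets H = 0, p = 1.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    x = table.values
    h = np.zeros(x.shape[1])
    p = np.ones(x.shape[1])
    masks = [labels == g for g in groups]
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            continue
        h[j], p[j] = stats.kruskal(*(col[m] for m in masks))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    report = pd.DataFrame({
        "feature": table.feature_names,
        "H": h,
        "p": p,
        "q": q,
    })
    selected = list(report.loc[report["q"] < fdr_level, "feature"])
    return selected, report


def stability_select(
    table: FeatureTable,
    binary_labels: np.ndarray,
    n_splits: int = 100,
    train_fraction: float = 0.8,
    freq_threshold: float = 0.10,
    seed: int = 20240101,
    cv_folds: int = 5,
) -> tuple[list[str], pd.Series]:
    """Stability selection: L1 logistic over repeated stratified splits.

    For each split, an L1-penalized logistic regression is fitted on the
    training fraction with the penalty chosen by ``cv_folds``-fold
    cross-validated deviance; a feature counts as selected in that split if
    its coefficient is nonzero.  Features selected in at least
    ``freq_threshold`` of the splits form the final candidate set.
    """
    y = np.asarray(binary_labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("stability selection needs exactly two classes")
    if counts.min() < 5:
        raise ValueError("each class needs at least 5 samples")
    x = table.standardized().values
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=seed % (2**31)
    )
    hits = np.zeros(x.shape[1])
    for train_idx, _ in splitter.split(x, y):
        model = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=10, cv=cv_folds,
            scoring="neg_log_loss", max_iter=2000,
            random_state=seed % (2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(x[train_idx], y[train_idx])
        hits += (np.abs(model.coef_[0]) > 1e-10).astype(float)
    freq = pd.Series(hits / n_splits, index=table.feature_names,
                     name="selection_frequency")
    selected = list(freq.index[freq >= freq_threshold])
    return selected, freq
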