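"""Choosing the number of subtypes.

The working criterion is the sum of the Clustering Prediction Index (CPI)
and the Gap statistic, maximized over a candidate range (default 2-8);
Davies-Bouldin and Calinski-Harabasz act as confirmatory indices.

CPI is a held-out criterion: the full hMKL pipeline is refitted on a
training split, held-out samples are placed into the training spectral
embedding by a Nystrom-style similarity projection, and CPI(k) is one
minus the held-out within-cluster sum of squares over the held-out total
sum of squares, averaged over repeats.  The Gap statistic follows
Tibshirani's formulation with a uniform range-box reference on the
concatenated standardized features, with K-means providing the dispersion
in both the observed and reference arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .hmkl import (
    adaptive_gaussian_kernel,
    hmkl_pipeline,
)
from .io import FeatureTable, RunConfig

logger = logging.getLogger("gliotype")


def _concat_standardized(tables: list[FeatureTable]) -> np.ndarray:
    return np.hstack([t.standardized().values for t in tables])


def _cross_similarity(
    x_train: np.ndarray,
    x_test: np.ndarray,
    kernel_weights: np.ndarray,
    config: RunConfig,
    top_k: int = 20,
) -> np.ndarray:
    """Weighted adaptive-Gaussian cross-kernel (test x train).

    Reuses the kernel-grid weights learned in stage 1, then keeps only each
    test sample's ``top_k`` strongest training neighbors: the dense kernel
    is dominated by noise directions, while the sparsified one carries the
    neighborhood structure the similarity learning identified.
    """
    joint = np.vstack([x_train, x_test])
    n_tr = x_train.shape[0]
    cross = np.zeros((x_test.shape[0], n_tr))
    li = 0
    for k_nn in config.knn_grid:
        for sigma in config.sigma_grid:
            k_full = adaptive_gaussian_kernel(
                joint, sigma, min(k_nn, joint.shape[0] - 1))
            cross += kernel_weights[li] * k_full[n_tr:, :n_tr]
            li += 1
    top_k = min(top_k, n_tr)
    thr = np.sort(cross, axis=1)[:, -top_k][:, None]
    return np.where(cross >= thr, cross, 0.0)


def cpi(
    tables: list[FeatureTable],
    k_range,
    n_repeats: int = 20,
    test_fraction: float = 0.3,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Clustering Prediction Index per k (higher = better).

    Per repeat, the hMKL pipeline is fitted on the training part; each
    held-out sample is projected into the training spectral embedding via
    its row-normalized cross-similarity to training samples and assigned
    to the nearest training-cluster centroid.  A repeat whose training
    clustering leaves an empty cluster is discarded and redrawn.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = tables[0].n_samples
    k_range = list(k_range)
    if max(k_range) > n // 3:
        raise ValueError("k_range must stay within [2, n/3]")
    values = {k: [] for k in k_range}
    n_test = max(1, int(round(test_fraction * n)))
    for k in k_range:
        done, attempts = 0, 0
        while done < n_repeats and attempts < 4 * n_repeats:
            attempts += 1
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            train_tabs = [t.select_samples([t.sample_ids[i] for i in train_idx])
                          for t in tables]
            try:
                fit = hmkl_pipeline(train_tabs, k, config, n_restarts=10)
            except Exception as exc:  # degenerate split
                logger.info("cpi: repeat discarded (%s)", exc)
                continue
            labels = fit.assignment.labels
            emb_train = fit.fused.embedding
            if len(np.unique(labels)) < k and np.ptp(emb_train) > 1e-9:
                logger.info("cpi: empty training cluster at k=%d, redrawn", k)
                continue
            # project held-out samples into the training embedding
            cross = np.zeros((n_test, len(train_idx)))
            for m, (t, beta) in enumerate(zip(tables,
                                              fit.fused.modality_weights)):
                z = t.standardized().values
                c = _cross_similarity(z[train_idx], z[test_idx],
                                      fit.stage1[m].kernel_weights, config)
                cross += beta * c
            row_sum = cross.sum(axis=1, keepdims=True)
            cross = cross / np.maximum(row_sum, 1e-12)
            emb_test = cross @ emb_train
            # the training embedding rows live on the unit sphere; put the
            # projected test rows back on it so dispersions are comparable
            norms = np.linalg.norm(emb_test, axis=1, keepdims=True)
            emb_test = emb_test / np.maximum(norms, 1e-12)
            centroids = np.vstack([
                emb_train[labels == c].mean(axis=0)
                for c in np.unique(labels)
            ])
            d2 = ((emb_test[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
            wss = d2.min(axis=1).sum()
            tss = ((emb_test - emb_test.mean(axis=0)) ** 2).sum()
            values[k].append(1.0 if tss <= 1e-15 else 1.0 - wss / tss)
            done += 1
        if done < n_repeats:
            logger.warning("cpi: only %d/%d valid repeats at k=%d",
                           done, n_repeats, k)
    return pd.Series({k: float(np.mean(v)) for k, v in values.items()},
                     name="CPI")


def gap_statistic(
    tables: list[FeatureTable] | np.ndarray,
    k_range,
    n_refs: int = 50,
    seed: int = 20240101,
    n_init: int = 10,
    observed_labels: dict | None = None,
) -> pd.DataFrame:
    """Gap(k) and its Monte-Carlo standard error per k.

    Gap(k) = mean_b log WSS_ref,b(k) - log WSS_obs(k), with the reference
    draws uniform over the per-feature range box of the concatenated
    standardized features; SE includes the sqrt(1 + 1/B) inflation.

    ``observed_labels`` maps k to the clustering under evaluation (e.g. the
    hMKL assignment); its within-cluster dispersion then provides the
    observed arm.  Without it, K-means supplies both arms.  Using the
    pipeline's own labels matters when many noise features are present:
    K-means keeps harvesting noise variance past the true k, inflating the
    observed-arm drop, whereas a forced extra split of a genuine cluster
    barely reduces dispersion — so the Gap then declines past the true k
    as it should.
    """
    x = (tables if isinstance(tables, np.ndarray)
         else _concat_standardized(list(tables)))
    rng = np.random.default_rng(seed)
    k_range = list(k_range)
    lo, hi = x.min(axis=0), x.max(axis=0)
    refs = [rng.uniform(lo, hi, size=x.shape) for _ in range(n_refs)]

    def _wss(data, labels):
        return sum(((data[labels == c] - data[labels == c].mean(0)) ** 2
                    ).sum() for c in np.unique(labels))

    rows = []
    for k in k_range:
        if observed_labels is not None:
            obs = _wss(x, np.asarray(observed_labels[k]))
        else:
            km = KMeans(k, n_init=n_init, random_state=seed % (2**31))
            obs = km.fit(x).inertia_
        log_obs = np.log(max(obs, 1e-300))
        log_refs = np.array([
            np.log(max(KMeans(k, n_init=n_init,
                              random_state=(seed + b + 1) % (2**31)
                              ).fit(r).inertia_, 1e-300))
            for b, r in enumerate(refs)
        ])
        gap = log_refs.mean() - log_obs
        se = log_refs.std(ddof=1) * np.sqrt(1.0 + 1.0 / n_refs)
        rows.append((k, gap, se))
    return pd.DataFrame(rows, columns=["k", "gap", "se"]).set_index("k")


def select_k(cpi_values: pd.Series, gap_values: pd.Series) -> int:
    """k* = argmax_k CPI(k) + Gap(k); ties break toward smaller k."""
    cpi_values = pd.Series(cpi_values)
    gap_values = pd.Series(gap_values)
    if list(cpi_values.index) != list(gap_values.index):
        raise ValueError("CPI and Gap must cover the same k range")
    total = cpi_values + gap_values
    best = total.max()
    return int(min(k for k in total.index if total[k] >= best - 1e-12))


def dbi(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index (lower = better)."""
    _check_partition(features, labels)
    return float(davies_bouldin_score(features, labels))


def ch_index(features: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index (higher = better)."""
    _check_partition(features, labels)
    return float(calinski_harabasz_score(features, labels))


def _check_partition(features: np.ndarray, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two nonempty clusters")
    if np.all(counts == 1):
        raise ValueError("singleton-only clustering is degenerate")


@dataclass
class KSelectionReport:
    table: pd.DataFrame
    k_star: int


def select_k_report(
    tables: list[FeatureTable],
    k_range,
    config: RunConfig | None = None,
    n_repeats: int = 20,
    n_refs: int = 50,
    compute_confirmatory: bool = True,
) -> KSelectionReport:
    """CPI, Gap, their sum, and confirmatory DBI/CH over the k range.

    The full-data hMKL assignment at each candidate k provides the
    observed arm of the Gap statistic and the partitions scored by the
    confirmatory indices.
    """
    config = config or RunConfig()
    k_range = list(k_range)
    labels_by_k = {
        k: hmkl_pipeline(tables, k, config, n_restarts=10).assignment.labels
        for k in k_range
    }
    cpi_vals = cpi(tables, k_range, n_repeats=n_repeats, config=config)
    gap_df = gap_statistic(tables, k_range, n_refs=n_refs, seed=config.seed,
                           observed_labels=labels_by_k)
    k_star = select_k(cpi_vals, gap_df["gap"])
    rows = {
        "k": k_range,
        "CPI": [cpi_vals[k] for k in k_range],
        "gap": [gap_df.loc[k, "gap"] for k in k_range],
        "gap_se": [gap_df.loc[k, "se"] for k in k_range],
        "CPI_plus_gap": [cpi_vals[k] + gap_df.loc[k, "gap"] for k in k_range],
    }
    if compute_confirmatory:
        x = _concat_standardized(tables)
        dbis, chs = [], []
        for k in k_range:
            labels = labels_by_k[k]
            if len(np.unique(labels)) < 2:
                dbis.append(np.nan)
                chs.append(np.nan)
            else:
                dbis.append(dbi(x, labels))
                chs.append(ch_index(x, labels))
        rows["DBI"] = dbis
        rows["CH"] = chs
    return KSelectionReport(pd.DataFrame(rows), k_star)
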