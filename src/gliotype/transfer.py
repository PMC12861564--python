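"""Subtype transfer to an external cohort via Similarity Network Fusion.

The training cohort's subtype labels are propagated to new samples by
building joint (train + test) affinity networks per modality, fusing them
with the published SNF cross-diffusion, and iterating label propagation
with the training rows clamped until convergence.
"""

from __future__ import annotations

import logging

import numpy as np

from .hmkl import adaptive_gaussian_kernel
from .io import FeatureTable

logger = logging.getLogger("gliotype")

SNF_SIGMA = 0.5
SNF_K = 20
SNF_T = 20


def snf_affinity(x: np.ndarray, sigma: float = SNF_SIGMA,
                 k_neighbors: int = SNF_K) -> np.ndarray:
    """Neighborhood-adaptive Gaussian affinity used for SNF views."""
    return adaptive_gaussian_kernel(x, sigma, k_neighbors)


def _full_transition(w: np.ndarray) -> np.ndarray:
    """Full transition matrix: off-diagonal mass 1/2, diagonal 1/2."""
    n = w.shape[0]
    off = w - np.diag(np.diag(w))
    row = off.sum(axis=1, keepdims=True)
    p = np.where(row > 0, off / (2.0 * row), 0.0)
    p[np.arange(n), np.arange(n)] = 0.5
    # rows with no off-diagonal mass keep all mass on the diagonal
    zero = (row[:, 0] == 0)
    p[zero, :] = 0.0
    p[zero, zero] = 1.0
    return p


def _local_transition(w: np.ndarray, k_neighbors: int) -> np.ndarray:
    """k-NN-sparsified, row-normalized transition matrix."""
    n = w.shape[0]
    masked = w - np.diag(np.diag(w))
    order = np.argsort(masked, axis=1)
    s = np.zeros_like(w)
    rows = np.arange(n)[:, None]
    top = order[:, -k_neighbors:]
    s[rows, top] = masked[rows, top]
    row = s.sum(axis=1, keepdims=True)
    return np.where(row > 0, s / row, 0.0)


def snf_fuse(
    affinities: list[np.ndarray],
    k_neighbors: int = SNF_K,
    t_iterations: int = SNF_T,
) -> np.ndarray:
    """Published SNF cross-diffusion of per-view affinity networks.

    Each view's full transition matrix is iteratively updated through the
    average of the other views' statuses, carried by its own k-NN local
    transition matrix; the fused network is the symmetrized average after
    ``t_iterations`` rounds.
    """
    if len(affinities) < 2:
        raise ValueError("SNF needs at least two affinity matrices")
    n = affinities[0].shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < n")
    for a in affinities:
        if a.shape != (n, n):
            raise ValueError("all affinities must share the same sample order")
    p_full = [_full_transition(a) for a in affinities]
    p_loc = [_local_transition(a, k_neighbors) for a in affinities]
    m = len(affinities)
    for _ in range(t_iterations):
        new = []
        for v in range(m):
            others = sum(p_full[u] for u in range(m) if u != v) / (m - 1)
            p = p_loc[v] @ others @ p_loc[v].T
            new.append(_full_transition((p + p.T) / 2.0))
        p_full = new
    fused = sum(p_full) / m
    fused = (fused + fused.T) / 2.0
    # small self-regularization as in the published implementation
    fused = fused + np.eye(n) * fused.max()
    return (fused + fused.T) / 2.0


def propagate_labels(
    fused: np.ndarray,
    train_mask: np.ndarray,
    train_labels: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Clamped label propagation Y <- P Y on the fused network.

    Returns (labels for all samples, class-score matrix).  Training rows
    are clamped to their one-hot labels at every step; convergence is
    max-norm change below ``tol``.
    """
    classes = np.unique(train_labels)
    n = fused.shape[0]
    p = fused / fused.sum(axis=1, keepdims=True)
    y = np.zeros((n, len(classes)))
    for j, c in enumerate(classes):
        y[train_mask, j] = (train_labels == c).astype(float)
    for it in range(max_iter):
        y_new = p @ y
        y_new[train_mask] = y[train_mask]
        delta = np.abs(y_new - y).max()
        y = y_new
        if delta < tol:
            logger.info("propagate_labels: converged in %d iterations", it + 1)
            break
    else:
        logger.warning("propagate_labels: no convergence in %d iterations",
                       max_iter)
    labels = classes[np.argmax(y, axis=1)]
    return labels, y


def group_predict(
    train_tables: list[FeatureTable],
    train_labels: np.ndarray,
    test_tables: list[FeatureTable],
    k_neighbors: int = SNF_K,
    t_iterations: int = SNF_T,
) -> np.ndarray:
    """Predict test-cohort subtype labels by SNF label propagation.

    Features are matched to the intersection of each modality's columns,
    z-scored per cohort (train and test separately), stacked, fused across
    modalities with SNF, and the training labels are propagated to the
    test rows.  Returns one label per test sample, in test order.
    """
    if len(train_tables) != len(test_tables):
        raise ValueError("need matching modality lists")
    train_labels = np.asarray(train_labels)
    n_train = train_tables[0].n_samples
    n_test = test_tables[0].n_samples
    if len(train_labels) != n_train:
        raise ValueError("one training label per training sample required")
    affinities = []
    for tr, te in zip(train_tables, test_tables):
        common = [f for f in tr.feature_names if f in set(te.feature_names)]
        if not common:
            raise ValueError(
                f"no shared features between cohorts for {tr.modality}")
        z = np.vstack([
            tr.select_features(common).standardized().values,
            te.select_features(common).standardized().values,
        ])
        affinities.append(
            snf_affinity(z, k_neighbors=min(k_neighbors, z.shape[0] - 1)))
    if len(affinities) == 1:
        fused = affinities[0] + np.eye(n_train + n_test) * affinities[0].max()
    else:
        fused = snf_fuse(affinities, k_neighbors=min(k_neighbors,
                                                     n_train + n_test - 1),
                         t_iterations=t_iterations)
    mask = np.zeros(n_train + n_test, dtype=bool)
    mask[:n_train] = True
    labels, _ = propagate_labels(fused, mask, train_labels)
    return labels[n_train:]
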