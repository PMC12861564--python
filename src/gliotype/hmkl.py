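"""Hierarchical multi-kernel learning (hMKL) for multimodal subtyping.

Stage 1 learns, per modality, a sparse sample-similarity matrix from a bank
of neighborhood-adaptive Gaussian kernels by alternating minimization of a
CIMLR-type objective: a weighted-kernel fit of the similarity with an
entrywise l2 penalty, a rank-k term through the bottom-k eigenvectors of
the similarity's graph Laplacian, and entropy-regularized kernel weights.
Stage 2 fuses the per-modality similarities with consensus (STATIS-type)
weights from the leading eigenvector of their pairwise inner-product
matrix.  Subtypes come from K-means on the normalized spectral embedding of
the fused similarity.

The ``SubtypeModel`` / ``SubtypeResults`` pair wraps the three stages in a
fit-once interface; the stage functions remain usable on their own.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .io import FeatureTable, RunConfig

logger = logging.getLogger("gliotype")

DEFAULT_SIGMA_GRID = (1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5)
DEFAULT_KNN_GRID = (10, 15, 20, 25, 30)


# ---------------------------------------------------------------------------
# kernels


def adaptive_gaussian_kernel(
    x: np.ndarray, sigma: float, k_neighbors: int
) -> np.ndarray:
    """Neighborhood-adaptive Gaussian kernel.

    K(i,j) = exp(-d(i,j)^2 / (2 eps_ij^2)) with eps_ij = sigma *
    (mu_ik + mu_jk) / 2, where mu_ik is sample i's mean Euclidean distance
    to its k nearest neighbors (self excluded, distance ties broken by
    sample order).  Result is symmetrized as (K + K.T) / 2.
    """
    n = x.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n={n}")
    d = squareform(pdist(x))
    # k smallest distances excluding self (diagonal is 0)
    sorted_d = np.sort(d, axis=1)[:, 1:k_neighbors + 1]
    mu = sorted_d.mean(axis=1)
    eps = sigma * (mu[:, None] + mu[None, :]) / 2.0
    eps = np.maximum(eps, 1e-12)
    kmat = np.exp(-(d ** 2) / (2.0 * eps ** 2))
    return (kmat + kmat.T) / 2.0


@dataclass
class KernelBank:
    """Bank of adaptive Gaussian kernels for one modality."""

    modality: str
    kernels: list[np.ndarray]
    params: list[tuple[float, int]]  # (sigma multiplier, k neighbors)
    weights: np.ndarray | None = None

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)


def build_kernel_bank(
    table: FeatureTable,
    sigma_grid=DEFAULT_SIGMA_GRID,
    knn_grid=DEFAULT_KNN_GRID,
    standardize: bool = True,
) -> KernelBank:
    """Construct the (sigma x k) kernel grid on per-feature z-scores."""
    if not len(sigma_grid) or not len(knn_grid):
        raise ValueError("kernel grids must be nonempty")
    x = table.standardized().values if standardize else table.values
    kernels, params = [], []
    for k_nn in knn_grid:
        for sigma in sigma_grid:
            kernels.append(adaptive_gaussian_kernel(x, sigma, k_nn))
            params.append((float(sigma), int(k_nn)))
    return KernelBank(table.modality, kernels, params)


# ---------------------------------------------------------------------------
# stage 1: CIMLR-type similarity learning


def _project_rows_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, m = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, m + 1)
    cond = u - css / ind > 0
    rho = m - np.argmax(cond[:, ::-1], axis=1) - 1  # last true index
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(v - theta[:, None], 0.0)


def _pairwise_sq_dists(l_mat: np.ndarray) -> np.ndarray:
    sq = (l_mat ** 2).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * l_mat @ l_mat.T
    return np.maximum(d, 0.0)


@dataclass
class Stage1Result:
    similarity: np.ndarray           # symmetrized learned similarity
    kernel_weights: np.ndarray       # on the simplex, one per bank kernel
    objective_trace: list[float]
    converged: bool
    embedding: np.ndarray            # bottom-k Laplacian eigenvectors


def cimlr_stage1(
    bank: KernelBank,
    k: int,
    beta: float = 0.2,
    gamma: float | None = None,
    rho: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> Stage1Result:
    """Learn one modality's similarity by alternating exact minimization.

    Objective (rows of S constrained to the probability simplex, L with
    orthonormal columns):

        J(S, w, L) = sum_ij [ beta*S_ij^2 - W_ij*S_ij + (gamma/2)*D_ij*S_ij ]
                     + rho*n * sum_l w_l log w_l,

    where W = sum_l w_l K_l and D_ij = ||L_i - L_j||^2.  Each of the three
    block updates is an exact minimizer (simplex projection / eigenvectors /
    softmax), so the objective is non-increasing across iterations.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = bank.kernels[0].shape[0]
    m = bank.n_kernels
    if gamma is None:
        gamma = n / k
    rho_eff = rho * n

    w = np.full(m, 1.0 / m)
    kernel_stack = np.stack(bank.kernels)          # m x n x n
    wmat = np.tensordot(w, kernel_stack, axes=1)

    # initialize L from the average kernel's Laplacian
    p0 = (wmat + wmat.T) / 2.0
    lap0 = np.diag(p0.sum(axis=1)) - p0
    _, vecs = eigh(lap0, subset_by_index=[0, k - 1])
    l_mat = vecs

    def objective(s, w_vec, d_mat, w_kernel):
        fit = beta * (s ** 2).sum() - (w_kernel * s).sum()
        rank = 0.5 * gamma * (d_mat * s).sum()
        ent = rho_eff * float(np.sum(w_vec * np.log(np.maximum(w_vec, 1e-300))))
        return fit + rank + ent

    trace: list[float] = []
    s = None
    for _ in range(max_iter):
        d_mat = _pairwise_sq_dists(l_mat)
        # S-step: exact row-wise quadratic minimization over the simplex
        s = _project_rows_to_simplex((wmat - 0.5 * gamma * d_mat) / (2.0 * beta))
        # L-step: bottom-k eigenvectors of the symmetrized Laplacian
        p = (s + s.T) / 2.0
        lap = np.diag(p.sum(axis=1)) - p
        _, l_mat = eigh(lap, subset_by_index=[0, k - 1])
        # w-step: entropy-regularized exact minimizer (softmax)
        align = np.tensordot(kernel_stack, s, axes=([1, 2], [0, 1]))
        z = align / rho_eff
        z -= z.max()
        w = np.exp(z)
        w /= w.sum()
        wmat = np.tensordot(w, kernel_stack, axes=1)
        d_mat = _pairwise_sq_dists(l_mat)
        trace.append(objective(s, w, d_mat, wmat))
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) <= tol * max(1.0, abs(trace[-2])):
            return Stage1Result((s + s.T) / 2.0, w, trace, True, l_mat)
    logger.warning("cimlr_stage1: no convergence after %d iterations", max_iter)
    return Stage1Result((s + s.T) / 2.0, w, trace, False, l_mat)


# ---------------------------------------------------------------------------
# stage 2: consensus fusion


def rv_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine (RV-type) agreement between two symmetric similarity matrices."""
    num = float((a * b).sum())
    den = float(np.linalg.norm(a) * np.linalg.norm(b))
    return num / den if den > 0 else 0.0


def graph_modularity(s: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of a partition on a weighted similarity graph."""
    total = s.sum()
    if total <= 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        m = labels == c
        q += s[np.ix_(m, m)].sum() / total - (s[m, :].sum() / total) ** 2
    return float(q)


@dataclass
class FusedSimilarity:
    similarity: np.ndarray
    modality_weights: np.ndarray
    rv_matrix: np.ndarray
    qualities: np.ndarray | None = None
    embedding: np.ndarray | None = None


def umkl_fuse(
    similarities: list[np.ndarray],
    k: int | None = None,
    seed: int = 0,
) -> FusedSimilarity:
    """Consensus weighting of per-modality similarities (STATIS-type).

    The modality weights beta are the leading eigenvector — elementwise
    nonnegative by Perron-Frobenius — of ``diag(q) R diag(q)``, normalized
    to the simplex, where R is the matrix of RV coefficients between the
    double-centered similarities and q_m is each modality's own cluster
    quality: the graph modularity of its k-way spectral partition.  With
    two views any pairwise agreement measure is symmetric, so the
    modularity term is what lets a structured modality outweigh a
    structureless one; when ``k`` is None, q = 1 and the weights are the
    plain RV consensus.  The fused matrix is the beta-weighted sum of the
    raw similarities.
    """
    if not similarities:
        raise ValueError("need at least one similarity")
    m = len(similarities)
    if m == 1:
        s = similarities[0]
        return FusedSimilarity(s.copy(), np.array([1.0]), np.array([[1.0]]))
    centered = []
    for s in similarities:
        row = s.mean(axis=1, keepdims=True)
        col = s.mean(axis=0, keepdims=True)
        centered.append(s - row - col + s.mean())
    rv_raw = np.empty((m, m))
    rv_cent = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            rv_raw[i, j] = rv_coefficient(similarities[i], similarities[j])
            rv_cent[i, j] = rv_coefficient(centered[i], centered[j])
    if k is not None:
        q = np.empty(m)
        for i, s in enumerate(similarities):
            emb = spectral_embedding(s, k)
            lab = KMeans(k, n_init=10, random_state=seed % (2**31)).fit_predict(emb)
            q[i] = max(graph_modularity(s, lab), 1e-3)
    else:
        q = np.ones(m)
    gram = np.outer(q, q) * rv_cent
    vals, vecs = eigh(gram)
    beta = np.abs(vecs[:, -1])
    beta = beta / beta.sum()
    fused = sum(b * s for b, s in zip(beta, similarities))
    return FusedSimilarity(fused, beta, rv_raw, q)


# ---------------------------------------------------------------------------
# clustering on the fused similarity


@dataclass
class SubtypeAssignment:
    labels: np.ndarray            # 1..k per sample
    k: int
    sample_ids: list[str] | None = None
    seed: int | None = None
    config_hash: str | None = None


def spectral_embedding(
    s: np.ndarray, k: int, diffuse: bool = True, teleport: float = 0.01
) -> np.ndarray:
    """Top-k eigenvectors of D^-1/2 S D^-1/2, rows scaled to unit norm.

    The learned similarities are sparse (row-simplex projection), so the
    raw graph can fragment within clusters; a two-hop diffusion step
    (P P^T on the row-normalized similarity) smooths intra-cluster
    substructure and a small uniform teleport term keeps the graph
    connected before the eigendecomposition.
    """
    deg = s.sum(axis=1)
    if np.any(deg <= 0):
        raise np.linalg.LinAlgError("degenerate similarity: zero-degree sample")
    if diffuse:
        p = s / deg[:, None]
        s = p @ p.T
        s = (s + s.T) / 2.0
    if teleport > 0:
        s = s + teleport * s.mean() * np.ones_like(s)
    deg = s.sum(axis=1)
    d_inv = 1.0 / np.sqrt(deg)
    sn = d_inv[:, None] * s * d_inv[None, :]
    sn = (sn + sn.T) / 2.0
    _, vecs = eigh(sn, subset_by_index=[s.shape[0] - k, s.shape[0] - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    return vecs / np.maximum(norms, 1e-12)


def cluster_fused(
    fused: FusedSimilarity | np.ndarray,
    k: int,
    seed: int = 20240101,
    n_restarts: int = 100,
    sample_ids: list[str] | None = None,
) -> SubtypeAssignment:
    """K-means (best of ``n_restarts`` inertia) on the spectral embedding."""
    if k < 2:
        raise ValueError("k must be >= 2")
    s = fused.similarity if isinstance(fused, FusedSimilarity) else fused
    emb = spectral_embedding(s, k)
    if isinstance(fused, FusedSimilarity):
        fused.embedding = emb
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**31))
    labels = km.fit_predict(emb) + 1
    return SubtypeAssignment(labels, k, sample_ids, seed)


# ---------------------------------------------------------------------------
# end-to-end pipeline and the Model/Results pair


@dataclass
class HMKLFit:
    assignment: SubtypeAssignment
    fused: FusedSimilarity
    stage1: list[Stage1Result]
    banks: list[KernelBank]


def hmkl_pipeline(
    tables: list[FeatureTable],
    k: int,
    config: RunConfig | None = None,
    n_restarts: int = 100,
) -> HMKLFit:
    """Kernel banks -> per-modality CIMLR -> consensus fusion -> K-means."""
    config = config or RunConfig()
    ids = tables[0].sample_ids
    for t in tables[1:]:
        if t.sample_ids != ids:
            raise ValueError("tables are not aligned; call align_cohort first")
    banks = [
        build_kernel_bank(t, config.sigma_grid, config.knn_grid) for t in tables
    ]
    stage1 = [cimlr_stage1(b, k) for b in banks]
    for b, s1 in zip(banks, stage1):
        b.weights = s1.kernel_weights
    fused = umkl_fuse([s1.similarity for s1 in stage1], k=k, seed=config.seed)
    assignment = cluster_fused(fused, k, seed=config.seed,
                               n_restarts=n_restarts, sample_ids=ids)
    return HMKLFit(assignment, fused, stage1, banks)


class SubtypeModel:
    """Unsupervised multimodal subtyping model.

    Parameters
    ----------
    tables : list of FeatureTable
        Aligned per-modality feature tables (same sample IDs, same order).
    config : RunConfig, optional
        Kernel grids, k-range and seed.

    ``fit(k)`` runs the full hMKL pipeline at a fixed cluster count;
    ``fit()`` first selects k by maximizing CPI + Gap over the configured
    k-range and then fits at the winner.
    """

    def __init__(self, tables: list[FeatureTable],
                 config: RunConfig | None = None):
        self.tables = tables
        self.config = config or RunConfig()

    def fit(self, k: int | None = None, n_restarts: int = 100,
            selection_kwargs: dict | None = None) -> "SubtypeResults":
        selection = None
        if k is None:
            from .cluster_number import select_k_report
            selection = select_k_report(
                self.tables, range(self.config.k_min, self.config.k_max + 1),
                config=self.config, **(selection_kwargs or {}),
            )
            k = selection.k_star
        fit = hmkl_pipeline(self.tables, k, self.config, n_restarts)
        return SubtypeResults(self, fit, selection)


@dataclass
class SubtypeResults:
    """Fitted subtyping: labels, fused similarity, and learned weights."""

    model: SubtypeModel
    fit: HMKLFit
    selection: "object | None" = None

    @property
    def labels_(self) -> np.ndarray:
        return self.fit.assignment.labels

    @property
    def k(self) -> int:
        return self.fit.assignment.k

    @property
    def modality_weights_(self) -> pd.Series:
        return pd.Series(self.fit.fused.modality_weights,
                         index=[t.modality for t in self.model.tables])

    @property
    def fused_similarity_(self) -> np.ndarray:
        return self.fit.fused.similarity

    def label_series(self) -> pd.Series:
        return pd.Series(self.labels_, index=self.model.tables[0].sample_ids,
                         name="subtype")

    def summary(self) -> str:
        lines = [
            "Multimodal subtype model (hMKL)",
            "=" * 38,
            f"samples: {self.model.tables[0].n_samples}"
            f"   modalities: {len(self.model.tables)}   k: {self.k}",
            "cluster sizes: " + ", ".join(
                f"{c}: {int((self.labels_ == c).sum())}"
                for c in range(1, self.k + 1)
            ),
            "modality weights (beta): " + ", ".join(
                f"{m}={b:.3f}" for m, b in self.modality_weights_.items()
            ),
        ]
        if self.selection is not None:
            lines.append(f"k selected by CPI + Gap over "
                         f"{list(self.selection.table['k'])}: "
                         f"k* = {self.selection.k_star}")
        for t, bank, s1 in zip(self.model.tables, self.fit.banks,
                               self.fit.stage1):
            top = np.argsort(s1.kernel_weights)[::-1][:3]
            lines.append(
                f"{t.modality}: converged={s1.converged}, top kernels " +
                ", ".join(f"(sigma={bank.params[i][0]}, "
                          f"k={bank.params[i][1]})" for i in top)
            )
        return "\n".join(lines)


def config_hash(config: RunConfig) -> str:
    payload = repr(sorted(config.to_dict().items())).encode()
    return hashlib.sha1(payload).hexdigest()[:12]
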