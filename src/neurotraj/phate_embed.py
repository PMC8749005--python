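"""Diffusion-potential manifold embedding (PHATE-style), from scratch.

The recipe, stage by stage:

1. pairwise Euclidean distances between time-samples (rows of the response
   matrix, features = regions);
2. alpha-decay kernel with adaptive per-point bandwidth (distance to the
   k-th nearest neighbor), symmetrized:
   ``K_ij = 1/2 exp(-(d_ij/eps_i)^alpha) + 1/2 exp(-(d_ij/eps_j)^alpha)``;
3. row-normalization into a diffusion operator P (random-walk transition
   probabilities);
4. diffusion-time selection at the knee of the von Neumann entropy of the
   operator's spectrum, H(t) over t = 1..t_max;
5. potential distances between t-step diffusion profiles,
   ``U_ij = || log(P^t_i + gamma) - log(P^t_j + gamma) ||_2``;
6. metric MDS (classical-scaling initialization, then SMACOF stress
   majorization) into ``n_dims`` coordinates.

Per-dimension variance fractions and per-region spatial weights (Pearson
correlation of each region's response course with each embedding
coordinate) summarize the embedding.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .containers import ResponseMatrix
from .exceptions import ConfigurationError, ContractError

__all__ = [
    "PhateParams",
    "AffinityMatrix",
    "DiffusionOperator",
    "Embedding",
    "alpha_decay_kernel",
    "diffusion_operator",
    "select_t_vne",
    "potential_distance",
    "metric_mds",
    "variance_explained",
    "spatial_weights",
    "phate",
]

logger = logging.getLogger(__name__)

LOG_FLOOR = 1e-12  # gamma regularizer inside the potential log


@dataclass(frozen=True)
class PhateParams:
    """Embedding hyperparameters (defaults follow the analysis settings:
    alpha-decay 35, k_nn 10, 5 embedding dimensions with the top 3 used for
    trajectories, diffusion time from the VNE knee unless fixed)."""

    n_dims: int = 5
    alpha: float = 35.0
    knn: int = 10
    t: int | str = "auto"
    t_max: int = 100
    mds_max_iter: int = 200
    mds_tol: float = 1e-6
    seed: int = 0

    def validate(self, n_points: int | None = None) -> None:
        if self.alpha <= 0:
            raise ConfigurationError(f"alpha: must be > 0, got {self.alpha}")
        if self.knn < 1:
            raise ConfigurationError(f"knn: must be >= 1, got {self.knn}")
        if n_points is not None and self.knn >= n_points:
            raise ConfigurationError(f"knn: must be < n_points, got {self.knn} >= {n_points}")
        if self.n_dims < 3:
            raise ConfigurationError(f"n_dims: must be >= 3, got {self.n_dims}")
        if self.t != "auto" and (not isinstance(self.t, (int, np.integer)) or self.t < 1):
            raise ConfigurationError(f"t: must be 'auto' or a positive integer, got {self.t!r}")
        if self.t_max < 3:
            raise ConfigurationError(f"t_max: must be >= 3, got {self.t_max}")


@dataclass
class AffinityMatrix:
    K: np.ndarray
    bandwidths: np.ndarray  # eps_k(i): distance to i's knn-th neighbor
    knn: int
    alpha: float


@dataclass
class DiffusionOperator:
    """Row-stochastic diffusion operator with cached spectral decomposition
    of its symmetric conjugate M = D^1/2 P D^-1/2."""

    P: np.ndarray
    eigenvalues: np.ndarray  # of the symmetric conjugate, descending |.|
    eigenvectors: np.ndarray  # orthonormal columns of the conjugate
    row_sums: np.ndarray  # degree vector of K
    t_selected: int | None = None
    vne_curve: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def power(self, t: int) -> np.ndarray:
        """P^t via the cached eigendecomposition."""
        d = self.row_sums
        V = self.eigenvectors
        lam_t = np.sign(self.eigenvalues) ** (t % 2) * np.abs(self.eigenvalues) ** t
        inner = (V * lam_t) @ V.T
        Pt = (inner / np.sqrt(d)[:, None]) * np.sqrt(d)[None, :]
        return np.clip(Pt, 0.0, None)


@dataclass
class Embedding:
    coords: np.ndarray  # n x n_dims, dimensions ordered by variance
    variance_fraction: np.ndarray
    stress: float
    t_selected: int
    params: PhateParams
    spatial_weights: np.ndarray | None = None
    embedding_id: str = ""
    meta: dict = field(default_factory=dict)


def alpha_decay_kernel(X: np.ndarray, knn: int = 10, alpha: float = 35.0) -> AffinityMatrix:
    """Adaptive-bandwidth alpha-decay affinity between the rows of X."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if knn >= n:
        raise ConfigurationError(f"knn: must be < n_points, got {knn} >= {n}")
    D = squareform(pdist(X))
    # distance to the knn-th neighbor, self excluded
    eps = np.partition(D, knn, axis=1)[:, knn]
    zero = np.nonzero(eps == 0)[0]
    if zero.size:
        raise ContractError(
            f"zero adaptive bandwidth at points {zero[:10].tolist()} "
            f"(>= {knn} duplicate points); deduplicate or jitter the input"
        )
    with np.errstate(over="ignore", under="ignore"):
        Ki = np.exp(-((D / eps[:, None]) ** alpha))
        Kj = np.exp(-((D / eps[None, :]) ** alpha))
    K = 0.5 * Ki + 0.5 * Kj
    np.fill_diagonal(K, 1.0)
    return AffinityMatrix(K=K, bandwidths=eps, knn=knn, alpha=alpha)


def diffusion_operator(K: AffinityMatrix | np.ndarray) -> DiffusionOperator:
    """Row-normalize an affinity matrix and cache the spectrum of its
    symmetric conjugate for fast powers and entropy curves."""
    Kmat = K.K if isinstance(K, AffinityMatrix) else np.asarray(K, dtype=float)
    if Kmat.shape[0] != Kmat.shape[1]:
        raise ContractError("affinity matrix must be square")
    if not np.allclose(Kmat, Kmat.T, atol=1e-10):
        raise ContractError("affinity matrix must be symmetric")
    d = Kmat.sum(axis=1)
    if np.any(d <= 0):
        raise ContractError("zero row sum in affinity matrix")
    P = Kmat / d[:, None]
    M = Kmat / np.sqrt(np.outer(d, d))
    lam, V = np.linalg.eigh(M)
    order = np.argsort(-np.abs(lam))
    return DiffusionOperator(
        P=P, eigenvalues=lam[order], eigenvectors=V[:, order], row_sums=d
    )


def von_neumann_entropy(op: DiffusionOperator, t_max: int = 100) -> np.ndarray:
    """H(t) for t = 1..t_max from the eigenvalue magnitudes."""
    lam = np.abs(op.eigenvalues)
    H = np.empty(t_max)
    for i, t in enumerate(range(1, t_max + 1)):
        p = lam**t
        total = p.sum()
        if total <= 0:
            H[i] = 0.0
            continue
        eta = p / total
        nz = eta > 0
        H[i] = float(-(eta[nz] * np.log(eta[nz])).sum())
    return H


def select_t_vne(op: DiffusionOperator, t_max: int = 100) -> int:
    """Diffusion time at the knee of H(t): the point of maximum
    perpendicular distance from the chord joining (1, H(1)) and
    (t_max, H(t_max))."""
    if t_max < 3:
        raise ConfigurationError(f"t_max: must be >= 3, got {t_max}")
    H = von_neumann_entropy(op, t_max)
    op.vne_curve = H
    if np.ptp(H) < 1e-12:
        raise ContractError("von Neumann entropy is constant; supply t explicitly")
    ts = np.arange(1, t_max + 1, dtype=float)
    x0, y0 = ts[0], H[0]
    x1, y1 = ts[-1], H[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * ts - (x1 - x0) * H + x1 * y0 - y1 * x0) / norm
    t_sel = int(ts[int(np.argmax(dist))])
    op.t_selected = t_sel
    return t_sel


def potential_distance(op: DiffusionOperator, t: int, gamma: float = LOG_FLOOR,
                       require_connected: bool = True) -> np.ndarray:
    """Euclidean distances between log-transformed t-step diffusion
    profiles.  By default a disconnected affinity graph is an error (the
    components are named); with ``require_connected=False`` the gamma
    log-floor regularizes the zero transition probabilities instead."""
    if t < 1:
        raise ConfigurationError(f"t: must be >= 1, got {t}")
    n_comp, labels = connected_components(op.P > 0, directed=False)
    if n_comp > 1 and require_connected:
        sizes = np.bincount(labels)
        raise ContractError(
            f"affinity graph has {n_comp} connected components (sizes {sizes.tolist()}); "
            "embed components separately, densify the kernel, or pass "
            "require_connected=False to regularize"
        )
    Pt = op.power(int(t))
    logPt = np.log(Pt + gamma)
    return squareform(pdist(logPt))


def _classical_mds(U: np.ndarray, n_dims: int) -> np.ndarray:
    n = U.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (U**2) @ J
    lam, V = np.linalg.eigh(B)
    order = np.argsort(-lam)[:n_dims]
    lam_top = np.clip(lam[order], 0.0, None)
    return V[:, order] * np.sqrt(lam_top)


def _stress(U: np.ndarray, coords: np.ndarray) -> float:
    D = squareform(pdist(coords))
    iu = np.triu_indices_from(U, k=1)
    return float(np.sum((U[iu] - D[iu]) ** 2))


def metric_mds(U: np.ndarray, n_dims: int = 5, max_iter: int = 200,
               tol: float = 1e-6) -> tuple[np.ndarray, float]:
    """Metric MDS: classical-scaling initialization refined by SMACOF
    stress majorization (Guttman transform).  Deterministic; the returned
    stress never exceeds the initialization stress."""
    U = np.asarray(U, dtype=float)
    if U.shape[0] != U.shape[1] or not np.allclose(U, U.T, atol=1e-8):
        raise ContractError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(U), 0.0, atol=1e-8):
        raise ContractError("distance matrix must have a zero diagonal")
    n = U.shape[0]
    X = _classical_mds(U, n_dims)
    stress = _stress(U, X)
    for _ in range(max_iter):
        D = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(D > 0, U / np.where(D > 0, D, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = (B @ X) / n
        stress_new = _stress(U, X_new)
        if stress > 0 and (stress - stress_new) < tol * stress:
            X = X_new
            stress = stress_new
            break
        X, stress = X_new, stress_new
    # order output dimensions by variance
    var = X.var(axis=0)
    X = X[:, np.argsort(-var)]
    return X, stress


def variance_explained(coords: np.ndarray) -> np.ndarray:
    """Per-dimension share of the embedding's total coordinate variance."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise ContractError("need >= 2 retained dimensions")
    var = coords.var(axis=0)
    total = var.sum()
    if total <= 0:
        raise ContractError("zero total variance in embedding coordinates")
    return var / total


def spatial_weights(responses: ResponseMatrix | np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Per-region weight of each embedding dimension: Pearson correlation
    between the region's concatenated response course and the coordinate
    course.  Zero-variance regions get weight 0 (with a warning)."""
    R = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses, float)
    coords = np.asarray(coords, dtype=float)
    if R.shape[0] != coords.shape[0]:
        raise ContractError(
            f"response rows ({R.shape[0]}) must align with embedding rows ({coords.shape[0]})"
        )
    Rc = R - R.mean(axis=0)
    Cc = coords - coords.mean(axis=0)
    r_sd = Rc.std(axis=0)
    c_sd = Cc.std(axis=0)
    dead = r_sd == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-variance regions; their spatial weights are set to 0",
            stacklevel=2,
        )
    if np.any(c_sd == 0):
        raise ContractError("zero-variance embedding coordinate")
    denom = np.outer(np.where(dead, 1.0, r_sd), c_sd) * R.shape[0]
    W = (Rc.T @ Cc) / denom
    W[dead] = 0.0
    return W


def phate(X: np.ndarray, params: PhateParams = PhateParams()) -> Embedding:
    """Full embedding recipe on the rows of X (samples x features)."""
    X = np.asarray(X, dtype=float)
    params.validate(n_points=X.shape[0])
    aff = alpha_decay_kernel(X, knn=params.knn, alpha=params.alpha)
    op = diffusion_operator(aff)
    t = select_t_vne(op, params.t_max) if params.t == "auto" else int(params.t)
    U = potential_distance(op, t, require_connected=False)
    coords, stress = metric_mds(U, params.n_dims, params.mds_max_iter, params.mds_tol)
    frac = variance_explained(coords)
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(X).tobytes())
    digest.update(repr(params).encode())
    return Embedding(
        coords=coords,
        variance_fraction=frac,
        stress=stress,
        t_selected=t,
        params=params,
        embedding_id=digest.hexdigest()[:16],
        meta={"n_points": X.shape[0], "n_features": X.shape[1]},
    )
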