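"""t-distributed stochastic neighbour embedding, implemented from scratch.

High-dimensional similarities are Gaussian conditionals

    p_{j|i} = exp(-||x_i - x_j||^2 / 2 sigma_i^2) / sum_{k != i} exp(...),

with each bandwidth sigma_i calibrated by bisection so the row perplexity
2^{H(P_i)} (H in bits) matches the requested value.  Conditionals are
symmetrized to the joint P_ij = (p_{j|i} + p_{i|j}) / 2n.  Low-dimensional
similarities use the Cauchy (Student-t, one degree of freedom) kernel, and
the embedding minimizes KL(P || Q) by gradient descent with constant
momentum:

    Y_t = Y_{t-1} + eta * (-grad) + alpha * (Y_{t-1} - Y_{t-2}).

Defaults (two output dimensions, perplexity 3, learning rate 50, momentum
0.5, 500 iterations) suit tables of a dozen-odd sites; no early
exaggeration is applied unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

__all__ = [
    "TsneParams",
    "Affinities",
    "EmbeddingResult",
    "conditional_affinities",
    "joint_probabilities",
    "low_dim_affinities",
    "kl_divergence",
    "kl_gradient",
    "tsne_run",
    "TSNE",
]


@dataclass(frozen=True)
class TsneParams:
    """Hyperparameters of the embedding optimizer.

    ``perplexity`` is the effective neighbour count (must be < n);
    ``learning_rate`` (eta) scales the gradient step; ``momentum`` (alpha)
    is the constant momentum coefficient, conventionally in [0.5, 0.9].
    ``sigma_tol`` is the bandwidth-calibration tolerance in bits.
    """

    out_dims: int = 2
    perplexity: float = 3.0
    learning_rate: float = 50.0
    momentum: float = 0.5
    max_iter: int = 500
    seed: int = 0
    sigma_tol: float = 1e-5
    sigma_max_iter: int = 100
    early_exaggeration: float = 1.0
    early_exaggeration_iter: int = 0

    def validate(self, n: int | None = None) -> None:
        if self.out_dims < 1:
            raise ValueError("out_dims must be >= 1")
        if self.perplexity <= 1:
            raise ValueError("perplexity must exceed 1")
        if n is not None and self.perplexity >= n:
            raise ValueError(f"perplexity must be < n = {n}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Affinities:
    """Calibrated high-dimensional affinities."""

    sigma: np.ndarray
    conditional: np.ndarray  # p_{j|i}, rows sum to 1
    joint: np.ndarray  # symmetrized P, sums to 1
    entropy_bits: np.ndarray  # achieved H(P_i)


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates and the optimization trace."""

    Y: np.ndarray
    kl_trace: np.ndarray
    final_kl: float
    params: TsneParams


def _row_affinity(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """p_{j|i} and entropy (bits) for one point at precision beta = 1/(2 sigma^2)."""
    w = np.exp(-d2_row * beta)
    total = w.sum()
    if total <= 0:
        return np.zeros_like(w), 0.0
    p = w / total
    nz = p > 0
    h = float(-(p[nz] * np.log2(p[nz])).sum())
    return p, h


def conditional_affinities(X: np.ndarray, perplexity: float,
                           tol: float = 1e-5, max_iter: int = 100) -> Affinities:
    """Calibrate per-point bandwidths to the target perplexity by bisection.

    Raises if two points coincide (their conditional row cannot reach the
    target entropy) or if the perplexity is not in (1, n).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if not 1 < perplexity < n:
        raise ValueError(f"perplexity must lie in (1, n={n})")
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    dup = np.argwhere((D2 + np.eye(n)) == 0)
    if dup.size:
        i, j = dup[0]
        raise ValueError(f"points {i} and {j} coincide; affinity calibration impossible")

    target = float(np.log2(perplexity))
    P = np.zeros((n, n))
    sigma = np.empty(n)
    entropy = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        d2 = D2[i, idx != i]
        beta, lo, hi = 1.0, 0.0, np.inf
        p, h = _row_affinity(d2, beta)
        for _ in range(max_iter):
            if abs(h - target) <= tol:
                break
            if h > target:  # too flat -> narrow the Gaussian
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (lo + hi)
            else:
                hi = beta
                beta = 0.5 * (lo + hi)
            p, h = _row_affinity(d2, beta)
        P[i, idx != i] = p
        sigma[i] = np.sqrt(0.5 / beta)
        entropy[i] = h
    joint = (P + P.T) / (2.0 * n)
    return Affinities(sigma=sigma, conditional=P, joint=joint, entropy_bits=entropy)


def joint_probabilities(affinities: Affinities) -> np.ndarray:
    """Symmetrized joint distribution P_ij = (p_{j|i} + p_{i|j}) / 2n."""
    return affinities.joint


def low_dim_affinities(Y: np.ndarray) -> np.ndarray:
    """Cauchy-kernel joint similarities q_ij in the embedding space."""
    Y = np.asarray(Y, dtype=float)
    num = 1.0 / (1.0 + squareform(pdist(Y, metric="sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    return num / num.sum()


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) over off-diagonal entries, 0 log 0 taken as 0."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise ValueError("Q vanishes where P has mass; KL undefined")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def kl_gradient(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic gradient of KL(P||Q(Y)) w.r.t. the embedding coordinates.

    dC/dy_i = 4 sum_j (P_ij - q_ij) (1 + ||y_i - y_j||^2)^-1 (y_i - y_j).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    num = 1.0 / (1.0 + squareform(pdist(Y, metric="sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    PQ = (P - Q) * num
    grad = np.empty_like(Y)
    for i in range(n):
        grad[i] = 4.0 * (PQ[i, :, None] * (Y[i] - Y)).sum(axis=0)
    return grad


def tsne_run(X: np.ndarray, params: TsneParams | None = None) -> EmbeddingResult:
    """Run the full embedding optimization; deterministic given the seed."""
    params = params or TsneParams()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    params.validate(n)
    aff = conditional_affinities(X, params.perplexity, params.sigma_tol, params.sigma_max_iter)
    P = aff.joint

    rng = np.random.default_rng(params.seed)
    Y = rng.standard_normal((n, params.out_dims)) * 1e-4
    Y_prev = Y.copy()
    kl_trace = np.empty(params.max_iter)
    for it in range(params.max_iter):
        P_eff = P * params.early_exaggeration if it < params.early_exaggeration_iter else P
        grad = kl_gradient(P_eff, Y)
        Y_new = Y - params.learning_rate * grad + params.momentum * (Y - Y_prev)
        Y_prev, Y = Y, Y_new
        kl = kl_divergence(P, low_dim_affinities(Y))
        if not np.isfinite(kl):
            raise FloatingPointError(f"embedding diverged at iteration {it}")
        kl_trace[it] = kl
    return EmbeddingResult(Y=Y, kl_trace=kl_trace, final_kl=float(kl_trace[-1]), params=params)


class TSNE(BaseEstimator):
    """Estimator wrapper around :func:`tsne_run`.

    Attributes after :meth:`fit`: ``embedding_`` (n x out_dims),
    ``kl_trace_`` and ``final_kl_``.
    """

    def __init__(self, out_dims: int = 2, perplexity: float = 3.0,
                 learning_rate: float = 50.0, momentum: float = 0.5,
                 max_iter: int = 500, seed: int = 0):
        self.out_dims = out_dims
        self.perplexity = perplexity
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_iter = max_iter
        self.seed = seed

    def _params(self) -> TsneParams:
        return TsneParams(
            out_dims=self.out_dims,
            perplexity=self.perplexity,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            max_iter=self.max_iter,
            seed=self.seed,
        )

    def fit(self, X, y=None):
        result = tsne_run(np.asarray(X, dtype=float), self._params())
        self.embedding_ = result.Y
        self.kl_trace_ = result.kl_trace
        self.final_kl_ = result.final_kl
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.embedding_
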