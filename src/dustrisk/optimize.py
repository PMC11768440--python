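"""Bayesian optimization of t-SNE hyperparameters.

A Gaussian-process surrogate (Matern 5/2 kernel on inputs rescaled to the
unit cube) is fitted to the evaluated objective values; the next candidate
maximizes expected improvement over the incumbent, with a small jitter for
numerical stability.  The initial design is a seeded Latin hypercube.

Three embedding-quality objectives are supported, all minimized:

* ``kl`` — the final KL divergence of the optimized embedding;
* ``silhouette`` — negated mean silhouette of a k-means clustering of the
  embedding (auto-k), so that maximizing cluster fit minimizes the
  objective;
* ``sammon`` — the Sammon mapping stress against the input distances.

Each t-SNE evaluation uses a seed derived deterministically from the master
seed and the evaluation index, so the objective is a deterministic function
of the hyperparameters and the optimization trace is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .cluster import assign_clusters, sammon_error, silhouette_score
from .tsne import TsneParams, tsne_run

__all__ = ["BayesOptResult", "bayes_minimize", "optimize_tsne", "tsne_objective", "default_bounds", "evaluation_seed"]

OBJECTIVES = ("kl", "silhouette", "sammon")


@dataclass
class BayesOptResult:
    """Optimization outcome: incumbent, trace, and bookkeeping."""

    best_params: dict[str, float]
    best_objective: float
    eval_trace: list[tuple[dict[str, float], float]] = field(default_factory=list)
    budget: int = 0
    seed: int = 0
    objective: str = ""

    @property
    def incumbent_trace(self) -> np.ndarray:
        """Best objective value seen up to each evaluation (non-increasing)."""
        vals = np.array([v for _, v in self.eval_trace])
        return np.minimum.accumulate(vals)


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float, jitter: float = 1e-6) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    imp = best - mu - jitter
    z = imp / sd
    return imp * norm.cdf(z) + sd * norm.pdf(z)


def bayes_minimize(
    func,
    bounds: dict[str, tuple[float, float]],
    budget: int = 30,
    seed: int = 0,
    n_initial: int = 8,
    n_candidates: int = 512,
) -> BayesOptResult:
    """Minimize a black-box function over a box with GP + expected improvement.

    ``func`` maps a dict of parameter values to a scalar.  The first
    ``n_initial`` evaluations form a Latin-hypercube design; subsequent
    points maximize EI over a fresh random candidate set each iteration.
    """
    names = list(bounds)
    if not names:
        raise ValueError("bounds must name at least one parameter")
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("every bound must satisfy low < high")
    if budget < n_initial:
        raise ValueError(f"budget must be >= initial design size ({n_initial})")

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(names), seed=rng)
    U = sampler.random(n_initial)

    X_unit: list[np.ndarray] = []
    y: list[float] = []
    trace: list[tuple[dict[str, float], float]] = []

    def evaluate(u: np.ndarray) -> None:
        x = lo + u * (hi - lo)
        params = dict(zip(names, map(float, x)))
        val = float(func(params))
        X_unit.append(u)
        y.append(val)
        trace.append((params, val))

    for u in U:
        evaluate(u)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(len(names), 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    for _ in range(budget - n_initial):
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(X_unit), np.asarray(y))
        cand = rng.random((n_candidates, len(names)))
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, min(y))
        evaluate(cand[int(np.argmax(ei))])

    best_i = int(np.argmin(y))
    return BayesOptResult(
        best_params=trace[best_i][0],
        best_objective=y[best_i],
        eval_trace=trace,
        budget=budget,
        seed=seed,
    )


def default_bounds(n: int) -> dict[str, tuple[float, float]]:
    """Search box for the three influential t-SNE hyperparameters."""
    return {
        "perplexity": (2.0, float(n - 2)),
        "learning_rate": (10.0, 1000.0),
        "momentum": (0.5, 0.9),
    }


def evaluation_seed(master_seed: int, index: int) -> int:
    # one seeded SeedSequence child per evaluation index, kept below 2**31
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def tsne_objective(
    X: np.ndarray,
    objective: str,
    params: dict[str, float],
    seed: int,
    base: TsneParams | None = None,
) -> float:
    """Evaluate one embedding-quality objective at given hyperparameters."""
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    base = base or TsneParams()
    p = TsneParams(
        out_dims=base.out_dims,
        perplexity=float(params["perplexity"]),
        learning_rate=float(params["learning_rate"]),
        momentum=float(params["momentum"]),
        max_iter=base.max_iter,
        seed=seed,
        sigma_tol=base.sigma_tol,
        sigma_max_iter=base.sigma_max_iter,
    )
    result = tsne_run(X, p)
    if objective == "kl":
        return result.final_kl
    if objective == "sammon":
        return sammon_error(X, result.Y)
    labels = assign_clusters(result.Y, seed=seed).labels
    return -silhouette_score(result.Y, labels)


def optimize_tsne(
    X: np.ndarray,
    objective: str = "kl",
    budget: int = 30,
    seed: int = 0,
    base: TsneParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> BayesOptResult:
    """Bayesian-optimize (perplexity, learning rate, momentum) for one dataset.

    Every evaluation embeds with a seed derived from (seed, evaluation
    index); the silhouette objective is negated internally so that all
    three objectives minimize.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    bounds = bounds or default_bounds(n)
    counter = {"i": 0}

    def func(params: dict[str, float]) -> float:
        eval_seed = evaluation_seed(seed, counter["i"])
        counter["i"] += 1
        return tsne_objective(X, objective, params, eval_seed, base)

    result = bayes_minimize(func, bounds, budget=budget, seed=seed)
    result.objective = objective
    return result
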