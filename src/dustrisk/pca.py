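"""Correlation-matrix PCA with model-order selection.

Variables (metal concentrations) are standardized to zero mean and unit
sample standard deviation, so PCA operates on the sample correlation matrix
R.  Component j has eigenvalue lambda_j, orthonormal eigenvector e_j, score
y_j = e_j' z per site, and explains the fraction t_j = lambda_j / sum(lambda)
of the total variance.

Four retention rules are provided:

* Kaiser: keep components with lambda_j > 1 (strict);
* cumulative variance: smallest k whose cumulative t reaches a threshold
  (default 0.80);
* AIC/BIC minimisation over k, with the log-likelihood L_k taken from the
  probabilistic-PCA profile: the covariance is reconstructed from the top-k
  eigencomponents with an isotropic residual equal to the mean of the
  discarded eigenvalues;
* sequential eigenvalue thresholds: under the same likelihood, accepting
  one more component under AIC reduces asymptotically to
  lambda_{k+1} > exp(-2/n), and under BIC to lambda_{k+1} > n^(1/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["standardize", "CorrelationPCA", "ComponentSelection", "select_components", "pca_log_likelihood"]


def standardize(table: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Standardize columns to mean 0 and unit sample SD (n-1 denominator).

    A constant column cannot be standardized and raises a ValueError naming
    the offending variable.
    """
    values = np.asarray(table, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("standardization needs at least two rows")
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        name = table.columns[j] if isinstance(table, pd.DataFrame) else f"column {j}"
        raise ValueError(f"cannot standardize constant column {name}")
    z = (values - values.mean(axis=0)) / sd
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(z, index=table.index, columns=table.columns)
    return z


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """PCA on the correlation matrix of (internally standardized) data.

    Parameters
    ----------
    cumvar_threshold : float
        Cumulative-variance fraction used by :meth:`select`, in (0, 1].

    Attributes
    ----------
    correlation_ : ndarray (p, p)
        Sample correlation matrix of the standardized variables.
    eigenvalues_ : ndarray (p,)
        Descending; sums to p.
    components_ : ndarray (p, p)
        Orthonormal eigenvectors as *columns*, sign-fixed so each column's
        largest-magnitude entry is positive.
    variance_fraction_ : ndarray (p,)
        t_j = lambda_j / p.
    scores_ : ndarray (n, p)
        Site scores y = Z E from the fit data.
    cos2_variables_ : ndarray (p, p)
        Squared correlation of each variable with each component score.
    cos2_individuals_ : ndarray (n, p)
        Squared cosine of each site on each component.
    contributions_ : ndarray (p, p)
        Per-component variable contributions, percent (columns sum to 100).
    """

    def __init__(self, cumvar_threshold: float = 0.80):
        self.cumvar_threshold = cumvar_threshold

    def fit(self, X, y=None):
        X = X if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        z = standardize(X)
        Z = np.asarray(z, dtype=float)
        n, p = Z.shape
        self.n_samples_, self.n_features_in_ = n, p
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)

        R = Z.T @ Z / (n - 1)
        w, V = np.linalg.eigh(R)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(p):
            i = np.argmax(np.abs(V[:, j]))
            if V[i, j] < 0:
                V[:, j] = -V[:, j]

        scores = Z @ V
        self.correlation_ = R
        self.eigenvalues_ = w
        self.components_ = V
        self.variance_fraction_ = w / w.sum()
        self.scores_ = scores

        # variable cos2: squared loading of variable on component, where the
        # loading is the correlation between variable and score:
        # corr(x_v, y_j) = e_vj * sqrt(lambda_j) for standardized data.
        load = V * np.sqrt(np.clip(w, 0.0, None))[None, :]
        self.cos2_variables_ = load**2
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = 100.0 * (V**2)
        self.contributions_ = contrib
        row_norm2 = (scores**2).sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.cos2_individuals_ = np.where(row_norm2 > 0, scores**2 / row_norm2, 0.0)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        z = standardize(X)
        return np.asarray(z, dtype=float) @ self.components_

    def select(self) -> "ComponentSelection":
        check_is_fitted(self, "components_")
        return select_components(self.eigenvalues_, self.n_samples_, self.cumvar_threshold)

    def eigen_table(self) -> pd.DataFrame:
        """Scree data: component, eigenvalue, percent and cumulative percent."""
        check_is_fitted(self, "components_")
        pct = 100.0 * self.variance_fraction_
        return pd.DataFrame(
            {
                "component": np.arange(1, len(pct) + 1),
                "eigenvalue": self.eigenvalues_,
                "pct": pct,
                "cum_pct": np.cumsum(pct),
            }
        )


def pca_log_likelihood(eigenvalues: np.ndarray, k: int, n: int) -> float:
    """Gaussian profile log-likelihood of a rank-k PCA model.

    The model covariance keeps the top-k eigencomponents and replaces the
    rest with an isotropic residual variance equal to the mean of the
    discarded eigenvalues; at that profile maximum the log-likelihood has
    the closed form

        L_k = -(n/2) [ p ln(2 pi) + sum_{j<=k} ln lambda_j
                       + (p-k) ln(mean of the rest) + p ].
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = lam.size
    if not 1 <= k < p:
        raise ValueError(f"k must satisfy 1 <= k < p={p}")
    top = lam[:k]
    resid = float(lam[k:].mean())
    if np.any(top <= 0) or resid <= 0:
        raise ValueError("eigenvalues must be positive for the Gaussian likelihood")
    return float(-0.5 * n * (p * np.log(2 * np.pi) + np.log(top).sum() + (p - k) * np.log(resid) + p))


@dataclass
class ComponentSelection:
    """Retention counts under each rule, plus the underlying curves."""

    n: int
    kaiser_k: int
    cumvar_k: int
    cumvar_threshold: float
    aic_curve: dict[int, float]
    bic_curve: dict[int, float]
    aic_k: int
    bic_k: int
    aic_threshold: float
    bic_threshold: float
    aic_threshold_k: int
    bic_threshold_k: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "kaiser_k": self.kaiser_k,
            "cumvar_k": self.cumvar_k,
            "cumvar_threshold": self.cumvar_threshold,
            "aic_curve": {str(k): v for k, v in self.aic_curve.items()},
            "bic_curve": {str(k): v for k, v in self.bic_curve.items()},
            "aic_k": self.aic_k,
            "bic_k": self.bic_k,
            "aic_threshold": self.aic_threshold,
            "bic_threshold": self.bic_threshold,
            "aic_threshold_k": self.aic_threshold_k,
            "bic_threshold_k": self.bic_threshold_k,
        }


def _sequential_threshold_k(eigenvalues: np.ndarray, threshold: float) -> int:
    """Add component k+1 while lambda_{k+1} exceeds the threshold."""
    k = 0
    for lam in eigenvalues:
        if lam > threshold:
            k += 1
        else:
            break
    return k


def select_components(
    eigenvalues: np.ndarray, n: int, cumvar_threshold: float = 0.80
) -> ComponentSelection:
    """Apply the four retention rules to a descending eigenvalue spectrum."""
    lam = np.asarray(eigenvalues, dtype=float)
    if not 0 < cumvar_threshold <= 1:
        raise ValueError("cumvar_threshold must be in (0, 1]")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    p = lam.size
    kaiser_k = int(np.sum(lam > 1.0))
    t = lam / lam.sum()
    cum = np.cumsum(t)
    cumvar_k = int(np.searchsorted(cum, cumvar_threshold - 1e-12) + 1)

    aic_curve, bic_curve = {}, {}
    for k in range(1, p):
        ll = pca_log_likelihood(lam, k, n)
        aic_curve[k] = -2.0 * ll + 2.0 * k
        bic_curve[k] = -2.0 * ll + k * np.log(n)
    aic_k = min(aic_curve, key=aic_curve.get)
    bic_k = min(bic_curve, key=bic_curve.get)

    aic_threshold = float(np.exp(-2.0 / n))
    bic_threshold = float(n ** (1.0 / n))
    return ComponentSelection(
        n=n,
        kaiser_k=kaiser_k,
        cumvar_k=cumvar_k,
        cumvar_threshold=cumvar_threshold,
        aic_curve=aic_curve,
        bic_curve=bic_curve,
        aic_k=aic_k,
        bic_k=bic_k,
        aic_threshold=aic_threshold,
        bic_threshold=bic_threshold,
        aic_threshold_k=_sequential_threshold_k(lam, aic_threshold),
        bic_threshold_k=_sequential_threshold_k(lam, bic_threshold),
    )
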