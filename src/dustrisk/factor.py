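"""Maximum-likelihood factor analysis with oblique rotation and diagnostics.

The common-factor model decomposes the correlation matrix R of p
standardized variables into m common factors and unique variances,

    Sigma = Lambda Phi Lambda' + Psi,

with Lambda the p x m pattern matrix, Phi the factor correlation matrix and
Psi diagonal.  Extraction minimizes the ML discrepancy

    F = log|Sigma| - log|R| + tr(R Sigma^-1) - p

by profiling Lambda out: for fixed Psi the optimal loadings come from the
eigenstructure of Psi^-1/2 R Psi^-1/2, leaving a p-dimensional optimization
over the uniquenesses (bounded below at 0.001; hitting the bound is a
Heywood case, recorded as a warning on the result).

Rotation is oblimin (quartimin), computed with the oblique gradient
projection algorithm, so factors may correlate — required whenever the
fitted factor correlations are materially nonzero.

Diagnostics mirror the standard exploratory-FA report: communalities h2,
uniquenesses u2, Hoffman row complexity (sum(l^2))^2 / sum(l^4), SS
loadings, chi-square fit test with Bartlett's correction, RMSR, TLI,
information criteria, parallel analysis, very-simple-structure (VSS)
curves, and regression factor-score adequacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .pca import standardize

__all__ = [
    "MLFactorAnalysis",
    "FaFitStats",
    "FaSelection",
    "fa_fit",
    "hoffman_complexity",
    "oblique_communalities",
    "parallel_analysis",
    "vss",
    "select_m",
]

_PSI_FLOOR = 1e-3


def max_factors(p: int) -> int:
    """Largest m with non-negative model degrees of freedom."""
    m = 0
    while ((p - (m + 1)) ** 2 - (p + m + 1)) / 2 >= 0:
        m += 1
    return m


def hoffman_complexity(loadings: np.ndarray) -> np.ndarray:
    """Hoffman row complexity (sum l^2)^2 / sum l^4 per variable.

    Equals 1 when a variable loads on a single factor and approaches the
    factor count for perfectly even loadings.
    """
    lam2 = np.asarray(loadings, dtype=float) ** 2
    num = lam2.sum(axis=1) ** 2
    den = (lam2**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def oblique_communalities(loadings: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Communalities h2 = diag(Lambda Phi Lambda') of an oblique solution."""
    lam = np.atleast_2d(np.asarray(loadings, dtype=float))
    phi = np.asarray(phi, dtype=float)
    return np.einsum("ij,jk,ik->i", lam, phi, lam)


# ---------------------------------------------------------------------------
# ML extraction


def _profile_objective(log_psi: np.ndarray, R: np.ndarray, m: int) -> tuple[float, np.ndarray]:
    """ML discrepancy profiled over loadings, with gradient w.r.t. log psi.

    The gradient uses the classical identity
    dF/dpsi_i = diag(Lambda Lambda' + Psi - R)_i / psi_i^2 evaluated at the
    profile-optimal loadings.
    """
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(d, d)
    w, V = np.linalg.eigh(Rstar)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tail = np.clip(w[m:], 1e-12, None)
    f = float(np.sum(tail - np.log(tail) - 1.0))
    lam = _loadings_from_psi(psi, R, m, eig=(w, V))
    resid_diag = np.einsum("ij,ij->i", lam, lam) + psi - np.diag(R)
    grad = resid_diag / psi  # d/dlog psi = psi * d/dpsi
    return f, grad


def _loadings_from_psi(psi: np.ndarray, R: np.ndarray, m: int, eig=None) -> np.ndarray:
    if eig is None:
        d = 1.0 / np.sqrt(psi)
        Rstar = R * np.outer(d, d)
        w, V = np.linalg.eigh(Rstar)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
    else:
        w, V = eig
    theta, Vm = w[:m], V[:, :m]
    scale = np.sqrt(np.clip(theta - 1.0, 0.0, None))
    return (np.sqrt(psi)[:, None] * Vm) * scale[None, :]


def _ml_extract(R: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Unrotated ML loadings, uniquenesses, minimized discrepancy, Heywood flag."""
    p = R.shape[0]
    start = np.log(np.clip(1.0 - 0.5 * np.abs(R - np.eye(p)).max(axis=1), 0.05, 1.0))
    res = optimize.minimize(
        _profile_objective,
        start,
        args=(R, m),
        method="L-BFGS-B",
        jac=True,
        bounds=[(np.log(_PSI_FLOOR), 0.0)] * p,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    psi = np.exp(res.x)
    heywood = bool(np.any(psi <= _PSI_FLOOR * (1 + 1e-6)))
    lam = _loadings_from_psi(psi, R, m)
    return lam, psi, float(res.fun), heywood


# ---------------------------------------------------------------------------
# Oblimin (quartimin) rotation via oblique gradient projection


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    L2 = L**2
    m = L.shape[1]
    N = np.ones((m, m)) - np.eye(m)
    f = float(np.sum(L2 * (L2 @ N)) / 4.0)
    G = L * (L2 @ N)
    return f, G


def _oblimin_rotate(
    A: np.ndarray, max_iter: int = 500, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique gradient-projection rotation minimizing the quartimin criterion.

    Returns the rotated pattern matrix and the factor correlation matrix.
    """
    m = A.shape[1]
    if m < 2:
        return A.copy(), np.eye(m)
    T = np.eye(m)
    Tinv = np.linalg.inv(T)
    L = A @ Tinv.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Tinv).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            X = X @ np.diag(1.0 / np.sqrt(np.sum(X**2, axis=0)))
            Tinv = np.linalg.inv(X)
            L = A @ Tinv.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = X
        f = ft
        G = -(L.T @ Gq @ Tinv).T
    Phi = T.T @ T
    return L, Phi


def _order_and_sign(lam: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order factors by SS loadings (descending) and fix signs.

    Each factor's loading column is flipped so its largest-magnitude entry
    is positive; Phi rows/columns are permuted and flipped consistently.
    """
    ss = (lam**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    lam = lam[:, order]
    phi = phi[np.ix_(order, order)]
    for j in range(lam.shape[1]):
        i = np.argmax(np.abs(lam[:, j]))
        if lam[i, j] < 0:
            lam[:, j] = -lam[:, j]
            phi[j, :] = -phi[j, :]
            phi[:, j] = -phi[:, j]
            phi[j, j] = abs(phi[j, j])
    return lam, phi


# ---------------------------------------------------------------------------
# Fit statistics


@dataclass
class FaFitStats:
    """Chi-square fit of the m-factor model plus information criteria.

    ``bic`` and ``aic`` follow the chi-square +/- 2 df convention used in
    this pipeline's reports; ``bic_ln_n`` (chi2 - df ln n) and
    ``aic_relative`` (chi2 - 2 df) are the textbook saturated-model-relative
    variants, reported alongside for comparison.
    """

    chi_square: float
    df: int
    p_value: float
    rmsr: float
    tli: float
    bic: float
    aic: float
    bic_ln_n: float
    aic_relative: float
    objective: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "chi_square", "df", "p_value", "rmsr", "tli", "bic", "aic",
            "bic_ln_n", "aic_relative", "objective")}


def _fit_statistics(R: np.ndarray, objective: float, m: int, n: int,
                    sigma: np.ndarray) -> FaFitStats:
    p = R.shape[0]
    df = ((p - m) ** 2 - (p + m)) // 2
    if df < 1:
        raise ValueError(f"m={m} saturates the model for p={p} (df={df})")
    correction = n - 1 - (2 * p + 5) / 6.0 - 2 * m / 3.0
    chi2 = max(correction * objective, 0.0)
    p_value = float(stats.chi2.sf(chi2, df))
    resid = R - sigma
    off = ~np.eye(p, dtype=bool)
    rmsr = float(np.sqrt(np.mean(resid[off] ** 2)))
    # null (independence) model: Sigma = I on a correlation matrix
    f_null = float(-np.linalg.slogdet(R)[1])
    chi2_null = max((n - 1 - (2 * p + 5) / 6.0) * f_null, 0.0)
    df_null = p * (p - 1) // 2
    denom = chi2_null / df_null - 1.0
    tli = float((chi2_null / df_null - chi2 / df) / denom) if denom != 0 else np.nan
    return FaFitStats(
        chi_square=float(chi2),
        df=int(df),
        p_value=p_value,
        rmsr=rmsr,
        tli=tli,
        bic=float(chi2 - 2 * df),
        aic=float(chi2 + 2 * df),
        bic_ln_n=float(chi2 - df * np.log(n)),
        aic_relative=float(chi2 - 2 * df),
        objective=float(objective),
    )


# ---------------------------------------------------------------------------
# Estimator


class MLFactorAnalysis(BaseEstimator, TransformerMixin):
    """Maximum-likelihood exploratory factor analysis on the correlation matrix.

    Parameters
    ----------
    n_factors : int
        Number of common factors m.
    rotation : {"oblimin", None}
        Oblique quartimin rotation (default) or no rotation.

    Attributes
    ----------
    loadings_ : ndarray (p, m)
        Rotated pattern matrix, factors ordered by SS loadings.
    factor_corr_ : ndarray (m, m)
        Factor correlation matrix Phi (identity when unrotated).
    communalities_ : ndarray (p,)
        h2 = diag(Lambda Phi Lambda').
    uniquenesses_ : ndarray (p,)
        u2 from the ML fit (1 - h2 up to convergence tolerance).
    complexity_ : ndarray (p,)
        Hoffman row complexity of the pattern matrix.
    ss_loadings_, proportion_var_, cumulative_var_ : ndarray (m,)
        Structure-convention SS loadings and variance shares.
    fit_stats_ : FaFitStats
    score_adequacy_ : DataFrame
        Per factor: correlation of regression scores with factors, multiple
        R-square, and minimum correlation 2 R^2 - 1.
    heywood_ : bool
        True when a uniqueness hit the 0.001 floor.
    """

    def __init__(self, n_factors: int = 3, rotation: str | None = "oblimin"):
        self.n_factors = n_factors
        self.rotation = rotation

    def fit(self, X, y=None):
        X_df = X if isinstance(X, pd.DataFrame) else None
        z = standardize(X)
        Z = np.asarray(z, dtype=float)
        n, p = Z.shape
        R = Z.T @ Z / (n - 1)
        self._fit_correlation(R, n, feature_names=None if X_df is None else list(X_df.columns))
        self._Z = Z
        return self

    def fit_correlation(self, R: np.ndarray, n: int, feature_names=None):
        """Fit from a correlation matrix and its sample size directly."""
        self._fit_correlation(np.asarray(R, dtype=float), n, feature_names)
        self._Z = None
        return self

    def _fit_correlation(self, R: np.ndarray, n: int, feature_names=None) -> None:
        p = R.shape[0]
        m = self.n_factors
        if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("R must be a symmetric correlation matrix")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("R must be positive definite")
        if not 1 <= m <= max_factors(p):
            raise ValueError(f"n_factors must be in [1, {max_factors(p)}] for p={p}")

        lam0, psi, objective, heywood = _ml_extract(R, m)
        if self.rotation not in ("oblimin", None, "none"):
            raise ValueError(f"unknown rotation {self.rotation!r}")
        if self.rotation == "oblimin" and m >= 2:
            lam, phi = _oblimin_rotate(lam0)
        else:
            lam, phi = lam0, np.eye(m)
        lam, phi = _order_and_sign(lam, phi)

        h2 = oblique_communalities(lam, phi)
        structure = lam @ phi
        ss = np.sum(lam * structure, axis=0)

        self.n_samples_ = n
        self.n_features_in_ = p
        self.feature_names_in_ = feature_names
        self.correlation_ = R
        self.loadings_ = lam
        self.loadings_unrotated_ = lam0
        self.factor_corr_ = phi
        self.communalities_ = h2
        self.uniquenesses_ = psi
        self.complexity_ = hoffman_complexity(lam)
        self.ss_loadings_ = ss
        self.proportion_var_ = ss / p
        self.cumulative_var_ = np.cumsum(ss / p)
        self.heywood_ = heywood
        sigma = lam @ phi @ lam.T + np.diag(psi)
        self.model_correlation_ = sigma
        # saturated models (df < 1) carry no chi-square test
        df = ((p - m) ** 2 - (p + m)) // 2
        self.fit_stats_ = _fit_statistics(R, objective, m, n, sigma) if df >= 1 else None

        # regression (Thurstone) factor-score adequacy
        Rinv = np.linalg.inv(R)
        W = Rinv @ structure
        r2 = np.clip(np.einsum("ij,ik,kj->j", structure, Rinv, structure), 0.0, 1.0)
        self.score_weights_ = W
        self.score_adequacy_ = pd.DataFrame(
            {
                "correlation": np.sqrt(r2),
                "r_square": r2,
                "min_correlation": 2 * r2 - 1,
            },
            index=[f"F{j + 1}" for j in range(m)],
        )

    def transform(self, X):
        """Regression-method factor scores for (standardized) new data."""
        check_is_fitted(self, "loadings_")
        z = standardize(X)
        return np.asarray(z, dtype=float) @ self.score_weights_

    def scores(self) -> np.ndarray:
        """Factor scores of the training data (data-fitted models only)."""
        check_is_fitted(self, "loadings_")
        if self._Z is None:
            raise ValueError("model was fitted from a correlation matrix; no training scores")
        return self._Z @ self.score_weights_

    def loadings_table(self) -> pd.DataFrame:
        """Pattern loadings with h2, u2 and complexity, one row per variable."""
        check_is_fitted(self, "loadings_")
        m = self.loadings_.shape[1]
        names = self.feature_names_in_ or [f"x{i + 1}" for i in range(self.n_features_in_)]
        out = pd.DataFrame(
            self.loadings_, index=names, columns=[f"F{j + 1}" for j in range(m)]
        )
        out["h2"] = self.communalities_
        out["u2"] = self.uniquenesses_
        out["com"] = self.complexity_
        return out


def fa_fit(R: np.ndarray, m: int, n: int) -> MLFactorAnalysis:
    """Functional wrapper: ML factor model with oblimin rotation from R."""
    return MLFactorAnalysis(n_factors=m).fit_correlation(R, n)


# ---------------------------------------------------------------------------
# Factor-count selection


@dataclass
class FaSelection:
    """Factor-count diagnostics: parallel analysis, VSS, AIC/BIC curves."""

    pa_retained: int
    random_eigen_means: np.ndarray
    observed_eigenvalues: np.ndarray
    vss_curve: dict[int, dict[int, float]] = field(default_factory=dict)
    aic_curve: dict[int, float] = field(default_factory=dict)
    bic_curve: dict[int, float] = field(default_factory=dict)
    bic_ln_n_curve: dict[int, float] = field(default_factory=dict)
    selected_m: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pa_retained": self.pa_retained,
            "random_eigen_means": list(map(float, self.random_eigen_means)),
            "observed_eigenvalues": list(map(float, self.observed_eigenvalues)),
            "vss_curve": {str(c): {str(m): v for m, v in curve.items()}
                          for c, curve in self.vss_curve.items()},
            "aic_curve": {str(m): v for m, v in self.aic_curve.items()},
            "bic_curve": {str(m): v for m, v in self.bic_curve.items()},
            "bic_ln_n_curve": {str(m): v for m, v in self.bic_ln_n_curve.items()},
            "selected_m": dict(self.selected_m),
        }


def parallel_analysis(data: np.ndarray | pd.DataFrame, reps: int = 100, seed: int = 0) -> FaSelection:
    """Horn's parallel analysis with mean random eigenvalues.

    Observed correlation eigenvalues are compared with the mean eigenvalues
    of correlation matrices of standard-normal data of the same shape;
    factors are retained while lambda_j exceeds the random mean.
    """
    if reps < 20:
        raise ValueError("parallel analysis needs at least 20 replicates")
    Z = np.asarray(standardize(data), dtype=float)
    n, p = Z.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.empty((reps, p))
    for r in range(reps):
        Xr = rng.standard_normal((n, p))
        rand[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(Xr, rowvar=False)))[::-1]
    means = rand.mean(axis=0)
    retained = 0
    for j in range(p):
        if obs[j] > means[j]:
            retained += 1
        else:
            break
    return FaSelection(pa_retained=retained, random_eigen_means=means, observed_eigenvalues=obs)


def vss(R: np.ndarray, n: int, m_max: int, complexities: tuple[int, ...] = (1, 2)) -> dict[int, dict[int, float]]:
    """Very-simple-structure index per factor count and complexity.

    For each m the model is refit; the pattern matrix is simplified to its
    c largest-magnitude loadings per row, and the index is one minus the
    ratio of squared off-diagonal residuals of the simplified model to the
    squared off-diagonal entries of R.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    m_max = min(m_max, max_factors(p))
    off = ~np.eye(p, dtype=bool)
    denom = float(np.sum(R[off] ** 2))
    curves: dict[int, dict[int, float]] = {c: {} for c in complexities}
    for m in range(1, m_max + 1):
        model = fa_fit(R, m, n)
        lam, phi = model.loadings_, model.factor_corr_
        for c in complexities:
            lam_s = np.zeros_like(lam)
            keep = min(c, m)
            for i in range(p):
                idx = np.argsort(np.abs(lam[i]))[::-1][:keep]
                lam_s[i, idx] = lam[i, idx]
            resid = R - lam_s @ phi @ lam_s.T
            curves[c][m] = float(1.0 - np.sum(resid[off] ** 2) / denom)
    return curves


def select_m(
    R: np.ndarray,
    n: int,
    m_max: int | None = None,
    data: np.ndarray | None = None,
    reps: int = 100,
    seed: int = 0,
) -> FaSelection:
    """Run every factor-count rule and report each selection.

    The pipeline's default rule is argmin BIC; parallel analysis requires
    the raw ``data`` matrix and is reported when available.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    m_max = min(m_max or max_factors(p), max_factors(p))
    aic_curve, bic_curve, bic_ln_n_curve = {}, {}, {}
    for m in range(1, m_max + 1):
        df = ((p - m) ** 2 - (p + m)) // 2
        if df < 1:
            break
        model = fa_fit(R, m, n)
        aic_curve[m] = model.fit_stats_.aic
        bic_curve[m] = model.fit_stats_.bic
        bic_ln_n_curve[m] = model.fit_stats_.bic_ln_n
    vss_curve = vss(R, n, m_max)
    if data is not None:
        sel = parallel_analysis(data, reps=reps, seed=seed)
    else:
        sel = FaSelection(pa_retained=0, random_eigen_means=np.array([]),
                          observed_eigenvalues=np.sort(np.linalg.eigvalsh(R))[::-1])
    sel.vss_curve = vss_curve
    sel.aic_curve = aic_curve
    sel.bic_curve = bic_curve
    sel.bic_ln_n_curve = bic_ln_n_curve
    sel.selected_m = {
        "aic": min(aic_curve, key=aic_curve.get),
        "bic": min(bic_curve, key=bic_curve.get),
        "bic_ln_n": min(bic_ln_n_curve, key=bic_ln_n_curve.get),
        **({"parallel_analysis": sel.pa_retained} if data is not None else {}),
        **{f"vss_c{c}": max(curve, key=curve.get) for c, curve in vss_curve.items()},
    }
    # the sample-size-penalized BIC is the package's model-selection default:
    # the chi2 - 2 df variant carries no n-dependence and overfits at large n
    sel.selected_m["default"] = sel.selected_m["bic_ln_n"]
    return sel
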