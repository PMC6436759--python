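"""Marginal GLM score statistics and their correlation from genotype data.

Given an ``n x d`` genotype dosage matrix ``G``, covariates ``X`` (first
column constant) and a phenotype ``Y``, the null GLM ``g(mu) = X alpha`` is
fitted once, and each SNP ``j`` receives the marginal score statistic

    Z_j = G_j' (Y - mu0_hat) / sqrt(G_j' P G_j)

where ``P = W - W X (X' W X)^-1 X' W`` is the weighted projection that
annihilates the covariate space, and ``W = diag{a(phi) v(mu0_i)}`` is the GLM
weight matrix.  The consistent correlation estimate between statistics is

    Sigma_jk = G_j' P G_k / sqrt(G_j' P G_j  G_k' P G_k).

``P`` is never materialised: both quantities are computed through the
residualisation ``Gt_j = W^1/2 G_j - W^1/2 X (X' W X)^-1 X' W G_j``, so the
cost is O(n d q) rather than O(n^2 d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CORR_EPS, CorrMatrix, ZVector

__all__ = [
    "ScoreInputs",
    "NullFit",
    "fit_null_glm",
    "score_statistics",
    "estimate_correlation",
    "nearest_correlation",
]

_FAMILIES = ("gaussian", "binomial")

_IRLS_MAXITER = 50
_IRLS_TOL = 1e-8


class FittingError(RuntimeError):
    """Raised when the null GLM cannot be fitted."""


class DegenerateSNPError(ValueError):
    """Raised when G_j' P G_j <= 0 for some SNP j (no residual variance)."""


@dataclass
class ScoreInputs:
    """Validated genotype-level inputs for the score machinery.

    Missing genotype entries (NaN) are mean-imputed per SNP on construction;
    constant genotype columns are rejected since the score statistic is then
    undefined.
    """

    G: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    family: str = "gaussian"

    def __post_init__(self) -> None:
        self.G = np.array(self.G, dtype=float, copy=True)
        if self.G.ndim == 1:
            self.G = self.G[:, None]
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.Y.size
        if self.G.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("G, X, Y sample dimensions disagree")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if n <= self.X.shape[1]:
            raise ValueError("need n > q")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")
        if self.family == "binomial":
            uniq = np.unique(self.Y)
            if not np.all(np.isin(uniq, [0.0, 1.0])) or uniq.size < 2:
                raise ValueError("binomial Y must be {0,1} with both classes")
        # mean-impute missing dosages per SNP
        if np.isnan(self.G).any():
            means = np.nanmean(self.G, axis=0)
            idx = np.where(np.isnan(self.G))
            self.G[idx] = np.take(means, idx[1])
        sd = self.G.std(axis=0)
        if np.any(sd == 0.0):
            j = int(np.flatnonzero(sd == 0.0)[0])
            raise ValueError(f"genotype column {j} is constant")

    @property
    def n(self) -> int:
        return int(self.Y.size)

    @property
    def d(self) -> int:
        return int(self.G.shape[1])


@dataclass
class NullFit:
    """Null-model GLM fit (beta = 0): coefficients, fitted means, weights.

    For the gaussian family ``W_i = dispersion`` (ML convention, RSS/n); for
    the binomial family ``W_i = mu0_i (1 - mu0_i)`` and dispersion 1.
    """

    alpha0_hat: np.ndarray
    mu0_hat: np.ndarray
    W: np.ndarray
    dispersion: float
    family: str


def fit_null_glm(X: np.ndarray, Y: np.ndarray, family: str = "gaussian") -> NullFit:
    """Fit the GLM under H0: no genotype effect.

    Gaussian phenotypes use ordinary least squares with ML dispersion
    (sum of squared residuals over n); binomial phenotypes use IRLS
    (statsmodels) with convergence tolerance 1e-8 and at most 50 iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Y = np.asarray(Y, dtype=float).ravel()
    if family == "gaussian":
        alpha, *_ = np.linalg.lstsq(X, Y, rcond=None)
        mu0 = X @ alpha
        resid = Y - mu0
        dispersion = float(resid @ resid / Y.size)
        W = np.full(Y.size, dispersion)
        return NullFit(alpha, mu0, W, dispersion, family)
    if family == "binomial":
        import statsmodels.api as sm

        model = sm.GLM(Y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=_IRLS_MAXITER, tol=_IRLS_TOL)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise FittingError(f"binomial null fit failed: {exc}") from exc
        if not res.converged:
            raise FittingError(
                f"binomial IRLS did not converge in {_IRLS_MAXITER} iterations"
            )
        mu0 = np.asarray(res.fittedvalues)
        if np.any(mu0 <= 1e-10) or np.any(mu0 >= 1 - 1e-10):
            j = int(np.argmax(np.abs(mu0 - 0.5)))
            raise FittingError(
                f"separation detected in binomial fit (fitted mean for sample {j} "
                "at the boundary); check covariates"
            )
        W = mu0 * (1.0 - mu0)
        return NullFit(np.asarray(res.params), mu0, W, 1.0, family)
    raise ValueError(f"family must be one of {_FAMILIES}")


def _residualized(inputs: ScoreInputs, fit: NullFit) -> np.ndarray:
    """W^1/2-residualised genotypes: columns Gt_j with Gt_j'Gt_k = G_j' P G_k."""
    w = np.asarray(fit.W, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative GLM weights")
    sw = np.sqrt(w)
    A = inputs.X * sw[:, None]
    B = inputs.G * sw[:, None]
    # project B off the column space of A via QR (stable for q up to ~dozens)
    Q, _ = np.linalg.qr(A)
    return B - Q @ (Q.T @ B)


def score_statistics(inputs: ScoreInputs, fit: NullFit) -> ZVector:
    """Per-SNP marginal score statistics under the fitted null."""
    resid0 = inputs.Y - fit.mu0_hat
    if np.allclose(resid0, 0.0):
        # exactly zero residuals (constant phenotype): no evidence anywhere
        return ZVector(np.zeros(inputs.d))
    Gt = _residualized(inputs, fit)
    denom2 = np.einsum("ij,ij->j", Gt, Gt)
    bad = denom2 <= 1e-12
    if np.any(bad):
        j = int(np.flatnonzero(bad)[0])
        raise DegenerateSNPError(
            f"SNP column {j} has no residual variance after projection"
        )
    resid = inputs.Y - fit.mu0_hat
    num = inputs.G.T @ resid
    return ZVector(num / np.sqrt(denom2))


def estimate_correlation(inputs: ScoreInputs, fit: NullFit) -> CorrMatrix:
    """Consistent correlation estimate of the score statistics.

    Off-diagonals are clipped into [-1+eps, 1-eps]; if clipping leaves the
    matrix indefinite (smallest eigenvalue below -1e-8) it is projected to the
    nearest correlation matrix so downstream MVN computations stay valid.
    """
    Gt = _residualized(inputs, fit)
    denom2 = np.einsum("ij,ij->j", Gt, Gt)
    bad = denom2 <= 1e-12
    if np.any(bad):
        j = int(np.flatnonzero(bad)[0])
        raise DegenerateSNPError(
            f"SNP column {j} has no residual variance after projection"
        )
    C = Gt.T @ Gt
    s = 1.0 / np.sqrt(denom2)
    sigma = C * s[:, None] * s[None, :]
    sigma = _regularize(sigma)
    return CorrMatrix(sigma, source="individual_level")


def _regularize(sigma: np.ndarray) -> np.ndarray:
    d = sigma.shape[0]
    off = ~np.eye(d, dtype=bool)
    sigma = sigma.copy()
    sigma[off] = np.clip(sigma[off], -1.0 + CORR_EPS, 1.0 - CORR_EPS)
    np.fill_diagonal(sigma, 1.0)
    sigma = 0.5 * (sigma + sigma.T)
    if d > 1:
        wmin = float(np.linalg.eigvalsh(sigma)[0])
        if wmin < -1e-8:
            sigma = nearest_correlation(sigma)
            sigma[off] = np.clip(sigma[off], -1.0 + CORR_EPS, 1.0 - CORR_EPS)
            np.fill_diagonal(sigma, 1.0)
    return sigma


def nearest_correlation(sigma: np.ndarray, threshold: float = 1e-8) -> np.ndarray:
    """Nearest correlation matrix by alternating projections (statsmodels)."""
    from statsmodels.stats.correlation_tools import corr_nearest

    return np.asarray(corr_nearest(sigma, threshold=threshold, n_fact=1000))
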