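"""Distribution of the exceedance count S(t) under correlated z-statistics.

For a set of d statistics ``Z ~ MVN(mu 1, Sigma)``, the thresholding function

    S(t) = sum_j 1(|Z_j| >= t)

has a Binomial(d, pi) distribution under independence, with
``pi = P(|Z| >= t)``.  Under correlation, S(t) is overdispersed; following the
generalized goodness-of-fit framework, it is modelled by an extended
beta-binomial whose mean equals the exact MVN mean ``d pi`` and whose variance
matches the exact MVN variance

    Var S(t) = d pi (1 - pi) + sum_{j != k} [ P(|Z_j|>=t, |Z_k|>=t) - pi^2 ].

The pairwise covariance term is evaluated with a Mehler (Hermite tensor)
expansion of the bivariate-normal covariance in powers of the pair
correlation, which is numerically stable down to rare-event thresholds where
direct bivariate-CDF formulas lose all relative precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, ndtr

from .containers import CorrMatrix

__all__ = [
    "ExceedanceModel",
    "CorrelatedExceedance",
    "correlated_count_model",
    "exceedance_count",
    "solve_shifted_mean",
    "two_sided_pi",
    "ebb_logpmf",
    "pair_indicator_cov",
    "solve_effective_rho",
    "factor_exceedance_prob",
]

#: series truncation: absolute tail below this is ignored
_SERIES_TOL = 1e-14
_MAX_TERMS = 2000


def _sf(x):
    return ndtr(-np.asarray(x, dtype=float))


def two_sided_pi(t, mu=0.0):
    """P(|Z| >= t) for Z ~ N(mu, 1): survival of the folded shifted normal."""
    t = np.asarray(t, dtype=float)
    return _sf(t - mu) + ndtr(-t - np.asarray(mu, dtype=float))


def exceedance_count(z, t: float) -> int:
    """S(t): number of statistics with |z_j| >= t."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    zv = np.asarray(getattr(z, "z", z), dtype=float)
    return int(np.sum(np.abs(zv) >= t))


def solve_shifted_mean(j, d, t):
    """Shifted mean mu > 0 with exceedance probability j/d at threshold t.

    Solves ``j/d = 1 - {Phi(t - mu) - Phi(-t - mu)}`` by bisection; the left
    side is strictly increasing in mu.  Requires the qualifying condition
    ``2 * Phibar(t) < j/d`` (otherwise the root would be negative).
    Vectorised over ``j`` and ``t``.
    """
    j = np.asarray(j, dtype=float)
    t = np.asarray(t, dtype=float)
    target = j / float(d)
    if np.any(two_sided_pi(t) >= target):
        raise ValueError("qualifying condition 2*Phibar(t) < j/d violated")
    lo = np.zeros(np.broadcast(j, t).shape)
    hi = np.broadcast_to(t + 15.0, lo.shape).copy()
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        high = two_sided_pi(t, mid) >= target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    out = 0.5 * (lo + hi)
    return out if out.shape else float(out)


def ebb_logpmf(s, n, pi, rho):
    """Log pmf of the extended beta-binomial ``EBB(n, pi, rho)``.

    With ``gamma = rho / (1 - rho)``,

        P(S=s) = C(n,s) prod_{i<s}(pi + i g) prod_{i<n-s}(1 - pi + i g)
                 / prod_{i<n}(1 + i g).

    ``rho = 0`` recovers Binomial(n, pi) exactly.  Vectorised over ``s``.
    """
    s = np.atleast_1d(np.asarray(s, dtype=int))
    n = int(n)
    if np.any((s < 0) | (s > n)):
        raise ValueError("s out of range")
    pi = float(pi)
    rho = float(rho)
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must be in (0,1)")
    if rho < 1e-14:
        i = np.arange(n, dtype=float)
        cum_p = np.concatenate(([0.0], np.cumsum(np.full(n, np.log(pi)))))
        cum_q = np.concatenate(([0.0], np.cumsum(np.full(n, np.log1p(-pi)))))
        cum_d = np.zeros(n + 1)
    else:
        g = rho / (1.0 - rho)
        i = np.arange(n, dtype=float)
        cum_p = np.concatenate(([0.0], np.cumsum(np.log(pi + i * g))))
        cum_q = np.concatenate(([0.0], np.cumsum(np.log(1.0 - pi + i * g))))
        cum_d = np.concatenate(([0.0], np.cumsum(np.log1p(i * g))))
    logc = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
    out = logc + cum_p[s] + cum_q[n - s] - cum_d[n]
    return out if out.shape != (1,) or np.ndim(s) else out[0]


def _one_factor_strength(sigma: np.ndarray, iters: int = 20) -> float:
    """Average |lambda_i lambda_j| over pairs for a one-factor fit of sigma.

    Iteratively fits ``sigma ~ lambda lambda' + diag(psi)`` (principal-factor
    iterations); returns ``((sum|l|)^2 - sum l^2) / (d (d-1))`` clipped to
    [0, 0.99].  Exact exchangeable correlation rho returns rho; a sign-flipped
    exchangeable matrix returns the same value; near-full-rank diffuse noise
    returns nearly 0.
    """
    d = sigma.shape[0]
    if d < 2:
        return 0.0
    R = sigma.copy()
    lam = np.full(d, np.sqrt(max(np.abs(sigma - np.eye(d)).max(), 1e-4)))
    # start from the column with the strongest off-diagonal mass; the all-ones
    # vector can be exactly orthogonal to the leading eigenvector
    off2 = (sigma * sigma).sum(axis=0) - 1.0
    v = sigma[:, int(np.argmax(off2))].copy()
    if np.linalg.norm(v) <= 0:
        return 0.0
    v = v / np.linalg.norm(v)
    for _ in range(iters):
        np.fill_diagonal(R, np.clip(lam * lam, 0.0, 1.0))
        for _ in range(8):  # leading eigenpair by power iteration
            v = R @ v
            nrm = np.linalg.norm(v)
            if nrm <= 0:
                return 0.0
            v = v / nrm
        lead = max(float(v @ (R @ v)), 0.0)
        lam = np.clip(np.abs(v) * np.sqrt(lead), 0.0, 1.0)
    num = lam.sum() ** 2 - float(lam @ lam)
    return float(np.clip(num / (d * (d - 1.0)), 0.0, 0.99))


class ExceedanceModel:
    """The count model for S(t) at one fixed threshold.

    ``rho_t`` is the extended-beta-binomial overdispersion that matches the
    exact MVN variance of S(t); it is 0 under independence, where the model is
    exactly Binomial(d, pi).
    """

    def __init__(self, t: float, d: int, pi: float, variance: float):
        self.t = float(t)
        self.d = int(d)
        self.pi = float(pi)
        self.variance = float(variance)
        base = d * pi * (1.0 - pi)
        if d > 1 and base > 0:
            rho = (variance - base) / (base * (d - 1))
        else:
            rho = 0.0
        # negative estimated overdispersion is clamped (model stays binomial)
        self.rho_t = float(min(max(rho, 0.0), 1.0 - 1e-8))

    def logpmf(self, s):
        return ebb_logpmf(s, self.d, self.pi, self.rho_t)

    def pmf(self, s):
        return np.exp(self.logpmf(s))


class CorrelatedExceedance:
    """Moment machinery for S(t) given a correlation matrix.

    Pairwise covariances are summed through power sums of the off-diagonal
    correlations, so evaluation at a point costs O(N_terms) independent of d.
    """

    def __init__(self, sigma: CorrMatrix | np.ndarray):
        if not isinstance(sigma, CorrMatrix):
            sigma = CorrMatrix(np.asarray(sigma))
        self.d = sigma.d
        off = sigma.offdiag()
        rmax = float(np.max(np.abs(off))) if off.size else 0.0
        rmax = min(rmax, 1.0 - 1e-6)
        #: average pair correlation explained by a one-factor fit to Sigma,
        #: on the magnitude scale (|z| exceedance events are even in the pair
        #: correlation, so loading signs are irrelevant); diffuse full-rank
        #: noise contributes almost nothing here
        self.factor_r = _one_factor_strength(sigma.sigma) if off.size else 0.0
        if off.size == 0 or rmax == 0.0:
            self.n_terms = 0
            self.power_sums = np.zeros(0)
        else:
            n_terms = int(np.ceil(np.log(_SERIES_TOL) / np.log(rmax))) if rmax < 1 else _MAX_TERMS
            self.n_terms = int(min(max(n_terms, 40), _MAX_TERMS))
            # S_n = sum_{j != k} rho_jk^n  (both orderings)
            p = off.copy()
            sums = np.empty(self.n_terms)
            for n in range(self.n_terms):
                sums[n] = 2.0 * p.sum()
                p *= off
            self.power_sums = sums

    # -- moments ---------------------------------------------------------

    def pi(self, t, mu=0.0):
        return two_sided_pi(t, mu)

    def pair_sum(self, t, mu=0.0):
        """sum_{j != k} Cov{1(|Z_j|>=t), 1(|Z_k|>=t)} for common mean mu.

        Mehler expansion: the covariance of a pair with correlation r is
        ``sum_{n>=1} r^n c_n^2 / n!`` with Hermite coefficients
        ``c_n = phi(a) He_{n-1}(a) - phi(c) He_{n-1}(c)``, a = t - mu,
        c = -t - mu.  Summing over pairs turns r^n into the stored power sums.
        """
        t = np.asarray(t, dtype=float)
        mu = np.asarray(mu, dtype=float)
        a, c = t - mu, -t - mu
        out = np.zeros(np.broadcast(a, c).shape)
        if self.n_terms == 0:
            return out if out.shape else float(out)
        # u_n(x) = phi(x) He_n(x) / sqrt(n!); contribution of order n is
        # S_n (u_{n-1}(a) - u_{n-1}(c))^2 / n
        phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        ua_prev, uc_prev = np.zeros_like(out), np.zeros_like(out)
        ua = phi(a) * np.ones_like(out)
        uc = phi(c) * np.ones_like(out)
        for n in range(1, self.n_terms + 1):
            diff = ua - uc
            out += self.power_sums[n - 1] * diff * diff / n
            if n < self.n_terms:
                rn = np.sqrt(n)
                ua_next = (a * ua - np.sqrt(n - 1) * ua_prev) / rn
                uc_next = (c * uc - np.sqrt(n - 1) * uc_prev) / rn
                ua_prev, uc_prev, ua, uc = ua, uc, ua_next, uc_next
        return out if out.shape else float(out)

    def var(self, t, mu=0.0):
        p = self.pi(t, mu)
        return self.d * p * (1.0 - p) + self.pair_sum(t, mu)

    def rho(self, t, mu=0.0):
        """EBB overdispersion matching the exact variance at (t, mu)."""
        p = self.pi(t, mu)
        base = self.d * p * (1.0 - p)
        out = np.zeros(np.broadcast(np.asarray(t), np.asarray(mu)).shape)
        if self.d > 1:
            with np.errstate(divide="ignore", invalid="ignore"):
                r = self.pair_sum(t, mu) / (base * (self.d - 1))
            r = np.where(np.isfinite(r), r, 0.0)
            out = np.clip(r, 0.0, 1.0 - 1e-8)
        return out if out.shape else float(out)

    def model_at(self, t: float, mu: float = 0.0) -> ExceedanceModel:
        return ExceedanceModel(t, self.d, float(self.pi(t, mu)), float(self.var(t, mu)))

    # -- fast interpolated overdispersion --------------------------------

    _T_MAX = 46.0

    def _build_rho_interp(self) -> None:
        from scipy.interpolate import RectBivariateSpline

        tg = np.linspace(0.0, self._T_MAX, 120)
        mg = np.linspace(0.0, self._T_MAX, 80)
        T, M = np.meshgrid(tg, mg, indexing="ij")
        R = np.asarray(self.rho(T.ravel(), M.ravel())).reshape(T.shape)
        self._rho_spline = RectBivariateSpline(tg, mg, R, kx=3, ky=3)

    def rho_interp(self, t, mu=0.0):
        """Spline-cached rho(t, mu); exact 0 under independence."""
        t = np.asarray(t, dtype=float)
        mu = np.broadcast_to(np.asarray(mu, dtype=float), t.shape)
        if self.n_terms == 0:
            out = np.zeros(t.shape)
            return out if out.shape else float(out)
        if not hasattr(self, "_rho_spline"):
            self._build_rho_interp()
        tt = np.clip(t, 0.0, self._T_MAX)
        mm = np.clip(mu, 0.0, self._T_MAX)
        out = np.clip(self._rho_spline(tt.ravel(), mm.ravel(), grid=False), 0.0, 1.0 - 1e-8)
        out = out.reshape(t.shape)
        return out if out.shape else float(out)


def correlated_count_model(t: float, sigma: CorrMatrix) -> ExceedanceModel:
    """Extended beta-binomial model for S(t) conditional on Sigma."""
    return CorrelatedExceedance(sigma).model_at(t)


def _mehler_coefficients(t, mu=0.0, n_terms: int = 300):
    """Coefficients k_n with Cov-pair(r) = sum_n k_n r^n; shape (n_terms, K)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    mu = np.asarray(mu, dtype=float)
    a, c = t - mu, -t - mu
    phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    ua_prev = np.zeros_like(a)
    uc_prev = np.zeros_like(c)
    ua, uc = phi(a), phi(c)
    coef = np.empty((n_terms, t.size))
    for n in range(1, n_terms + 1):
        diff = ua - uc
        coef[n - 1] = diff * diff / n
        if n < n_terms:
            rn = np.sqrt(n)
            ua_next = (a * ua - np.sqrt(n - 1) * ua_prev) / rn
            uc_next = (c * uc - np.sqrt(n - 1) * uc_prev) / rn
            ua_prev, uc_prev, ua, uc = ua, uc, ua_next, uc_next
    return coef


def pair_indicator_cov(t, r, mu=0.0, n_terms: int = 300):
    """Cov{1(|Z_1|>=t), 1(|Z_2|>=t)} for a bivariate normal pair.

    Mehler series in the pair correlation ``r``; vectorised over ``t`` and
    ``r`` jointly.  Used to calibrate effective one-factor correlations.
    """
    coef = _mehler_coefficients(t, mu, n_terms)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    powers = np.power(r[None, :], np.arange(1, n_terms + 1)[:, None])
    out = np.einsum("nk,nk->k", coef, powers)
    return out if np.ndim(t) or np.ndim(r) else float(out[0])


def solve_effective_rho(t, target_cov, r_max: float = 0.99, n_terms: int = 300):
    """Effective exchangeable correlation with given pair-indicator covariance.

    For each threshold t_k, finds r_k in [0, r_max] with
    ``pair_indicator_cov(t_k, r_k) = target_cov_k`` (monotone in r); targets
    at or below 0 give r = 0, unattainably large targets give r_max.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    target = np.atleast_1d(np.asarray(target_cov, dtype=float))
    coef = _mehler_coefficients(t, 0.0, n_terms)

    def cov_at(r):
        powers = np.power(r[None, :], np.arange(1, n_terms + 1)[:, None])
        return np.einsum("nk,nk->k", coef, powers)

    lo = np.zeros_like(t)
    hi = np.full_like(t, r_max)
    attain = cov_at(hi) >= target
    for _ in range(42):
        mid = 0.5 * (lo + hi)
        high = cov_at(mid) >= target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    r = 0.5 * (lo + hi)
    r = np.where(target <= 0.0, 0.0, np.where(attain, r, r_max))
    return r


def factor_exceedance_prob(t, r, x):
    """P(|Z| >= t | W = x) under the one-factor model Z = sqrt(r) W + e.

    ``t`` and ``r`` are per-threshold vectors, ``x`` the latent factor values;
    returns an array of shape (len(t), len(x)).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
    r = np.atleast_1d(np.asarray(r, dtype=float))[:, None]
    x = np.atleast_1d(np.asarray(x, dtype=float))[None, :]
    s = np.sqrt(np.clip(r, 0.0, 1.0 - 1e-12))
    denom = np.sqrt(np.clip(1.0 - r, 1e-12, 1.0))
    return _sf((t - s * x) / denom) + ndtr((-t - s * x) / denom)
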