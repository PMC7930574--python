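"""Random-intercept linear mixed model via REML, with Satterthwaite df.

The model is y = Xβ + Zu + ε with one random intercept per cluster
(subject), u_i ~ N(0, τ²) and ε ~ N(0, σ²).  For this structure the
marginal covariance of cluster i is V_i = σ²(I + λJ) with λ = τ²/σ², which
admits closed forms:

    V_i⁻¹ = (1/σ²)(I − w_i J),   w_i = λ / (1 + m_i λ)
    log|V_i| = m_i log σ² + log(1 + m_i λ)

so the REML criterion reduces to a one-dimensional profile over λ with σ²
solved analytically — orders of magnitude faster than a generic mixed-model
optimizer, which matters because the subject-level bootstrap refits the
model inside every replicate.  Cluster contributions enter only through
per-cluster sufficient statistics (XᵀX, Xᵀ1, Xᵀy, 1ᵀy, yᵀy), so resampling
clusters with replacement is a cheap re-summation of precomputed blocks.

Satterthwaite degrees of freedom for a contrast c use the standard
variance-of-variance approximation

    df = 2 g(θ̂)² / (∇g ᵀ I(θ̂)⁻¹ ∇g),   g(θ) = c ᵀ Var(β̂; θ) c,

with θ = (σ², τ²), I the observed REML information (numeric Hessian) and
∇g a numeric gradient.  When the random-intercept variance collapses to the
boundary the model degenerates to OLS and df = n − p is used, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DegenerateDataError

__all__ = ["RandomInterceptREML", "REMLResult"]

_LAM_TINY = 1e-8


@dataclass
class REMLResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    lam: float
    loglik: float
    n_obs: int
    n_clusters: int
    n_params: int
    converged: bool
    singular: bool  # random-intercept variance at (or numerically at) zero

    def contrast(self, c) -> tuple[float, float]:
        """(estimate, standard error) of cᵀβ."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        return est, se


class RandomInterceptREML:
    """REML fitter for a fixed design, supporting cluster re-weighting.

    Parameters
    ----------
    X : (n, p) fixed-effects design matrix
    y : (n,) response
    clusters : (n,) integer cluster labels (0..S-1, any order)
    """

    def __init__(self, X, y, clusters):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        clusters = np.asarray(clusters)
        if X.ndim != 2 or len(y) != X.shape[0] or len(clusters) != X.shape[0]:
            raise ValueError("X, y and clusters must have matching first dimension")
        labels, inv = np.unique(clusters, return_inverse=True)
        S = labels.size
        p = X.shape[1]
        self.p = p
        self.n_total = X.shape[0]
        # per-cluster sufficient statistics, stacked
        self.XtX = np.zeros((S, p, p))
        self.xbar = np.zeros((S, p))
        self.Xty = np.zeros((S, p))
        self.ybar = np.zeros(S)
        self.yty = np.zeros(S)
        self.m = np.zeros(S)
        for s in range(S):
            sel = inv == s
            Xi, yi = X[sel], y[sel]
            self.XtX[s] = Xi.T @ Xi
            self.xbar[s] = Xi.sum(axis=0)
            self.Xty[s] = Xi.T @ yi
            self.ybar[s] = yi.sum()
            self.yty[s] = yi @ yi
            self.m[s] = sel.sum()
        self.S = S
        self.labels = labels

    # -- internals ---------------------------------------------------------

    def _sums(self, idx):
        """Summed blocks over a multiset of cluster indices (with repeats)."""
        if idx is None:
            idx = np.arange(self.S)
        idx = np.asarray(idx)
        m = self.m[idx]
        return {
            "XtX": self.XtX[idx].sum(axis=0),
            "Xty": self.Xty[idx].sum(axis=0),
            "yty": self.yty[idx].sum(),
            "xbar": self.xbar[idx],
            "ybar": self.ybar[idx],
            "m": m,
            "n": float(m.sum()),
            "S": idx.size,
        }

    @staticmethod
    def _assemble(sums, lam):
        """A(λ), b(λ), q_yy(λ) and Σ log(1 + m_i λ)."""
        w = lam / (1.0 + sums["m"] * lam)
        A = sums["XtX"] - np.einsum("s,sp,sq->pq", w, sums["xbar"], sums["xbar"])
        b = sums["Xty"] - (w * sums["ybar"]) @ sums["xbar"]
        q = sums["yty"] - float(w @ (sums["ybar"] ** 2))
        logdet_v = float(np.sum(np.log1p(sums["m"] * lam)))
        return A, b, q, logdet_v

    def _profile_neg2_reml(self, lam, sums):
        """−2·profiled REML criterion (σ² solved out), up to a constant."""
        A, b, q, logdet_v = self._assemble(sums, lam)
        n, p = sums["n"], self.p
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, b)
        Q = q - float(b @ beta)
        if Q <= 0:
            return np.inf
        sigma2 = Q / (n - p)
        return (n - p) * np.log(sigma2) + logdet_v + logdet_a

    def neg2_reml(self, sigma2, tau2, idx=None):
        """Full −2 REML log-likelihood at θ = (σ², τ²), up to a constant."""
        sums = self._sums(idx)
        lam = tau2 / sigma2
        A, b, q, logdet_v = self._assemble(sums, lam)
        n, p = sums["n"], self.p
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, b)
        Q = q - float(b @ beta)
        return (n - p) * np.log(sigma2) + logdet_v + logdet_a + Q / sigma2

    # -- fitting -----------------------------------------------------------

    def fit(self, idx=None) -> REMLResult:
        """REML fit over all clusters, or the multiset ``idx`` of clusters."""
        sums = self._sums(idx)
        n, p = sums["n"], self.p
        if n <= p:
            raise DegenerateDataError(f"{n:.0f} observations cannot identify {p} fixed effects")

        def obj(rho):
            return self._profile_neg2_reml(np.exp(rho), sums)

        res = optimize.minimize_scalar(obj, bounds=(-15.0, 8.0), method="bounded",
                                       options={"xatol": 1e-9})
        if not res.success:
            raise ConvergenceError("REML profile optimization failed",
                                   optimizer_message=getattr(res, "message", None))
        lam = float(np.exp(res.x))
        crit = float(res.fun)
        crit0 = self._profile_neg2_reml(0.0, sums)
        if crit0 <= crit:
            lam, crit = 0.0, float(crit0)
        if not np.isfinite(crit):
            raise DegenerateDataError("REML criterion is not finite (zero-variance response?)")
        A, b, q, _ = self._assemble(sums, lam)
        beta = np.linalg.solve(A, b)
        Q = q - float(b @ beta)
        sigma2 = Q / (n - p)
        if sigma2 <= 0 or not np.isfinite(sigma2):
            raise DegenerateDataError("residual variance is not positive")
        tau2 = lam * sigma2
        cov_beta = np.linalg.inv(A) * sigma2
        return REMLResult(
            beta=beta, cov_beta=cov_beta, sigma2=float(sigma2), tau2=float(tau2),
            lam=lam, loglik=-0.5 * crit, n_obs=int(n), n_clusters=int(sums["S"]),
            n_params=p, converged=True, singular=lam <= _LAM_TINY,
        )

    # -- inference ---------------------------------------------------------

    def _contrast_var(self, c, sigma2, tau2, sums):
        A, _, _, _ = self._assemble(sums, tau2 / sigma2)
        return float(c @ np.linalg.solve(A, c)) * sigma2

    def satterthwaite_df(self, result: REMLResult, c, idx=None) -> tuple[float, bool]:
        """(df, approximate) for the contrast cᵀβ.

        ``approximate`` is True when the Satterthwaite machinery was
        unavailable (boundary variance or ill-conditioned information) and
        the residual df n − p was used instead.
        """
        c = np.asarray(c, dtype=float)
        sums = self._sums(idx)
        n, p = sums["n"], self.p
        resid_df = n - p
        if result.singular:
            return float(resid_df), True
        theta = np.array([result.sigma2, result.tau2])
        steps = np.maximum(1e-4 * theta, 1e-10)

        def g(th):
            return self._contrast_var(c, th[0], th[1], sums)

        def ll(th):
            return self.neg2_reml(th[0], th[1], idx)

        grad = np.zeros(2)
        H = np.zeros((2, 2))
        for j in range(2):
            ej = np.zeros(2)
            ej[j] = steps[j]
            grad[j] = (g(theta + ej) - g(theta - ej)) / (2 * steps[j])
        f0 = ll(theta)
        for j in range(2):
            for k in range(j, 2):
                ej = np.zeros(2); ej[j] = steps[j]
                ek = np.zeros(2); ek[k] = steps[k]
                if j == k:
                    H[j, j] = (ll(theta + ej) - 2 * f0 + ll(theta - ej)) / steps[j] ** 2
                else:
                    H[j, k] = H[k, j] = (
                        ll(theta + ej + ek) - ll(theta + ej - ek)
                        - ll(theta - ej + ek) + ll(theta - ej - ek)
                    ) / (4 * steps[j] * steps[k])
        # information of −2·loglik is 2×Fisher information; Var(θ̂) ≈ 2 H⁻¹
        try:
            cov_theta = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(resid_df), True
        denom = float(grad @ cov_theta @ grad)
        if not np.isfinite(denom) or denom <= 0:
            return float(resid_df), True
        df = 2.0 * g(theta) ** 2 / denom
        if not np.isfinite(df) or df <= 0:
            return float(resid_df), True
        return float(min(df, resid_df * 10)), False
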