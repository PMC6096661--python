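"""Random-effects Stage 1: multivariate meta-analysis of correlations.

Each study's observed correlation vector r_i is modeled as

    r_i ~ Normal( mu_i,  V_i + T^2 )        (observed subvector thereof)

where mu is the population mean correlation vector, V_i the known
within-study sampling covariance (from :mod:`masem.sampling`, scaled by
1/n_i) and T^2 the between-study covariance of the study-level random
deviations.  Estimation is full-information maximum likelihood over all
studies; T^2 may be diagonal (the usual restriction when the number of
studies is modest) or a full PSD matrix via a Cholesky factor.

Working parameterization keeps iterates valid: means through atanh,
diagonal between-study variances through logs, full T^2 through a
Cholesky factor with log-diagonal.  A between-study variance whose
log drops below -15 is reported as the tau^2 = 0 boundary.

The asymptotic covariance of the estimated means — the Stage-2 weight
ingredient — is the inverse of the expected information
sum_i (V_i + T^2)^{-1}, which is exact for the mean block of a normal
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import MasemDataset, unvech, vech, vech_indices
from .sampling import correlation_acov_base

__all__ = ["RandomStage1Result", "pool_random", "i_squared", "RandomLik"]

_LOG_TAU_MIN = -30.0
_LOG_TAU_MAX = 5.0
_BOUNDARY = -15.0
_LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class RandomStage1Result:
    """Pooled random-effects means with between-study covariance."""

    P: np.ndarray
    T2: np.ndarray
    acov: np.ndarray
    i2: np.ndarray
    minus2ll: float
    total_n: int
    converged: bool
    structure: str = "diagonal"
    grad_norm: float = np.nan
    kind: str = field(default="random", repr=False)

    @property
    def r_vec(self) -> np.ndarray:
        return vech(self.P)


def i_squared(tau2: np.ndarray, typical_v: np.ndarray) -> np.ndarray:
    """Proportion of study-level variance: tau^2 / (tau^2 + typical v)."""
    tau2 = np.asarray(tau2, float)
    typical_v = np.asarray(typical_v, float)
    if (typical_v <= 0).any():
        raise ValueError("typical sampling variance must be positive")
    return tau2 / (tau2 + typical_v)


class RandomLik:
    """-2 log-likelihood machinery for one dataset (reusable for joint fits)."""

    def __init__(self, data: MasemDataset, eval_point: str = "pooled"):
        self.data = data
        self.p = data.p
        self.pairs = vech_indices(self.p)
        self.q = len(self.pairs)
        pooled = data.naive_pooled()
        self.r = np.array([s.r_vec for s in data.studies])  # (k, q), NaN = missing
        self.masks = ~np.isnan(self.r)
        self.complete = bool(self.masks.all())
        ns = np.array([s.n for s in data.studies], float)
        if eval_point == "pooled":
            base = correlation_acov_base(pooled)
            self.V = base[None, :, :] / ns[:, None, None]
        elif eval_point == "study":
            mats = []
            for s in data.studies:
                corr = np.where(np.isnan(s.corr), pooled, s.corr)
                mats.append(correlation_acov_base(corr) / s.n)
            self.V = np.stack(mats)
        else:
            raise ValueError("eval_point must be 'pooled' or 'study'")
        self.k = len(data.studies)

    # -- natural-scale value and gradients ------------------------------

    def m2ll_parts(self, mu: np.ndarray, T2: np.ndarray):
        """Returns (-2ll, d/dmu, d/dT2) on the natural scale.

        The T2 gradient is a full symmetric matrix derivative
        d(-2ll)/dT2 (so callers can chain to diagonal or Cholesky
        parameterizations).
        """
        if self.complete:
            Sigma = self.V + T2[None, :, :]
            try:
                L = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            logdet = 2.0 * np.log(np.einsum("kii->ki", L)).sum(axis=1)
            E = self.r - mu[None, :]
            x = np.linalg.solve(Sigma, E[:, :, None])[:, :, 0]
            m2ll = float(np.sum(logdet + np.einsum("ki,ki->k", E, x)) + self.k * self.q * _LN2PI)
            g_mu = -2.0 * x.sum(axis=0)
            invSigma = np.linalg.inv(Sigma)
            A = invSigma - x[:, :, None] * x[:, None, :]
            return m2ll, g_mu, A.sum(axis=0)
        # incomplete: per-study subvectors
        m2ll = 0.0
        g_mu = np.zeros(self.q)
        g_T2 = np.zeros((self.q, self.q))
        for i in range(self.k):
            m = self.masks[i]
            qi = int(m.sum())
            Sigma = self.V[i][np.ix_(m, m)] + T2[np.ix_(m, m)]
            sign, logdet = np.linalg.slogdet(Sigma)
            if sign <= 0:
                return np.inf, None, None
            e = self.r[i, m] - mu[m]
            invSigma = np.linalg.inv(Sigma)
            x = invSigma @ e
            m2ll += logdet + e @ x + qi * _LN2PI
            g_mu[m] += -2.0 * x
            g_T2[np.ix_(m, m)] += invSigma - np.outer(x, x)
        return float(m2ll), g_mu, g_T2

    def acov_means(self, T2: np.ndarray) -> np.ndarray:
        info = np.zeros((self.q, self.q))
        for i in range(self.k):
            m = self.masks[i]
            Sigma = self.V[i][np.ix_(m, m)] + T2[np.ix_(m, m)]
            info[np.ix_(m, m)] += np.linalg.inv(Sigma)
        return np.linalg.inv(info)

    def typical_v(self) -> np.ndarray:
        """Harmonic mean of per-study sampling variances, per pair."""
        out = np.empty(self.q)
        for j in range(self.q):
            obs = self.masks[:, j]
            out[j] = 1.0 / np.mean(1.0 / self.V[obs, j, j])
        return out

    def start_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Means from the n-weighted average; tau^2 by method of moments."""
        mu0 = np.clip(vech(self.data.naive_pooled()), -0.98, 0.98)
        tau0 = np.empty(self.q)
        for j in range(self.q):
            obs = self.masks[:, j]
            rj = self.r[obs, j]
            mom = rj.var(ddof=1) - self.V[obs, j, j].mean() if obs.sum() > 1 else 0.0
            tau0[j] = max(mom, 1e-4)
        return mu0, tau0

    def gls_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form GLS means under T^2 = 0 (fixed-effects limit)."""
        info = np.zeros((self.q, self.q))
        rhs = np.zeros(self.q)
        for i in range(self.k):
            m = self.masks[i]
            W = np.linalg.inv(self.V[i][np.ix_(m, m)])
            info[np.ix_(m, m)] += W
            rhs[m] += W @ self.r[i, m]
        acov = np.linalg.inv(info)
        return acov @ rhs, acov


def _projected_grad(g: np.ndarray, x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> float:
    g = g.copy()
    at_lb = (x <= lb + 1e-10) & (g > 0)
    at_ub = (x >= ub - 1e-10) & (g < 0)
    g[at_lb | at_ub] = 0.0
    return float(np.max(np.abs(g))) if g.size else 0.0


def pool_random(
    data: MasemDataset,
    structure: str = "diagonal",
    eval_point: str = "pooled",
    gtol: float = 1e-4,
    max_restarts: int = 2,
    seed: int = 0,
) -> RandomStage1Result:
    """FIML random-effects pooling of a dataset's correlation vectors.

    ``structure`` selects between-study covariance: "diagonal" (default,
    the common restriction), "full" (Cholesky-parameterized PSD), or
    "zero" (T^2 fixed at 0, closed-form GLS — the fixed-effects limit
    useful for equivalence checks).

    Non-convergence is reported in the result (``converged=False``), not
    raised: the simulation experiment counts such outcomes.
    """
    lik = RandomLik(data, eval_point=eval_point)
    q = lik.q

    if structure == "zero":
        mu, acov = lik.gls_means()
        T2 = np.zeros((q, q))
        m2ll, _, _ = lik.m2ll_parts(mu, T2)
        return RandomStage1Result(
            P=unvech(mu), T2=T2, acov=acov, i2=np.zeros(q), minus2ll=m2ll,
            total_n=data.total_n, converged=True, structure=structure, grad_norm=0.0,
        )

    if structure not in ("diagonal", "full"):
        raise ValueError("structure must be 'diagonal', 'full' or 'zero'")

    if data.k == 1:
        # no between-study information: mean is the single study, tau^2 = 0
        mu = np.clip(lik.r[0], -0.999, 0.999)
        T2 = np.zeros((q, q))
        m2ll, _, _ = lik.m2ll_parts(mu, T2)
        return RandomStage1Result(
            P=unvech(mu), T2=T2, acov=lik.acov_means(T2), i2=np.zeros(q),
            minus2ll=m2ll, total_n=data.total_n, converged=True,
            structure=structure, grad_norm=0.0,
        )

    mu0, tau0 = lik.start_values()
    n_free_tau = q if structure == "diagonal" else q * (q + 1) // 2
    if data.k < n_free_tau:
        warnings.warn(
            f"{data.k} studies for {n_free_tau} between-study (co)variance "
            "parameters; T^2 estimates will be poorly determined",
            stacklevel=2,
        )

    tril = np.tril_indices(q, -1)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        mu = np.tanh(x[:q])
        if structure == "diagonal":
            return mu, np.diag(np.exp(x[q:])), None
        L = np.zeros((q, q))
        L[np.diag_indices(q)] = np.exp(x[q : 2 * q])
        L[tril] = x[2 * q :]
        return mu, L @ L.T, L

    scale = 1.0 / lik.k  # per-study objective keeps gradients O(1) at any k

    def objective(x: np.ndarray):
        mu, T2, L = unpack(x)
        m2ll, g_mu, g_T2 = lik.m2ll_parts(mu, T2)
        if not np.isfinite(m2ll):
            return np.inf, np.zeros_like(x)
        gz = g_mu * (1.0 - mu**2)
        if structure == "diagonal":
            gt = np.diag(g_T2) * np.diag(T2)
            return m2ll * scale, np.concatenate([gz, gt]) * scale
        gL = 2.0 * g_T2 @ L
        g_logdiag = np.diag(gL) * np.diag(L)
        return m2ll * scale, np.concatenate([gz, g_logdiag, gL[tril]]) * scale

    # starting point (for "full", start at the diagonal solution's scale)
    z0 = np.arctanh(mu0)
    t0 = np.log(np.clip(tau0, 1e-6, None))
    if structure == "full":
        diag_fit = pool_random(data, "diagonal", eval_point, gtol, max_restarts, seed)
        z0 = np.arctanh(np.clip(vech(diag_fit.P), -0.999, 0.999))
        t0 = 0.5 * np.log(np.clip(np.diag(diag_fit.T2), 1e-12, None))
        t0 = np.clip(t0, _LOG_TAU_MIN, _LOG_TAU_MAX)
        x0 = np.concatenate([z0, t0, np.zeros(len(tril[0]))])
        lb = np.concatenate([np.full(q, -np.inf), np.full(q, _LOG_TAU_MIN), np.full(len(tril[0]), -np.inf)])
        ub = np.concatenate([np.full(q, np.inf), np.full(q, _LOG_TAU_MAX), np.full(len(tril[0]), np.inf)])
    else:
        x0 = np.concatenate([z0, np.clip(t0, _LOG_TAU_MIN, _LOG_TAU_MAX)])
        lb = np.concatenate([np.full(q, -np.inf), np.full(q, _LOG_TAU_MIN)])
        ub = np.concatenate([np.full(q, np.inf), np.full(q, _LOG_TAU_MAX)])

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        xs = x0 if attempt == 0 else x0 + rng.normal(scale=0.1, size=x0.size)
        res = optimize.minimize(
            objective, xs, jac=True, method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-15, "gtol": 1e-9},
        )
        # gradient criterion relative to the objective magnitude: achievable
        # precision of the per-study -2ll scales with its size
        pg = _projected_grad(res.jac, res.x, lb, ub) / max(1.0, abs(float(res.fun)))
        if best is None or res.fun < best[0].fun - 1e-10:
            best = (res, pg)
        if pg < gtol:
            best = min(best, (res, pg), key=lambda t: t[0].fun)
            break
    res, pg = best

    mu, T2, _ = unpack(res.x)
    if structure == "diagonal":
        logtau = res.x[q:]
        tau2 = np.where(logtau < _BOUNDARY, 0.0, np.exp(logtau))
        T2 = np.diag(tau2)
    else:
        d = res.x[q : 2 * q]
        if (d < _BOUNDARY).any():
            L = np.zeros((q, q))
            L[np.diag_indices(q)] = np.where(d < _BOUNDARY, 0.0, np.exp(d))
            L[tril] = res.x[2 * q :]
            T2 = L @ L.T

    converged = bool(np.isfinite(res.fun) and pg < gtol)
    m2ll = float(res.fun) * lik.k
    acov = lik.acov_means(T2)
    i2 = i_squared(np.diag(T2), lik.typical_v())
    return RandomStage1Result(
        P=unvech(mu), T2=T2, acov=acov, i2=i2, minus2ll=m2ll,
        total_n=data.total_n, converged=converged, structure=structure,
        grad_norm=pg,
    )
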