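"""Fixed-effects Stage 1: pooling correlation matrices under homogeneity.

The fixed-effects model assumes every study estimates one common
population correlation matrix P_F; between-study differences are pure
sampling error.  P_F is estimated by maximum likelihood in a multigroup
model where study i's correlation matrix is modeled as

    Sigma_i = D_i P_F D_i,

with study-specific free positive diagonal scalings D_i (nuisance
parameters that absorb the arbitrary scale of correlation input).  The
discrepancy function

    F = sum_i (N_i - 1) [ ln|Sigma_i| + tr(S_i Sigma_i^{-1})
                          - ln|S_i| - p_i ]

is zero iff every study's matrix is reproduced exactly; its minimum is
the homogeneity chi-square with df = sum_i p_i(p_i-1)/2 - p(p-1)/2.

Optimization runs on an unconstrained reparameterization (off-diagonal
correlations via atanh, scalings via log) so that iterates stay valid.
The asymptotic covariance of vech(P_F) — the Stage-2 weight-matrix
ingredient — is the corresponding block of the inverse observed
information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import MasemDataset, vech, vech_indices
from .fitstats import FitIndexBundle, fit_bundle

__all__ = ["FixedStage1Result", "pool_fixed", "fixed_stage1_df"]


@dataclass
class FixedStage1Result:
    """Pooled fixed-effects correlation matrix with homogeneity test."""

    P: np.ndarray
    acov: np.ndarray | None
    chi2: float
    df: int
    total_n: int
    converged: bool
    fit: FitIndexBundle | None = None
    grad_norm: float = np.nan
    kind: str = field(default="fixed", repr=False)

    @property
    def r_vec(self) -> np.ndarray:
        return vech(self.P)


def fixed_stage1_df(study_patterns: list[int], p: int) -> int:
    """Homogeneity-model degrees of freedom from observed-variable counts.

    Each study contributes p_i(p_i-1)/2 observed correlations; the pooled
    model estimates p(p-1)/2 of them.
    """
    if any(pi > p for pi in study_patterns):
        raise ValueError("a study cannot observe more variables than declared")
    return sum(pi * (pi - 1) // 2 for pi in study_patterns) - p * (p - 1) // 2


def _study_blocks(data: MasemDataset) -> list[dict]:
    """Per-study complete submatrices after row/column deletion.

    A study's block covers the largest variable subset on which its
    correlation matrix is complete; variables with missing pairs are
    dropped greedily (most-missing first).
    """
    blocks = []
    for s in data.studies:
        obs = ~np.isnan(s.corr)
        keep = [v for v in range(data.p) if obs[v].sum() > 1 or obs[v, v]]
        keep = [v for v in keep if any(obs[v, u] for u in range(data.p) if u != v)]
        # greedy deletion until the submatrix is complete
        while True:
            sub = s.corr[np.ix_(keep, keep)]
            miss = np.isnan(sub).sum(axis=0)
            if miss.sum() == 0:
                break
            keep.pop(int(np.argmax(miss)))
        if len(keep) < 2:
            continue
        S = s.corr[np.ix_(keep, keep)]
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError(f"study {s.study_id}: correlation matrix not positive definite")
        blocks.append(
            {"study_id": s.study_id, "vars": keep, "S": S, "w": s.n - 1.0, "logdetS": logdet}
        )
    return blocks


class _FixedLik:
    """F and its gradient; batched when all studies observe all variables."""

    def __init__(self, data: MasemDataset):
        self.p = data.p
        self.pairs = vech_indices(self.p)
        self.q = len(self.pairs)
        self.blocks = _study_blocks(data)
        if not self.blocks:
            raise ValueError("no study contributes a usable correlation block")
        self.complete = all(len(b["vars"]) == self.p for b in self.blocks)
        self.k = len(self.blocks)
        if self.complete:
            self.S = np.stack([b["S"] for b in self.blocks])
            self.w = np.array([b["w"] for b in self.blocks])
            self.logdetS = np.array([b["logdetS"] for b in self.blocks])
        self.nd = sum(len(b["vars"]) for b in self.blocks)  # nuisance diagonals
        self.w_total = float(sum(b["w"] for b in self.blocks))
        self.dim = self.q + self.nd
        rows, cols = zip(*self.pairs)
        self._rows, self._cols = np.array(rows), np.array(cols)

    # ---- parameter packing: x = [atanh(vech P), log d (per study)] ----

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        P = np.eye(self.p)
        rho = np.tanh(x[: self.q])
        P[self._rows, self._cols] = rho
        P[self._cols, self._rows] = rho
        ds, off = [], self.q
        for b in self.blocks:
            m = len(b["vars"])
            ds.append(np.exp(x[off : off + m]))
            off += m
        return P, ds

    def natural(self, x: np.ndarray) -> np.ndarray:
        """Natural-scale parameters: vech(P) then raw diagonals."""
        P, ds = self.unpack(x)
        return np.concatenate([P[self._rows, self._cols], np.concatenate(ds)])

    def value_grad(self, x: np.ndarray, natural_grad: bool = False):
        """Scaled discrepancy F / sum(N_i - 1) and its gradient.

        The scaling keeps gradient magnitudes O(1) so one absolute
        convergence tolerance works at any total sample size; the
        homogeneity chi-square is the unscaled minimum.
        """
        F_, g_ = self._value_grad_raw(x, natural_grad)
        return F_ / self.w_total, g_ / self.w_total

    def _value_grad_raw(self, x: np.ndarray, natural_grad: bool = False):
        P, ds = self.unpack(x)
        if self.complete:
            D = np.stack(ds)  # (k, p)
            Sigma = P[None, :, :] * D[:, :, None] * D[:, None, :]
            try:
                L = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros(self.dim)
            logdet = 2.0 * np.log(np.einsum("kii->ki", L)).sum(axis=1)
            invSigma = np.linalg.inv(Sigma)
            SinvS = invSigma @ self.S
            tr = np.einsum("kii->k", SinvS)
            F = float(np.sum(self.w * (logdet + tr - self.logdetS - self.p)))
            G = self.w[:, None, None] * (invSigma - invSigma @ self.S @ invSigma)
            DGD = G * D[:, :, None] * D[:, None, :]
            M = DGD.sum(axis=0)
            gP = 2.0 * M[self._rows, self._cols]
            GDP = (G * D[:, None, :]) @ P
            gD = 2.0 * np.einsum("kii->ki", GDP)  # dF/dD
            if natural_grad:
                return F, np.concatenate([gP, gD.ravel()])
            gz = gP * (1.0 - np.tanh(x[: self.q]) ** 2)
            return F, np.concatenate([gz, (gD * D).ravel()])
        # general (incomplete) path: loop over study blocks
        F = 0.0
        gP_mat = np.zeros((self.p, self.p))
        gDs = []
        for b, d in zip(self.blocks, ds):
            idx = b["vars"]
            Psub = P[np.ix_(idx, idx)]
            Sigma = Psub * np.outer(d, d)
            sign, logdet = np.linalg.slogdet(Sigma)
            if sign <= 0:
                return np.inf, np.zeros(self.dim)
            invSigma = np.linalg.inv(Sigma)
            F += b["w"] * (
                logdet + np.trace(invSigma @ b["S"]) - b["logdetS"] - len(idx)
            )
            G = b["w"] * (invSigma - invSigma @ b["S"] @ invSigma)
            DGD = G * np.outer(d, d)
            gP_mat[np.ix_(idx, idx)] += DGD
            gDs.append(2.0 * np.diag((G * d[None, :]) @ Psub))
        gP = 2.0 * gP_mat[self._rows, self._cols]
        gD = np.concatenate(gDs)
        if natural_grad:
            return float(F), np.concatenate([gP, gD])
        gz = gP * (1.0 - np.tanh(x[: self.q]) ** 2)
        dvec = np.concatenate(ds)
        return float(F), np.concatenate([gz, gD * dvec])

    def start(self, P0: np.ndarray, jitter: float = 0.0, rng=None) -> np.ndarray:
        z = np.arctanh(np.clip(P0[self._rows, self._cols], -0.99, 0.99))
        x = np.concatenate([z, np.zeros(self.nd)])
        if jitter > 0:
            x = x + rng.normal(scale=jitter, size=x.size)
        return x


def _observed_info(lik: _FixedLik, x_opt: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Observed information (0.5 * Hessian of F) on the natural scale."""
    theta = lik.natural(x_opt)
    dim = theta.size
    q = lik.q

    def nat_grad(th: np.ndarray) -> np.ndarray:
        # re-encode natural -> working coordinates
        z = np.arctanh(np.clip(th[:q], -0.999999, 0.999999))
        d = np.log(np.clip(th[q:], 1e-8, None))
        _, g = lik.value_grad(np.concatenate([z, d]), natural_grad=True)
        return g

    H = np.empty((dim, dim))
    for a in range(dim):
        e = np.zeros(dim)
        e[a] = step
        H[a] = (nat_grad(theta + e) - nat_grad(theta - e)) / (2 * step)
    H = 0.5 * (H + H.T) * lik.w_total  # undo the objective scaling
    return 0.5 * H


def pool_fixed(
    data: MasemDataset,
    compute_acov: bool = True,
    compute_fit: bool = True,
    max_restarts: int = 3,
    gtol: float = 1e-6,
    seed: int = 0,
) -> FixedStage1Result:
    """Estimate the common correlation matrix P_F and the homogeneity test.

    Convergence requires optimizer success and a gradient max-norm below
    ``gtol`` on the working scale; up to ``max_restarts`` jittered
    restarts are attempted.  ``compute_acov`` controls the (finite
    difference) observed-information inversion, the expensive part.
    """
    if data.k < 2:
        raise ValueError("fixed-effects pooling needs at least 2 studies")
    lik = _FixedLik(data)
    P0 = data.naive_pooled()
    rng = np.random.default_rng(seed)

    best = None
    for attempt in range(max_restarts + 1):
        x0 = lik.start(P0, jitter=0.05 * attempt, rng=rng)
        res = optimize.minimize(
            lik.value_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-15, "gtol": 1e-10},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol:
            break
    res, gnorm = best
    converged = bool(gnorm < gtol and np.isfinite(res.fun))

    P, _ = lik.unpack(res.x)
    chi2 = max(0.0, float(res.fun) * lik.w_total)
    df = fixed_stage1_df([len(b["vars"]) for b in lik.blocks], data.p)

    acov = None
    if compute_acov:
        H = _observed_info(lik, res.x)
        cov_all = np.linalg.inv(H)
        acov = cov_all[: lik.q, : lik.q]
        acov = 0.5 * (acov + acov.T)

    fit = None
    if compute_fit:
        # independence baseline: P = I with free scalings, which closes to
        # d = 1, hence chi2_0 = -sum (N_i - 1) ln|S_i|
        chi2_base = float(sum(-b["w"] * b["logdetS"] for b in lik.blocks))
        df_base = sum(len(b["vars"]) * (len(b["vars"]) - 1) // 2 for b in lik.blocks)
        sr = []
        for b in lik.blocks:
            idx = b["vars"]
            resid = b["S"] - P[np.ix_(idx, idx)]
            tri = np.tril_indices(len(idx), -1)
            sr.append(float(np.sqrt(np.mean(resid[tri] ** 2))))
        fit = fit_bundle(
            chi2=chi2,
            df=df,
            n=data.total_n,
            groups=1,
            chi2_baseline=chi2_base,
            df_baseline=df_base,
            srmr_value=float(np.mean(sr)),
        )

    return FixedStage1Result(
        P=P,
        acov=acov,
        chi2=chi2,
        df=df,
        total_n=data.total_n,
        converged=converged,
        fit=fit,
        grad_norm=gnorm,
    )
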