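"""Large-sample covariance of sample correlation coefficients.

The within-study sampling covariance matrix V_i of a study's vector of
Pearson correlations is treated as known throughout two-stage pooling.
Entries follow the classical large-sample (Olkin–Siotani) result: for
pairs (i,j) and (k,l), evaluated at a population correlation matrix rho,

    n * Cov(r_ij, r_kl) =
        0.5 * rho_ij rho_kl (rho_ik^2 + rho_il^2 + rho_jk^2 + rho_jl^2)
        + rho_ik rho_jl + rho_il rho_jk
        - (rho_ij rho_ik rho_il + rho_ij rho_jk rho_jl
           + rho_kl rho_ik rho_jk + rho_kl rho_il rho_jl)

with the variance special case Var(r_ij) = (1 - rho_ij^2)^2 / n.

Because the expression scales exactly as 1/n, the n-free "base" matrix is
computed once per evaluation point and divided by each study's n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import vech_indices

__all__ = ["SamplingCov", "sampling_cov_matrix", "correlation_acov_base"]


@dataclass
class SamplingCov:
    study_id: str
    V: np.ndarray
    basis: list[tuple[int, int]]


def correlation_acov_base(rho: np.ndarray, pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
    """n * Cov of sample correlations at evaluation point ``rho``.

    ``pairs`` defaults to the full strict-lower-triangle basis.  The
    evaluation point must be a valid (positive semi-definite) correlation
    matrix.
    """
    rho = np.asarray(rho, dtype=float)
    p = rho.shape[0]
    if pairs is None:
        pairs = vech_indices(p)
    if not np.allclose(rho, rho.T, atol=1e-10):
        raise ValueError("evaluation point must be symmetric")
    if np.linalg.eigvalsh(rho).min() < -1e-8:
        raise ValueError("evaluation point is not positive semi-definite")

    q = len(pairs)
    V = np.empty((q, q))
    for a in range(q):
        i, j = pairs[a]
        for b in range(a, q):
            k, l = pairs[b]
            r_ij, r_kl = rho[i, j], rho[k, l]
            r_ik, r_il = rho[i, k], rho[i, l]
            r_jk, r_jl = rho[j, k], rho[j, l]
            val = (
                0.5 * r_ij * r_kl * (r_ik**2 + r_il**2 + r_jk**2 + r_jl**2)
                + r_ik * r_jl
                + r_il * r_jk
                - (
                    r_ij * r_ik * r_il
                    + r_ij * r_jk * r_jl
                    + r_kl * r_ik * r_jk
                    + r_kl * r_il * r_jl
                )
            )
            V[a, b] = V[b, a] = val
    return V


def sampling_cov_matrix(
    rho: np.ndarray,
    n: int,
    pairs: list[tuple[int, int]] | None = None,
    study_id: str = "",
) -> SamplingCov:
    """Sampling covariance V_i of a study's observed correlation vector.

    ``pairs`` restricts the basis to the study's observed pairs
    (row/column deletion — no imputation for missing correlations).
    """
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    rho = np.asarray(rho, dtype=float)
    if pairs is None:
        pairs = vech_indices(rho.shape[0])
    base = correlation_acov_base(rho, list(pairs))
    return SamplingCov(study_id=study_id, V=base / n, basis=list(pairs))
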