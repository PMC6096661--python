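"""Fit indices and chi-square difference tests.

RMSEA with its noncentral-chi-square confidence interval, CFI against a
zero-correlation baseline, SRMR over unique off-diagonal residuals, and
the likelihood-ratio-style chi-square difference test used for nested
equality constraints.

Conventions (documented because different software differs):

* the RMSEA sample size is the total N summed over all groups and no
  multiple-group multiplier is applied;
* the CFI baseline is the model with all correlations zero, fitted with
  the same weight matrix as the target model;
* multigroup SRMR is the unweighted mean of per-group SRMRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FitIndexBundle",
    "rmsea_with_ci",
    "cfi",
    "srmr",
    "chisq_diff",
    "fit_bundle",
]


@dataclass
class FitIndexBundle:
    chi2: float
    df: int
    p_value: float
    rmsea: float | None
    rmsea_ci95: tuple[float, float] | None
    cfi: float | None
    srmr: float | None
    n_used: int
    groups: int = 1

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "rmsea_ci95": list(self.rmsea_ci95) if self.rmsea_ci95 else None,
            "cfi": self.cfi,
            "srmr": self.srmr,
            "n_used": self.n_used,
            "groups": self.groups,
        }


def _ncp_bound(chi2: float, df: int, prob: float) -> float:
    """Noncentrality lambda with chi2 at the given percentile of chi2(df, lambda)."""
    if stats.ncx2.cdf(chi2, df, 1e-10) <= prob:
        return 0.0
    hi = max(chi2, 1.0)
    while stats.ncx2.cdf(chi2, df, hi) > prob:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - pathological
            return hi
    return float(optimize.brentq(lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob, 1e-12, hi))


def rmsea_with_ci(
    chi2: float, df: int, n: int, groups: int = 1
) -> tuple[float, tuple[float, float]]:
    """Point RMSEA and 95% CI by inverting the noncentral chi-square.

    RMSEA = sqrt(max(0, (chi2 - df) / (df (n - 1)))) with n the total
    sample size over all groups; the CI endpoints come from the
    noncentrality values at which chi2 sits at the 97.5th / 2.5th
    percentile.
    """
    if df <= 0:
        raise ValueError("RMSEA undefined for df <= 0")
    if n <= 1:
        raise ValueError("RMSEA needs n > 1")
    scale = df * (n - 1)
    point = float(np.sqrt(max(0.0, (chi2 - df) / scale)))
    lam_lo = _ncp_bound(chi2, df, 0.975)
    lam_hi = _ncp_bound(chi2, df, 0.025)
    return point, (float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale)))


def cfi(chi2: float, df: int, chi2_baseline: float, df_baseline: int) -> float:
    """Comparative fit index against the zero-correlation baseline."""
    if df_baseline <= df:
        raise ValueError("baseline must be nested above the target model")
    excess = max(chi2 - df, 0.0)
    denom = max(chi2_baseline - df_baseline, excess, 0.0)
    if denom == 0.0:
        return 1.0
    return 1.0 - excess / denom


def srmr(pooled: np.ndarray, implied: np.ndarray) -> float:
    """Root mean squared residual over unique off-diagonal elements."""
    pooled = np.asarray(pooled, float)
    implied = np.asarray(implied, float)
    if pooled.shape != implied.shape:
        raise ValueError("matrices must have equal dimensions")
    tri = np.tril_indices(pooled.shape[0], -1)
    resid = (pooled - implied)[tri]
    return float(np.sqrt(np.mean(resid**2)))


def srmr_multigroup(per_group: list[float]) -> float:
    return float(np.mean(per_group))


def chisq_diff(
    chi2_constrained: float,
    df_constrained: int,
    chi2_free: float,
    df_free: int,
    tol: float = 1e-6,
) -> tuple[float, int, float]:
    """Chi-square difference test for nested models on identical data.

    Returns (delta chi2, delta df, upper-tail p).  A negative difference
    beyond numerical tolerance signals an optimization failure in one of
    the fits and raises rather than reporting a bogus test.
    """
    ddf = df_constrained - df_free
    if ddf <= 0:
        raise ValueError("constrained model must have more df than the free model")
    dchi = chi2_constrained - chi2_free
    if dchi < -tol:
        raise ValueError(
            f"constrained chi2 smaller than free chi2 by {-dchi:.3g}: "
            "one of the optimizations did not reach its minimum"
        )
    dchi = max(dchi, 0.0)
    p = float(stats.chi2.sf(dchi, ddf))
    return float(dchi), int(ddf), p


def fit_bundle(
    chi2: float,
    df: int,
    n: int,
    groups: int = 1,
    chi2_baseline: float | None = None,
    df_baseline: int | None = None,
    srmr_value: float | None = None,
) -> FitIndexBundle:
    """Assemble a bundle, leaving indices None where undefined (df = 0)."""
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df > 0:
        point, ci = rmsea_with_ci(chi2, df, n, groups)
    else:
        point, ci = None, None
    cfi_val = None
    if chi2_baseline is not None and df_baseline is not None and df_baseline > df:
        cfi_val = cfi(chi2, df, chi2_baseline, df_baseline)
    return FitIndexBundle(
        chi2=chi2,
        df=df,
        p_value=p_value,
        rmsea=point,
        rmsea_ci95=ci,
        cfi=cfi_val,
        srmr=srmr_value,
        n_used=n,
        groups=groups,
    )
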