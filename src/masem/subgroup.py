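"""Subgroup moderator analysis: the package's core workflow.

Studies are split on a categorical (or dichotomized continuous)
study-level moderator.  Stage 1 is run per subgroup; Stage 2 fits the
structural model jointly across subgroups, once without cross-group
constraints (the baseline whose chi-square and df are the sums of the
per-group fits) and once per hypothesized constraint set with the chosen
labels equated across groups.  Each constraint set is tested against the
baseline with a chi-square difference test at the configured alpha.

Stage-1 equality across subgroups (equal mean correlation matrices, and
for random effects optionally equal between-study variances) is tested
by comparing the -2 log-likelihoods of the joint constrained and free
fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import MasemDataset, vech
from .fitstats import chisq_diff
from .model import MultiGroupModel, RamModel
from .stage1_fixed import pool_fixed
from .stage1_random import _BOUNDARY, _LOG_TAU_MAX, _LOG_TAU_MIN, RandomLik, pool_random, _projected_grad
from .stage2 import Stage2Result, fit_wls_multigroup

__all__ = [
    "SubgroupAnalysis",
    "split_dataset",
    "test_stage1_equality",
    "fit_multigroup_stage2",
    "test_parameter_equality",
    "subgroup_analysis",
]


@dataclass
class SubgroupAnalysis:
    groups: list[str]
    stage1: dict[str, object]
    stage2_free: Stage2Result
    stage2_constrained: dict[str, Stage2Result] = field(default_factory=dict)
    tests: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    alpha: float = 0.05

    def decision(self, name: str) -> str:
        _, _, p = self.tests[name]
        return "rejected" if p < self.alpha else "not rejected"


def split_dataset(
    data: MasemDataset, moderator: dict[str, float], threshold: float,
    labels: tuple[str, str] = ("high", "low"),
) -> MasemDataset:
    """Dichotomize a continuous study-level moderator.

    Studies with moderator value strictly above ``threshold`` get the
    first label, the rest the second (an exact-threshold study falls in
    the second group).  Dichotomization requires this explicit threshold;
    no automatic split search is performed.
    """
    missing = [s.study_id for s in data.studies if s.study_id not in moderator]
    if missing:
        raise ValueError(f"moderator value missing for studies: {missing}")
    studies = []
    for s in data.studies:
        g = labels[0] if moderator[s.study_id] > threshold else labels[1]
        studies.append(type(s)(s.study_id, s.n, s.corr.copy(), group=g))
    out = MasemDataset(data.variables, studies)
    counts = {g: sum(1 for s in studies if s.group == g) for g in labels}
    for g, c in counts.items():
        if c < 2:
            raise ValueError(
                f"subgroup {g!r} has {c} studies (< 2); choose another threshold"
            )
    return out


def _joint_random_fit(
    datasets: list[MasemDataset],
    share_means: bool,
    share_tau: bool,
    gtol: float = 1e-4,
) -> tuple[float, bool]:
    """-2ll of a joint diagonal-T^2 random-effects fit with sharing.

    Returns (minus2ll, converged).  Parameters: one mean vector per
    group (or one shared) and one log-variance vector per group (or one
    shared), on the atanh / log working scales.
    """
    liks = [RandomLik(d) for d in datasets]
    q = liks[0].q
    G = len(liks)
    n_mu = 1 if share_means else G
    n_tau = 1 if share_tau else G

    mu0s, tau0s = zip(*[lk.start_values() for lk in liks])
    mu0 = np.mean(mu0s, axis=0) if share_means else None
    tau0 = np.mean(tau0s, axis=0) if share_tau else None

    x0, lb, ub = [], [], []
    for b in range(n_mu):
        x0.append(np.arctanh(mu0 if share_means else mu0s[b]))
        lb.append(np.full(q, -np.inf))
        ub.append(np.full(q, np.inf))
    for b in range(n_tau):
        t = np.log(np.clip(tau0 if share_tau else tau0s[b], 1e-6, None))
        x0.append(np.clip(t, _LOG_TAU_MIN, _LOG_TAU_MAX))
        lb.append(np.full(q, _LOG_TAU_MIN))
        ub.append(np.full(q, _LOG_TAU_MAX))
    x0, lb, ub = np.concatenate(x0), np.concatenate(lb), np.concatenate(ub)

    scale = 1.0 / sum(lk.k for lk in liks)

    def objective(x: np.ndarray):
        total = 0.0
        grad = np.zeros_like(x)
        for g, lk in enumerate(liks):
            # mean block im; tau blocks follow all mean blocks
            im = 0 if share_means else g
            it = n_mu + (0 if share_tau else g)
            z = x[im * q : (im + 1) * q]
            t = x[it * q : (it + 1) * q]
            mu = np.tanh(z)
            T2 = np.diag(np.exp(t))
            m2ll, g_mu, g_T2 = lk.m2ll_parts(mu, T2)
            if not np.isfinite(m2ll):
                return np.inf, grad
            total += m2ll
            grad[im * q : (im + 1) * q] += g_mu * (1.0 - mu**2)
            grad[it * q : (it + 1) * q] += np.diag(g_T2) * np.exp(t)
        return total * scale, grad * scale

    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-15, "gtol": 1e-9},
    )
    pg = _projected_grad(res.jac, res.x, lb, ub) / max(1.0, abs(float(res.fun)))
    m2ll = float(res.fun) / scale
    return m2ll, bool(np.isfinite(res.fun) and pg < gtol)


def test_stage1_equality(
    data: MasemDataset,
    effects: str = "fixed",
    what: str = "means",
) -> tuple[float, int, float]:
    """Test equality of Stage-1 parameters across subgroups.

    Fixed effects: the constrained model pools all subgroups into one
    homogeneity fit; Delta chi2 = chi2_pooled - sum of per-subgroup chi2
    with df equal to the number of constrained correlations times (G-1).

    Random effects (diagonal T^2): the constrained joint FIML fit shares
    the mean vector ("means") or the between-study variances ("tsq")
    across subgroups; the -2 log-likelihood difference is referred to a
    chi-square with df = constrained quantities times (G-1).
    """
    groups = data.group_levels
    if len(groups) < 2:
        raise ValueError("no subgroup labels (need at least 2 subgroups)")
    subsets = [data.subset(g) for g in groups]
    for g, d in zip(groups, subsets):
        if d.k < 2:
            raise ValueError(f"subgroup {g!r} has fewer than 2 studies")
    q = data.n_pairs
    G = len(groups)

    if effects == "fixed":
        if what != "means":
            raise ValueError("fixed-effects Stage 1 has no T^2 to constrain")
        fits = [pool_fixed(d, compute_acov=False, compute_fit=False) for d in subsets]
        pooled = pool_fixed(data, compute_acov=False, compute_fit=False)
        if not (pooled.converged and all(f.converged for f in fits)):
            raise RuntimeError("a Stage-1 fit did not converge; equality test invalid")
        chi2_free = sum(f.chi2 for f in fits)
        ddf = q * (G - 1)
        return chisq_diff(pooled.chi2, ddf, chi2_free, 0)
    if effects != "random":
        raise ValueError("effects must be 'fixed' or 'random'")
    if what not in ("means", "tsq"):
        raise ValueError("what must be 'means' or 'tsq'")

    free_fits = [pool_random(d, "diagonal") for d in subsets]
    m2ll_free = sum(f.minus2ll for f in free_fits)
    if not all(f.converged for f in free_fits):
        raise RuntimeError("a free Stage-1 fit did not converge; equality test invalid")
    m2ll_con, ok = _joint_random_fit(
        subsets, share_means=(what == "means"), share_tau=(what == "tsq")
    )
    if not ok:
        raise RuntimeError("constrained Stage-1 fit did not converge; equality test invalid")
    ddf = q * (G - 1)
    return chisq_diff(m2ll_con, ddf, m2ll_free, 0)


def fit_multigroup_stage2(
    stage1_per_group: dict[str, object], mgmodel: MultiGroupModel, seed: int = 0
) -> Stage2Result:
    """Joint Stage-2 fit across subgroups (delegates to the WLS engine)."""
    return fit_wls_multigroup(stage1_per_group, mgmodel, seed=seed)


def test_parameter_equality(
    free: Stage2Result, constrained: Stage2Result, alpha: float = 0.05
) -> dict:
    """Moderator test: constrained vs free multigroup Stage-2 fits.

    Both fits must come from the same Stage-1 inputs (otherwise the
    difference test is meaningless) and be nested with more df in the
    constrained model.
    """
    if free.stage1_token != constrained.stage1_token:
        raise ValueError("fits are based on different stage-1 inputs; test invalid")
    dchi, ddf, p = chisq_diff(constrained.chi2, constrained.df, free.chi2, free.df)
    return {
        "delta_chi2": dchi,
        "delta_df": ddf,
        "p_value": p,
        "alpha": alpha,
        "decision": "rejected" if p < alpha else "not rejected",
        "estimates_free": free.theta,
        "estimates_constrained": constrained.theta,
    }


def subgroup_analysis(
    data: MasemDataset,
    model_builder,
    constraint_sets: dict[str, set[str]],
    effects: str = "random",
    structure: str = "diagonal",
    alpha: float = 0.05,
    seed: int = 0,
) -> SubgroupAnalysis:
    """Full subgroup workflow: per-group Stage 1, free and constrained Stage 2.

    ``model_builder`` maps a group label to its :class:`RamModel` (often
    the same syntax for every group); ``constraint_sets`` maps a test
    name to the set of labels equated across groups for that test.
    """
    groups = data.group_levels
    if len(groups) < 2:
        raise ValueError("no subgroup labels (need at least 2 subgroups)")
    stage1 = {}
    for g in groups:
        sub = data.subset(g)
        if sub.k < 2:
            raise ValueError(f"subgroup {g!r} has fewer than 2 studies")
        if effects == "fixed":
            stage1[g] = pool_fixed(sub)
        else:
            stage1[g] = pool_random(sub, structure)
    models = {g: model_builder(g) for g in groups}
    mg_free = MultiGroupModel(groups, models, set())
    stage2_free = fit_wls_multigroup(stage1, mg_free, seed=seed)
    result = SubgroupAnalysis(
        groups=groups, stage1=stage1, stage2_free=stage2_free, alpha=alpha
    )
    for name, labels in constraint_sets.items():
        mg_con = MultiGroupModel(groups, models, set(labels))
        fit_con = fit_wls_multigroup(stage1, mg_con, seed=seed)
        result.stage2_constrained[name] = fit_con
        result.tests[name] = chisq_diff(
            fit_con.chi2, fit_con.df, stage2_free.chi2, stage2_free.df
        )
    return result
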