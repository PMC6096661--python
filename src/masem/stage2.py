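"""Stage 2: weighted least squares fitting of a structural model.

The pooled correlation vector r from Stage 1 carries an asymptotic
covariance matrix; its inverse W is the WLS weight.  Stage 2 minimizes

    F(theta) = (r - rho(theta))' W (r - rho(theta)),

where rho(theta) is the half-vectorized model-implied correlation
matrix.  Because the Stage-1 covariance already reflects the total
sample size, the minimum of F is itself the chi-square test of the
structural model.  Standard errors come from the usual WLS sandwich-free
form sqrt(diag((Delta' W Delta)^{-1})) with Delta the Jacobian of
rho(theta) at the optimum; confidence intervals are Wald.

Multiple groups are handled by stacking residuals: F_total = sum_g F_g,
with parameters carrying a cross-group-equated label forced identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dataset import vech
from .fitstats import FitIndexBundle, fit_bundle, srmr
from .model import (
    MultiGroupModel,
    RamModel,
    implied_matrix,
    model_df,
    remainder_values,
)

__all__ = ["Stage2Result", "fit_wls", "fit_wls_multigroup", "derived_parameter", "saturated_model"]


@dataclass
class Stage2Result:
    theta: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    chi2: float
    df: int
    fit: FitIndexBundle
    weight_source: str
    converged: bool
    vcov: np.ndarray = field(repr=False, default=None)
    param_names: list[str] = field(default_factory=list)
    per_group: dict[str, dict] = field(default_factory=dict)
    remainders: dict[str, float] = field(default_factory=dict)
    stage1_token: tuple = field(default=(), repr=False)  # identity of stage-1 inputs

    def estimate(self, name: str) -> float:
        return self.theta[name]


def saturated_model(obs_vars: list[str]) -> RamModel:
    """All pairwise correlations free: chi2 = 0, df = 0 by construction."""
    from .model import parse_model

    lines = []
    for j, b in enumerate(obs_vars):
        for a in obs_vars[j + 1 :]:
            lines.append(f"{b} ~~ {a}")
    return parse_model("\n".join(lines), obs_vars)


def _start_value(model: RamModel, label: str) -> float:
    for (t, s), cell in model.A.items():
        if cell[0] == "free" and cell[1] == label:
            return 0.3 if s in model.latent_vars else 0.1
    return 0.0


def _apply_sign_convention(groups, name_index: dict[str, int], x: np.ndarray) -> np.ndarray:
    """Flip any factor whose first declared loading is negative.

    A reporting convention only: negating every path touching a latent
    variable (an odd number of times when covariances link two flipped
    factors) leaves the implied matrix, chi-square and |estimates|
    unchanged.
    """
    from collections import Counter

    flip: set[str] = set()  # parity is resolved within each group, then unioned
    for _, _, model, lmap in groups:
        toggles: Counter[str] = Counter()
        for f in model.latent_vars:
            loadings = [
                (t, s) for (t, s), cell in model.A.items()
                if s == f and cell[0] == "free"
            ]
            if not loadings:
                continue
            first = lmap[model.A[loadings[0]][1]]
            if x[name_index[first]] >= 0:
                continue
            for (t, s), cell in model.A.items():
                if cell[0] != "free":
                    continue
                toggles[lmap[cell[1]]] += int(s == f) + int(t == f)
            for (a, b), cell in model.S.items():
                if cell[0] == "free":
                    toggles[lmap[cell[1]]] += int(a == f) + int(b == f)
        flip |= {name for name, count in toggles.items() if count % 2 == 1}
    out = x.copy()
    for name in flip:
        out[name_index[name]] = -out[name_index[name]]
    return out


def _group_setup(stage1, model: RamModel):
    r = stage1.r_vec if hasattr(stage1, "r_vec") else vech(np.asarray(stage1))
    acov = stage1.acov
    if acov is None:
        raise ValueError("stage-1 result has no asymptotic covariance; refit with compute_acov")
    W = np.linalg.inv(acov)
    W = 0.5 * (W + W.T)
    Lw = np.linalg.cholesky(W)
    return np.asarray(r, float), Lw


def _fit_core(
    groups: list[tuple[np.ndarray, np.ndarray, RamModel, dict[str, str]]],
    param_names: list[str],
    df: int,
    weight_source: str,
    total_n: int,
    n_restarts: int = 10,
    seed: int = 0,
    stage1_token: tuple = (),
) -> Stage2Result:
    """Shared single-/multi-group WLS engine.

    ``groups``: per group (r, Lw, model, local-label -> global-name map).
    """
    name_index = {nm: i for i, nm in enumerate(param_names)}
    t = len(param_names)

    def rho_g(theta_vec: np.ndarray, g: int) -> np.ndarray:
        _, _, model, lmap = groups[g]
        local = {lab: theta_vec[name_index[glob]] for lab, glob in lmap.items()}
        return vech(implied_matrix(model, local, check_admissible=False))

    def residuals(theta_vec: np.ndarray) -> np.ndarray:
        out = []
        for g, (r, Lw, _, _) in enumerate(groups):
            out.append(Lw.T @ (r - rho_g(theta_vec, g)))
        return np.concatenate(out)

    # start: role-based heuristic, refined by an unweighted pre-fit
    x0 = np.zeros(t)
    for g, (_, _, model, lmap) in enumerate(groups):
        for lab, glob in lmap.items():
            x0[name_index[glob]] = _start_value(model, lab)

    def unweighted(theta_vec: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [r - rho_g(theta_vec, g) for g, (r, _, _, _) in enumerate(groups)]
        )

    rng = np.random.default_rng(seed)
    if t > 0:
        pre = optimize.least_squares(unweighted, x0, method="lm", xtol=1e-10, ftol=1e-10)
        x0 = pre.x

    best = None
    for attempt in range(n_restarts + 1):
        xs = x0 if attempt == 0 else x0 + rng.normal(scale=0.1, size=t)
        if t == 0:
            f = residuals(np.zeros(0))
            best = (None, np.zeros(0), float(f @ f))
            break
        res = optimize.least_squares(
            residuals, xs, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        chi2 = float(2.0 * res.cost)
        if best is None or chi2 < best[2] - 1e-9:
            best = (res, res.x, chi2)
        if res.success:
            # accept the first successful solve; restarts are for failures
            break
    res, x_opt, chi2 = best
    chi2 = max(0.0, chi2)
    if t > 0:
        x_opt = _apply_sign_convention(groups, name_index, x_opt)

    # admissibility of remainder residuals in every group
    admissible = True
    remainders: dict[str, float] = {}
    for g, (_, _, model, lmap) in enumerate(groups):
        local = {lab: x_opt[name_index[glob]] for lab, glob in lmap.items()}
        rem = remainder_values(model, local)
        for v, val in rem.items():
            key = v if len(groups) == 1 else f"{v}@g{g}"
            remainders[key] = val
            if val < -1e-8:
                admissible = False
    converged = bool((res is None or res.success) and admissible)

    # delta-method covariance from the weighted Jacobian (central differences)
    vcov = np.zeros((t, t))
    if t > 0:
        step = 1e-6
        Jw = np.empty((sum(len(r) for r, *_ in groups), t))
        for a in range(t):
            e = np.zeros(t)
            e[a] = step
            Jw[:, a] = (residuals(x_opt + e) - residuals(x_opt - e)) / (2 * step)
        JtJ = Jw.T @ Jw
        try:
            vcov = np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            vcov = np.full((t, t), np.nan)
            converged = False

    theta = {nm: float(v) for nm, v in zip(param_names, x_opt)}
    se = {nm: float(np.sqrt(max(vcov[i, i], 0.0))) for nm, i in name_index.items()}
    ci95 = {
        nm: (theta[nm] - 1.96 * se[nm], theta[nm] + 1.96 * se[nm]) for nm in param_names
    }

    # fit indices: baseline = all correlations zero under the same weights
    chi2_base, df_base, srmrs, per_group = 0.0, 0, [], {}
    for g, (r, Lw, model, lmap) in enumerate(groups):
        f0 = Lw.T @ r
        chi2_base += float(f0 @ f0)
        df_base += len(r)
        local = {lab: theta[glob] for lab, glob in lmap.items()}
        implied = implied_matrix(model, local, check_admissible=False)
        from .dataset import unvech

        srmr_g = srmr(unvech(r), implied)
        srmrs.append(srmr_g)
        fg = Lw.T @ (r - vech(implied))
        per_group[f"g{g}"] = {"chi2": float(fg @ fg), "srmr": srmr_g}
    fit = fit_bundle(
        chi2=chi2,
        df=df,
        n=total_n,
        groups=len(groups),
        chi2_baseline=chi2_base,
        df_baseline=df_base,
        srmr_value=float(np.mean(srmrs)),
    )

    return Stage2Result(
        theta=theta,
        se=se,
        ci95=ci95,
        chi2=chi2,
        df=df,
        fit=fit,
        weight_source=weight_source,
        converged=converged,
        vcov=vcov,
        param_names=list(param_names),
        per_group=per_group,
        remainders=remainders,
        stage1_token=stage1_token,
    )


def fit_wls(stage1, model: RamModel, seed: int = 0) -> Stage2Result:
    """Fit a structural model to one pooled correlation vector by WLS."""
    df = model_df(model)
    if df < 0:
        raise ValueError(f"model is not identified: df = {df} < 0")
    r, Lw = _group_setup(stage1, model)
    lmap = {lab: lab for lab in model.param_names}
    token = (id(stage1),)
    return _fit_core(
        [(r, Lw, model, lmap)],
        model.param_names,
        df,
        getattr(stage1, "kind", "fixed"),
        getattr(stage1, "total_n", 0),
        seed=seed,
        stage1_token=token,
    )


def fit_wls_multigroup(stage1_per_group: dict[str, object], mgmodel: MultiGroupModel, seed: int = 0) -> Stage2Result:
    """Joint WLS fit across subgroups with cross-group equality labels.

    Each group keeps its own Stage-1 weight matrix; shared labels force
    identical estimates across groups.  With no constraints the joint
    chi-square and df are exactly the sums of per-group values.
    """
    df = model_df(mgmodel)
    if df < 0:
        raise ValueError(f"model is not identified: df = {df} < 0")
    groups = []
    for g in mgmodel.groups:
        if g not in stage1_per_group:
            raise ValueError(f"no stage-1 result for subgroup {g!r}")
        model = mgmodel.models[g]
        r, Lw = _group_setup(stage1_per_group[g], model)
        lmap = {lab: mgmodel.effective_label(g, lab) for lab in model.param_names}
        missing = mgmodel.cross_group_constraints - set(model.param_names)
        if missing:
            raise ValueError(f"constraint label(s) {sorted(missing)} absent from group {g!r}")
        groups.append((r, Lw, model, lmap))
    total_n = sum(getattr(stage1_per_group[g], "total_n", 0) for g in mgmodel.groups)
    kinds = {getattr(stage1_per_group[g], "kind", "fixed") for g in mgmodel.groups}
    token = tuple(id(stage1_per_group[g]) for g in mgmodel.groups)
    return _fit_core(
        groups,
        mgmodel.param_names,
        df,
        kinds.pop() if len(kinds) == 1 else "mixed",
        total_n,
        seed=seed,
        stage1_token=token,
    )


def derived_parameter(
    result: Stage2Result, names: list[str]
) -> tuple[float, float, tuple[float, float]]:
    """Product of named parameters with a first-order delta-method SE.

    For theta_d = prod_j theta_j the gradient is prod_{i != j} theta_i and
    se = sqrt(g' V g) using the full estimated parameter covariance.
    """
    for nm in names:
        if nm not in result.theta:
            raise KeyError(f"unknown parameter {nm!r}")
    idx = [result.param_names.index(nm) for nm in names]
    vals = np.array([result.theta[nm] for nm in names])
    est = float(np.prod(vals))
    grad = np.zeros(len(result.param_names))
    for pos, i in enumerate(idx):
        others = np.prod(np.delete(vals, pos))
        grad[i] += others
    var = float(grad @ result.vcov @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    return est, se, (est - 1.96 * se, est + 1.96 * se)
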