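"""Monte-Carlo experiment: subgroup versus overall random-effects MASEM.

The generator emulates a two-subgroup meta-analytic universe built on a
four-variable mediation path model (positive and negative relations ->
engagement -> achievement):

* each subgroup has a population mean correlation vector implied by the
  path coefficients; the third path (engagement -> achievement) differs
  by .10 between subgroups (.288 vs .388 by default);
* each study's own population correlation vector is the subgroup mean
  plus independent normal between-study deviations (SD ``tau`` per
  correlation), redrawn until the assembled matrix is positive definite;
* the study then contributes the sample Pearson correlations of n
  multivariate-normal observations from that population matrix.

Per replication the correct model is fitted three ways — once to all
studies combined (overall random effects, diagonal T^2) and once per
subgroup — through both stages.  Reported metrics follow the usual
Monte-Carlo conventions: convergence proportion per analysis, relative
estimation bias 100 (mean estimate - truth) / truth, and relative SE
bias 100 (mean SE - empirical SD) / empirical SD, with bias metrics
computed only over replications in which all compared analyses
converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MasemDataset, StudyRecord, unvech, vech
from .model import implied_matrix, parse_model
from .stage1_random import pool_random
from .stage2 import fit_wls

__all__ = [
    "SimulationCondition",
    "SimulationMetrics",
    "PATH_MODEL_SYNTAX",
    "path_population_matrix",
    "generate_meta_dataset",
    "relative_bias",
    "se_bias",
    "run_condition",
]

PATH_MODEL_SYNTAX = """
v3 ~ b31:v1 + b32:v2
v4 ~ b43:v3
v1 ~~ psi12:v2
"""

_VARIABLES = ["v1", "v2", "v3", "v4"]
_PATH_MODEL = parse_model(PATH_MODEL_SYNTAX, _VARIABLES)


@dataclass
class SimulationCondition:
    """Generating parameters for one experimental condition.

    Defaults are the study conditions of the experiment this module
    runs: subgroup-1 direct effects (.265, -.307, .288), exogenous
    correlation -.329, subgroup-2 third path .388 (a .10 difference),
    n = 200 observations per study, and a between-study SD of 0.10 for
    every correlation (diagonal between-study covariance).
    """

    k_per_subgroup: int
    n_per_study: int = 200
    beta31: float = 0.265
    beta32: float = -0.307
    beta43_g1: float = 0.288
    beta43_g2: float = 0.388
    psi12: float = -0.329
    tau: float | np.ndarray = 0.10
    reps: int = 200
    seed: int = 0

    def group_truth(self) -> dict[str, float]:
        return {"g1": self.beta43_g1, "g2": self.beta43_g2}


@dataclass
class SimulationMetrics:
    condition: SimulationCondition
    convergence: dict[str, float]
    rel_bias: dict[str, float]
    se_bias: dict[str, float]
    n_converged_joint: int
    reps: int
    estimates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "k_per_subgroup": self.condition.k_per_subgroup,
            "n_per_study": self.condition.n_per_study,
            "reps": self.reps,
            "n_converged_joint": self.n_converged_joint,
            "convergence": self.convergence,
            "rel_bias": self.rel_bias,
            "se_bias": self.se_bias,
        }


def path_population_matrix(beta31: float, beta32: float, beta43: float, psi12: float) -> np.ndarray:
    """Population correlation matrix implied by the mediation path model."""
    theta = {"b31": beta31, "b32": beta32, "b43": beta43, "psi12": psi12}
    return implied_matrix(_PATH_MODEL, theta)


def generate_meta_dataset(cond: SimulationCondition, rng: np.random.Generator) -> MasemDataset:
    """Draw one meta-analytic dataset of 2k studies with subgroup labels."""
    tau = np.broadcast_to(np.asarray(cond.tau, float), (6,)).copy()
    means = {
        "g1": vech(path_population_matrix(cond.beta31, cond.beta32, cond.beta43_g1, cond.psi12)),
        "g2": vech(path_population_matrix(cond.beta31, cond.beta32, cond.beta43_g2, cond.psi12)),
    }
    studies = []
    n = cond.n_per_study
    for g, mean_vec in means.items():
        for s in range(cond.k_per_subgroup):
            for attempt in range(100):
                rho_vec = mean_vec + tau * rng.standard_normal(6)
                if np.abs(rho_vec).max() >= 1.0:
                    continue
                Sigma = unvech(rho_vec)
                if np.linalg.eigvalsh(Sigma).min() > 1e-6:
                    break
            else:
                raise RuntimeError(
                    "no positive-definite study population matrix in 100 draws; "
                    "condition too extreme"
                )
            L = np.linalg.cholesky(Sigma)
            X = rng.standard_normal((n, 4)) @ L.T
            R = np.corrcoef(X, rowvar=False)
            studies.append(StudyRecord(f"{g}_s{s + 1}", n, R, group=g))
    return MasemDataset(list(_VARIABLES), studies)


def relative_bias(estimates: np.ndarray, truth: float) -> float:
    """Relative percentage estimation bias: 100 (mean - truth) / truth."""
    estimates = np.asarray(estimates, float)
    if estimates.size < 1:
        raise ValueError("need at least one converged replication")
    if truth == 0:
        raise ValueError("relative bias undefined for zero truth")
    return float(100.0 * (estimates.mean() - truth) / truth)


def se_bias(se_values: np.ndarray, estimates: np.ndarray) -> float:
    """Relative percentage SE bias: 100 (mean SE - empirical SD) / SD."""
    se_values = np.asarray(se_values, float)
    estimates = np.asarray(estimates, float)
    if estimates.size < 2:
        raise ValueError("need at least two converged replications")
    sd = estimates.std(ddof=1)
    if sd == 0:
        raise ValueError("zero empirical SD")
    return float(100.0 * (se_values.mean() - sd) / sd)


def _fit_one(data: MasemDataset) -> tuple[bool, float, float]:
    """Random-effects TSSEM through Stage 2; returns (converged, b43, se)."""
    s1 = pool_random(data, structure="diagonal")
    try:
        s2 = fit_wls(s1, _PATH_MODEL)
    except np.linalg.LinAlgError:
        return False, np.nan, np.nan
    ok = bool(s1.converged and s2.converged)
    return ok, s2.theta.get("b43", np.nan), s2.se.get("b43", np.nan)


def run_condition(cond: SimulationCondition, modes: tuple[str, ...] = ("overall", "subgroup")) -> SimulationMetrics:
    """Run one condition: generate, fit per analysis mode, aggregate.

    Modes: "overall" pools all 2k studies in one random-effects TSSEM;
    "subgroup" fits each subgroup separately.  Convergence requires both
    stages (FIML stationarity and an admissible WLS solution).  Bias and
    SE-bias metrics use only replications converged in *all* fitted
    analyses; convergence proportions use all replications.
    """
    seeds = np.random.SeedSequence(cond.seed).spawn(cond.reps)
    rows = []
    for rep in range(cond.reps):
        rng = np.random.default_rng(seeds[rep])
        data = generate_meta_dataset(cond, rng)
        row: dict[str, float | bool] = {}
        if "overall" in modes:
            ok, est, se = _fit_one(data)
            row.update(overall_ok=ok, overall_est=est, overall_se=se)
        if "subgroup" in modes:
            for g in ("g1", "g2"):
                ok, est, se = _fit_one(data.subset(g))
                row.update({f"{g}_ok": ok, f"{g}_est": est, f"{g}_se": se})
        rows.append(row)

    def col(name: str) -> np.ndarray:
        return np.array([r[name] for r in rows])

    convergence: dict[str, float] = {}
    ok_all = np.ones(cond.reps, dtype=bool)
    if "overall" in modes:
        convergence["overall"] = float(col("overall_ok").mean())
        ok_all &= col("overall_ok").astype(bool)
    if "subgroup" in modes:
        sub_ok = col("g1_ok").astype(bool) & col("g2_ok").astype(bool)
        convergence["subgroup"] = float(sub_ok.mean())
        ok_all &= sub_ok

    truth = cond.group_truth()
    rel, seb, estimates = {}, {}, {}
    if ok_all.sum() >= 2:
        if "overall" in modes:
            est = col("overall_est")[ok_all]
            ses = col("overall_se")[ok_all]
            estimates["overall"] = est
            rel["overall_vs_g1"] = relative_bias(est, truth["g1"])
            rel["overall_vs_g2"] = relative_bias(est, truth["g2"])
            seb["overall"] = se_bias(ses, est)
        if "subgroup" in modes:
            for g in ("g1", "g2"):
                est = col(f"{g}_est")[ok_all]
                ses = col(f"{g}_se")[ok_all]
                estimates[f"subgroup_{g}"] = est
                rel[f"subgroup_{g}"] = relative_bias(est, truth[g])
                seb[f"subgroup_{g}"] = se_bias(ses, est)

    return SimulationMetrics(
        condition=cond,
        convergence=convergence,
        rel_bias=rel,
        se_bias=seb,
        n_converged_joint=int(ok_all.sum()),
        reps=cond.reps,
        estimates=estimates,
    )
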