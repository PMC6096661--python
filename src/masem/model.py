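"""Structural models in RAM form for correlation-structure fitting.

A model is specified in a small lavaan-like text syntax:

* ``F =~ v1 + v2 + v3``     — factor loadings (F latent, indicators observed)
* ``y ~ x1 + x2``           — regressions / path coefficients
* ``a ~~ b``                — covariance (or variance when ``a == b``)
* any right-hand term may carry a ``label:`` prefix; terms sharing a
  label are constrained equal and are counted as one free parameter.

Internally everything becomes one reticular-action-model (RAM) pair of
matrices: A holds asymmetric paths (loadings and regressions), S holds
symmetric (co)variances.  The implied covariance of the observed
variables is F (I - A)^{-1} S (I - A)^{-T} F'.

Because the input is a pooled *correlation* matrix, the model operates
in a fully standardized metric: latent variances are fixed to 1, and the
residual variances of endogenous observed variables are not free
parameters but *remainders* — solved so that every implied diagonal
element equals exactly 1 (diag(I) - diag of the explained part).  A
negative remainder means an implied communality above 1: the parameter
point is inadmissible.

Exogenous observed variables get fixed unit variance; their mutual
covariances are free only when declared with ``~~`` (they are then
correlations in this metric).  Latent factors are orthogonal unless a
covariance is declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import vech_indices

__all__ = [
    "RamModel",
    "MultiGroupModel",
    "ModelSyntaxError",
    "InadmissibleParameterError",
    "parse_model",
    "implied_matrix",
    "model_df",
]


class ModelSyntaxError(ValueError):
    pass


class InadmissibleParameterError(ValueError):
    """Implied communality exceeds 1: the remainder residual is negative."""


# a cell is ("fixed", value) | ("free", label) | ("remainder", None)
Cell = tuple


@dataclass
class RamModel:
    obs_vars: list[str]
    latent_vars: list[str]
    A: dict[tuple[str, str], Cell]  # (target, source) -> cell
    S: dict[tuple[str, str], Cell]  # unordered symmetric; key stored sorted
    syntax: str = ""

    @property
    def p(self) -> int:
        return len(self.obs_vars)

    @property
    def all_vars(self) -> list[str]:
        return self.obs_vars + self.latent_vars

    @property
    def param_names(self) -> list[str]:
        """Distinct free-parameter labels, in first-appearance order."""
        seen: list[str] = []
        for cell in list(self.A.values()) + list(self.S.values()):
            if cell[0] == "free" and cell[1] not in seen:
                seen.append(cell[1])
        return seen

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def to_syntax(self) -> str:
        """Canonical serialization; parsing it back reproduces the model."""
        lines = []
        for (t, s), cell in self.A.items():
            if cell[0] != "free":
                continue
            op = "=~" if s in self.latent_vars and t in self.obs_vars else "~"
            if op == "=~":
                lines.append(f"{s} =~ {cell[1]}:{t}")
            else:
                lines.append(f"{t} ~ {cell[1]}:{s}")
        for (a, b), cell in self.S.items():
            if cell[0] == "free":
                lines.append(f"{a} ~~ {cell[1]}:{b}")
        return "\n".join(lines)


@dataclass
class MultiGroupModel:
    """Per-group structural models with optional cross-group equalities.

    Labels listed in ``cross_group_constraints`` refer to the *base*
    label; within each group the effective label is ``label@group`` for
    unconstrained parameters and the bare label for constrained ones.
    """

    groups: list[str]
    models: dict[str, RamModel]
    cross_group_constraints: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        obs = None
        for g in self.groups:
            m = self.models[g]
            if obs is None:
                obs = m.obs_vars
            elif m.obs_vars != obs:
                raise ModelSyntaxError("all groups must share the observed-variable ordering")

    def effective_label(self, group: str, label: str) -> str:
        return label if label in self.cross_group_constraints else f"{label}@{group}"

    @property
    def param_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            for lab in self.models[g].param_names:
                eff = self.effective_label(g, lab)
                if eff not in seen:
                    seen.append(eff)
        return seen

    @property
    def n_free(self) -> int:
        return len(self.param_names)


def _split_term(term: str) -> tuple[str | None, str]:
    term = term.strip()
    if ":" in term:
        label, var = term.split(":", 1)
        label, var = label.strip(), var.strip()
        if not label or not var:
            raise ModelSyntaxError(f"malformed labeled term {term!r}")
        return label, var
    return None, term


def parse_model(text: str, obs_vars: list[str]) -> RamModel:
    """Parse model syntax into a RAM representation.

    ``obs_vars`` is the declared observed-variable ordering (shared with
    the dataset); anything appearing on the left of ``=~`` is latent.
    Undeclared variables and duplicate paths are errors.
    """
    statements: list[tuple[str, str, str]] = []  # (op, lhs, rhs)
    for raw in text.replace(";", "\n").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for op in ("=~", "~~", "~"):
            if op in line:
                lhs, rhs = line.split(op, 1)
                statements.append((op, lhs.strip(), rhs.strip()))
                break
        else:
            raise ModelSyntaxError(f"cannot parse line: {raw!r}")

    latent_vars = []
    for op, lhs, _ in statements:
        if op == "=~":
            if lhs in obs_vars:
                raise ModelSyntaxError(f"{lhs!r} is observed; it cannot define a factor")
            if lhs not in latent_vars:
                latent_vars.append(lhs)

    known = set(obs_vars) | set(latent_vars)
    A: dict[tuple[str, str], Cell] = {}
    S: dict[tuple[str, str], Cell] = {}

    def check_var(v: str) -> None:
        if v not in known:
            raise ModelSyntaxError(f"undeclared variable {v!r}")

    def add_A(target: str, source: str, label: str | None, default: str) -> None:
        if (target, source) in A:
            raise ModelSyntaxError(f"duplicate path {source!r} -> {target!r}")
        A[(target, source)] = ("free", label or default)

    def skey(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    for op, lhs, rhs in statements:
        if op == "=~":
            for term in rhs.split("+"):
                label, var = _split_term(term)
                check_var(var)
                add_A(var, lhs, label, f"{lhs}=~{var}")
        elif op == "~":
            check_var(lhs)
            for term in rhs.split("+"):
                label, var = _split_term(term)
                check_var(var)
                add_A(lhs, var, label, f"{lhs}~{var}")
        else:  # ~~
            check_var(lhs)
            for term in rhs.split("+"):
                label, var = _split_term(term)
                check_var(var)
                key = skey(lhs, var)
                if key in S:
                    raise ModelSyntaxError(f"duplicate covariance {lhs!r} ~~ {var!r}")
                S[key] = ("free", label or f"{key[0]}~~{key[1]}")

    # defaults
    endogenous = {t for (t, _) in A}
    for lv in latent_vars:
        if (lv, lv) in S:
            raise ModelSyntaxError(
                f"latent variance of {lv!r} is fixed to 1 for identification; "
                "it cannot be declared"
            )
        S[(lv, lv)] = ("fixed", 1.0)
    for i, a in enumerate(latent_vars):
        for b in latent_vars[i + 1 :]:
            S.setdefault((a, b) if a <= b else (b, a), ("fixed", 0.0))
    for v in obs_vars:
        if (v, v) in S:
            raise ModelSyntaxError(
                f"observed variance of {v!r} is determined by the unit-diagonal "
                "constraint; it cannot be declared"
            )
        S[(v, v)] = ("remainder", None) if v in endogenous else ("fixed", 1.0)

    # labels must not span cells of different roles
    roles: dict[str, str] = {}
    for (t, s), cell in A.items():
        if cell[0] == "free":
            role = "loading" if s in latent_vars else "regression"
            if roles.setdefault(cell[1], role) != role:
                raise ModelSyntaxError(f"label {cell[1]!r} spans cells of different roles")
    for key, cell in S.items():
        if cell[0] == "free":
            if roles.setdefault(cell[1], "covariance") != "covariance":
                raise ModelSyntaxError(f"label {cell[1]!r} spans cells of different roles")

    return RamModel(obs_vars=list(obs_vars), latent_vars=latent_vars, A=A, S=S, syntax=text)


def _assemble(model: RamModel, theta: dict[str, float]):
    """Numeric A and S (remainders zeroed), plus remainder bookkeeping."""
    order = {v: i for i, v in enumerate(model.all_vars)}
    m = len(order)
    A = np.zeros((m, m))
    S = np.zeros((m, m))
    for (t, s), cell in model.A.items():
        A[order[t], order[s]] = cell[1] if cell[0] == "fixed" else theta[cell[1]]
    remainder_vars: list[int] = []
    for (a, b), cell in model.S.items():
        i, j = order[a], order[b]
        if cell[0] == "remainder":
            remainder_vars.append(i)
            continue
        val = cell[1] if cell[0] == "fixed" else theta[cell[1]]
        S[i, j] = S[j, i] = val
    return A, S, sorted(remainder_vars)


def implied_matrix(
    model: RamModel, theta: dict[str, float] | np.ndarray, check_admissible: bool = True
) -> np.ndarray:
    """Model-implied correlation matrix with exact unit diagonal.

    Residual variances of endogenous observed variables are solved as
    remainders so that every diagonal element equals 1.  With
    ``check_admissible`` a negative remainder raises
    :class:`InadmissibleParameterError` naming the variable; fitting
    routines disable the check and validate admissibility at the
    solution instead.
    """
    if not isinstance(theta, dict):
        theta = dict(zip(model.param_names, np.asarray(theta, float)))
    A, S, rem = _assemble(model, theta)
    p, m = model.p, len(model.all_vars)
    B = np.linalg.solve(np.eye(m) - A, np.eye(m))[:p, :]  # F (I-A)^{-1}
    C0 = B @ S @ B.T
    if rem:
        M = B[np.ix_(rem, rem)] ** 2
        rhs = 1.0 - np.diag(C0)[rem]
        s_rem = np.linalg.solve(M, rhs)
        if check_admissible:
            for idx, val in zip(rem, s_rem):
                if val < 0:
                    raise InadmissibleParameterError(
                        f"negative remainder residual for {model.obs_vars[idx]!r}: "
                        f"{val:.4f} (implied communality > 1)"
                    )
        Srem = np.zeros((m, m))
        Srem[rem, rem] = s_rem
        C0 = C0 + B @ Srem @ B.T
    if not np.allclose(np.diag(C0), 1.0, atol=1e-10):
        bad = model.obs_vars[int(np.argmax(np.abs(np.diag(C0) - 1.0)))]
        raise InadmissibleParameterError(
            f"implied variance of {bad!r} is not 1; check the model's exogenous structure"
        )
    out = C0.copy()
    np.fill_diagonal(out, 1.0)
    return out


def remainder_values(model: RamModel, theta: dict[str, float] | np.ndarray) -> dict[str, float]:
    """The solved remainder residual variances at ``theta``."""
    if not isinstance(theta, dict):
        theta = dict(zip(model.param_names, np.asarray(theta, float)))
    A, S, rem = _assemble(model, theta)
    p, m = model.p, len(model.all_vars)
    B = np.linalg.solve(np.eye(m) - A, np.eye(m))[:p, :]
    C0 = B @ S @ B.T
    if not rem:
        return {}
    M = B[np.ix_(rem, rem)] ** 2
    s_rem = np.linalg.solve(M, 1.0 - np.diag(C0)[rem])
    return {model.obs_vars[i]: float(v) for i, v in zip(rem, s_rem)}


def model_df(model: RamModel | MultiGroupModel, p: int | None = None) -> int:
    """Degrees of freedom: G * p(p-1)/2 minus distinct free parameters."""
    if isinstance(model, MultiGroupModel):
        any_model = model.models[model.groups[0]]
        p = p or any_model.p
        G = len(model.groups)
        free = model.n_free
    else:
        p = p or model.p
        G = 1
        free = model.n_free
    return G * p * (p - 1) // 2 - free
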