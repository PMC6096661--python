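"""Study-level correlation data: containers, half-vectorization, text I/O.

A meta-analytic SEM dataset is a collection of per-study Pearson
correlation matrices over a shared, explicitly declared variable list,
together with study sample sizes and optional subgroup labels.  Studies
may observe only a subset of the correlations; unobserved cells are NaN,
never zero.

The on-disk format is long (tidy): one row per observed correlation,
header exactly ``study_id,n,group,var_row,var_col,r`` (comma or tab
separated).  Variable ordering always comes from the declared list, so
every vector, weight matrix and pair basis in the package shares a single
ordering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "MasemDataset",
    "DatasetError",
    "vech",
    "unvech",
    "vech_indices",
    "read_dataset",
    "write_dataset",
    "dataset_from_matrices",
]

HEADER = ["study_id", "n", "group", "var_row", "var_col", "r"]


class DatasetError(ValueError):
    """Malformed or invalid study-level correlation data."""


def vech_indices(p: int) -> list[tuple[int, int]]:
    """Strict lower-triangle index pairs of a ``p`` x ``p`` matrix.

    Column-major order: (1,0), (2,0), ..., (p-1,0), (2,1), ...  Every
    pooled vector, sampling-covariance basis and weight matrix in the
    package uses this single ordering.
    """
    return [(i, j) for j in range(p) for i in range(j + 1, p)]


def vech(mat: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (strict lower triangle).

    Returns the p(p-1)/2 off-diagonal elements in column-major order.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DatasetError(f"vech expects a square matrix, got shape {mat.shape}")
    p = mat.shape[0]
    return np.array([mat[i, j] for i, j in vech_indices(p)])


def unvech(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vech` with a constant (unit) diagonal."""
    vec = np.asarray(vec, dtype=float)
    q = vec.size
    p = int(round((1 + np.sqrt(1 + 8 * q)) / 2))
    if p * (p - 1) // 2 != q:
        raise DatasetError(f"length {q} is not p(p-1)/2 for integer p")
    out = np.eye(p) * diag
    for val, (i, j) in zip(vec, vech_indices(p)):
        out[i, j] = out[j, i] = val
    return out


@dataclass
class StudyRecord:
    """One study's (possibly incomplete) correlation matrix.

    ``corr`` is p x p over the dataset's declared variable list with NaN
    for unobserved pairs and an exact unit diagonal.
    """

    study_id: str
    n: int
    corr: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        p = self.corr.shape[0]
        if self.corr.shape != (p, p):
            raise DatasetError(f"study {self.study_id}: corr must be square")
        if self.n < 4:
            raise DatasetError(f"study {self.study_id}: n must be >= 4, got {self.n}")
        np.fill_diagonal(self.corr, 1.0)
        obs = ~np.isnan(self.corr)
        if not np.array_equal(obs, obs.T):
            raise DatasetError(f"study {self.study_id}: asymmetric missingness pattern")
        if not np.allclose(
            np.where(obs, self.corr, 0.0), np.where(obs, self.corr, 0.0).T, atol=1e-12
        ):
            raise DatasetError(f"study {self.study_id}: correlation matrix not symmetric")
        off = self.corr[~np.eye(p, dtype=bool)]
        bad = np.abs(off[~np.isnan(off)]) > 1.0
        if bad.any():
            raise DatasetError(f"study {self.study_id}: correlation outside [-1, 1]")

    @property
    def observed_pairs(self) -> np.ndarray:
        """Boolean mask over vech_indices(p): which pairs were measured."""
        p = self.corr.shape[0]
        return np.array([not np.isnan(self.corr[i, j]) for i, j in vech_indices(p)])

    @property
    def r_vec(self) -> np.ndarray:
        """Observed correlations in the shared vech ordering (NaN = missing)."""
        return vech(self.corr)


@dataclass
class MasemDataset:
    """A collection of studies over one declared variable list."""

    variables: list[str]
    studies: list[StudyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = len(self.variables)
        if len(set(self.variables)) != p:
            raise DatasetError("duplicate variable names")
        for s in self.studies:
            if s.corr.shape != (p, p):
                raise DatasetError(
                    f"study {s.study_id}: matrix is {s.corr.shape[0]}-variate, "
                    f"dataset declares {p} variables"
                )
        if len(self.studies) < 1:
            raise DatasetError("dataset needs at least one study")

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def n_pairs(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def group_levels(self) -> list[str]:
        seen: list[str] = []
        for s in self.studies:
            if s.group is not None and s.group not in seen:
                seen.append(s.group)
        return seen

    @property
    def total_n(self) -> int:
        return int(sum(s.n for s in self.studies))

    def subset(self, group: str) -> "MasemDataset":
        studies = [s for s in self.studies if s.group == group]
        if not studies:
            raise DatasetError(f"no studies in subgroup {group!r}")
        return MasemDataset(self.variables, studies)

    def by_group(self) -> dict[str, "MasemDataset"]:
        levels = self.group_levels
        if not levels:
            raise DatasetError("no subgroup labels in dataset")
        return {g: self.subset(g) for g in levels}

    def naive_pooled(self) -> np.ndarray:
        """n-weighted average correlation matrix over observed cells.

        Used as a starting value for likelihood-based pooling and as the
        default evaluation point for sampling covariances.
        """
        p = self.p
        num = np.zeros((p, p))
        den = np.zeros((p, p))
        for s in self.studies:
            obs = ~np.isnan(s.corr)
            num[obs] += s.n * s.corr[obs]
            den[obs] += s.n
        if (den[~np.eye(p, dtype=bool)] == 0).any():
            missing = [
                (self.variables[i], self.variables[j])
                for i, j in vech_indices(p)
                if den[i, j] == 0
            ]
            raise DatasetError(f"correlation pair(s) observed in no study: {missing}")
        out = num / den
        np.fill_diagonal(out, 1.0)
        return np.clip(out, -0.99, 0.99) * (1 - np.eye(p)) + np.eye(p)


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_dataset(path: str, variables: list[str]) -> MasemDataset:
    """Read a long-format correlation file into a validated dataset.

    One row per observed correlation per study; missing pairs are simply
    absent rows.  Duplicate (study, pair) rows, out-of-range correlations
    and inconsistent sample sizes within a study raise
    :class:`DatasetError` naming the offending line or study.
    """
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != HEADER:
        raise DatasetError(
            f"header must be exactly {','.join(HEADER)}, got {','.join(df.columns)}"
        )
    var_index = {v: i for i, v in enumerate(variables)}
    p = len(variables)

    per_study: dict[str, dict] = {}
    seen_pairs: set[tuple[str, int, int]] = set()
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.study_id.strip()
        if not sid:
            raise DatasetError(f"line {row_num}: empty study_id")
        try:
            n = int(row.n)
        except ValueError:
            raise DatasetError(f"line {row_num}: sample size {row.n!r} is not an integer")
        try:
            r = float(row.r)
        except ValueError:
            raise DatasetError(f"line {row_num}: correlation {row.r!r} is not a number")
        for v in (row.var_row, row.var_col):
            if v not in var_index:
                raise DatasetError(
                    f"line {row_num}: variable {v!r} not in declared list"
                )
        i, j = var_index[row.var_row], var_index[row.var_col]
        if i == j:
            raise DatasetError(f"line {row_num}: diagonal entry for {row.var_row!r}")
        if abs(r) > 1:
            raise DatasetError(
                f"study {sid}, pair ({row.var_row},{row.var_col}): r = {r} outside [-1, 1]"
            )
        key = (sid, min(i, j), max(i, j))
        if key in seen_pairs:
            raise DatasetError(
                f"line {row_num}: duplicate pair ({row.var_row},{row.var_col}) "
                f"for study {sid}"
            )
        seen_pairs.add(key)
        entry = per_study.setdefault(
            sid, {"n": n, "group": row.group.strip() or None, "corr": np.full((p, p), np.nan)}
        )
        if entry["n"] != n:
            raise DatasetError(f"study {sid}: inconsistent sample sizes {entry['n']} vs {n}")
        np.fill_diagonal(entry["corr"], 1.0)
        entry["corr"][i, j] = entry["corr"][j, i] = r

    studies = [
        StudyRecord(sid, d["n"], d["corr"], group=d["group"])
        for sid, d in per_study.items()
    ]
    return MasemDataset(list(variables), studies)


def write_dataset(data: MasemDataset, path: str, sep: str = ",") -> None:
    """Write a dataset back to the long text format (round-trip safe)."""
    rows = []
    for s in data.studies:
        for i, j in vech_indices(data.p):
            if not np.isnan(s.corr[i, j]):
                rows.append(
                    {
                        "study_id": s.study_id,
                        "n": s.n,
                        "group": s.group or "",
                        "var_row": data.variables[i],
                        "var_col": data.variables[j],
                        "r": repr(float(s.corr[i, j])),
                    }
                )
    pd.DataFrame(rows, columns=HEADER).to_csv(path, sep=sep, index=False)


def dataset_from_matrices(
    variables: list[str],
    matrices: dict[str, np.ndarray],
    ns: dict[str, int],
    groups: dict[str, str] | None = None,
) -> MasemDataset:
    """Convenience converter from square per-study matrices."""
    studies = [
        StudyRecord(sid, ns[sid], m, group=(groups or {}).get(sid))
        for sid, m in matrices.items()
    ]
    return MasemDataset(list(variables), studies)
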