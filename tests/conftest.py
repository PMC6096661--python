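import numpy as np
import pytest

from masem.dataset import MasemDataset, StudyRecord


def make_homogeneous_dataset(
    P0: np.ndarray,
    k: int,
    n: int,
    rng: np.random.Generator,
    group: str | None = None,
    prefix: str = "s",
) -> MasemDataset:
    """Studies sampling from one common population correlation matrix."""
    L = np.linalg.cholesky(P0)
    p = P0.shape[0]
    studies = []
    for i in range(k):
        X = rng.standard_normal((n, p)) @ L.T
        studies.append(
            StudyRecord(f"{prefix}{i}", n, np.corrcoef(X, rowvar=False), group=group)
        )
    return MasemDataset([f"v{j + 1}" for j in range(p)], studies)


@pytest.fixture
def rho3() -> np.ndarray:
    return np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.4], [0.2, 0.4, 1.0]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
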