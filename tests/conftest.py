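import numpy as np
import pytest

from fluencynet import (
    CorrelationMatrix,
    FluencyDataset,
    build_response_matrix,
)


@pytest.fixture
def two_group_dataset() -> dict[str, FluencyDataset]:
    """Tiny two-group dataset with known vocabulary overlap."""
    return {
        "nh": FluencyDataset(
            group_label="nh",
            subjects=[
                ("n1", ["dog", "cat", "horse", "cow"]),
                ("n2", ["cat", "dog", "shark"]),
                ("n3", ["dog", "whale", "cat"]),
            ],
        ),
        "ci": FluencyDataset(
            group_label="ci",
            subjects=[
                ("c1", ["dog", "cat"]),
                ("c2", ["cat", "horse", "dog"]),
                ("c3", ["shark", "dog"]),
            ],
        ),
    }


@pytest.fixture
def response_matrices(two_group_dataset):
    return {
        k: build_response_matrix(ds) for k, ds in two_group_dataset.items()
    }


def random_correlation_like(n: int, rng: np.random.Generator) -> CorrelationMatrix:
    """Symmetric matrix with distinct off-diagonal weights in (-1, 1)."""
    w = rng.uniform(-0.99, 0.99, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    labels = [f"w{i:03d}" for i in range(n)]
    return CorrelationMatrix(vocabulary=labels, values=w)


@pytest.fixture
def corr_factory():
    return random_correlation_like
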