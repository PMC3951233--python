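import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset():
    """3 compounds x 2 descriptors with hand-chosen normalized values.

    PK (normalized): [0.0, 0.05, 0.5] — pair (0,1) is PK-similar at the
    default epsilon 0.1, pairs (0,2) and (1,2) are not.
    """
    from qspkr.io_normalize import QSPkRDataset, ScaleInfo

    X = np.array([[0.1, 0.5], [0.2, 0.5], [0.9, 0.5]])
    dp = np.array([0.0, 0.05, 0.5])
    return QSPkRDataset(
        compound_ids=["a", "b", "c"],
        descriptor_names=["d1", "d2"],
        X=X,
        dp=dp,
        descriptor_scale=ScaleInfo(np.zeros(2), np.ones(2)),
        pk_scale=ScaleInfo(np.array([10.0]), np.array([55.0])),
        constant_descriptors=np.zeros(2, dtype=bool),
        pk_name="cl",
        pk_unit="mL/min/kg",
    )


def make_random_dataset(n_compounds, n_descriptors, seed, grid=None):
    """Random valid dataset; with ``grid`` set, values are multiples of
    1/grid so fitness sums are exact in floating point under any order."""
    from qspkr.io_normalize import QSPkRDataset, ScaleInfo

    rng = np.random.default_rng(seed)
    if grid:
        X = rng.integers(0, grid + 1, size=(n_compounds, n_descriptors)) / grid
        dp = rng.integers(0, grid + 1, size=n_compounds) / grid
    else:
        X = rng.random((n_compounds, n_descriptors))
        dp = rng.random(n_compounds)
    return QSPkRDataset(
        compound_ids=[f"c{i}" for i in range(n_compounds)],
        descriptor_names=[f"d{k}" for k in range(n_descriptors)],
        X=X,
        dp=dp,
        descriptor_scale=ScaleInfo(np.zeros(n_descriptors), np.ones(n_descriptors)),
        pk_scale=ScaleInfo(np.array([0.0]), np.array([1.0])),
        constant_descriptors=np.zeros(n_descriptors, dtype=bool),
    )
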