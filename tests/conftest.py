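import numpy as np
import pytest

from stlmm import (
    CovarianceParams,
    DesignSpec,
    SimTruth,
    STSample,
    assign_labels,
    make_layout,
    simulate_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_sample() -> STSample:
    """3 genes x 4 units with counts, two domains on a unit square."""
    counts = np.array([[1, 0, 2, 3], [4, 1, 0, 2], [2, 2, 2, 2]])
    return STSample(
        unit_ids=["u1", "u2", "u3", "u4"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        counts=counts,
        gene_ids=["g1", "g2", "g3"],
        labels=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture(scope="session")
def grid_sample() -> STSample:
    """60-unit grid sample with simulated expression, moderate spatial signal."""
    coords = make_layout("squaregrid", n_rows=6, n_cols=10, spacing=1.0)
    labels = assign_labels(coords, 2, geometry="blocks", seed=0)
    truth = SimTruth(
        layout="squaregrid",
        n_units=60,
        params=CovarianceParams(tau2=0.5, rho=2.0, sigma2=0.5),
        label_geometry="blocks",
        seed=0,
    )
    return simulate_expression(coords, labels, truth, n_genes=8)


@pytest.fixture
def balanced_design() -> DesignSpec:
    ind = np.zeros(10)
    ind[:5] = 1.0
    return DesignSpec(ind)
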