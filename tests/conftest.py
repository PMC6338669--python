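import numpy as np
import pandas as pd
import pytest

from cytoinfo.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_cells(expression, response, dose=1.0, time=15, replicate="r1", line="MEF"):
    """Assemble a minimal valid cell table from arrays."""
    return pd.DataFrame(
        {
            "expression": np.asarray(expression, dtype=float),
            "response": np.asarray(response, dtype=float),
            "dose": dose,
            "time": time,
            "replicate": replicate,
            "line": line,
        }
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Scaled-down synthetic dataset: 500 cells/condition, 12 doses, 2 reps."""
    cfg = SimulationConfig(n_cells=500, n_replicates=2, seed=7)
    cells, truth = simulate_dataset(cfg)
    return cells, truth


@pytest.fixture(scope="session")
def gaussian_pairs():
    """Correlated standard-normal pairs at several rho, one fixed seed each."""
    out = {}
    for i, rho in enumerate([0.0, 0.3, 0.5, 0.7, 0.9]):
        r = np.random.default_rng(100 + i)
        xy = r.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=5000)
        out[rho] = (xy[:, 0], xy[:, 1])
    return out
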