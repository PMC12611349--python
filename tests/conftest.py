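import numpy as np
import pandas as pd
import pytest

from ipcz.grid import GridSpec
from ipcz.synthetic import SyntheticScenario, default_scenario


@pytest.fixture(scope="session")
def spec() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def small_spec() -> GridSpec:
    """A 5x5 one-degree lattice for hand-checkable cases."""
    return GridSpec(lat_min=0, lat_max=5, lon_min=100, lon_max=105)


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return default_scenario(seed=42)


@pytest.fixture(scope="session")
def occurrences(scenario, spec) -> pd.DataFrame:
    from ipcz.synthetic import generate_occurrences

    return generate_occurrences(scenario, spec)


def naive_gi_star(values: np.ndarray, spec: GridSpec, scheme: str = "queen") -> np.ndarray:
    """Independent double-loop Gi* oracle (full-lattice background).

    Evaluates the statistic cell by cell straight from its definition:
    binary weights over the focal cell plus its contiguity neighbors,
    global mean and population standard deviation over all n cells.
    """
    from ipcz.grid import cell_neighbors

    x = np.asarray(values, dtype=float).reshape(spec.n_rows, spec.n_cols)
    n = x.size
    xbar = x.sum() / n
    s = np.sqrt((x**2).sum() / n - xbar**2)
    z = np.zeros((spec.n_rows, spec.n_cols))
    if s == 0:
        return z.ravel()
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            neigh = cell_neighbors((r, c), spec, scheme) | {(r, c)}
            w = len(neigh)
            local = sum(x[rr, cc] for rr, cc in neigh)
            denom = s * np.sqrt((n * w - w**2) / (n - 1))
            z[r, c] = (local - xbar * w) / denom
    return z.ravel()
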