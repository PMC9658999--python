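import numpy as np
import pytest

from cyclesig import synthdata as sd
from cyclesig.cyclealign import traces_to_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# shared ground truth for GP population fixtures: a 117-min window sampled at
# 40 points (3-min frames), oscillatory mean, sd ~1.3, length scale ~25 min
GP_TIMES = np.linspace(0.0, 117.0, 40)
GP_ALPHA = np.array([5, 6, 5, 4, 5, 6, 5, 4, 5, 6], dtype=float)
GP_BETA = np.full(5, 0.2)
GP_GAMMA = np.full(5, 1.5)
GP_TAU = 0.3


def population_spec(n_cells=60, seed=0, **kw):
    base = dict(
        time_grid=GP_TIMES, alpha=GP_ALPHA, beta=GP_BETA, gamma=GP_GAMMA,
        tau=GP_TAU, n_cells=n_cells, seed=seed,
    )
    base.update(kw)
    return sd.PopulationSpec(**base)


def population_matrix(n_cells=60, seed=0, **kw):
    return traces_to_matrix(sd.simulate_population(population_spec(n_cells, seed, **kw)))
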