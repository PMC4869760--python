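import warnings

import numpy as np
import pytest

from cyclegs.gsmodel import NoGeneticSignalWarning
from cyclegs.simdata import simulate_genotypes, simulate_program, small_config
from cyclegs.validate import dataset_from_simulation


@pytest.fixture(autouse=True)
def _quiet_no_signal():
    """Boundary-variance warnings are expected in null scenarios."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoGeneticSignalWarning)
        yield


@pytest.fixture(scope="session")
def small_pop():
    """Five-cycle population with missing calls (session-wide, read-only)."""
    return simulate_genotypes(small_config(seed=7))


@pytest.fixture(scope="session")
def sim_data():
    """Five-cycle dataset with line-mean adjusted means and truth."""
    cfg = small_config(seed=7, missing_rate=0.0, n_validation_lines=36)
    pop, plots = simulate_program(cfg)
    return dataset_from_simulation(pop, plots)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
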