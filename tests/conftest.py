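import numpy as np
import pandas as pd
import pytest

from ripscore import derive_weights, score_cohort, to_relative
from ripscore.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic study: 2000 genes, 60 samples."""
    cfg = SimulationConfig(seed=11, n_genes=2000, n_down=120, n_up=60,
                           n_samples=60)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    """Weights + relative matrix + scores for the reduced study."""
    w = derive_weights(small_cohort.control_replicates,
                       small_cohort.knockdown_replicates)
    m = to_relative(small_cohort.tumors)
    scores = score_cohort(m, w, n_perm=300, seed=5)
    return w, m, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
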