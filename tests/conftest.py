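import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import binate as bn

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy4():
    """Hand-computable 4-row dataset: one unit per (W, T) cell.

    Cell means: mu(0,0)=1, mu(1,0)=3, mu(0,1)=2, mu(1,1)=6, so
    BATE = ((3-1)+(6-2))/2 = 3 and CAB(1) = (3+3+6+6)/4 - 3 = 1.5.
    """
    return bn.BinarizedDataset(
        W=pd.DataFrame({"W": [0.0, 0.0, 1.0, 1.0]}),
        T=np.array([0, 1, 0, 1]),
        Y=np.array([1.0, 3.0, 2.0, 6.0]),
    )


@pytest.fixture
def toy4_models(toy4):
    om = bn.fit_outcome_regression(toy4)
    pm = bn.fit_propensity(toy4)
    return om, pm


@pytest.fixture
def sim_sample():
    """A moderate draw from the benchmark DGP, binarized at its cut-off."""
    obs = bn.sample_dgp(400, 2024)
    return bn.apply_binarization(obs, bn.BinarizationSpec.at_least(6.0))


def _paper_scale_study():
    cfg = bn.StudyConfig(
        seed=1, n_values=(150, 300, 500), replicates=5000,
        methods=("regression", "ipw", "aipw"), estimands=("BATE", "CAB1"))
    return bn.run_simulation_study(cfg)


@pytest.fixture(scope="session")
def paper_scale_study():
    """The full replicate study (3 sample sizes x 5000 replicates)."""
    return _paper_scale_study()
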