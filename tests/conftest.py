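import numpy as np
import pytest
from scipy.special import logit

import wetlandbirds as wb
from wetlandbirds.io_data import ModelSpec
from wetlandbirds.synthetic_data import SimulationScenario, simulate_covariates


@pytest.fixture(scope="session")
def small_study():
    """One complete synthetic study at the default (field-scale) design."""
    return wb.simulate_study(SimulationScenario(seed=42))


@pytest.fixture(scope="session")
def study_dir(small_study, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    wb.write_study(small_study, outdir)
    return outdir


def make_intercept_only_study(n_sites_target: int, psi: float, p: float,
                              seed: int):
    """Covariates plus detections from an intercept-only occupancy model.

    Returns (det, sc, vc, z, design); design has intercept-only X and W.
    """
    n_wetlands = max(2, int(np.ceil(n_sites_target / 8)))  # ~4 pts x 2 yrs
    scenario = SimulationScenario(n_acep=(n_wetlands + 1) // 2,
                                  n_reference=n_wetlands // 2, seed=seed)
    sc, vc, _ = simulate_covariates(scenario, seed=seed)
    spec = ModelSpec([], [], species="sosp")
    det, z, design = wb.simulate_detections(
        sc, vc, [logit(psi)], [logit(p)], seed=seed + 1, spec=spec)
    return det, sc, vc, z, design
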