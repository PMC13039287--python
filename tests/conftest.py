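"""Shared fixtures.

The expensive end-to-end objects (synthetic curve, least-squares fit, MCMC
chains at the reduced validation scale) are session-scoped so the recovery
checks and the sampler diagnostics reuse one computation.
"""

import warnings

import numpy as np
import pytest

from nernstfit.fitting import fit_nls
from nernstfit.io import TimeActivityCurve
from nernstfit.mcmc import adaptive_metropolis, posterior_summary
from nernstfit.model import model_signal
from nernstfit.simulate import (
    SimulationScenario,
    generate_tac,
    scaled_times,
    simulation_study_truth,
)

#: Seed used for every seeded stochastic check in the suite.
SUITE_SEED = 1
#: Reduced validation protocol: 600 timepoints, 3 chains, 3000 retained.
PROTOCOL = dict(n_iter=4000, n_chains=3, burn_in=1000)


@pytest.fixture(scope="session")
def grid():
    return scaled_times()


@pytest.fixture(scope="session")
def high_flow_truth():
    return simulation_study_truth(kf=2.0)


@pytest.fixture(scope="session")
def study_tac(grid, high_flow_truth):
    """Seeded noisy curve from the simulation-study truth at kf = 2.0."""
    scen = SimulationScenario(
        truth=high_flow_truth, times=grid, count_scale=1e4, seed=SUITE_SEED
    )
    return generate_tac(scen)


@pytest.fixture(scope="session")
def noise_free_tac(grid, high_flow_truth):
    sig = model_signal(high_flow_truth, times=grid)
    return TimeActivityCurve(grid, sig, metadata={})


@pytest.fixture(scope="session")
def study_fit(study_tac):
    """Least-squares fit of the seeded study curve (baseline pinned at 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_nls(study_tac, fixed={"B": 0.0})


@pytest.fixture(scope="session")
def study_chains(study_tac, study_fit):
    """Adaptive-Metropolis chains at the reduced validation scale."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return adaptive_metropolis(
            study_tac, study_fit, seed=SUITE_SEED, **PROTOCOL
        )


@pytest.fixture(scope="session")
def study_summary(study_chains):
    return posterior_summary(study_chains)
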