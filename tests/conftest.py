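import numpy as np
import pytest
from hypothesis import settings

import neurotraj as nt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hrf_basis():
    return nt.build_hrf_basis(dt=0.1)


@pytest.fixture(scope="session")
def short_config():
    """Two-run short-variant session: 26 trials per load condition."""
    return nt.TaskConfig.for_variant("short", n_runs=2)


@pytest.fixture(scope="session")
def long_config():
    return nt.TaskConfig.for_variant("long", seed=7)


@pytest.fixture(scope="session")
def noiseless_session(short_config):
    """Noiseless simulated session with a planted 2.5x expansion."""
    truth = nt.TruthParams(expansion_factor=2.5, noise_sd=0.0)
    return nt.simulate_session(short_config, truth, seed=42)


@pytest.fixture(scope="session")
def noisy_session(short_config):
    """Simulated session at the study's trial-level SNR of 2."""
    truth = nt.TruthParams(expansion_factor=1.3, snr=2.0)
    return nt.simulate_session(short_config, truth, seed=7)


@pytest.fixture(scope="session")
def fitted_responses(noisy_session, hrf_basis):
    sim = noisy_session
    design = nt.build_design_matrix(sim.schedule, hrf_basis, n_scans=sim.ts.n_time)
    return nt.fit_trial_responses(sim.ts, design, hrf_basis)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
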