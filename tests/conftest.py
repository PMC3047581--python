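import numpy as np
import pytest

from lreqpcr import SimSpec, Strandedness, simulate_profile, simulate_run


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def noiseless_profile():
    """A clean, undistorted profile with its truth record."""
    return simulate_profile(SimSpec(noise_sd=0.0, seed=1))


@pytest.fixture
def noiseless_bare_profile():
    """Clean profile with zero instrument background: analysis of it is an
    exact fixed point (no baseline-estimation contamination)."""
    return simulate_profile(SimSpec(noise_sd=0.0, baseline=0.0, seed=1))


@pytest.fixture
def small_run():
    """A 2x2x3 noisy run with known per-set truth."""
    n_star = {
        ("AMP1", "S1"): 1e3,
        ("AMP1", "S2"): 1e4,
        ("AMP2", "S1"): 1e5,
        ("AMP2", "S2"): 5e3,
    }
    sim = simulate_run(2, 2, 3, seed=99, base_spec=SimSpec(), n_star=n_star)
    return sim, n_star
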