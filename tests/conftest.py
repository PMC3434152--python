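import numpy as np
import pytest

from whisknovelty.evaluate import run_scenario_grid


@pytest.fixture(scope="session")
def battery_grid():
    """Scaled scenario grid shared by the ordering, positivity and sweep
    checks: both whisking modes, k in {0, 0.025, 0.05}, 400 s, 10 trials."""
    return run_scenario_grid(
        whisking_modes=("stochastic", "periodic"),
        ks=(0.0, 0.025, 0.05),
        duration_s=400.0,
        n_trials=10,
        base_seed=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
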