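import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aircausal import default_config, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic dataset shared across tests (600 days, seed 7)."""
    cfg = default_config(n_days=600, seed=7)
    env, visits = simulate(cfg)
    return cfg, env, visits
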