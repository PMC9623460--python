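import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from trackfeat.simulate import ScenarioSpec, generate, generate_worked_sc6_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210101)


@pytest.fixture(scope="session")
def sc6_fixture():
    """Hand-built worked bundle plus the expected per-step tracks."""
    return generate_worked_sc6_fixture()


@pytest.fixture(scope="session")
def small_bundles():
    """One small generated bundle per scenario (shared across tests)."""
    return {
        sc: generate(ScenarioSpec(scenario=sc, n_units=6, seed=17))
        for sc in ("sc1", "sc2", "sc3", "sc4", "sc5", "sc6", "sc7", "sc8")
    }
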