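import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from plastdiv import Alignment, SimulationConfig, simulate


@pytest.fixture
def toy_alignment() -> Alignment:
    """Five taxa, hand-written columns exercising every site class."""
    return Alignment.from_strings([
        ("qxa", "ACGTA-CGTA"),
        ("qsp", "ACGTAACGTA"),
        ("qal", "ACCTAACGTA"),
        ("qaq", "ACGTAACGTA"),
        ("qru", "ACGTAACGAA"),
    ])


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated world (5 ingroup + outgroup, 10 kb)."""
    config = SimulationConfig(lsc_length=5_600, ira_length=1_600,
                              ssc_length=1_200, seed=11)
    reference, features, alignment, truth = simulate(config)
    return config, reference, features, alignment, truth
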