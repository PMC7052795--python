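import pytest

from loopasm.fixtures import generate_library, paper_test_designs
from loopasm.planner import plan_design, simulate_plan
from loopasm.schema import OverhangTable

SEED = 42


@pytest.fixture(scope="session")
def table():
    return OverhangTable.default()


@pytest.fixture(scope="session")
def library():
    return generate_library(seed=SEED, kits=("pCA",))


@pytest.fixture(scope="session")
def designs():
    return paper_test_designs(kit="pCA")


@pytest.fixture(scope="session")
def l4_sim(library, designs):
    """Simulated full level-4 tree (shared: this is the expensive fixture)."""
    plan = plan_design(designs["L4"], library)
    return simulate_plan(plan)


@pytest.fixture(scope="session")
def l1_product(library, designs):
    plan = plan_design(designs["L1-4_sfGFP"], library)
    return simulate_plan(plan)["root"]
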