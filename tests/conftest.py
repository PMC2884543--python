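import pytest

from tfdynamics.core import GeneCatalog, GeneRecord
from tfdynamics.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim_data():
    """One default synthetic dataset shared across read-only tests."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture()
def small_catalog():
    """Ten genes, three of them TFs in two families."""
    recs = [
        GeneRecord("g01", "alpha", True, "Homeobox"),
        GeneRecord("g02", "beta", True, "zf-C2H2"),
        GeneRecord("g03", "gamma", True, "none"),
    ] + [GeneRecord(f"g{i:02d}", f"sym{i}", False, "none") for i in range(4, 11)]
    return GeneCatalog(recs)


def make_catalog(n: int, k: int) -> GeneCatalog:
    """n genes, the first k flagged as TFs."""
    return GeneCatalog(
        [GeneRecord(f"g{i:04d}", f"g{i:04d}", i < k, "none") for i in range(n)]
    )
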