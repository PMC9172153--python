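import pytest

from splicedrift.exon_usage import usage_table
from splicedrift.readthrough import readthrough_table
from splicedrift.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def planted_sim():
    """One planted simulation at the default study conditions (seed 1)."""
    return simulate(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def planted_usage(planted_sim):
    g, s = planted_sim.genome, planted_sim.samples
    return usage_table(g.exons, s.junctions, s.expression, s.design)


@pytest.fixture(scope="session")
def planted_readthrough(planted_sim):
    g, s = planted_sim.genome, planted_sim.samples
    return readthrough_table(g.pas, s.coverage, s.expression, s.design)
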