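import hypothesis
import pytest

from comorbnet import GeneDiseaseTable, Interactome
from comorbnet.synthetic import SimulationConfig, simulate

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def tiny_gd():
    """4 diseases over 7 genes; D^T = 4 for the uniqueness examples."""
    records = [
        ("DA", "disease A", g) for g in ("g1", "g2", "g3")
    ] + [
        ("DB", "disease B", g) for g in ("g2", "g3", "g4", "g5")
    ] + [
        ("DC", "disease C", g) for g in ("g6",)
    ] + [
        ("DD", "disease D", g) for g in ("g1", "g6", "g7")
    ]
    return GeneDiseaseTable(records)


@pytest.fixture
def path_net():
    """The 4-node path a-b-c-d used throughout the separation examples."""
    return Interactome.from_edges([("a", "b", None), ("b", "c", None), ("c", "d", None)])


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down universe used by the CLI and round-trip tests."""
    return SimulationConfig(
        seed=11,
        n_genes=240,
        n_diseases=20,
        n_pathways=20,
        n_terms=60,
        n_mirnas=30,
        n_communities=6,
        genes_per_disease=(6, 10),
    )


@pytest.fixture(scope="session")
def small_universe(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def default_universe():
    """One universe at the standard study conditions (500 genes, 8 communities)."""
    return simulate(SimulationConfig(seed=7))
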