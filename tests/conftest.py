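import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from psanet.simulate import SimulationParams, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A fast cohort with every planted structure present."""
    return SimulationParams(
        n_genes=120,
        n_lncrnas=30,
        n_mirnas=15,
        frac_de_genes=0.5,
        frac_de_lncrnas=0.4,
        frac_de_mirnas=0.4,
        n_regulator_lncrnas=3,
        n_planted_modules=3,
        module_size=10,
        n_terms=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_params):
    return generate_cohort(small_params)


@pytest.fixture()
def two_triangles_bridge() -> nx.Graph:
    """Two triangles joined by a single bridge edge."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c")])
    g.add_edges_from([("d", "e"), ("d", "f"), ("e", "f")])
    g.add_edge("c", "d")
    return g
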