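import networkx as nx
import pytest

from famnet.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture
def star5() -> nx.Graph:
    """K1,4: center C with leaves L1..L4."""
    g = nx.Graph()
    g.add_edges_from([("C", f"L{i}") for i in range(1, 5)])
    return g


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic bundle shared by read-only tests."""
    cfg = SyntheticConfig(
        seed=11,
        n_background=400,
        n_family=12,
        planted_terms={"PLANTED": tuple(f"FAM{i:03d}" for i in range(1, 13))},
        planted_fold_changes={"FAM001": ("EAC", 4.0, "up")},
    )
    return generate_bundle(cfg)


def random_graph(rng, n: int, p: float) -> nx.Graph:
    """Erdős–Rényi graph over string labels, driven by a numpy Generator."""
    g = nx.Graph()
    labels = [f"N{i}" for i in range(n)]
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(labels[i], labels[j])
    return g
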