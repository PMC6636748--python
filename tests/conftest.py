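import numpy as np
import pytest

from cardigan import AnnotationCorpus, Interactome, Ontology, make_world


@pytest.fixture
def k2():
    """Single-edge network A-B with unit weight."""
    return Interactome.from_edges([("A", "B", 1.0)])


@pytest.fixture
def path3():
    """Path A-B-C with unit weights: degrees (1, 2, 1)."""
    return Interactome.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture(scope="session")
def world():
    """Default planted-module world shared by read-only tests."""
    return make_world(seed=11)


@pytest.fixture(scope="session")
def world_similarity(world):
    return world.similarity()


@pytest.fixture
def toy_ontology():
    """Six-term DAG:  root -> {x, y};  x -> {a, b};  y -> c;  {x,y} -> d."""
    return Ontology(
        {
            "root": [],
            "x": ["root"],
            "y": ["root"],
            "a": ["x"],
            "b": ["x"],
            "c": ["y"],
            "d": ["x", "y"],
        }
    )


@pytest.fixture
def toy_corpus(toy_ontology):
    ann = {
        "d1": {"a", "d"},
        "d2": {"b", "c"},
        "d3": {"c"},
        "d4": {"a"},
    }
    return AnnotationCorpus(ann, toy_ontology)


def random_interactome(rng: np.random.Generator, n: int, p: float = 0.3,
                       weighted: bool = False,
                       connect_isolated: bool = False) -> Interactome:
    """Erdős–Rényi helper used by property tests.

    ``connect_isolated`` attaches any degree-zero node to a random other
    node (fixtures for the cost-minimizer oracle need every degree > 0,
    where the closed form and the quadratic cost describe the same
    stationarity condition).
    """
    genes = [f"g{i:03d}" for i in range(n)]
    edges = []
    touched = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.1, 1.0)) if weighted else 1.0
                edges.append((genes[i], genes[j], w))
                touched.update((i, j))
    if connect_isolated:
        for i in range(n):
            if i not in touched:
                j = int(rng.integers(n - 1))
                j = j if j < i else j + 1
                edges.append((genes[i], genes[j], 1.0))
                touched.update((i, j))
    return Interactome.from_edges(edges, extra_genes=genes)
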