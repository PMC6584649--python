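import networkx as nx
import pytest

from phytoppi import FixtureSpec, generate_world
from phytoppi.go_semantics import GoDag, build_ic


@pytest.fixture()
def toy_go():
    """A 5-term DAG with a hand-counted annotation corpus of 8 proteins.

    Structure (child -> parent): C -> A, D -> A, D -> B, A -> R, B -> R.
    Propagated protein counts: R:8, A:5, B:4, C:2, D:2.
    """
    g = nx.DiGraph([("C", "A"), ("D", "A"), ("D", "B"), ("A", "R"), ("B", "R")])
    dag = GoDag(g, aspect_of={t: "CC" for t in g})
    annotations = {
        "p1": {"C"}, "p2": {"C"}, "p3": {"D"}, "p4": {"D"},
        "p5": {"A"}, "p6": {"B"}, "p7": {"B"}, "p8": {"R"},
    }
    build_ic(dag, annotations)
    return dag, annotations


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic organism shared by the module tests."""
    spec = FixtureSpec(
        n_proteins=80,
        n_positive_pairs=48,
        n_samples=30,
        n_reference_genomes=60,
        seed=11,
    )
    return generate_world(spec)
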