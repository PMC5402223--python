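import networkx as nx
import pytest
from hypothesis import settings

from ovaryseq.config import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def sim_config():
    """Small but fully featured synthetic study configuration."""
    return SimulationConfig(n_genes=300, n_reads=80, n_go_terms=40, seed=7)


@pytest.fixture
def chain_dag():
    """One namespace, a 4-term is_a chain under the root: t3->t2->t1->root."""
    dag = nx.DiGraph()
    dag.add_node("GO:0000001", name="bp root", namespace="BP")
    for i in (2, 3, 4):
        dag.add_node(f"GO:{i:07d}", name=f"t{i - 1}", namespace="BP")
        dag.add_edge(f"GO:{i:07d}", f"GO:{i - 1:07d}")
    return dag


@pytest.fixture
def small_dag():
    """Six terms in one namespace for hand-enumerated counting.

    R <- A <- B ; R <- C ; D is_a A and is_a C.
    """
    dag = nx.DiGraph()
    for term, name in [("R", "root"), ("A", "a"), ("B", "b"), ("C", "c"), ("D", "d")]:
        dag.add_node(term, name=name, namespace="BP")
    dag.add_edges_from([("A", "R"), ("B", "A"), ("C", "R"), ("D", "A"), ("D", "C")])
    return dag


def brute_force_ancestors(dag, term):
    """Independent reachability oracle: DFS over is_a edges."""
    seen = set()
    stack = [term]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(dag.successors(node))
    return seen
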