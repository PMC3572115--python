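import numpy as np
import pytest

from goganpa.netbuild import FunctionalNetwork
from goganpa.ontology import AnnotationSet, propagate
from goganpa.semsim import information_content
from goganpa.synthdata import gene_names, toy5
from goganpa.weighting import GeneSetCollection, weight_gene_sets


@pytest.fixture(scope="session")
def toy5_dag():
    return toy5()


@pytest.fixture(scope="session")
def toy5_anns(toy5_dag):
    """Four genes annotated to T3, T1, T2 and the root, propagated."""
    direct = {
        "g1": frozenset({"T3"}),
        "g2": frozenset({"T1"}),
        "g3": frozenset({"T2"}),
        "g4": frozenset({"R"}),
    }
    return propagate(toy5_dag, AnnotationSet(direct=direct))


@pytest.fixture(scope="session")
def toy5_ic(toy5_dag, toy5_anns):
    return information_content(toy5_anns, toy5_dag)


@pytest.fixture(scope="session")
def star_fixture():
    """A 50-gene network with one hub whose edges all fall inside a 10-gene
    set, while the 9 leaves also connect to 10 out-of-set genes each; only
    the hub ends up with weight > 1."""
    N = 50
    genes = gene_names(N)
    adj = np.zeros((N, N), dtype=bool)
    for j in range(1, 10):
        adj[0, j] = adj[j, 0] = True
    rng = np.random.default_rng(0)
    for j in range(1, 10):
        outs = rng.choice(np.arange(10, N), size=10, replace=False)
        adj[j, outs] = adj[outs, j] = True
    net = FunctionalNetwork(nodes=genes, adjacency=adj)
    coll = GeneSetCollection(
        sets={"STAR": frozenset(genes[:10])}, min_size=5, max_size=50
    )
    table = weight_gene_sets(net, coll)
    return net, coll, table


def brute_force_ancestors(edges: dict[str, set[str]], term: str) -> set[str]:
    """Independent transitive-closure oracle: repeated parent expansion."""
    out = {term}
    frontier = {term}
    while frontier:
        nxt = set()
        for t in frontier:
            nxt |= edges.get(t, set())
        frontier = nxt - out
        out |= nxt
    return out
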