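import numpy as np
import pytest
from hypothesis import settings

from numtclock.alignment import Alignment
from numtclock.gtr import GTRModel
from numtclock.tree import Tree

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def jc_model():
    return GTRModel()


@pytest.fixture
def gtr_model():
    return GTRModel(
        exchangeabilities=(1.2, 2.3, 0.8, 1.1, 3.3, 1.0),
        base_freqs=(0.3, 0.2, 0.25, 0.25),
    )


@pytest.fixture
def four_taxon_tree():
    return Tree.from_newick("((A:0.10,B:0.23):0.05,(C:0.30,D:0.02):0.11);")


@pytest.fixture
def small_alignment():
    return Alignment.from_sequences(
        {"A": "ACGTAC", "B": "ACGTTC", "C": "AAGT-C", "D": "ACGTNC"}
    )


def random_model(rng: np.random.Generator) -> GTRModel:
    ex = tuple(rng.uniform(0.3, 3.0, size=6))
    pi = rng.dirichlet(np.ones(4) * 5)
    return GTRModel(exchangeabilities=ex, base_freqs=tuple(pi))


def random_tree(rng: np.random.Generator, n_leaves: int) -> Tree:
    """Random rooted binary topology with uniform branch lengths."""
    from numtclock.tree import Node

    nodes = [Node(name=chr(65 + i), length=rng.uniform(0.01, 0.5)) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=rng.uniform(0.01, 0.5))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    return Tree(root)


def random_alignment(rng: np.random.Generator, ids, n_columns: int, p_gap=0.05) -> Alignment:
    chars = np.array(list("ACGT-"))
    probs = [0.25 * (1 - p_gap)] * 4 + [p_gap]
    data = rng.choice(5, size=(len(ids), n_columns), p=probs)
    return Alignment(ids=list(ids), data=chars[data])


def brute_force_loglik(tree: Tree, alignment: Alignment, model: GTRModel) -> float:
    """Exhaustive sum over all internal-node state assignments (test oracle)."""
    import itertools

    pi = np.array(model.base_freqs)
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    P = {id(n): model.transition_probabilities(n.length) for n in nodes}
    codes = {sid: alignment.row(sid) for sid in alignment.ids}
    total = 0.0
    for col in range(alignment.n_columns):
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            prob = pi[amap[id(tree.root)]]
            for n in nodes:
                if n is tree.root:
                    continue
                parent_state = amap[id(n.parent)]
                if n.is_leaf:
                    st = codes[n.name][col]
                    prob *= 1.0 if st == 4 else P[id(n)][parent_state, st]
                else:
                    prob *= P[id(n)][parent_state, amap[id(n)]]
            site += prob
        total += np.log(site)
    return total
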