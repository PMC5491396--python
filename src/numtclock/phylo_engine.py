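"""GTR maximum-likelihood machinery on fixed topologies.

Implements Felsenstein pruning with alignment-pattern compression, ML branch
length optimisation by cyclic per-edge univariate optimisation, neighbor
joining starting trees, and marginal ancestral state reconstruction by
inside–outside message passing.  Gaps and Ns are missing data: a tip with a
missing state contributes a vector of ones.

The engine is intentionally compact: it targets the small taxon counts
(<= a few dozen) of NUMT/mtDNA cassette alignments, not large-tree search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment, MISSING
from .gtr import GTRModel
from .tree import Node, Tree, TreeError

MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0
#: stop optimisation cycles once the log-likelihood gain drops below this
LL_TOL = 1e-6
MAX_CYCLES = 50


def _pattern_compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique alignment columns, their weights, and column->pattern map."""
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse


def _tip_partials(codes_row: np.ndarray) -> np.ndarray:
    """(n_patterns, 4) indicator partials; missing data -> all-ones."""
    P = np.zeros((codes_row.size, 4))
    obs = codes_row != MISSING
    P[obs, codes_row[obs]] = 1.0
    P[~obs, :] = 1.0
    return P


class LikelihoodEngine:
    """Pruning likelihood for one (tree, alignment, model) triple.

    Branch lengths are read from (and written back to) the tree's nodes.
    """

    def __init__(self, tree: Tree, alignment: Alignment, model: GTRModel):
        leaf_names = set(tree.leaf_names())
        if not leaf_names <= set(alignment.ids):
            missing = leaf_names - set(alignment.ids)
            raise TreeError(f"alignment lacks sequences for leaves: {sorted(missing)}")
        self.tree = tree
        self.model = model
        self.rates = model.gamma_rates()
        self.freqs = np.asarray(model.base_freqs)
        codes = np.stack([alignment.row(n.name) for n in tree.leaves()])
        self.patterns, self.weights, self.col_to_pattern = _pattern_compress(codes)
        self.n_patterns = self.patterns.shape[1]
        self._tips = {
            leaf.index: _tip_partials(self.patterns[i])
            for i, leaf in enumerate(tree.leaves())
        }

    # -- messages ----------------------------------------------------------
    def _edge_matrices(self, node: Node) -> np.ndarray:
        """(K,4,4) transition matrices for the branch above ``node``."""
        return self.model.transition_probabilities_many(node.length * self.rates)

    def _down_pass(self) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
        """Inside (post-order) partials.

        Returns ``down[v]`` = P(data below v | state at v), shape (K, P, 4),
        and ``up_msg[v]`` = message through the branch above v toward its
        parent, same shape.
        """
        K = len(self.rates)
        down: dict[int, np.ndarray] = {}
        up_msg: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                d = np.broadcast_to(self._tips[node.index], (K, self.n_patterns, 4))
            else:
                d = np.ones((K, self.n_patterns, 4))
                for child in node.children:
                    d = d * up_msg[child.index]
            down[node.index] = d
            if node is not self.tree.root:
                P = self._edge_matrices(node)
                up_msg[node.index] = np.einsum("kij,kpj->kpi", P, d)
        return down, up_msg

    def _site_likelihoods(self, down_root: np.ndarray) -> np.ndarray:
        """(P,) per-pattern likelihoods, averaged over rate categories."""
        per_cat = np.einsum("i,kpi->kp", self.freqs, down_root)
        return per_cat.mean(axis=0)

    def log_likelihood(self) -> float:
        down, _ = self._down_pass()
        site = self._site_likelihoods(down[self.tree.root.index])
        return float(self.weights @ np.log(site))

    def _outside_pass(
        self, down: dict[int, np.ndarray], up_msg: dict[int, np.ndarray]
    ) -> dict[int, np.ndarray]:
        """``out[v]`` = P(data outside v's subtree, state at v) incl. prior."""
        K = len(self.rates)
        out: dict[int, np.ndarray] = {
            self.tree.root.index: np.broadcast_to(
                self.freqs, (K, self.n_patterns, 4)
            ).copy()
        }
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            for child in node.children:
                above = out[node.index].copy()
                for sib in node.children:
                    if sib is not child:
                        above *= up_msg[sib.index]
                P = self._edge_matrices(child)
                out[child.index] = np.einsum("kij,kpi->kpj", P, above)
        return out

    # -- branch length optimisation ----------------------------------------
    def _optimize_edge(
        self,
        node: Node,
        down: dict[int, np.ndarray],
        up_msg: dict[int, np.ndarray],
        out: dict[int, np.ndarray],
    ) -> None:
        """ML length for the branch above ``node``, others fixed."""
        parent = node.parent
        above = out[parent.index].copy()
        for sib in parent.children:
            if sib is not node:
                above *= up_msg[sib.index]
        below = down[node.index]

        def neg_ll(log_t: float) -> float:
            P = self.model.transition_probabilities_many(np.exp(log_t) * self.rates)
            site = np.einsum("kpi,kij,kpj->p", above, P, below) / len(self.rates)
            return -float(self.weights @ np.log(np.maximum(site, 1e-300)))

        res = minimize_scalar(
            neg_ll,
            bounds=(np.log(MIN_BRANCH), np.log(MAX_BRANCH)),
            method="bounded",
            options={"xatol": 1e-7},
        )
        node.length = float(np.exp(res.x))

    def optimize_branch_lengths(self) -> float:
        """Cycle per-edge optimisation to convergence; returns final logL."""
        last = self.log_likelihood()
        for _ in range(MAX_CYCLES):
            edges = [n for n in self.tree.postorder() if n is not self.tree.root]
            for node in edges:
                down, up_msg = self._down_pass()
                out = self._outside_pass(down, up_msg)
                self._optimize_edge(node, down, up_msg, out)
            current = self.log_likelihood()
            if current - last < LL_TOL:
                return current
            last = current
        warnings.warn("branch-length optimisation did not converge; best so far kept")
        return last

    # -- ancestral states ----------------------------------------------------
    def marginal_posteriors(self) -> dict[int, np.ndarray]:
        """Per-node (n_columns, 4) marginal posteriors over {A,C,G,T}.

        Gamma categories are averaged with their posterior weights per site.
        """
        down, up_msg = self._down_pass()
        out = self._outside_pass(down, up_msg)
        site = self._site_likelihoods(down[self.tree.root.index])  # (P,)
        K = len(self.rates)
        posteriors: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            joint = (out[node.index] * down[node.index]).sum(axis=0) / K  # (P,4)
            post = joint / site[:, None]
            posteriors[node.index] = post[self.col_to_pattern]
        return posteriors


@dataclass
class AncestralStates:
    """Marginal ancestral reconstruction over a rooted tree.

    ``posteriors[node.index]`` is an (n_columns, 4) array summing to 1 per
    column; ``states[node.index]`` holds the argmax state codes, ties broken
    alphabetically (A < C < G < T).
    """

    tree: Tree
    posteriors: dict[int, np.ndarray]
    states: dict[int, np.ndarray]


def transition_probabilities(model: GTRModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the normalised GTR rate matrix; rows sum to 1."""
    return model.transition_probabilities(t)


def log_likelihood(tree: Tree, alignment: Alignment, model: GTRModel) -> float:
    """Pruning-algorithm log likelihood of the alignment on the tree."""
    return LikelihoodEngine(tree, alignment, model).log_likelihood()


def optimize_branch_lengths(
    tree: Tree, alignment: Alignment, model: GTRModel
) -> tuple[Tree, float]:
    """ML branch lengths on a fixed topology (tree is copied, not mutated)."""
    result = tree.copy()
    engine = LikelihoodEngine(result, alignment, model)
    ll = engine.optimize_branch_lengths()
    return result, ll


def marginal_ancestral_states(
    tree: Tree, alignment: Alignment, model: GTRModel
) -> AncestralStates:
    """Marginal (per-node, per-column) ancestral posteriors and argmax states."""
    engine = LikelihoodEngine(tree, alignment, model)
    posteriors = engine.marginal_posteriors()
    states = {idx: np.argmax(post, axis=1).astype(np.int8) for idx, post in posteriors.items()}
    return AncestralStates(tree=tree, posteriors=posteriors, states=states)


# -- distances and neighbor joining ---------------------------------------

def jc_distance_matrix(alignment: Alignment) -> tuple[np.ndarray, list[str]]:
    """Jukes–Cantor corrected pairwise distances, gaps/N excluded pairwise."""
    codes = alignment.encoded()
    n = alignment.n_seqs
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] != MISSING) & (codes[j] != MISSING)
            m = ok.sum()
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {alignment.ids[i]} and {alignment.ids[j]}"
                )
            p = np.mean(codes[i][ok] != codes[j][ok])
            p = min(p, 0.74)  # keep the JC correction finite
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D, list(alignment.ids)


def neighbor_joining(distance_matrix: np.ndarray, labels: list[str]) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (label_i, label_j) pair, where a cluster is labelled by its smallest
    member leaf; input row order therefore does not affect the topology.
    Negative branch-length estimates are clamped to zero.  The returned tree
    is the conventional unrooted NJ tree represented with a trifurcating
    root (bifurcating for fewer than four taxa).
    """
    D = np.array(distance_matrix, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if len(labels) != D.shape[0]:
        raise ValueError("labels do not match matrix size")
    nodes = [Node(name=lbl) for lbl in labels]
    keys = list(labels)  # cluster label = smallest member leaf name

    while len(nodes) > 3:
        n = len(nodes)
        totals = D.sum(axis=1)
        Q = (n - 2) * D - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in zip(*np.where(np.isclose(Q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, i, j = min(candidates)
        d_i = 0.5 * D[i, j] + (totals[i] - totals[j]) / (2.0 * (n - 2))
        d_j = D[i, j] - d_i
        parent = Node()
        nodes[i].length = max(d_i, 0.0)
        nodes[j].length = max(d_j, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_dists = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_dists[keep]])
        D = np.hstack([D, np.append(new_dists[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    root = Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lengths = [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2]
        for node, ln in zip(nodes, lengths):
            node.length = max(ln, 0.0)
            root.add_child(node)
    elif len(nodes) == 2:
        nodes[0].length = max(D[0, 1] / 2, 0.0)
        nodes[1].length = max(D[0, 1] / 2, 0.0)
        root.add_child(nodes[0])
        root.add_child(nodes[1])
    else:
        root = nodes[0]
    return Tree(root)


def infer_tree(
    alignment: Alignment, model: GTRModel, outgroup: str | None = None
) -> tuple[Tree, float]:
    """NJ starting topology + ML branch lengths; rooted on ``outgroup`` if given."""
    D, labels = jc_distance_matrix(alignment)
    topo = neighbor_joining(D, labels)
    if outgroup is not None:
        topo = topo.root_with_outgroup(outgroup)
    return optimize_branch_lengths(topo, alignment, model)
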