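"""Rooted phylogenetic tree with branch lengths in expected substitutions/site.

A deliberately small tree class: parent links, named leaves, traversals,
MRCA/path queries, rerooting on an outgroup, and Newick round-tripping
(parsing and serialisation are delegated to dendropy).  Branch roles that
matter to NUMT dating — the NUMT terminal branch, the human reference
branch, the stem between the NUMT attachment point and the human–chimp
coalescence — are derived from leaf names by :func:`branch_roles`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "parent", "children", "index")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length  # length of the branch above this node
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.index: int = -1  # assigned by Tree._reindex

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name or '*'}, len={self.length:.4g})"


class Tree:
    """Rooted tree; the root's ``length`` is ignored."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    def _reindex(self) -> None:
        self.nodes: list[Node] = list(self.postorder())
        for i, node in enumerate(self.nodes):
            node.index = i
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf names")
        self._by_name = {n.name: n for n in self.nodes if n.name is not None}

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise TreeError(f"no node named {name!r}") from None

    # -- queries -----------------------------------------------------------
    def ancestors(self, node: Node) -> list[Node]:
        """Ancestors from the parent of ``node`` up to and including the root."""
        out = []
        while node.parent is not None:
            node = node.parent
            out.append(node)
        return out

    def mrca(self, names: list[str]) -> Node:
        if not names:
            raise TreeError("mrca of empty set")
        paths = []
        for nm in names:
            node = self.find(nm)
            paths.append([node] + self.ancestors(node))
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first along any root-ward path
        for node in paths[0]:
            if node in common:
                return node
        raise TreeError("disconnected tree")  # pragma: no cover

    def distance(self, a: str | Node, b: str | Node) -> float:
        """Sum of branch lengths along the path between two nodes."""
        na = self.find(a) if isinstance(a, str) else a
        nb = self.find(b) if isinstance(b, str) else b
        anc_a = {n: i for i, n in enumerate([na] + self.ancestors(na))}
        total = 0.0
        node = nb
        while node not in anc_a:
            total += node.length
            node = node.parent
            if node is None:
                raise TreeError("nodes not connected")
        meet = node
        node = na
        while node is not meet:
            total += node.length
            node = node.parent
        return total

    def clade_leaf_names(self, node: Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf set below each internal (non-root, non-trivial) edge."""
        all_leaves = frozenset(self.leaf_names())
        out = []
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = self.clade_leaf_names(node)
            if 1 < len(side) < len(all_leaves):
                out.append(side)
        return out

    def has_clade(self, names: set[str]) -> bool:
        """True if some node's leaf set equals ``names`` exactly."""
        target = frozenset(names)
        return any(self.clade_leaf_names(n) == target for n in self.postorder())

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root))

    # -- rerooting ---------------------------------------------------------
    def root_with_outgroup(self, outgroup: str) -> "Tree":
        """Return a copy rooted on the branch above the outgroup leaf.

        The outgroup's branch is split in half by the new root.  A tree
        already rooted this way is returned unchanged (as a copy).
        """
        tree = self.copy()
        leaf = tree.find(outgroup)
        if leaf.parent is tree.root and len(tree.root.children) == 2:
            return tree
        # invert parent links from leaf.parent up to the old root; the edge
        # between path[i] and path[i+1] keeps its original length
        path = [leaf.parent] + tree.ancestors(leaf.parent)
        orig_len = [n.length for n in path]
        for node in path[:-1]:
            node.parent.children.remove(node)
        for i in range(len(path) - 1):
            lower, upper = path[i], path[i + 1]
            lower.children.append(upper)
            upper.parent = lower
            upper.length = orig_len[i]
        path[0].parent = None
        old_root = path[-1]
        if len(old_root.children) == 1:
            # suppress the degree-2 node left behind by rerooting
            only = old_root.children[0]
            parent = old_root.parent
            parent.children.remove(old_root)
            parent.children.append(only)
            only.parent = parent
            only.length += old_root.length
        pivot = path[0]
        pivot.children.remove(leaf)
        new_root = Node()
        half = leaf.length / 2.0
        leaf.length = half
        pivot.length = half
        pivot.parent = None
        new_root.add_child(leaf)
        new_root.add_child(pivot)
        return Tree(new_root)

    # -- newick ------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise TreeError(f"malformed newick: {exc}") from exc

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    body += node.name
            if node is self.root:
                return body
            return f"{body}:{node.length:.{precision}g}"

        return fmt(self.root) + ";"

    @classmethod
    def read_newick(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({len(self.leaves())} leaves)"


@dataclass
class BranchRoles:
    """The three quantities of the dating formula, read off a rooted tree.

    l_numt is the NUMT terminal branch length; l_stem the path length from
    the NUMT attachment node to the human–chimp coalescence node; l_human
    the path length from that coalescence node to the extant human
    reference tip.
    """

    numt_node: Node
    attachment_node: Node
    coalescence_node: Node
    human_ref_node: Node
    l_numt: float
    l_stem: float
    l_human: float


def branch_roles(
    tree: Tree, numt_id: str, human_ref_id: str, chimp_ids: list[str]
) -> BranchRoles:
    """Identify the NUMT, stem, and human branches on a rooted tree.

    The tree must be rooted so that the human–chimp coalescence is the MRCA
    of the human reference and the chimpanzee leaves (root with an outgroup
    first).
    """
    numt = tree.find(numt_id)
    luca = tree.mrca([human_ref_id] + list(chimp_ids))
    attach = numt.parent
    if attach is None:
        raise TreeError("NUMT leaf cannot be the root")
    return BranchRoles(
        numt_node=numt,
        attachment_node=attach,
        coalescence_node=luca,
        human_ref_node=tree.find(human_ref_id),
        l_numt=numt.length,
        l_stem=tree.distance(attach, luca),
        l_human=tree.distance(luca, human_ref_id),
    )
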