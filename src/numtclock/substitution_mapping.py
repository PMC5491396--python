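"""Branch assignment of substitutions and the conservation-score mixing model.

Substitutions on the NUMT terminal branch are a mixture: some happened
while the sequence still evolved as mtDNA (before nuclear insertion), the
rest accumulated neutrally as a pseudogene.  Because mitochondrial
evolution avoids conserved positions while neutral evolution does not, the
fraction of "variable"-bin (high conservation score) substitutions on a
branch carries a signature of its regime.  With

* ``F_numt`` — variable fraction of NUMT-branch substitutions,
* ``F_mito`` — variable fraction on the human mitochondrial branch,
* ``F_psd``  — variable fraction of random position sets (neutral null),

the mitochondrial share of NUMT-branch substitutions is estimated by the
linear mixing model ``f = 1 - (F_mito - F_numt) / (F_mito - F_psd)``.

Before the fractions are computed, a "hidden substitution" correction
repairs a known ancestral-reconstruction artifact: at a conserved site
where only the NUMT differs from every other leaf of its clade (and the
clade's ancestors), an erroneous state at the clade ancestor manufactures a
substitution-plus-reversion on interior branches; the correction collapses
it onto the NUMT terminal branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, MISSING, SiteScoreTable, CODE_TO_NUC
from .phylo_engine import AncestralStates
from .tree import Node, Tree

N_PSD_SETS = 500

CONSERVED = "conserved"
VARIABLE = "variable"


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class MutationEvent:
    """A single inferred substitution on one branch.

    ``branch`` is the name-or-index of the child node of the branch (leaf
    names for terminal branches); ``column`` is the 0-based alignment
    column; states are nucleotide characters.
    """

    branch: str
    column: int
    from_state: str
    to_state: str
    hidden_reassigned: bool = False


@dataclass
class MutationSet:
    events: list[MutationEvent] = field(default_factory=list)

    def on_branch(self, branch: str) -> list[MutationEvent]:
        return [e for e in self.events if e.branch == branch]

    def __len__(self) -> int:
        return len(self.events)


def _branch_label(node: Node) -> str:
    return node.name if node.name is not None else f"node{node.index}"


def _node_states(
    tree: Tree, ancestral: AncestralStates, alignment: Alignment
) -> dict[int, np.ndarray]:
    """Per-node state codes: observed at leaves, argmax posteriors inside."""
    states = {}
    for node in tree.postorder():
        if node.is_leaf:
            states[node.index] = alignment.row(node.name)
        else:
            states[node.index] = ancestral.states[node.index]
    return states


def assign_mutations(
    tree: Tree, ancestral: AncestralStates, alignment: Alignment
) -> MutationSet:
    """One event per (branch, column) where child state differs from parent.

    Columns with a gap or N at either end of a branch are skipped on that
    branch (indel history is not reconstructed).
    """
    states = _node_states(tree, ancestral, alignment)
    events = []
    for node in tree.postorder():
        if node is tree.root:
            continue
        child = states[node.index]
        parent = states[node.parent.index]
        ok = (child != MISSING) & (parent != MISSING) & (child != parent)
        for col in np.nonzero(ok)[0]:
            events.append(
                MutationEvent(
                    branch=_branch_label(node),
                    column=int(col),
                    from_state=CODE_TO_NUC[parent[col]],
                    to_state=CODE_TO_NUC[child[col]],
                )
            )
    return MutationSet(events=events)


def bin_score(score: float, range_low: float = -9.75, range_high: float = 4.87) -> str:
    """Classify a conservation score into the conserved or variable bin.

    The two bins split the declared score range at its midpoint; a score
    exactly on the boundary is "variable".  Scores outside the range are
    clamped with a warning.
    """
    if not np.isfinite(score):
        raise MappingError("score must be finite")
    if score < range_low or score > range_high:
        warnings.warn(f"score {score} outside declared range; clamped")
        score = min(max(score, range_low), range_high)
    boundary = (range_low + range_high) / 2.0
    return CONSERVED if score < boundary else VARIABLE


def column_positions(alignment: Alignment, ref_id: str) -> np.ndarray:
    """1-based ungapped reference position per alignment column (0 = gap)."""
    ref = alignment.row(ref_id)
    pos = np.cumsum(ref != MISSING)
    return np.where(ref != MISSING, pos, 0)


def column_bins(
    alignment: Alignment, ref_id: str, table: SiteScoreTable
) -> list[str | None]:
    """Conservation bin per alignment column; None where no score exists."""
    positions = column_positions(alignment, ref_id)
    out: list[str | None] = []
    for pos in positions:
        score = table.score_at(int(pos)) if pos > 0 else None
        out.append(
            None
            if score is None
            else bin_score(score, table.range_low, table.range_high)
        )
    return out


def detect_hidden(
    tree: Tree,
    ancestral: AncestralStates,
    alignment: Alignment,
    mutations: MutationSet,
    bins: list[str | None],
    numt_id: str,
) -> MutationSet:
    """Reassign "hidden" NUMT substitutions from interior stems.

    For every conserved-bin column where (a) all non-NUMT leaves of the
    NUMT-containing clade share one state, (b) every ancestor node above
    that clade is reconstructed with the same state, and (c) the NUMT leaf
    carries a different state, any substitution-then-reversion artifact —
    events at that column on the clade's stem or on its interior/terminal
    branches other than the NUMT branch — is replaced by a single flagged
    event on the NUMT terminal branch.
    """
    numt = tree.find(numt_id)
    clade = numt.parent
    if clade is None:
        return mutations
    states = _node_states(tree, ancestral, alignment)
    clade_nodes = {n.index for n in tree.postorder() if _is_descendant(n, clade)}
    sibling_leaves = [
        n for n in tree.leaves() if n.index in clade_nodes and n.name != numt_id
    ]
    ancestor_indices = [n.index for n in tree.ancestors(clade)]
    # branches whose events may be artifacts: the clade stem + everything
    # inside the clade except the NUMT terminal branch
    suspect = {_branch_label(n) for n in tree.postorder() if n.index in clade_nodes}
    suspect.discard(_branch_label(numt))

    numt_states = states[numt.index]
    events = list(mutations.events)
    for col, b in enumerate(bins):
        if b != CONSERVED:
            continue
        y = numt_states[col]
        if y == MISSING:
            continue
        leaf_states = {int(states[n.index][col]) for n in sibling_leaves}
        leaf_states.discard(MISSING)
        if len(leaf_states) != 1:
            continue
        x = leaf_states.pop()
        if y == x:
            continue
        if any(states[i][col] != x for i in ancestor_indices):
            continue
        removable = [
            e for e in events if e.column == col and e.branch in suspect
        ]
        if not removable:
            continue
        events = [e for e in events if not (e.column == col and e.branch in suspect)]
        events = [
            e for e in events if not (e.column == col and e.branch == _branch_label(numt))
        ]
        events.append(
            MutationEvent(
                branch=_branch_label(numt),
                column=col,
                from_state=CODE_TO_NUC[x],
                to_state=CODE_TO_NUC[y],
                hidden_reassigned=True,
            )
        )
    return MutationSet(events=events)


def _is_descendant(node: Node, ancestor: Node) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def variable_fraction(
    events: list[MutationEvent], bins: list[str | None]
) -> float:
    """Fraction of events at variable-bin columns.

    Events at columns without a conservation score are excluded from both
    numerator and denominator (with a warning).
    """
    if not events:
        raise MappingError("variable fraction undefined for zero events")
    scored = [e for e in events if bins[e.column] is not None]
    if len(scored) < len(events):
        warnings.warn(
            f"{len(events) - len(scored)} events at unscored positions excluded"
        )
    if not scored:
        raise MappingError("no events at scored positions")
    return float(np.mean([bins[e.column] == VARIABLE for e in scored]))


def simulated_psd_fraction(
    n_events: int,
    bins: list[str | None],
    n_sets: int = N_PSD_SETS,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Neutral-null variable fraction: mean over random position sets.

    Each of ``n_sets`` sets draws ``n_events`` distinct scored positions
    uniformly from the region and computes its variable fraction; the mean
    over sets estimates the variable fraction expected of substitutions
    placed with no regard to conservation.
    """
    scored = np.array([b == VARIABLE for b in bins if b is not None], dtype=float)
    if n_events < 1:
        raise MappingError("need at least one event")
    if n_events > scored.size:
        raise MappingError("more events than scored positions in the region")
    rng = np.random.default_rng(rng)
    fractions = np.empty(n_sets)
    for i in range(n_sets):
        picks = rng.choice(scored.size, size=n_events, replace=False)
        fractions[i] = scored[picks].mean()
    return float(fractions.mean())


@dataclass
class FractionEstimate:
    """Mixing-model estimate of the mitochondrial share of NUMT substitutions."""

    F_numt: float
    F_mito: float
    F_psd: float
    f_mito: float
    clamped: bool
    n_psd_sets: int = N_PSD_SETS


def mito_fraction(F_numt: float, F_mito: float, F_psd: float) -> FractionEstimate:
    """f = 1 - (F_mito - F_numt) / (F_mito - F_psd), clamped to [0, 1].

    Raises
    ------
    MappingError
        If F_mito == F_psd (degenerate contrast: the model cannot separate
        the regimes).  A warning is issued when F_mito < F_psd, which
        violates the model assumption that mitochondrial branches are
        enriched for variable-site substitutions.
    """
    for name, value in (("F_numt", F_numt), ("F_mito", F_mito), ("F_psd", F_psd)):
        if not 0.0 <= value <= 1.0:
            raise MappingError(f"{name} must be a fraction in [0, 1]")
    if F_mito == F_psd:
        raise MappingError("degenerate contrast: F_mito equals F_psd")
    if F_mito < F_psd:
        warnings.warn(
            "F_mito < F_psd: mitochondrial branch less variable-enriched than "
            "the neutral null; mixing-model assumption violated"
        )
    raw = 1.0 - (F_mito - F_numt) / (F_mito - F_psd)
    clamped = not 0.0 <= raw <= 1.0
    return FractionEstimate(
        F_numt=F_numt,
        F_mito=F_mito,
        F_psd=F_psd,
        f_mito=float(min(max(raw, 0.0), 1.0)),
        clamped=clamped,
    )
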