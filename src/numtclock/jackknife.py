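"""Diversity-aware jackknife resampling of alignment columns.

Instead of deleting columns uniformly, each replicate deletes a fixed
fraction (37% by default) of columns drawn without replacement with
probability proportional to the column's "diversity" — here the normalised
Shannon entropy of its residue frequencies.  Highly variable (nearly
neutral) positions are therefore deleted preferentially, weighting the
phylogenetic signal toward evolutionarily constrained positions.  The
replicate trees feed the topology-stability gate and the confidence
intervals of the insertion-time estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .gtr import GTRModel
from .tree import Tree
from . import phylo_engine

DEFAULT_FRACTION = 0.37
DEFAULT_REPLICATES = 200
#: pseudo-diversity added to every column so all-constant alignments still sample
EPSILON = 1e-6


@dataclass
class TaxonGroups:
    """Leaf-name roles in a NUMT/mtDNA cassette alignment."""

    numt_id: str
    human_ids: list[str]
    chimp_ids: list[str]
    gorilla_ids: list[str]
    outgroup_id: str | None = None
    human_ref_id: str | None = None

    def __post_init__(self) -> None:
        if self.human_ref_id is None:
            self.human_ref_id = self.human_ids[0]

    @property
    def mtdna_ids(self) -> list[str]:
        out = list(self.human_ids) + list(self.chimp_ids) + list(self.gorilla_ids)
        if self.outgroup_id:
            out.append(self.outgroup_id)
        return out


def column_diversity(alignment: Alignment) -> np.ndarray:
    """Per-column diversity in [0, 1]: Shannon entropy of the A/C/G/T
    frequencies (gaps and Ns excluded) normalised by log 4.

    Constant or fully missing columns score 0; an equal four-way split
    scores 1; an equal two-state split scores 0.5.
    """
    codes = alignment.encoded()
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)], axis=0).astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        plogp = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    entropy = -plogp.sum(axis=0)
    return entropy / np.log(4.0)


def column_polymorphism(alignment: Alignment) -> np.ndarray:
    """Per-column diversity as a fixed/variable indicator: 1 if the column
    carries more than one residue (gaps/N ignored), else 0.

    This is the coarsest diversity notion — evolutionarily fixed positions
    are (almost) never deleted, variable positions are deleted with equal
    probability — and the default weight for replicate tree inference.
    Deleting a constant column does not change the inferred tree, and
    uniform deletion over the variable columns is the unique weighting
    that leaves expected branch-length *ratios* unchanged; graded weights
    (entropy or state counts) preferentially remove whichever branch's
    signal happens to sit at high-scoring columns and bias the
    insertion-time replicates.
    """
    return (column_state_diversity(alignment) > 0).astype(float)


def column_state_diversity(alignment: Alignment) -> np.ndarray:
    """Per-column diversity as (number of observed states - 1) / 3, in [0, 1].

    An alternative to :func:`column_diversity` that scores a column by how
    many alternative residues it carries rather than by the balance of
    their frequencies: a neutrally evolving position tends to occur in
    several alternative states, while a clean two-state species split and a
    singleton substitution both score 1/3.
    """
    codes = alignment.encoded()
    n_states = np.stack([(codes == s).any(axis=0) for s in range(4)]).sum(axis=0)
    return np.maximum(n_states - 1, 0) / 3.0


def jackknife_sample(
    alignment: Alignment,
    diversity: np.ndarray | None = None,
    fraction: float = DEFAULT_FRACTION,
    rng: np.random.Generator | int | None = None,
) -> tuple[Alignment, np.ndarray]:
    """Delete exactly ``round(fraction * n_columns)`` columns.

    Columns are deleted without replacement with probability proportional to
    ``diversity + EPSILON`` (uniform when all diversities are zero).  Column
    order of the retained columns is preserved.

    Returns
    -------
    (sub_alignment, kept_columns)
        The jackknifed alignment and the 0-based indices of retained columns.
    """
    if not 0 < fraction < 1:
        raise ValueError("deletion fraction must be in (0, 1)")
    rng = np.random.default_rng(rng)
    if diversity is None:
        diversity = column_diversity(alignment)
    diversity = np.asarray(diversity, dtype=float)
    if diversity.shape != (alignment.n_columns,):
        raise ValueError("diversity length does not match alignment columns")
    n_delete = int(round(fraction * alignment.n_columns))
    weights = diversity + EPSILON
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    deleted = rng.choice(
        alignment.n_columns, size=n_delete, replace=False, p=weights / weights.sum()
    )
    mask = np.ones(alignment.n_columns, dtype=bool)
    mask[deleted] = False
    kept = np.nonzero(mask)[0]
    return alignment.take_columns(kept), kept


def replicate_trees(
    alignment: Alignment,
    model: GTRModel,
    n_replicates: int = DEFAULT_REPLICATES,
    fraction: float = DEFAULT_FRACTION,
    seed: int | None = None,
    outgroup: str | None = None,
    diversity_fn=column_polymorphism,
) -> list[Tree]:
    """Infer one tree (NJ start + ML branch lengths) per jackknife replicate.

    Replicate seeds are spawned deterministically from the master seed, so
    the same seed always yields the same list of trees.  ``diversity_fn``
    chooses the deletion-weight measure (the fixed/variable indicator by
    default; pass :func:`column_diversity` or
    :func:`column_state_diversity` for graded weightings).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    diversity = diversity_fn(alignment)
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    trees = []
    for i, stream in enumerate(streams):
        sub, _ = jackknife_sample(
            alignment, diversity, fraction, np.random.default_rng(stream)
        )
        try:
            tree, _ = phylo_engine.infer_tree(sub, model, outgroup=outgroup)
        except Exception as exc:  # noqa: BLE001 - annotate replicate index
            raise RuntimeError(f"replicate {i} failed: {exc}") from exc
        trees.append(tree)
    return trees


@dataclass
class SupportResult:
    n_replicates: int
    n_supporting: int

    @property
    def support(self) -> float:
        return self.n_supporting / self.n_replicates


def _tree_supports(tree: Tree, groups: TaxonGroups) -> bool:
    present = set(tree.leaf_names())
    humans = set(groups.human_ids) & present
    chimps = set(groups.chimp_ids) & present
    if groups.outgroup_id and groups.outgroup_id in present:
        tree = tree.root_with_outgroup(groups.outgroup_id)
    hc = humans | chimps
    species_ok = tree.has_clade(hc) or tree.has_clade(hc | {groups.numt_id})
    numt = tree.find(groups.numt_id)
    parent_leaves = tree.clade_leaf_names(numt.parent)
    numt_ok = parent_leaves <= (humans | {groups.numt_id})
    return species_ok and numt_ok


def topology_support(trees: list[Tree], groups: TaxonGroups) -> SupportResult:
    """Fraction of replicate trees with the correct species topology.

    A tree "supports" the reference grouping when (a) the human+chimp
    leaves form a clade to the exclusion of gorilla (with the NUMT allowed
    inside it), and (b) the NUMT attaches within, or sister to, the human
    clade.  Trees are rooted with the outgroup before evaluation, so the
    result does not depend on how replicates were rooted.
    """
    leaf_sets = {frozenset(t.leaf_names()) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("replicate trees do not share a leaf set")
    n_ok = sum(_tree_supports(t, groups) for t in trees)
    return SupportResult(n_replicates=len(trees), n_supporting=n_ok)
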