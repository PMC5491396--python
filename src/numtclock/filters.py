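"""Candidate-NUMT selection filters.

Three gates decide whether a NUMT enters the dating analysis:

1. pairwise divergence from the reference human mtDNA must not exceed 10%
   (more divergent NUMTs predate the target 0–6 Ma window; chimp mtDNA is
   at most ~8% divergent from human by the same measure);
2. an alignment-quality gate on log10 E-values: values above the outlier
   boundary Q3 + c*(Q3-Q1) (c = 0.5 by default) mark poorly mapped NUMTs;
3. a topology-stability gate: the jackknife support of the correct
   human/chimp/gorilla topology must be at least 70%.

A separate check flags NUMT pairs that share a pseudogene-only stem in a
joint tree — such pairs descend from a single ancestral insertion and must
not be counted as independent events.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alignment import MISSING
from .tree import Tree

DIVERGENCE_THRESHOLD = 0.10
SUPPORT_THRESHOLD = 0.70
IQR_CONSTANT = 0.5
#: E-values of exactly zero are capped here before taking log10
MIN_EVALUE = 1e-300


class FilterError(ValueError):
    pass


@dataclass
class FilterReport:
    """Per-NUMT record of every gate decision."""

    numt_id: str
    pairwise_divergence: float | None = None
    log10_evalue: float | None = None
    divergence_pass: bool = False
    evalue_pass: bool = True
    topology_support: float | None = None
    topology_pass: bool = False

    @property
    def final_pass(self) -> bool:
        return self.divergence_pass and self.evalue_pass and self.topology_pass


@dataclass
class IndependenceFlag:
    numt_pair: tuple[str, str]
    shared_stem: bool
    support: float | None = None


def pairwise_divergence(seq_a: np.ndarray | str, seq_b: np.ndarray | str) -> float:
    """Fraction of differing positions between two aligned sequences.

    Positions where either sequence has a gap or N are excluded from both
    numerator and denominator.  Accepts strings or integer-coded arrays.
    """
    from .alignment import Alignment

    if isinstance(seq_a, str) or isinstance(seq_b, str):
        aln = Alignment.from_sequences({"a": str(seq_a), "b": str(seq_b)})
        seq_a, seq_b = aln.encoded()
    seq_a = np.asarray(seq_a)
    seq_b = np.asarray(seq_b)
    if seq_a.shape != seq_b.shape:
        raise FilterError("sequences must be aligned to equal length")
    ok = (seq_a != MISSING) & (seq_b != MISSING)
    if not ok.any():
        raise FilterError("no comparable (non-gap, non-N) positions")
    return float(np.mean(seq_a[ok] != seq_b[ok]))


def divergence_filter(
    reports: list[FilterReport], threshold: float = DIVERGENCE_THRESHOLD
) -> tuple[list[FilterReport], list[FilterReport]]:
    """Partition reports into (retained, discarded) by the divergence gate.

    NUMTs diverging by *more than* the threshold are discarded; a NUMT at
    exactly the threshold is retained.
    """
    retained, discarded = [], []
    for rep in reports:
        rep.divergence_pass = rep.pairwise_divergence <= threshold
        (retained if rep.divergence_pass else discarded).append(rep)
    return retained, discarded


def evalue_outlier_boundary(
    log10_evalues: list[float] | np.ndarray, iqr_constant: float = IQR_CONSTANT
) -> float:
    """Outlier boundary Q3 + c*(Q3 - Q1) of log10 E-values.

    Quartiles use linear interpolation between order statistics.  Values
    strictly above the boundary mark poorly aligned NUMTs.
    """
    values = np.asarray(log10_evalues, dtype=float)
    if values.size < 4 or not np.isfinite(values).all():
        raise FilterError("need at least 4 finite log10 E-values")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 + iqr_constant * (q3 - q1))


def log10_evalue(evalue: float) -> float:
    """log10 of an E-value, with exact zeros capped at 1e-300."""
    return float(np.log10(max(evalue, MIN_EVALUE)))


def evalue_filter(
    reports: list[FilterReport], iqr_constant: float = IQR_CONSTANT
) -> tuple[list[FilterReport], list[FilterReport]]:
    """Apply the E-value outlier gate; reports lacking E-values pass."""
    scored = [r for r in reports if r.log10_evalue is not None]
    if len(scored) >= 4:
        boundary = evalue_outlier_boundary(
            [r.log10_evalue for r in scored], iqr_constant
        )
        for rep in scored:
            rep.evalue_pass = rep.log10_evalue <= boundary
    retained = [r for r in reports if r.evalue_pass]
    discarded = [r for r in reports if not r.evalue_pass]
    return retained, discarded


def topology_gate(support: float, threshold: float = SUPPORT_THRESHOLD) -> bool:
    """True (pass) unless the support is strictly below the threshold."""
    if not 0.0 <= support <= 1.0:
        raise FilterError("support must be a fraction in [0, 1]")
    return support >= threshold


def independence_check(
    tree: Tree,
    numt_ids: list[str],
    mtdna_ids: list[str],
    replicate_trees: list[Tree] | None = None,
) -> list[IndependenceFlag]:
    """Flag NUMT pairs that share a pseudogene-only stem.

    A pair shares a stem when some edge of the (unrooted) joint tree
    separates both NUMTs from every mtDNA leaf — evidence that the two
    copies descend from one ancestral pseudogene and are not independent
    insertions.  When ``replicate_trees`` is given, ``support`` is the
    fraction of those trees in which the pair shares a stem.
    """
    present = set(tree.leaf_names())
    for name in list(numt_ids) + list(mtdna_ids):
        if name not in present:
            raise FilterError(f"leaf {name!r} missing from tree")
    mt = set(mtdna_ids)

    def shares_stem(t: Tree, a: str, b: str) -> bool:
        all_leaves = set(t.leaf_names())
        for node in t.postorder():
            if node is t.root:
                continue
            side = set(t.clade_leaf_names(node))
            for component in (side, all_leaves - side):
                if {a, b} <= component and not (component & mt):
                    return True
        return False

    flags = []
    for a, b in itertools.combinations(sorted(numt_ids), 2):
        shared = shares_stem(tree, a, b)
        support = None
        if replicate_trees:
            support = float(np.mean([shares_stem(t, a, b) for t in replicate_trees]))
        flags.append(IndependenceFlag(numt_pair=(a, b), shared_stem=shared, support=support))
    return flags
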