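"""Synthetic NUMT/mtDNA cassette datasets with known truth.

Emulates the inputs of the dating analysis: a great-ape mtDNA species tree
(((human, chimp), gorilla), outgroup) with several tips per species plus
optional ancient-human tips, a NUMT lineage that leaves the human mtDNA
lineage at a known time and switches to a neutral substitution regime at a
known insertion time, and a per-position conservation-score table whose
scores correlate with site-wise substitution constraint.

Two site classes drive the signal the mixing model relies on: "conserved"
columns substitute at a reduced rate on mitochondrial-regime branches
(purifying selection) but at the full neutral rate after insertion;
"variable" columns are unconstrained throughout.  Conserved columns draw
scores from the lower half of the declared score range, variable columns
from the upper half, so the midpoint binning recovers the class exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignment import Alignment, CODE_TO_NUC, SiteScoreTable
from .gtr import GTRModel
from .jackknife import TaxonGroups
from .tree import Node, Tree

NUMT_ID = "NUMT"
HUMAN_REF_ID = "human_ref"
OUTGROUP_ID = "outgroup"

MITO = "mito"
PSEUDO = "pseudo"


class ConfigurationError(ValueError):
    pass


def _default_divergence_times() -> dict[str, float]:
    # the deep outgroup and within-clade TMRCAs give the cassette the high
    # overall polymorphism of real multi-genus mtDNA alignments; the
    # diversity-weighted jackknife then spends its deletion budget on the
    # hypervariable deep-branch columns rather than the species-split signal
    return {
        "human_chimp": 6.0,
        "gorilla": 16.0,
        "outgroup": 80.0,
        "human_tmrca": 0.4,
        "chimp_tmrca": 3.0,
        "gorilla_tmrca": 2.5,
    }


def _default_gtr() -> GTRModel:
    # transition-biased exchangeabilities and CG-poor frequencies, mtDNA-like
    return GTRModel(
        exchangeabilities=(1.0, 6.0, 1.0, 1.0, 6.0, 1.0),
        base_freqs=(0.31, 0.31, 0.13, 0.25),
    )


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Rates are in substitutions/site/Ma and are deliberately inflated
    relative to empirical mtDNA clocks so that kilobase-scale alignments
    carry enough substitutions for stable estimation.
    """

    n_taxa_per_species: int = 3
    n_ancient_humans: int = 1
    divergence_times: dict[str, float] = field(default_factory=_default_divergence_times)
    numt_branch_time: float = 4.5
    numt_insertion_time: float = 2.8
    seq_length: int = 4000
    mito_clock_rate: float = 0.018
    pseudo_clock_rate: float = 0.005
    conserved_site_fraction: float = 0.65
    conserved_rate_multiplier: float = 0.12
    ancient_tip_age: float = 0.05
    numt_gap_fraction: float = 0.0
    score_range: tuple[float, float] = (-9.75, 4.87)
    gtr: GTRModel = field(default_factory=_default_gtr)
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.divergence_times
        if not 0.0 <= self.numt_insertion_time <= self.numt_branch_time:
            raise ConfigurationError(
                "need 0 <= numt_insertion_time <= numt_branch_time"
            )
        if not self.numt_branch_time <= d["human_chimp"]:
            raise ConfigurationError("NUMT branching must predate the present "
                                     "and postdate the human–chimp split")
        if not d["human_tmrca"] < self.numt_branch_time:
            raise ConfigurationError(
                "NUMT must branch off before the human mtDNA coalescence"
            )
        if not d["human_chimp"] < d["gorilla"] < d["outgroup"]:
            raise ConfigurationError("splits must be ordered human-chimp < gorilla < outgroup")
        if min(self.mito_clock_rate, self.pseudo_clock_rate) <= 0:
            raise ConfigurationError("clock rates must be positive")
        if not 0.0 <= self.conserved_site_fraction <= 1.0:
            raise ConfigurationError("conserved_site_fraction must be in [0, 1]")
        if not 0.0 < self.conserved_rate_multiplier <= 1.0:
            raise ConfigurationError("conserved_rate_multiplier must be in (0, 1]")
        if self.n_taxa_per_species < 1 or self.seq_length < 1:
            raise ConfigurationError("need at least one taxon per species and one site")
        if not 0.0 <= self.numt_gap_fraction < 1.0:
            raise ConfigurationError("numt_gap_fraction must be in [0, 1)")

    def taxon_groups(self) -> TaxonGroups:
        humans = [HUMAN_REF_ID] + [
            f"human_{i}" for i in range(1, self.n_taxa_per_species)
        ] + [f"ancient_{i}" for i in range(1, self.n_ancient_humans + 1)]
        return TaxonGroups(
            numt_id=NUMT_ID,
            human_ids=humans,
            chimp_ids=[f"chimp_{i}" for i in range(1, self.n_taxa_per_species + 1)],
            gorilla_ids=[f"gorilla_{i}" for i in range(1, self.n_taxa_per_species + 1)],
            outgroup_id=OUTGROUP_ID,
            human_ref_id=HUMAN_REF_ID,
        )


@dataclass(frozen=True)
class SimEvent:
    """A simulated substitution (endpoint difference on a branch segment)."""

    branch: str
    column: int
    from_state: str
    to_state: str
    regime: str  # "mito" or "pseudo"


@dataclass
class TrueHistory:
    """Ground truth of a simulated dataset."""

    tree: Tree  # branch lengths in expected substitutions/site (class-averaged)
    node_ages: dict[str, float]
    insertion_time: float
    numt_branch_time: float
    per_site_class: np.ndarray  # "conserved" / "variable" per column
    mutation_log: list[SimEvent]

    def numt_events(self) -> list[SimEvent]:
        return [e for e in self.mutation_log if e.branch == NUMT_ID]

    @property
    def true_mito_fraction(self) -> float:
        events = self.numt_events()
        if not events:
            return float("nan")
        return float(np.mean([e.regime == MITO for e in events]))


def _build_time_tree(config: SimulationConfig) -> tuple[Tree, dict[str, float]]:
    """Species tree with the NUMT lineage; returns tree and node ages (Ma)."""
    d = config.divergence_times
    groups = config.taxon_groups()
    ages: dict[str, float] = {}

    def caterpillar(names, tip_ages, tmrca, label):
        spine = Node(name=names[0])
        ages[names[0]] = tip_ages[0]
        if len(names) == 1:
            return spine
        join_ages = [tmrca * i / (len(names) - 1) for i in range(1, len(names))]
        for i, (name, join_age) in enumerate(zip(names[1:], join_ages), start=1):
            tip = Node(name=name)
            ages[name] = tip_ages[i]
            parent = Node(name=f"anc_{label}_{i}")
            ages[parent.name] = join_age
            parent.add_child(spine)
            parent.add_child(tip)
            spine = parent
        return spine

    extant = [HUMAN_REF_ID] + [f"human_{i}" for i in range(1, config.n_taxa_per_species)]
    ancients = [f"ancient_{i}" for i in range(1, config.n_ancient_humans + 1)]
    human_names = extant + ancients
    human_tip_ages = [0.0] * len(extant) + [config.ancient_tip_age] * len(ancients)
    human = caterpillar(human_names, human_tip_ages, d["human_tmrca"], "human")

    chimp = caterpillar(
        groups.chimp_ids, [0.0] * len(groups.chimp_ids), d["chimp_tmrca"], "chimp"
    )
    gorilla = caterpillar(
        groups.gorilla_ids, [0.0] * len(groups.gorilla_ids), d["gorilla_tmrca"], "gorilla"
    )

    numt = Node(name=NUMT_ID)
    ages[NUMT_ID] = 0.0
    attach = Node(name="anc_numt")
    ages["anc_numt"] = config.numt_branch_time
    attach.add_child(human)
    attach.add_child(numt)

    luca = Node(name="luca")
    ages["luca"] = d["human_chimp"]
    luca.add_child(attach)
    luca.add_child(chimp)

    anc_gorilla = Node(name="anc_gorilla")
    ages["anc_gorilla"] = d["gorilla"]
    anc_gorilla.add_child(luca)
    anc_gorilla.add_child(gorilla)

    outgroup = Node(name=OUTGROUP_ID)
    ages[OUTGROUP_ID] = 0.0
    root = Node(name="root")
    ages["root"] = d["outgroup"]
    root.add_child(anc_gorilla)
    root.add_child(outgroup)
    return Tree(root), ages


def _class_rate(config: SimulationConfig) -> float:
    """Mean substitution rate multiplier across site classes (mito regime)."""
    csf = config.conserved_site_fraction
    return csf * config.conserved_rate_multiplier + (1.0 - csf)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Alignment, SiteScoreTable, TrueHistory]:
    """Evolve one NUMT/mtDNA cassette alignment under the configured history.

    Identical configs (including seed) produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    tree, ages = _build_time_tree(config)
    L = config.seq_length
    csf = config.conserved_site_fraction
    site_class = np.where(rng.random(L) < csf, "conserved", "variable")
    conserved_mask = site_class == "conserved"

    freqs = np.asarray(config.gtr.base_freqs)
    root_states = rng.choice(4, size=L, p=freqs)

    states: dict[str, np.ndarray] = {tree.root.name: root_states}
    events: list[SimEvent] = []

    def evolve_segment(parent_states, branch_lengths_by_class, branch, regime):
        """Sample child states given per-class branch lengths (subs/site)."""
        child = parent_states.copy()
        for cls, mask in (("conserved", conserved_mask), ("variable", ~conserved_mask)):
            t = branch_lengths_by_class[cls]
            if t <= 0 or not mask.any():
                continue
            P = config.gtr.transition_probabilities(t)
            for s in range(4):
                sel = mask & (parent_states == s)
                n = int(sel.sum())
                if n:
                    child[sel] = rng.choice(4, size=n, p=P[s])
        changed = np.nonzero(child != parent_states)[0]
        for col in changed:
            events.append(
                SimEvent(
                    branch=branch,
                    column=int(col),
                    from_state=CODE_TO_NUC[parent_states[col]],
                    to_state=CODE_TO_NUC[child[col]],
                    regime=regime,
                )
            )
        return child

    mult = config.conserved_rate_multiplier
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[node.parent.name]
        duration = ages[node.parent.name] - ages[node.name]
        if duration < 0:
            raise ConfigurationError(f"negative branch duration at {node.name}")
        if node.name == NUMT_ID:
            t_mito = config.numt_branch_time - config.numt_insertion_time
            mid = evolve_segment(
                parent_states,
                {
                    "conserved": t_mito * config.mito_clock_rate * mult,
                    "variable": t_mito * config.mito_clock_rate,
                },
                NUMT_ID,
                MITO,
            )
            t_psd = config.numt_insertion_time
            child = evolve_segment(
                mid,
                {
                    "conserved": t_psd * config.pseudo_clock_rate,
                    "variable": t_psd * config.pseudo_clock_rate,
                },
                NUMT_ID,
                PSEUDO,
            )
            node.length = (
                t_mito * config.mito_clock_rate * _class_rate(config)
                + t_psd * config.pseudo_clock_rate
            )
        else:
            child = evolve_segment(
                parent_states,
                {
                    "conserved": duration * config.mito_clock_rate * mult,
                    "variable": duration * config.mito_clock_rate,
                },
                node.name,
                MITO,
            )
            node.length = duration * config.mito_clock_rate * _class_rate(config)
        states[node.name] = child

    rows = {}
    for leaf in tree.leaves():
        seq = CODE_TO_NUC[states[leaf.name]].copy()
        if leaf.name == NUMT_ID and config.numt_gap_fraction > 0:
            gaps = rng.random(L) < config.numt_gap_fraction
            seq[gaps] = "-"
        rows[leaf.name] = "".join(seq)
    alignment = Alignment.from_sequences(rows, numt_id=NUMT_ID)

    low, high = config.score_range
    mid_score = (low + high) / 2.0
    scores = np.where(
        conserved_mask,
        rng.uniform(low, mid_score, size=L),
        rng.uniform(mid_score, high, size=L),
    )
    table = SiteScoreTable(
        positions=np.arange(1, L + 1), scores=scores, range_low=low, range_high=high
    )
    truth = TrueHistory(
        tree=tree,
        node_ages=ages,
        insertion_time=config.numt_insertion_time,
        numt_branch_time=config.numt_branch_time,
        per_site_class=site_class,
        mutation_log=events,
    )
    return alignment, table, truth


def simulate_cohort(
    base_config: SimulationConfig,
    insertion_times: list[float],
    branch_times: list[float] | None = None,
    seed: int | None = None,
) -> list[tuple[Alignment, SiteScoreTable, TrueHistory]]:
    """Independent datasets sharing the species tree, one NUMT each.

    Each cohort member reuses ``base_config`` with its own insertion time
    (and optionally branching time) and a seed spawned from ``seed``.
    """
    if branch_times is None:
        branch_times = [max(t, base_config.numt_branch_time) for t in insertion_times]
    if len(branch_times) != len(insertion_times):
        raise ConfigurationError("branch_times must match insertion_times")
    seeds = np.random.SeedSequence(seed).spawn(len(insertion_times))
    out = []
    for t_ins, t_branch, ss in zip(insertion_times, branch_times, seeds):
        cfg_dict = {
            **{k: v for k, v in base_config.__dict__.items()},
            "numt_insertion_time": t_ins,
            "numt_branch_time": t_branch,
            "seed": int(ss.generate_state(1)[0] % (2**31)),
        }
        out.append(simulate_dataset(SimulationConfig(**cfg_dict)))
    return out


# -- fixtures ---------------------------------------------------------------

def write_fixture(
    dataset: tuple[Alignment, SiteScoreTable, TrueHistory], directory: str | Path
) -> dict[str, Path]:
    """Write alignment.fasta, scores.tsv and truth.json into ``directory``."""
    alignment, table, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": directory / "alignment.fasta",
        "scores": directory / "scores.tsv",
        "truth": directory / "truth.json",
    }
    alignment.write_fasta(paths["alignment"])
    table.write_tsv(paths["scores"])
    record = {
        "insertion_time": truth.insertion_time,
        "numt_branch_time": truth.numt_branch_time,
        "true_mito_fraction": truth.true_mito_fraction,
        "n_numt_events": len(truth.numt_events()),
        "tree_newick": truth.tree.to_newick(),
        "node_ages": truth.node_ages,
        "per_site_class": "".join("C" if c == "conserved" else "V" for c in truth.per_site_class),
        "mutation_log": [asdict(e) for e in truth.mutation_log],
    }
    paths["truth"].write_text(json.dumps(record, indent=1))
    return paths


def read_fixture(directory: str | Path) -> tuple[Alignment, SiteScoreTable, dict]:
    """Load a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    alignment = Alignment.read_fasta(directory / "alignment.fasta", numt_id=NUMT_ID)
    table = SiteScoreTable.read_tsv(directory / "scores.tsv")
    truth = json.loads((directory / "truth.json").read_text())
    return alignment, table, truth
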