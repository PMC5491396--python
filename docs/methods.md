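# Methods

## The problem

NUMTs are nuclear copies of mitochondrial DNA. Until a NUMT inserts into a
chromosome its sequence evolves as mtDNA — fast, and under purifying
selection that suppresses change at functionally constrained positions.
After insertion it evolves as a neutral pseudogene — slower, and blind to
the old constraints. The terminal branch leading to a NUMT in an mtDNA
phylogeny is therefore a *mixture* of two substitution regimes, and the
mixture proportion encodes when the insertion happened.

`numtclock` estimates that time for NUMTs that inserted into the human
lineage after the human–chimpanzee divergence, and tests whether the
estimated insertion times cluster in a time window.

## Estimation procedure

For one NUMT aligned with a cassette of great-ape mtDNA sequences:

1. **Filters.** A NUMT more than 10% divergent from the reference human
   mtDNA predates the target window (chimp mtDNA is at most ~8% divergent
   by the same measure) and is discarded; the comparison excludes columns
   with gaps or Ns on either side, and a NUMT at exactly 10% is retained.
   When log10 BLAST E-values are supplied, values above
   `Q3 + 0.5·(Q3 − Q1)` (quartiles by linear interpolation) mark poorly
   aligned copies. The 0.5 constant is configurable; no objective rule
   exists for it, so it is carried as a parameter.
2. **Topology stability.** 200 jackknife replicates delete 37% of
   alignment columns each (see below), and a tree is inferred per
   replicate (neighbor joining on Jukes–Cantor distances, then ML branch
   lengths under GTR). A replicate supports the reference grouping when
   the human+chimp leaves form a clade against gorilla and the NUMT
   attaches within or sister to the human clade. Support below 70% means
   the insertion time would rest on an unstable topology; the NUMT is
   dropped. Support exactly at 70% passes.
3. **Branch lengths.** On the full alignment, the tree is inferred the
   same way and three quantities are read off the outgroup-rooted tree:
   `L_numt` (NUMT terminal branch), `L_stem` (path from the NUMT
   attachment node back to the human–chimp coalescence) and `L_human`
   (path from that coalescence to the extant human reference tip), all in
   expected substitutions per site.
4. **Mitochondrial fraction.** Marginal ancestral reconstruction assigns
   substitutions to branches; a hidden-substitution rule (below) repairs a
   known reconstruction artifact. Per-position conservation scores
   (GERP-style, range −9.75 to 4.87) are binned at the range midpoint
   −2.44 — scores below it are "conserved", the boundary itself and above
   "variable". With `F_numt`, `F_mito` the variable fractions of NUMT- and
   human-branch substitutions and `F_psd` the mean variable fraction of
   500 random position sets (each the size of the NUMT event count, drawn
   without replacement), the mitochondrial share of NUMT substitutions is

       f = 1 − (F_mito − F_numt) / (F_mito − F_psd),

   clamped to [0, 1] with a flag. The model is a two-point mixture:
   mitochondrial substitutions avoid conserved positions (`F_mito` high),
   neutral ones do not (`F_psd` low), so `F_numt` interpolates linearly in
   the mixture weight.
5. **Time conversion.** With the human–chimp divergence calibrated at
   D = 6 Ma and the human branch as the clock standard,

       t_insert = D − D · (L_stem + f · L_numt) / L_human,

   clamped to [0, D]. All times rescale linearly in D. Confidence
   intervals come from repeating the conversion with each replicate
   tree's branch lengths (f is estimated once, on the full alignment —
   the reconstruction stage deliberately uses unjackknifed data). The
   point estimate uses the full-alignment tree; mean, median, quartiles
   (linear interpolation) and variance summarize the replicate
   distribution.
6. **Clustering test.** Under the null, insertion times are uniform on
   [0, D]. The statistic is the number of NUMTs in a fixed window
   (2.5–2.9 Ma by default; closed interval). The p-value is the fraction
   of 10^6 random cohorts with an equal or larger count; the exact
   Binomial(n, width/D) upper tail is computed alongside as an analytic
   cross-check. The smallest resolvable non-zero p is 1/N. A 2-D scan
   repeats the test over assumed divergence times 5–9 Ma (times rescale
   linearly; the window, centred at 2.8 Ma, does not) and window widths
   0.2–2 Ma.

### Diversity-aware jackknife

Each replicate deletes exactly `round(0.37 · L)` columns, drawn without
replacement with probability proportional to a per-column diversity weight
plus a pseudo-count (1e−6, so all-constant alignments still resample).
The intent is to delete hypervariable, recurrently mutating (nearly
neutral) positions preferentially and concentrate the phylogenetic signal
in constrained positions.

Three diversity measures are provided:

* `column_diversity` — Shannon entropy of the column's A/C/G/T
  frequencies (gaps excluded) normalized by log 4, so a constant column
  scores 0, an even two-state split 0.5, an even four-state split 1.
* `column_state_diversity` — `(number of observed states − 1) / 3`.
* `column_polymorphism` — 1 for any polymorphic column, 0 for a constant
  one: the fixed/variable dichotomy itself, and the default for replicate
  tree inference.

The default is the coarsest measure, for a reason measured on synthetic
data. Deleting a constant column does not change the inferred tree, so a
weighting's entire effect on branch lengths runs through how it ranks
*polymorphic* columns — and any graded ranking couples deletion to which
branch a column supports. Entropy weighting deletes balanced species
splits (near the entropy maximum at small taxon counts) and collapses
replicate insertion times to zero. State-count weighting is subtler but
still biased: substitutions that accumulated on the NUMT branch after
insertion sit at conserved positions, whose columns stay clean two-state,
while human-branch substitutions sit at variable positions whose columns
are recurrently hit elsewhere in the tree, drift into the three-state
class, and are deleted first — replicate trees then retain ~25% more of
the NUMT branch than of the human branch, skewing the replicate times
about 0.3 Ma early. Uniform deletion over polymorphic columns is the
unique ratio-neutral choice, and it is also the dichotomy the procedure
is built on: fixed (functionally constrained) positions are kept,
variable (nearly neutral) positions are deleted with high probability.
The measure is a parameter (`diversity_fn`), so the graded weights can be
swapped back in.

### Hidden substitutions

At a conserved position, a reconstruction error at the NUMT's ancestor
node can convert one true NUMT-branch substitution into a
substitution-plus-reversion pair on neighboring branches. The correction:
for every conserved-bin column where all other leaves of the
NUMT-containing clade share one state, every ancestor node above the clade
is reconstructed with that same state, and the NUMT differs, any events at
that column on the clade stem or inside the clade (other than on the NUMT
terminal branch) are replaced by a single flagged event on the NUMT
branch. The clade is the NUMT's parent clade; the clade root itself is
deliberately excluded from the agreement check — it is the node whose
state may be wrong. Each correction removes at least one interior event
and adds exactly one NUMT event, so the event multiset never grows.

### Likelihood engine

Felsenstein pruning over unique column patterns; gaps and Ns are missing
data (a tip contributes a vector of ones). The GTR rate matrix is
normalized to one expected substitution per site per unit branch length;
transition probabilities come from the symmetric eigendecomposition, so
detailed balance holds to machine precision. Branch lengths are optimized
coordinate-wise (bounded scalar optimization on the log of each length,
bounds [1e−8, 10]), cycling until the log-likelihood gain falls below
1e−6 (cap 50 cycles, warning and best-so-far on non-convergence).
Ancestral posteriors use inside–outside message passing; argmax states
break ties alphabetically. Discrete-gamma rate variation (4 equal-weight
categories, mean-of-quantile-bin rates) is supported but off by default:
on two-rate-class synthetic data, GTR+Γ branch lengths did not improve
insertion-time recovery and cost four likelihood evaluations per one.
Topology search is neighbor joining (deterministic lexicographic
tie-breaking, negative NJ lengths clamped to zero) — adequate for the
≤ ~30-taxon cassettes this pipeline targets, not a general tree-search
engine.

## Synthetic data

The generator emulates the analysis inputs with known truth: a species
tree (((human, chimp), gorilla), outgroup) with several tips per species
(caterpillar coalescence within species), optional ancient-human tips with
shortened terminal branches, a NUMT lineage leaving the human mtDNA stem
at `numt_branch_time` and switching to the neutral regime at
`numt_insertion_time`, two i.i.d. site classes (conserved sites substitute
at `conserved_rate_multiplier` × rate on mitochondrial-regime branches,
at the full neutral rate after insertion), and a score table drawing
conserved columns from the lower half and variable columns from the upper
half of the declared score range — so midpoint binning recovers the class
exactly, a deliberately clean signal for the binning stage.

Defaults (chosen once, for desk-scale signal):

| parameter | default | why |
| --- | --- | --- |
| `seq_length` | 4000 bp | enough substitutions on the calibrating branches for stable estimates at laptop runtimes |
| `mito_clock_rate` | 0.018 /site/Ma | inflated relative to empirical mtDNA clocks; keeps NUMT–reference divergence under the 10% filter (measured max ≈ 0.07) while maximizing events |
| `pseudo_clock_rate` | 0.005 /site/Ma | slower than the mitochondrial clock, as for nuclear neutral DNA |
| `conserved_site_fraction` | 0.65 | sets the neutral-null variable fraction F_psd ≈ 0.35 |
| `conserved_rate_multiplier` | 0.12 | strong purifying selection; F_mito ≈ 0.8, a wide mixing-model contrast |
| splits | human–chimp 6, gorilla 16, outgroup 80 Ma | deep branches make >50% of columns polymorphic, as in real multi-genus mtDNA cassettes, so the 37% jackknife deletion lands mostly on deep hypervariable columns instead of the shallow signal |
| `numt_branch_time` | 4.5 Ma | NUMT lineage leaves the human mtDNA stem between the human mtDNA TMRCA and the species split |

What the generator does *not* emulate: realistic demography or
coalescent variation (within-species splits are deterministic), indel
evolution (gaps only via optional uniform masking of the NUMT), rate
autocorrelation along the sequence (site classes are i.i.d.), empirical
absolute rates, and hg18 genomic coordinates. Passing tests therefore
show the estimator is correct under its own model assumptions at realistic
signal strengths — not that real data satisfy those assumptions.

## Accuracy at desk scale

At the defaults (4 kb, 12 taxa, 50 jackknife replicates) the end-to-end
estimator's error is dominated by three irreducible terms: binomial noise
in `F_numt` (~100 NUMT-branch events), Poisson noise in the stem and
human branch lengths, and the [0, 1] clamp on f (which biases estimates
inward by ~0.2–0.35 Ma for insertions near the branching time or near the
present). Measured rmse is ≈ 0.5 Ma, so individual estimates within
±0.75 Ma are expected roughly 80–85% of the time; precision grows with
sequence length (the real mitochondrial genome is 16.5 kb, four times the
default here).

## Numerical and design choices

* Quantiles everywhere by linear interpolation between order statistics.
* A score exactly on the bin boundary (−2.44) is "variable"; a divergence
  of exactly 0.10 and a support of exactly 0.70 pass their gates (the
  discard rules are strict inequalities).
* E-values of exactly 0 are capped at 1e−300 before log10.
* Null position sets may include positions already mutated on the NUMT
  branch (inclusive sampling; the expectation equals the variable share
  of the region either way).
* Negative insertion times clamp to 0 with a diagnostic flag; the paper's
  headline scale D = 6 Ma is rescalable after the fact.
* Weighted sampling without replacement delegates to
  `numpy.random.Generator.choice`, which draws successively with
  renormalization; a pinned NumPy version reproduces samples exactly.
* One master seed derives all stage seeds by hashing stage names, so
  per-NUMT results do not depend on processing order.
* The point estimate comes from the full-alignment tree; replicate trees
  feed only the confidence intervals. (Consensus-tree point estimates are
  a reasonable alternative; the replicate summary is reported alongside.)
* When a gap admits alternative alignments of the same NUMT,
  `select_alignment_by_numt_parsimony` picks the candidate implying the
  fewest NUMT-branch substitutions (ties to the first); producing the
  alternatives is the caller's job.
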