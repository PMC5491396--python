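# numtclock

Dating the integration of mitochondrial pseudogenes (NUMTs) into the
nuclear genome.

## The problem

Fragments of mitochondrial DNA occasionally insert into chromosomes and
become NUMTs — nuclear pseudogenes of the mtDNA. Before insertion a
NUMT's sequence evolved as mtDNA: fast, and under purifying selection
that forbids change at conserved positions. After insertion it evolves as
a neutral pseudogene: slower, and indifferent to the old constraints. In
a phylogeny of the NUMT with great-ape mtDNA genomes, the branch leading
to the NUMT is therefore a mixture of the two regimes, and the mixture
proportion dates the insertion.

`numtclock` is for molecular evolutionists who want to place human-lineage
NUMT insertions on an absolute timescale and ask whether insertions
cluster in a time window (for example around the ~2.8 Ma climate
transition at the emergence of *Homo*).

## The method

For each candidate NUMT aligned with an mtDNA cassette
(((human, chimp), gorilla), outgroup):

1. **Filter.** Discard NUMTs > 10% divergent from the reference human
   mtDNA (they predate the human–chimp split) and, when BLAST E-values
   are available, log10 E-value outliers above Q3 + 0.5·(Q3 − Q1).
2. **Topology gate.** Infer trees from 200 diversity-aware jackknife
   replicates (each deletes 37% of alignment columns, preferentially the
   variable ones) and require ≥ 70% support for the correct
   human/chimp/gorilla topology with the NUMT in or sister to the human
   clade.
3. **Branch lengths** by maximum likelihood under GTR on the full
   alignment: `L_numt` (NUMT terminal branch), `L_stem` (NUMT attachment
   point back to the human–chimp coalescence), `L_human` (coalescence to
   the extant human tip).
4. **Mitochondrial fraction.** Assign substitutions to branches by
   marginal ancestral reconstruction (with a correction for "hidden"
   substitutions at conserved sites), bin sites by conservation score at
   the midpoint −2.44 of the range [−9.75, 4.87], and solve the linear
   mixing model

   `f = 1 − (F_mito − F_numt) / (F_mito − F_psd)`

   where `F_numt`, `F_mito`, `F_psd` are the variable-bin fractions of
   NUMT-branch substitutions, human-branch substitutions, and random
   position sets (the neutral null), respectively.
5. **Insertion time**, with the human branch as clock standard and the
   human–chimp divergence at D = 6 Ma (rescalable):

   `t = D − D · (L_stem + f · L_numt) / L_human`,

   with confidence intervals from the jackknife replicates.
6. **Clustering test.** The probability that as many insertion times fall
   in a window (default 2.5–2.9 Ma) by chance, from 10⁶ uniform
   randomizations, cross-checked against the exact binomial tail, plus a
   2-D robustness scan over assumed divergence times and window widths.

A synthetic-data module generates cassette alignments with known NUMT
history and conservation structure, so the whole chain is testable
without any downloads. See `docs/methods.md` for the model, parameter
defaults, and limitations.

## Worked example

```python
from numtclock import SimulationConfig, simulate_dataset, estimate_insertion_time

config = SimulationConfig(numt_insertion_time=2.8, seed=42)   # truth: 2.8 Ma
alignment, scores, truth = simulate_dataset(config)

result = estimate_insertion_time(
    alignment, scores, config.taxon_groups(), config.gtr,
    n_replicates=50, seed=42,
)
est = result["estimate"]
print(f"support            {result['support']:.2f}")
print(f"mito fraction f    {result['fraction'].f_mito:.2f}")
print(f"insertion time     {est.point_estimate:.2f} Ma")
print(f"replicate median   {est.median:.2f} Ma  (IQR {est.q25:.2f}-{est.q75:.2f})")
```

prints

```
support            1.00
mito fraction f    0.34
insertion time     2.73 Ma
replicate median   2.70 Ma  (IQR 2.36-2.99)
```

The topology gate passes (every jackknife replicate recovers the species
topology), a third of the NUMT branch's substitutions are inferred to be
mitochondrial, and the estimated insertion time lands within about a
tenth of a million years of the true 2.8 Ma, with the truth inside the
replicate interquartile range.

The same chain is available from the shell:

```sh
numtclock simulate --seed 42 --insertion-time 2.8 --out dataset/
numtclock demo --seed 1 --dir demo/        # 18-NUMT cohort, full pipeline
numtclock cluster 2.6 2.7 2.8 2.75 2.85 2.55 0.5 1.2 1.9 3.4 4.0 4.6 \
    --interval 2.5 2.9 --n-rand 1000000
```

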