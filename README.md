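# phagedepth

Depth- and time-resolved analysis of marine bacteriophage metagenome
assemblies.

Double-stranded DNA phages are the most abundant biological entities in
the oligotrophic ocean, yet how specific phage populations are structured
through the water column and through time is hard to see from single
samples. `phagedepth` is a library for the post-assembly half of that
question: given assembled viral contigs, gene calls, homology hit tables,
domain scores, and per-sample read coverage from a depth x time sampling
grid, it curates a high-confidence viral contig set, classifies contigs
against reference phage databases, quantifies spatiotemporal abundance
and temporal variability, clusters samples by phage-specific versus
cellular gene content, profiles lysogeny markers down the water column,
and nominates candidate novel (auxiliary metabolic) genes. It is written
for microbial oceanographers and viral ecologists who already have
assemblies and mappings in hand and want tested, reusable implementations
of the analysis layer.

Because the interesting behaviour lives in the statistics rather than in
any one dataset, the package ships a first-class synthetic-data generator
that emulates a stratified 7-depth x 12-occasion time series (83
samples), with planted depth groups, persistent vs sporadic temporal
regimes, a lysogeny gradient below the deep chlorophyll maximum, cellular
contaminants, and conserved-gene coverage spikes — so every stage is
testable against known truth with no downloads.

## The statistics at the core

* **Interquartile-mean coverage.** For a contig with sorted per-base
  depths x_(1) <= ... <= x_(L), the abundance estimate is the mean of the
  middle two quartiles, ranks [⌈L/4⌉, ⌊3L/4⌋). Conserved genes attract
  reads from related phages; trimming the outer quartiles keeps such
  spikes out of the estimate.
* **Relative abundance.** nucleotides mapped to contig / nucleotides
  mapped to all curated contigs in the sample.
* **Mean-normalized variance (index of dispersion).** For a contig's
  relative-abundance series x_1..x_T within a depth bin,
  D = Var_pop(x) / mean(x). Constant series give exactly 0; scaling by c
  scales D by c, equalizing the weight of high- and low-abundance contigs.
* **Majority-gene AAI classification.** A contig classifies to reference
  genome r iff f(r) = (genes best-hitting r)/(all genes) > 0.5 and the
  mean amino-acid identity of those genes > 60%; otherwise it is novel.
  All cutoff comparisons are strict; the length filter (>= 20 kbp) is
  inclusive.
* **Assemblage clustering.** Bray-Curtis distance
  d(i,j) = Σ|x_gi − x_gj| / Σ(x_gi + x_gj) on relative gene abundances,
  average-linkage (UPGMA) agglomeration, and a numeric tanglegram summary
  (cophenetic correlation, 7-group co-clustering agreement).
* **Lysogeny index.** Σ coverage(integrase, CI repressor, excisionase) /
  Σ coverage(capsid) per sample, detected at domain bit > 50; per-depth
  means are folded by the surface (25–75 m) mean. Marker copy numbers per
  cellular genome divide by the mean coverage of ten universal
  single-copy bacterial marker genes.
* **AMG colocalization.** A gene is a candidate novel gene iff it has a
  functional domain hit with bit > 30 to a label not already known from
  marine viromes and its contig carries a structural-family hit with
  bit > 10.

## Worked example

```sh
python examples/02_curation_cascade.py
```

```
length         150 ->  142  (length < 20000 bp)
structural     142 ->  129  (no structural-family hit with bit > 10.0)
contamination  129 ->  129  (ribosomal marker hit with bit > 50.0)
high-confidence viral contigs: 129
marker-hit genes: 5 (of which 5 recA/DNA-helicase)
completeness proxy: 0.000
```

Of 150 synthetic contigs, 142 pass the inclusive 20 kbp length filter,
13 are dropped for lacking any phage structural gene above 10 bits, and
no ribosomal contaminant survives — 129 high-confidence viral contigs.
The only single-copy-marker hits are recA/DNA-helicase, genes phages
legitimately carry, and the completeness proxy of 0 says the retained set
shows no detectable cellular genome signal.

```sh
python examples/06_life_history.py
```

```
fold vs surface mean, by depth:
25      0.98
75      1.02
125     0.96
200     2.89
500     4.99
770     4.90
1000    4.93

capsid copies per cellular genome, by depth:
25      3.01
75      2.94
125     4.02
200     2.00
500     1.04
770     0.72
1000    0.49

contigs flagged as prophage-marker-bearing (bit > 30 incl. Cro): 25
```

The fold profile recovers the planted five-fold mesopelagic enrichment of
lysogeny potential (with the transition below the deep chlorophyll
maximum), while capsid copies per cellular genome fall from ~3 in the
surface to ~0.5 at 1,000 m — fewer actively replicating lytic phages per
cell at depth.

The other `examples/*.py` scripts cover simulation, classification,
depth/time statistics, assemblage clustering, and AMG detection; each
prints the numbers it computes and a line on what they mean.

## Command line

A thin CLI wraps the library for shell use:

```sh
phagedepth simulate --seed 1 --out fixture/
phagedepth run-all -i fixture/ -o results/
```

Stages can also be run individually (`curate`, `classify`, `abundance`,
`assemblage`, `lifehistory`, `amg`). Exit codes: 0 success, 2
configuration error, 3 data error.

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
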