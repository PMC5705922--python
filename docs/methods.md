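# Methods

This note documents the models, conventions, and design choices behind
`phagedepth`: what each statistic assumes, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Study design and vocabulary

The analyses assume a water-column sampling grid: seven depths (25, 75,
125, 200, 500, 770, 1,000 m) sampled on twelve occasions; the full
design holds 83 samples (one grid cell is absent). Depths collapse into
four persistent habitat bins — surface (25–75 m), deep chlorophyll
maximum (DCM, ~125 m), 200 m, and mesopelagic (500–1,000 m) — plus a
fifth, "sporadic" group for contigs whose temporal behaviour is dominated
by boom-and-bust spikes.

## Thresholds

Every cutoff lives in `phagedepth.thresholds.Thresholds` with these
defaults: contig length >= 20,000 bp (the only inclusive comparison;
everything else is strict `>`); structural-gene domain bit > 10; AMG
functional bit > 30; catalog marker bit > 50; per-contig prophage-flag
bit > 30; photosystem bit > 30; classification AAI > 60%; viral-gene AAI
> 90%; gene fraction > 0.5; top-k = 13. Boundary behaviour (a hit at
exactly the cutoff never qualifies; a contig at exactly 20 kbp is
retained) is pinned by tests.

## Contig curation

Three per-contig predicates applied in order (length → structural →
contamination), so the retained set is order-insensitive and each stage's
output is a subset of its input. The structural requirement accepts any
of eight virion-protein families (terminase, portal, capsid, tail, base
plate, spike, neck, head); free-text family labels are normalized through
a fixed synonym table, since hit tables carry no ontology. The
contamination screen removes contigs with ribosomal single-copy-marker
hits above the marker bit; recA and DNA-helicase hits are tallied but
tolerated because phages encode homologous recombination/replication
genes. Cellular completeness is summarized by a deliberately simple
proxy — the fraction of non-ambiguous single-copy marker families
observed anywhere in the set — not a lineage-aware estimate; it is
compared only against planted truth. VirSorter-style confidence
categories are accepted as input labels (validated to 1–6) and never
recomputed.

## Classification

The majority-gene AAI rule is evaluated per reference *genome*, never
pooled across a database: pooling would let chimeric similarity to many
unrelated references masquerade as homology. The gene-fraction
denominator counts **all** genes on the contig, including genes with no
hit (a flag on `classify_contig` is unnecessary since callers can
pre-filter the gene list). Mean AAI is unweighted over the genes counted
in the fraction. Precedence among qualifying references: the curated
phage genome database (refseq75) first, then higher gene fraction, higher
mean AAI, lexicographic reference id. Note that with the all-genes
denominator and a strict 0.5 cutoff, at most one reference can qualify
per contig; precedence matters only under relaxed fractions. Per-gene
best hits maximize bit score, breaking ties by higher AAI then
lexicographic reference id. Category proportions are weighted by
nucleotides mapped (coverage x length), with the denominator restricted
to curated viral contigs, and summarized per habitat bin as mean ±
standard error (sd/√n, ddof = 1).

## Coverage statistics

**Interquartile mean.** Sorted per-base depths, half-open rank window
[⌈L/4⌉, ⌊3L/4⌋), arithmetic mean; no quantile interpolation. An exact
weighted-rank implementation operates directly on run-length-encoded
depth vectors and is property-tested against dense expansion.

One numerical property is worth stating plainly: a coverage spike
occupying the top fraction f of positions compresses the remaining base
draws into ranks [0, 1−f), so the middle-half window maps to
base-quantiles [0.25/(1−f), 0.75/(1−f)) and the statistic acquires a
positive bias of roughly 0.37·σ/μ relative (≈ 0.37/√λ for Poisson
depth). At f = 0.2 and a 10x base coverage the expectation is 11.07, not
10 — verified by a 1,000-replicate simulation and frozen into the unit
test. The ±10% robustness bound therefore holds for base coverage above
roughly 14x; the robustness suite evaluates it at 30x, typical of the
abundant contigs the statistic exists to protect, and the small-λ bias is
stated here rather than hidden.

**Dispersion.** Mean-normalized variance uses the population (divisor-T)
variance: the twelve occasions are treated as the window of interest, not
a sample from a longer process. The statistic scales linearly with the
series, which is precisely what removes the preferential weighting of
high-abundance contigs relative to raw variance; it is *not* scale-free,
so bins with few contigs (larger relative-abundance shares) have larger
persistent-contig dispersions — the practical limit on separating weak
sporadics from persistent contigs in sparse bins.

**Depth groups.** A contig's persistent bin is where its mean
interquartile-mean coverage peaks (ties resolve shallow-first); it is
relabelled sporadic when its dispersion within that bin exceeds a
threshold. The default threshold is the 90th percentile of all contigs'
dispersions — a data-adaptive surrogate for manual binning — and an
overrides mapping gives exact manual control. Top-k ranking uses mean
relative abundance per sampling depth with lexicographic tie-breaks.

## Assemblage clustering

Phage set: viral best-hit AAI strictly > 90%, minus photosystem genes
(bit > 30), whose phage and host copies cannot be distinguished; the
cellular set is the complement, so the partition is a disjoint cover.
Distances are computed on relative abundances normalized over the full
catalog (library size cancels), Bray-Curtis, then UPGMA via SciPy.
Because the field's tanglegram comparison is visual, the numeric
summaries here (cophenetic Pearson correlation; fraction of sample pairs
co-clustered identically at a 7-group cut, mirroring the seven sampling
depths) are package conventions, checked against planted structure only.
Taxon-panel summaries (summed relative abundance of labelled gene groups)
are a generic operation; which labels form a panel is configuration.

## Life history

Two marker rules coexist deliberately and are never conflated: the
catalog profile detects markers at domain bit > 50 against curated
models, while the per-contig prophage flag uses bit > 30 against
integrase, CI repressor, **Cro**, or excisionase. The lysogeny index sums
the three prophage families jointly over capsid coverage (per-family
indices are also reported, because integrase signal is known to be
inflated by non-phage mobile elements — the per-family view makes that
caveat testable: planted integrase-only inflation moves the integrase
index and leaves the excisionase/CI indices at the planted fold).
"Surface" for the fold normalization means the 25 and 75 m samples
(configurable). Copy numbers divide family coverage by the arithmetic
mean (geometric optional) of ten universal single-copy bacterial marker
families; both the index and copy numbers are invariant to uniform
rescaling of a sample's coverages, i.e. to sequencing depth.

## AMG detection

Candidacy requires a functional hit (bit > 30) whose normalized label is
outside the shipped, editable known-function list
(`data/known_amg_functions.txt`) *and* outside every structural, marker,
and single-copy-marker vocabulary, on a contig with structural support
(bit > 10). Depth specificity uses a presence floor of relative abundance
> 0.001 in at least two samples of a depth; "specific" means one depth or
two adjacent depths. Candidates are re-checked by an independent
plain-loop validator. No claim of verified function is made: in-silico
AMG calls are false-positive-prone by nature, and the distinction between
"novel gene" and "true AMG" is manual curation this package does not
automate.

## Synthetic data

The generator's defaults are the study conditions: 142 length-passing
candidate contigs (20–108 kbp, fixed 900 bp genes), 13 lacking
structural hits, a short-contig tail (1.7–20 kbp) carrying one ribosomal
contaminant, a 10/40/79 known/virome/novel classification split over the
129 curated contigs, a planted mesopelagic:surface lysogeny fold of 5
(200 m midway), and shallow-skewed phage-marker copy numbers.

Noise model: per-base depth is Poisson with a rate constant over 500 bp
(read-scale) blocks; between samples the rate is multiplied by a mean-one
lognormal (σ = 0.35 for contig coverage, 0.25 for catalog gene coverage),
giving positive, sample-level-overdispersed abundances with exact planted
expectations. Persistent contigs hold their base rate at all home-depth
occasions; sporadic contigs are boosted 5x at 2–4 random occasions and
sit at λ = 0.01 otherwise (a detection floor of λ < 0.05 defines
"absent" — a package convention, since no field-standard floor exists).
Conserved-gene spikes multiply the rate by 8 over a contiguous 10% of
each contig, at a fixed genomic position across samples. The dedicated
spiked-vector generator (`generate_spiked_coverage`) draws true per-base
i.i.d. Poisson depths and rejects spike fractions >= 0.5, which would
invade the middle quartiles.

The gene-centric catalog is planted independently of contig coverage
(as in the real two-track design): marker-family coverages are products
of planted per-depth copy numbers and a cellular abundance profile, so
the lysogeny index and copy numbers have exact planted values;
depth-block phage and cellular genes share the same depth structure so
both assemblage trees recover it. Everything flows from a single seeded
generator — equal seeds give byte-identical fixture files — and the
planted truth is serialized separately (`truth.json`), never read by any
pipeline stage.

What the generator does **not** emulate: read-level data (no FASTQ, no
assembly), sequence-realistic protein content (hits and scores are
planted, not computed from sequence), within-sample spatial coverage
autocorrelation beyond the block scale, seasonality, and real taxonomic
composition. Passing tests therefore demonstrate that the estimators
recover planted statistical structure under Poisson-lognormal noise —
not that any biological claim holds for real data.

## Problem sizes

The full-design fixture (142 candidates x 83 samples, coverage +
catalog) generates in ~1.5 s. Multi-seed recovery suites use scaled-down
fixtures as the package's own choice of problem size: 40 contigs x 83
samples for depth-group and dispersion recovery, and catalog-only
fixtures (no contig coverage) for lysogeny-fold and copy-number recovery;
20 seeds each. The worked-example computations run at the printed study
sizes (142 contigs; 197,713-gene catalog; 917 contigs).

## Known limitations

* The dispersion statistic's scale dependence (above) bounds sporadic /
  persistent separation in bins with few contigs; with default settings
  ~5% of contigs land on the wrong side of the adaptive threshold.
* The completeness proxy is not comparable to lineage-aware estimators.
* UPGMA tie-breaking follows SciPy's deterministic merge order; exact
  ties are measure-zero for the continuous distances used here.
* The classification precedence hierarchy only matters under relaxed
  gene fractions (see above); with defaults it reduces to "the unique
  qualifying reference wins".
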