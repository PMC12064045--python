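# Methods

## Scope and data model

The package analyses cell-type-resolved Argonaute-pulldown small-RNA
counts: a miRNA × sample integer matrix with condition labels (three
replicates per condition in the reference design: a neural-stem-cell
condition `nab`, a neuronal condition `elav`, a glial condition `repo`,
plus optional inputs), a catalog of mature miRNA sequences (RNA), 3'UTR
sequences (DNA, sense strand) or an external gene-by-family site-count
matrix, and per-gene expression summaries in reads per million.

## Seeds, families and canonical sites

The seed is miRNA positions 2–8 (1-based).  miRNAs with identical seeds
form one seed family and are one counting unit throughout; the family
identifier is the sorted member names joined with `/`.  Canonical sites on
the mRNA sense strand are 8mer (perfect match to positions 2–8 plus an `A`
across from position 1 — a literal adenosine regardless of the miRNA's
first base), 7mer-m8 (match to 2–8) and 7mer-A1 (match to 2–7 plus the A1).
Non-canonical, 3'-compensatory and wobble sites are out of scope, as are
context scores and conservation weights.

The scanner walks the UTR left to right; at each position it takes the
best site type starting there (8mer > 7mer-m8 > 7mer-A1) and jumps past
it.  Hence every counted locus has exactly one type, counted sites never
overlap, and counts are deterministic.  Coordinates are 1-based inclusive.
Seed-sharing miRNAs produce identical site strings, so each family is
scanned once through one representative — no double counting.

## Differential enrichment

Counts are modelled as negative binomial, `Var = μ + αμ²`.

* **Size factors** — median-of-ratios: factor_j = median over miRNAs with a
  positive geometric mean of `count_ij / geomean_i`.
* **Dispersion** — method of moments per condition with ≥ 2 replicates,
  `α_i = max(0, (s² − μ)/μ²)` on normalized counts, combined across
  conditions with weights `(n_c − 1)`, then shrunk toward a least-squares
  trend `α(μ) = a₀ + a₁/μ` by a weighted average (trend weight 0.3 by
  default; 0 disables shrinkage).  The trend stabilises per-miRNA
  estimates at three replicates, where raw moments are noisy.
* **Wald test** — two-sided on the log2 ratio of condition means with a
  symmetric pseudocount of 0.5 normalized-count units, standard error from
  the NB variance function via the delta method.  p-values are
  Benjamini–Hochberg adjusted (step-up).  Records sort by (padj, |log2fc|
  descending, name) so output order is deterministic.
* **Enrichment call** — padj < 0.05, correct fold-change sign, and ≥ 1000
  counts per million in at least one sample of the focal condition.

This is a re-implementation of the standard NB Wald pipeline, not a
wrapper around an existing DE package; numerical identity with any
particular tool is not promised.  Its calibration is instead verified
directly: on all-null simulations (300 miRNAs, 3 vs 3, dispersion 0.05)
p-values are uniform (KS < 0.1) and the discovery fraction at padj < 0.05
stays within Monte-Carlo slack of the nominal level; planted four-fold
changes at mean 2000 are recovered with sensitivity ≥ 0.95.

Library summaries: counts per million (columns scaled to 10⁶), per-row
mean scaling for heat maps (rows with zero mean are dropped with a
warning), and sample PCA on log2(x+1) data centered per miRNA, computed
by SVD.

## Target matrix and module genes

Entry (family, gene) is the number of canonical sites of that family in
the gene's 3'UTR (or the imported count).  Genes must exceed 100 reads per
million (mean) in at least one of the two focal conditions — the
expression filter is applied *before* thresholding — and genes targeted by
no family are dropped.  Module target genes are those with ≥ 5 cumulative
sites over all families, ordered by total then name.  The weighted
bipartite interactome has one edge per nonzero cell.

## Promiscuity and the randomized null

The promiscuity of a miRNA set toward a focal gene set is the per-member
total site count; the module is summarised as mean ± SEM (matching the
mean ± SEM convention used for the reference measurements).  The null pool
contains miRNAs whose expression share never exceeds 0.1% of any sample's
total.  Each of `n_draws` (default 1000) draws takes a size-matched set
without replacement and records its mean; the reported p is the add-one
upper tail `(1 + #{null ≥ observed}) / (1 + n_draws)`.  A single random
combination is an anecdote, not a test; the Monte-Carlo generalisation
keeps the construction (low-expression pool, same set size) and makes the
comparison inferential.  With few focal genes and sparse null counts the
add-one p is conservatively biased by ties at zero — its null mean sits
slightly above 0.5 — which is the expected behaviour of a discrete
upper-tail estimator, not an error; uniformity checks therefore score a
non-degenerate variant over all retained genes.

## Clustering

Families are clustered on their raw site-count rows with Euclidean
distance (correlation distance available via `--distance`); the tree is
built with Ward's minimum-variance criterion (Lance–Williams update, via
scipy's linkage) and cut into exactly `k` groups (default 3).  Cluster ids
are renumbered by each group's lexicographically smallest member, so the
labelling is order-independent.  The dendrogram serialises to Newick with
branch lengths equal to merge-height increments (the tree is ultrametric).
Low-expression members can be excluded upstream via the cpm threshold
rather than by hard-coded name lists.

## Sponge design

A binding site is the DNA reverse complement of the miRNA except at the
four site positions pairing miRNA 9–12 (site positions L−11…L−8 for
length L), substituted via a table (default A→C, U→C, G→A, C→A) chosen so
no substituted base can Watson–Crick or G:U wobble pair with its miRNA
counterpart: the central bulge blocks Ago2-mediated slicing while seed
pairing is preserved.  Cassettes carry 20 repeats separated by 4-nt
linkers drawn from the construct seed; a candidate linker is redrawn (up
to 100 times) if any canonical site for the target miRNA would overlap it,
so junctions never create new seed matches.  Linkers are internal only —
none before the first or after the last repeat.  A multi-sponge
concatenates member cassettes with one linker between cassettes, checked
against both neighbours' miRNAs.  Vector context (reporter CDS, UAS
sites) is annotation-only; no vector sequence is fabricated.

## Synthetic data generator

The generator mirrors the reference study's design so recovery is
measurable against known truth:

* **Counts** — 300 miRNAs, conditions (`nab`, `elav`, `repo`), 3
  replicates, NB dispersion 0.05, lognormal background means (median 100),
  lognormal library-size factors (σ = 0.15).  16 planted miRNAs (three
  shared-seed pairs → 13 families) get base means 1000–4000 and log2 fold
  changes 1.5–3 in the focal condition; their cpm always clears the
  1000-cpm filter, as in the data the thresholds were chosen for.
* **Transcriptome** — 12 module genes with 5–15 planted sites each
  (spread over the families, site types 8mer/7mer-m8/7mer-A1 at
  0.3/0.4/0.3), decoy genes at 1–4 sites above the expression filter and
  ≥ 5 sites below it (exercising both thresholds), and 44 background genes
  with Poisson(0.5) sites, half below the expression filter.  UTRs are
  uniform-random DNA of 150–450 nt (100 nt for decoys, keeping their
  planted counts sharp).  Sites are *inserted*, never overwritten, and the
  whole gene is rejection-sampled until the scanner recovers exactly the
  planted per-family multiplicities — so planted counts are exact and
  recovery metrics are well defined.
* All randomness flows from one seed through `numpy.random.SeedSequence`;
  the truth object echoes every generator parameter.

What the generator does **not** emulate: sequencing error, adapter and
ligation bias, isomiRs, UMI structure, phylogenetically realistic UTR
composition, correlated gene expression, or chance seed matches beyond the
planted rate (backgrounds are rejection-sampled clean).  Passing recovery
tests therefore demonstrates correctness of the computation under the
declared statistical model, not robustness to those real-data artefacts.

## Numerical choices and problem sizes

Ties in enrichment sorting break by miRNA name; Ward ties by smallest node
indices; cluster ids by smallest member name.  Degenerate inputs (all-zero
samples, empty pools, single replicates, too-short UTRs) raise informative
errors rather than propagating NaNs.  Test simulations use 200–500 miRNA
tables and a few hundred Monte-Carlo replicates — sizes at which the
checked properties (calibration, power, recovery) are already stable,
keeping the default suite fast.

## Known limitations

* Genome-wide target recomputation against a real prediction database is
  supported only through the `count_matrix` import path; the package does
  not ship or rebuild such a database.
* The NB Wald stage is asymptotic; at two replicates per condition with
  strong outliers its p-values are approximate.  No outlier refitting is
  performed.
* Whether the reference clustering used raw or transformed site counts is
  not documented; raw counts with Euclidean distance is the declared
  default, and correlation distance is exposed for sensitivity analysis.
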