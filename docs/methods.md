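# Methods

This note documents the models and procedures implemented in
`abyssalgv`, the assumptions behind them, the tunable parameters with
their defaults, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Scope and data model

The package operates strictly downstream of the standard bioinformatic
toolchain.  Sequencing, assembly, binning, read mapping, HMM searches,
amplicon denoising, external viral classifiers and tree inference are
all upstream: their outputs arrive as plain tables (TSV) and newick
trees, and the package's job is the decision rules and statistics
applied to them.  The core containers are a per-sample metadata table
(depth in metres, region, date, size fraction, assay), non-negative
feature × sample abundance matrices (TPM, counts or relative
abundance), genome × gene copy tables, per-contig classifier evidence,
and symmetric ANI matrices.  All tabular IO is TSV (UTF-8, header row,
`.` decimal) with floats written to 12 significant digits, which makes
write/read round trips lossless for every statistic produced here.

TPM follows the plain transcripts-per-million formula
`TPM_i = (c_i/l_i) / Σ_j (c_j/l_j) × 10⁶` with the annotated feature
length as the denominator; effective-length corrections used by some
quantifiers are not modelled.  An all-zero count vector maps to an
all-zero TPM vector rather than an error, because empty samples occur
legitimately in simulations.  N50 is the length at which the cumulative
sum of descending-sorted contig lengths first reaches half the total
(ties resolved by that "first reaches ≥ half" convention, which is
deterministic and order-invariant).

## Bin screening

A bin is a candidate nucleocytovirus MAG when its gene-density index
strictly exceeds **5.75**.  The index implemented by default is the
number of *distinct* markers present (copy ≥ 1, scores ignored) among
the 20 conserved nucleocytovirus marker genes, divided by the genome
size in Mb.  The exact published form of this index lives in external
tooling and is not restated in the literature the threshold comes from,
so the function is a pluggable strategy (`index_fn`) and the default is
documented as a reconstruction — anyone holding the reference
implementation can validate or substitute it without touching the
screening logic.

Mirusvirus candidacy requires at least one HK97 major-capsid-protein
hit with E-value < 10⁻³ **and** bit score > 100, both strict.
Decontamination retains a contig when either classifier calls it viral:
VirSorter max-score group equals "NCLDV" **or** ViralRecall score > 0
(a score of exactly 0 is dropped).  Contigs missing from the evidence
table are dropped with a warning by default (`missing="error"` to
raise).  The size window 50 kbp ≤ size ≤ 3 Mbp is evaluated on the
genome sizes as given, i.e. after whatever decontamination the caller
has applied.

Dereplication is single-linkage clustering at ANI ≥ 95% — connected
components of the identity graph, matching the behaviour of
single-linkage dereplication tools on a precomputed matrix.  Coverage
terms of alignment-based ANI are out of scope; the input is a plain
symmetric matrix.  Representatives are chosen by restricting to the
`ceil(0.3 n)` largest members (ceil guarantees a non-empty pool for any
cluster size) and taking the best N50, with ties broken toward the
lexicographically smallest genome id so the choice is
permutation-invariant.

## PIMA: phylogeny-informed MAG assessment

Universal completeness/contamination markers do not exist for giant
viruses, so quality is assessed per phylogenetic neighbourhood.

**RED.**  Relative evolutionary divergence follows the GTDB convention:
`RED(root) = 0`, `RED(leaf) = 1`, and for an internal node *n* with
parent *p* at branch length *d*,
`RED(n) = RED(p) + (d/u)(1 − RED(p))` where *u* is the mean branch
length from *p* to the leaves descending through *n*.  RED is
non-decreasing along every root-to-leaf path and clamped to [0, 1].  A
zero-length branch leaves the child at its parent's RED.  Trees with a
basal polytomy are treated as unrooted and midpoint-rooted with a
logged warning.

**Lineages.**  Lineages are cut at the shallowest node (closest to the
root on each path) with RED ≥ **0.65**, the level that corresponds
roughly to genus/family rank in giant-virus marker trees; nested
qualifying nodes defer to the shallower one, and leaves not under any
qualifying internal node become singleton lineages, so the assignment
is always a partition of the leaves.

**Core genes, consistency, redundancy.**  The core OG set of a lineage
is the OGs present (copy ≥ 1) in strictly more than `core_fraction`
(default 0.5) of its members — the source material does not define
"core", so the prevalence threshold is an explicit, tunable choice
following the common core-genome convention.  Consistency is the
fraction of lineage core OGs a genome carries.  Redundancy is the
fraction of core OGs whose copy number strictly exceeds the per-OG
*mode* across lineage members; mode ties break toward the smallest
value, the conservative direction (flags more duplication) and a
deterministic one.  MAGs with redundancy strictly above 0.5 are
removed.  Singleton lineages (and lineages whose core set is empty)
leave consistency and redundancy undefined (NaN): those MAGs are
flagged unassessable, never removed.  No consistency-based removal
cutoff is applied — only the redundancy rule is numeric in the source
procedure.

## Deep-sea specificity and biogeography

Samples are "deep sea" when depth is strictly greater than the cutoff
(default **200 m**, the epipelagic base).  A genome is
deep-sea-specific iff

1. **Overrepresentation**: one-sided Mann–Whitney U (deep > non-deep)
   on its abundance, with Benjamini–Hochberg correction across all
   genomes in the run, q < α (default 0.05); or
2. **Deep-only detection**: abundance strictly above the detection
   threshold (default 0, i.e. TPM > 0) in ≥ 1 deep sample and in no
   other sample.

The comparison group for rule 1 is every sample at ≤ 200 m; the
one-sided alternative reflects the directional question
(overrepresentation *at depth*), and is configurable.  The BH family is
all genomes tested in one call.  When both rules hold the reported
provenance is `deep_only`, the stronger observation.  All-zero genomes
are never specific.  Because the test is rank-based and detection is a
zero-pattern, the classification is invariant to sample order and to
rescaling all abundances by a positive constant.

The Mann–Whitney p value is exact for combined sample sizes ≤ 12: the
permutation distribution of U is enumerated over all
`C(n, n_x) ≤ 924` assignments of the pooled midranks, which handles
ties correctly.  Larger samples use the normal approximation with tie
correction and a 0.5 continuity correction.  BH adjustment is the
step-up `q_(i) = min_{j≥i} (m p_(j) / j)` capped at 1.

Region summaries count a genome as detected in a region when it
exceeds the detection threshold in at least one deep sample of that
region; from the genome × region presence matrix follow per-region
detected and unique counts, pairwise sharing, per-genome region ranges
and the fraction of genomes found in ≥ k regions.  The exclusivity rule
generalises rule 2 to any sample group (e.g. mesopelagic metagenomes of
one site).

## Community ecology

Rarefaction subsamples each sample without replacement to a common
depth via a multivariate hypergeometric draw; at table level, samples
with fewer reads than an explicit depth are dropped with a warning
(common practice), while the per-sample operation errors.  The analysis
order is rarefy → Hellinger (`h_ij = sqrt(x_ij / Σ_i x_ij)`) →
Bray–Curtis (`d = Σ|x−y| / Σ(x+y)`, 0 for two empty samples) →
PERMANOVA.

PERMANOVA is one-way only (single factors such as depth layer or
season).  The pseudo-F uses the distance-based decomposition
`SS_T = (1/N) Σ_{i<j} d²`, `SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d²`,
`F = (SS_A/(a−1)) / (SS_W/(N−a))`, with `R² = SS_A/SS_T`.  Labels are
permuted freely (no blocking/strata).  When the number of distinct
label arrangements does not exceed the permutation budget the
distribution is enumerated completely and the p value is exact
(observed arrangement included in the numerator and denominator);
otherwise p is the standard `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)` over
uniform random permutations (default 9,999).  A useful degenerate
property: for equidistant samples every labeling yields the same F, so
p is exactly 1.

Levins niche breadth renormalises a feature's profile over its n
paired samples to proportions and reports `B = 1/Σ p²` ∈ [1, n] and
`BA = (B−1)/(n−1)` ∈ [0, 1]; BA is invariant to positive rescaling.
Group comparisons of BA (e.g. mesopelagic vs surface ASVs) use the
one-sided Mann–Whitney test above.

## Association tests

**Enrichment.**  The Fisher contingency counts *genomes* (presence =
gene count ≥ 1), not summed gene copies: a 2×2 table of term presence ×
depth label per term.  Terms present in ≤ 2 genomes overall are
excluded before testing (`min_total_frequency = 3`).  The two-sided p
value is the minimum-likelihood sum — all tables with the observed
margins whose hypergeometric probability does not exceed the observed
one, with a 10⁻⁷ relative tolerance on the comparison, the dominant
convention in the scientific Python/R ecosystem.  BH correction runs
across tested terms, and the enriched side is the class with the larger
relative frequency when q < α.  Swapping the class labels provably
swaps the sides and leaves p and q unchanged.

**Co-occurrence.**  Spearman's rho is the Pearson correlation of
midranks; p is exact for n ≤ 8 (complete enumeration of orderings of
one rank vector, two-sided) and the t approximation beyond.  All
virus × ASV pairs over the shared sample set (≥ 3 samples) are scored;
pairs with a constant profile are excluded with a logged reason since
rho is undefined.  A pair is a candidate host link when rho > 0 and
p < α.  Raw p values are thresholded by default, mirroring the source
analysis at its small pair count; a BH-corrected mode is available
(`bh_correct=True`) and recommended for larger scans.  Sample matching
between the virus and ASV tables is by shared sample id; callers
pairing across assays should rename to a common key (date + fraction)
first.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs with the statistical structure the
analysis assumes, plus ground truth, so every classifier can be scored
without any external download.  One global seed drives child
generators through independent seed streams; identical configs give
bit-identical outputs.

* **Depth survey** (defaults: 20 deep + 20 surface samples, 200
  genomes, 30% planted deep-specific, 10-fold effect, log-scale sd
  0.2, 30% structural zeros).  Abundances are log-normal per genome
  with structural zeros; TPM closure is applied per sample.  Planted
  genomes have their deep-sample mean multiplied by the effect size and
  are consistently present at depth within their region range (the
  background dropout applies to exchangeable genomes and to the surface
  side), while their surface detection probability is suppressed to
  10% (`surface_dropout = 0.9`) — emulating taxa abundant at depth and
  only sporadically advected upward.  Non-specific genomes are
  exchangeable between layers.  Each genome occupies an independent
  Bernoulli region set (p = 0.7, resampled to be non-empty); outside
  its regions it is absent everywhere, which exercises the sharing and
  uniqueness summaries.
* **Bins.**  Giant-virus bins (80–800 kb, 8–16 distinct markers) land
  above the 5.75 gene-density threshold by construction of realistic
  marker counts, not by setting the score; cellular bins (1–5 Mb, ≤ 1
  spurious marker) land well below; chimeras concatenate two
  giant-virus bins.  Evidence tables mix ~10% contaminant-looking
  contigs into viral bins.  One cellular bin carries a weak HK97 hit
  that must fail the score thresholds.
* **Lineages.**  Each lineage has its own single-copy core OG set
  (default 15 OGs, 5% dropout, 2% duplication per clean genome).
  Chimeras merge two clean members of a lineage, so their core copies
  sit at twice the mode.  Clade stems are long (RED of each clade
  ancestor ≈ 2/3 ≥ 0.65) and spine branches short, so the RED cut
  recovers the simulated lineages exactly.
* **ASV tables.**  Counts are multinomial per sample (columns sum to
  the library size) over log-normal latent abundances.  For each
  planted link the ASV *is* the host — its latent log-abundance is the
  shared per-sample factor — and the paired virus tracks that factor at
  the configured loading (0.9), so their Spearman correlation is
  positive in expectation at about the loading.  The virus TPM closure
  includes a dominant cellular background-expression term, because
  viral transcripts are a small fraction of a real metatranscriptome
  and closing over a handful of viruses alone would overstate
  compositional noise.

Passing tests on these fixtures demonstrate that the decision rules
recover the signals they were designed for under the stated noise
model.  They do not demonstrate robustness to features of real surveys
that the generators deliberately omit: taxonomic correlation structure
between genomes, depth gradients within a layer, uneven sampling
effort across regions and seasons, mapping ambiguity between related
genomes, or compositional coupling between the virus and host tables
beyond the planted links.

## Problem sizes and numerical choices

The simulated problem sizes (200 genomes × 40 samples; 56-sample ASV
tables at 20,000 reads; 5 lineages × 8 genomes; 500-replicate null
batches at 199 permutations) were chosen so the full suite and the
acceptance script each run in minutes on a single core while keeping
Monte-Carlo standard errors small relative to the tolerances they are
checked against.  Exact-test switchover points (combined n ≤ 12 for
Mann–Whitney, n ≤ 8 for Spearman, arrangement count ≤ budget for
PERMANOVA) bound enumeration cost while keeping small-sample p values
exact.  Strictness conventions follow the source rules throughout:
index > 5.75, depth > 200 m, TPM > 0, redundancy > 0.5, E-value < 10⁻³,
bit score > 100, core prevalence > `core_fraction`, copy > mode.
Floating-point comparisons in enumeration tails carry small absolute
epsilons (10⁻⁹ on rank sums, 10⁻⁷ relative on hypergeometric weights)
so ties at the boundary are counted deterministically.

## Known limitations

* The gene-density index formula is a documented reconstruction (see
  above); screening results with the default should be reported as
  such.
* PERMANOVA supports neither multi-factor designs nor restricted
  permutation; seasonal blocking, if desired, must be approximated by
  subsetting.
* PIMA has no consistency-based removal rule and treats singleton
  lineages as unassessable rather than scoring them against a global
  core.
* The co-occurrence scan leaves p values uncorrected by default and,
  with many viruses × thousands of ASVs, will produce false positives
  at roughly the nominal rate; use the BH mode for catalogue-scale
  scans.
* ANI is consumed, never computed; coverage-weighted identity and
  alignment-fraction filters of dereplication tools are not modelled.
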