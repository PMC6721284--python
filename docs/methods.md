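# Methods

This note documents the models and procedures implemented in
`tsetse_compgen`, the parameter defaults and why they were chosen, the
conventions adopted where the underlying analyses left choices open, and
what the synthetic-data generators do and do not emulate.

## Muller element assignment

Gene content of the six chromosome arms (Muller elements A–F) is strongly
conserved across flies, so 1:1 orthologs with *D. melanogaster* act as arm
markers. `assign_genes` gives each gene the element of its reference
ortholog — exactly the genes with a 1:1 link are assigned, and a duplicated
gene id in the map is an error (it violates 1:1). `assign_scaffolds`
requires a *strict* majority: the top element must hold more than 50% of a
scaffold's informative genes. Exact ties and ≤ 50% pluralities are
unassigned. No minimum number of informative genes is imposed by default
(a single 1:1 ortholog assigns its scaffold); `min_informative` (default 1)
exposes stricter behaviour, and the tie rule is recorded in the output
header comments. Position plays no role in the vote — membership is by
scaffold only. The X-linked element set is configuration, defaulting to
{A, D, F} per the *Glossina* karyotype; species with a different karyotype
(the *G. brevipalpis* pattern) are handled by overriding `--x-elements`.

Element summaries count *all* annotated genes and the cumulative assembled
length over assigned scaffolds, plus the 1:1 ortholog count; unassigned
scaffolds are reported under their own pseudo-element.

Coordinates are 1-based inclusive in GFF3 on disk and converted to 0-based
half-open internally.

## Homologous synteny blocks

Markers are orthologous coordinate pairs (reference position, target
position). Within each reference scaffold, markers are sorted by reference
position; two ref-adjacent markers *chain* when their targets sit on one
target scaffold at adjacent target-rank positions. Maximal chains of length
≥ 2 are HSBs. Because every marker belongs to exactly one block and spans
run from first to last member position (half-open, no extension toward
neighbouring blocks), blocks on a reference scaffold are disjoint and can
never nest.

Two exceptions handle leftovers: (1) an unchained marker becomes a
singleton block; (2) two ref-consecutive singletons on the same target
scaffold, closer than the resolution threshold (default 10 kb) on the
reference, merge into one two-marker block. Merging is pairwise, left to
right (no chains of three), and requires a shared target scaffold so the
merged block has a well-defined target span. Whether the distance test is
also applied on the target genome is a flag (`merge_both_genomes`, default
off), and orientation changes break chains only under `--orientation-strict`
(default off; in strict mode the rank step must keep a constant sign, and
runs are taken greedily from the left). Both choices are recorded in output
metadata since the original tooling's behaviour is not determinate.

`hsb_oracle` is a brute-force reference (exhaustive window enumeration,
refused above 100 markers) used only in tests; `detect_hsbs` is checked
against it on thousands of random instances.

Syntenic fraction per 250-kb bin is interval-union coverage: overlapping
block spans are merged first, bins are 0-based and width-aligned, and the
final partial bin of a scaffold is normalised by its true width. Spans
beyond the scaffold length are errors.

## Sex- and stage-biased expression

The study design is single-replicate: one library each for males,
non-lactating females and lactating females. With no within-condition
variance to estimate, differential expression uses the classical
two-library proportion test: gene count x₁ out of library total n₁ against
x₂ of n₂, pooled-variance z statistic

    z = (x₁/n₁ − x₂/n₂) / sqrt( p̂(1−p̂)(1/n₁ + 1/n₂) ),  p̂ = (x₁+x₂)/(n₁+n₂)

two-sided. Degenerate cases (pooled proportion 0 or 1) carry no evidence
and return p = 1. The test is symmetric under swapping libraries and p
decreases monotonically in |x₁ − x₂| at fixed totals.

Genes with fewer than 5 summed counts across the contrast (configurable)
are excluded from testing, which also shrinks the Bonferroni denominator —
correction is over genes actually tested, at α = 0.05. Direction follows
"male-biased = upregulated in males relative to females"; log2 ratios use a
0.5-count pseudocount against infinities. TPM (each sample scaled to 10⁶
after dividing counts by gene length) is the reporting proxy only — the
test runs on raw counts, where the binomial model is defined. An all-zero
sample column makes TPM undefined and is an error.

Element summaries report the median log2 female:male ratio and bias-class
fractions per element; the X-versus-autosome contrast is a two-sided
Mann–Whitney U on per-gene log2 F:M. If either side is empty the
comparison is skipped with a warning rather than an error. Cross-species
overlap of enriched genes maps gene ids to ortholog-group ids and counts
the exclusive Venn partition over species subsets; the full-panel cell is
the "universal" count.

## Pairwise molecular evolution

ω = dN/dS is estimated per aligned sequence pair with Nei–Gojobori (1986)
counting and a Jukes–Cantor correction — a fully specified desk-scale
estimator; tree-wide ML codon models (branch or site models) are outside
this package's scope, and the group-comparison stage consumes ω values from
either source interchangeably.

Conventions, in order of application:

- **Masking.** Codon columns containing gaps or ambiguity codes, or that
  are stop codons in either sequence, are removed; then a sliding window of
  10 codons with codon-mismatch density > 0.5 masks its span. Defaults are
  declared configuration (`window`, `max_mismatch_density`) — the filter is
  a concrete instantiation of the usual pre-alignment cleanup, symmetric in
  the two sequences, and removal-only (difference counts can only drop).
- **Sites.** Per codon, the 9 one-step neighbours are classified; changes
  to stop codons are *excluded from the mutational opportunity* and the
  remainder renormalised so every codon contributes exactly 3 sites. This
  keeps the opportunity space consistent with the pathway rule below and
  with a substitution process in which stops never fix. N and S are
  averaged over the two sequences.
- **Differences.** Codon pairs differing at k positions are resolved over
  all k! minimal pathways, weighted equally; pathways through stop codons
  are skipped (if every pathway is blocked — possible only for some 2–3
  step pairs — all pathways are used as a fallback). Each step is
  synonymous iff it preserves the amino acid.
- **Correction.** dN = −¾ ln(1 − 4pN/3) and likewise dS; p ≥ ¾ saturates
  the correction and flags the result instead of producing a number.
  ω is defined only when dS > 0; dS = 0 (e.g. identical sequences) is
  flagged, not an error.

The estimator is symmetric in the sequence order. Tests verify the counts
against an exhaustive enumeration oracle and against Biopython's NG86 on
codons without stop neighbours, where the stop conventions provably
coincide.

Protein divergence is the p-distance × 100 over aligned non-gap,
unambiguous sites; zero comparable sites is an error.

Group comparisons (faster-X / slower-X) report, per stratum (all genes and
each expression-bias class), group sizes, medians, effect direction and a
two-sided Mann–Whitney U of X-linked versus autosomal ω. Empty groups skip
the contrast with a warning. No claim is made beyond the computed statistic.

## Orthogroup profiling

The species panel is the 12-Diptera set used in the comparative analysis:
six *Glossina* (sub-genera *Morsitans* = {*G. m. morsitans*,
*G. pallidipes*, *G. austeni*}, *Palpalis* = {*G. fuscipes*,
*G. palpalis*}, *Fusca* = {*G. brevipalpis*}) plus *D. melanogaster*,
*M. domestica*, *S. calcitrans* (Brachycera) and *A. gambiae*,
*A. aegypti*, *L. longipalpis* (Nematocera). Named classification levels
are Diptera, Brachycera, *Glossina*, *Morsitans*, *Palpalis*, and each
species. Nematocera and the single-species *Fusca* sub-genus are membership
groups, not levels: a group confined to Nematocera species classifies as
Diptera/partial, and a *G. brevipalpis*-only group is species-level. Because
named clades are nested or disjoint, the smallest covering clade of any
non-empty species set is unique.

A group is *universal* at its level iff every species of that clade is
present; a single-species group is universal by convention (clade of size
1). The (level, universality) categories partition all non-zero rows
exhaustively and disjointly, and the tabulation reports orthogroup counts
and summed gene counts per cell. All-zero rows are errors.

The expansion/contraction screen keeps rows whose copy-number variance
across the six *Glossina* is strictly greater than 2. Variance is the
*sample* variance (divisor n−1 = 5); the original divisor is unstated, so
the choice is recorded in output metadata and the threshold is
configurable. The output is labelled "candidates": the downstream
birth–death likelihood test that would filter them further is out of scope.
The candidate PCA centres count rows by species means and projects onto
SVD components, with each component's largest-magnitude loading forced
positive so results are deterministic; identical rows (zero variance after
centring) and fewer than 3 rows are errors.

## Symbiont insertion discrimination

Candidate segments arrive as alignment summaries (length, polymorphism
count, indel-event count, homology flag); the upstream homology search and
assembly are not re-run, and the homology threshold that set the flag is
treated as input metadata. The decision rule:

- **chromosomal_insertion** iff homologous AND polymorphism density
  ≥ 10/100 bp AND ≥ 1 indel event AND length ≥ 500 bp;
- **cytoplasmic** iff homologous AND density < 10/100 bp;
- **artifact** otherwise (short or non-homologous fragments).

Density and indels are conjunctive by default — the strict reading of
"high polymorphism *coupled with* insertions/deletions"; `--lenient`
implements the disjunctive alternative since the original application is
not fully determinate. The 500-bp floor is inferred from the smallest
insertion size the rule is meant to admit; both thresholds are
configuration. The density boundary is inclusive (exactly 10/100 bp
qualifies). Every call carries a `reasons` list recording each criterion's
outcome. Summaries give per-class counts and, for the insertion set,
N50/N90 (smallest length such that segments at least that long cover
50%/90% of the summed length) and mean length.

## Synthetic data: what it emulates, and what it does not

All generators are seeded (`numpy.random.default_rng`) and byte-identical
under identical spec + seed. Defaults define the study conditions:

- **Genomes** (`GenomeSpec`): 300 scaffolds of 0.2–2 Mb, 3–12 genes each,
  every gene on a scaffold sharing its true element; element weights
  (0.17, 0.18, 0.18, 0.19, 0.25, 0.03) mirror fly arm proportions with E
  distinctly the largest and F the tiny dot element; 75% of genes get a 1:1
  ortholog link and 5% of links point to a uniformly chosen wrong element.
  This emulates ortholog-based arm mapping with imperfect orthology calls;
  it does not emulate assembly fragmentation correlated with repeat
  content, or genes spanning scaffold joins.
- **Marker sets**: planted collinear blocks on private target scaffolds,
  exception-1 singleton intruders, and interleaved quadruples that force
  exception-2 merges; plus unstructured random instances for
  oracle-equivalence testing. Real marker sets from whole-genome alignment
  chains carry orientation structure and density gradients not modelled
  here.
- **Expression** (`BiasSpec`): one library per condition; negative binomial
  counts with variance m + φm² (φ = `dispersion`, default 0.05, degenerating
  to Poisson at 0 — the paper-scale design has single replicates, so φ is a
  free parameter, not an estimated one). Planted female-biased genes (20%
  of X-linked genes) are 2³-fold higher in both female libraries; planted
  male-biased genes (10% of autosomal genes) the reverse; expected count
  ratios equal 2^effect exactly because libraries are not renormalised
  after planting. Library size 5 × 10⁶. Not emulated: length-dependent
  sampling biases, batch effects, isoform structure.
- **Codon pairs** (`OmegaSpec`): random sense-codon ancestors; one copy
  accumulates Poisson(branch_length) *proposed* point mutations per codon
  (default 0.3) with transition/transversion ratio 2; synonymous proposals
  always fix, nonsynonymous fix with probability ω, stops are rejected.
  Accepted substitutions are therefore fewer than proposals when ω < 1.
  This is deliberately simpler than a full codon model (no codon-frequency
  bias, no rate heterogeneity); it is sufficient for ordering and recovery
  tests, and NG86's residual counting bias at this divergence is visible in
  the recovery medians the acceptance script reports.
- **Segments** (`SegmentSpec`): planted chromosomal insertions at 12
  polymorphisms/100 bp with indels, cytoplasmic copies at 3/100 bp without,
  lengths 1.5–8 kb. The minimum length keeps the planted density more than
  two binomial standard deviations above the 10/100 bp threshold, so
  classification is unambiguous in expectation — sampling noise near the
  boundary is a property of parameter choices, not of the rule.
- **Orthogroup matrices**: rows built to satisfy a requested
  (level, universality) pattern exactly, with per-present-species counts of
  1 + Poisson(0.5); impossible categories (partial at species level, or
  partial for a two-species clade, whose proper subsets all fall to species
  level) raise errors.

Passing tests on these data demonstrate correctness of the inference rules
and estimators under known truth; they do not validate upstream steps
(orthology inference, alignment, read mapping) or guarantee performance on
real genomes whose noise structure differs.

## Problem sizes and numerical notes

The test and acceptance workloads use 1000-scaffold genomes, 1000 random
marker instances (≤ 50 markers, where the exhaustive oracle is exact),
200 null expression studies of 5000 genes, 500 codon pairs of 300 codons
per planted ω, the full 2¹²−1 composition patterns, and 1000 candidate
segments — sizes at which every stochastic bound holds with wide margin
while the whole suite runs in seconds. Floating-point comparisons against
oracles use absolute tolerance 1e-9 (binning: 1e-12); TPM column sums are
required within 1e-3 of 10⁶. Ties in the scaffold vote are broken
deterministically by element label for reporting, but tied scaffolds are
never assigned, so the tie-break never affects calls.

## Known limitations

- The proportion test assumes binomial count sampling; under overdispersion
  it is anti-conservative. It is the appropriate single-replicate-era tool,
  isolated behind one function so a replicate-aware model could be swapped
  in.
- NG86 with equal mutation-rate site counting underestimates ω when the
  generating process has transition bias; the acceptance medians quantify
  this at κ = 2 and branch length 0.3.
- HSB detection treats markers as points; span ends are marker positions,
  not alignment-block boundaries.
- The variance screen is a pre-filter only; it makes no significance claim
  about family expansion.
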