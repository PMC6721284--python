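# tsetse-compgen

Comparative-genomics inference stages for tsetse fly (*Glossina*) genome
studies, reimplemented as a tested, reusable Python package. Tsetse flies
transmit African trypanosomiasis, and comparisons of the six *Glossina*
genomes against *Drosophila melanogaster* and other Diptera rely on a chain
of bespoke analysis steps between the standard tooling. This package
implements those steps as a library with a CLI, and ships a synthetic-data
module that generates every input with planted ground truth, so the whole
chain is testable without any genome downloads.

## What it computes

- **Muller element assignment** (`muller`). Chromosome-arm gene content
  (Muller elements A–F) is conserved across flies, so a gene is assigned to
  an element when it is a 1:1 ortholog of a *D. melanogaster* gene, and a
  scaffold is assigned when a strict majority (> 50%) of its ortholog-bearing
  genes agree on one element. Element sizes are summarised as gene counts and
  cumulative scaffold length; scaffolds on elements A, D, F (the *Glossina*
  X) are flagged X-linked.
- **Homologous synteny blocks** (`synteny`). An HSB is a run of two or more
  consecutive orthologous markers occupying homologous regions of the two
  genomes with no other block nested inside its span, plus two exceptions:
  leftover single markers form singleton blocks, and two consecutive
  singletons closer than the resolution threshold (10 kb) merge. Block
  coverage is aggregated into 250-kb bins of syntenic fraction (a Circos-style
  histogram track).
- **Sex-/stage-biased expression** (`expression`). With one library per
  condition (male, non-lactating female, lactating female), a gene's count is
  compared between libraries with the pooled two-proportion z-test,
  Bonferroni-corrected at α = 0.05; TPM is the reporting proxy. Element-level
  summaries and an X-versus-autosome rank-sum contrast quantify the excess of
  female-biased expression on X-linked elements; a Venn-style overlap counts
  enriched ortholog groups shared across species.
- **Molecular evolution** (`molevol`). Pairwise ω = dN/dS by Nei–Gojobori
  (1986) counting with Jukes–Cantor correction, after masking gap, stop and
  high-mismatch alignment windows; protein divergence as substitutions per
  100 aligned sites; faster-X / slower-X group comparisons by Mann–Whitney U
  over ω stratified by expression bias class.
- **Orthogroup profiling** (`orthogroups`). Each orthology group is
  classified by the smallest named clade containing all its member species
  (Diptera, Brachycera, *Glossina*, the *Morsitans*/*Palpalis* sub-genera, or
  a single species), universal versus partial; an expansion/contraction
  screen keeps groups whose copy-number variance across the six *Glossina*
  exceeds 2, with a PCA over candidate count rows.
- **Symbiont insertion detection** (`hgt`). Candidate *Wolbachia*-homologous
  segments are called chromosomal insertions when homologous, ≥ 500 bp, at
  ≥ 10 polymorphisms/100 bp against the symbiont reference *and* carrying
  indels; near-identical segments are cytoplasmic; the rest are artifacts.
  Insertion sets are summarised by N50/N90/mean length.
- **Synthetic data** (`synthetic`). Deterministic, seeded generators for all
  of the above with planted truth: noisy ortholog maps, marker sets with
  planted blocks, overdispersed count matrices with planted sex-biased genes,
  codon pairs evolved at a planted ω, orthogroup matrices with planted
  composition categories, and segment tables with planted polymorphism
  densities.

## Worked example

```python
from tsetse_compgen import synthetic, muller, molevol
import numpy as np

genome, orthologs, truth = synthetic.gen_genome(
    synthetic.GenomeSpec(n_scaffolds=500, mislabel_rate=0.05, seed=11)
)
gene_calls = muller.assign_genes(orthologs, genome.genes)
scaffold_calls = muller.assign_scaffolds(gene_calls, genome.scaffolds)
accuracy = np.mean([a.element == t
                    for a, t in zip(scaffold_calls, truth["true_element"])])
print(f"scaffolds assigned correctly: {accuracy:.1%}")
for s in muller.summarize_elements(scaffold_calls, genome.genes,
                                   genome.scaffolds, orthologs):
    print(f"element {s.element:>10}: {s.n_genes:5d} genes, "
          f"{s.cumulative_length/1e6:7.1f} Mb, {s.n_one_to_one:5d} 1:1 orthologs")

pairs, planted = synthetic.gen_codon_pairs(
    synthetic.OmegaSpec(n_pairs=200, codons_per_pair=300,
                        omega=0.2, branch_length=0.3, seed=11)
)
estimates = [r.omega for r in map(molevol.ng86_dnds, pairs)
             if r.omega is not None]
print(f"planted omega = {planted}, median NG86 estimate = {np.median(estimates):.3f}")
```

prints

```
scaffolds assigned correctly: 98.8%
element          A:   748 genes,   109.6 Mb,   568 1:1 orthologs
element          B:   643 genes,    94.0 Mb,   484 1:1 orthologs
element          C:   735 genes,   106.1 Mb,   543 1:1 orthologs
element          D:   708 genes,    92.6 Mb,   558 1:1 orthologs
element          E:   917 genes,   124.1 Mb,   688 1:1 orthologs
element          F:    68 genes,     9.6 Mb,    51 1:1 orthologs
element unassigned:    20 genes,     6.3 Mb,    14 1:1 orthologs
planted omega = 0.2, median NG86 estimate = 0.177
```

With 5% of ortholog links mislabelled, 98.8% of scaffolds still recover
their true element (the majority vote absorbs the noise); element E comes
out largest and F smallest, matching the planted arm proportions; and the
pairwise NG86 estimator recovers a planted ω = 0.2 to within its expected
counting bias at this divergence.

The same stages are available from the shell:

```bash
tsetse-compgen demo --seed 42 --outdir demo_run     # simulate + all stages
tsetse-compgen muller --gff genes.gff3 --lengths scaffolds.tsv \
    --orthologs orthologs.tsv --x-elements A,D,F --outdir out
```

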