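"""Generator contracts: planted truth, seeded determinism, distributional sanity."""

import numpy as np
import pandas as pd
import pytest

from tsetse_compgen import synthetic
from tsetse_compgen.molevol import STOP_CODONS


class TestGenGenome:
    def test_no_noise_links_all_carry_true_element(self):
        spec = synthetic.GenomeSpec(n_scaffolds=20, mislabel_rate=0.0, ortholog_rate=1.0, seed=1)
        genome, ortho, truth = synthetic.gen_genome(spec)
        true_of = dict(zip(truth["scaffold_id"], truth["true_element"]))
        scaffold_of = dict(zip(genome.genes["gene_id"], genome.genes["scaffold_id"]))
        assert len(ortho) == len(genome.genes)
        assert all(
            e == true_of[scaffold_of[g]] for g, e in zip(ortho["gene_id"], ortho["ref_element"])
        )

    def test_total_corruption_never_true_element(self):
        spec = synthetic.GenomeSpec(
            n_scaffolds=20, element_labels=("A", "B"), element_weights=(0.5, 0.5),
            mislabel_rate=1.0, ortholog_rate=1.0, seed=2,
        )
        genome, ortho, truth = synthetic.gen_genome(spec)
        true_of = dict(zip(truth["scaffold_id"], truth["true_element"]))
        scaffold_of = dict(zip(genome.genes["gene_id"], genome.genes["scaffold_id"]))
        assert all(
            e != true_of[scaffold_of[g]] for g, e in zip(ortho["gene_id"], ortho["ref_element"])
        )

    def test_genes_lie_within_scaffolds(self):
        genome, _, _ = synthetic.gen_genome(synthetic.GenomeSpec(n_scaffolds=30, seed=3))
        merged = genome.genes.merge(genome.scaffolds, on="scaffold_id")
        assert ((merged["start"] >= 0) & (merged["end"] <= merged["length"])).all()

    def test_seeded_determinism_bytewise(self):
        spec = synthetic.GenomeSpec(n_scaffolds=15, seed=7)
        a = synthetic.gen_genome(spec)
        b = synthetic.gen_genome(spec)
        for left, right in [(a[0].scaffolds, b[0].scaffolds), (a[0].genes, b[0].genes),
                            (a[1], b[1]), (a[2], b[2])]:
            assert left.to_csv() == right.to_csv()

    def test_validation_error_names_field(self):
        with pytest.raises(ValueError, match="ortholog_rate"):
            synthetic.GenomeSpec(ortholog_rate=1.5)
        with pytest.raises(ValueError, match="element_weights"):
            synthetic.GenomeSpec(element_weights=(0.5, 0.5, 0.5, 0.5, 0.5, 0.5))


class TestGenMarkerSet:
    def test_single_block_truth(self):
        markers, truth = synthetic.gen_marker_set(1, markers_per_block=5, spacing=1000, seed=0)
        assert truth == [(frozenset(range(5)), False)]

    def test_blocks_on_distinct_target_scaffolds(self):
        markers, truth = synthetic.gen_marker_set(2, markers_per_block=3, seed=1)
        tgt = {markers[i].tgt_scaffold for group, _ in truth for i in group}
        assert len(tgt) == 2

    def test_block_markers_collinear_in_both_genomes(self):
        markers, truth = synthetic.gen_marker_set(3, markers_per_block=4, seed=2)
        for group, singleton in truth:
            idx = sorted(group, key=lambda i: markers[i].ref_pos)
            tgt_pos = [markers[i].tgt_pos for i in idx]
            assert tgt_pos == sorted(tgt_pos)

    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError, match="spacing"):
            synthetic.gen_marker_set(1, spacing=0)


class TestGenExpression:
    def _genome(self, n=150, seed=4, x_only=False):
        weights = (1.0, 0, 0, 0, 0, 0) if x_only else None
        kwargs = {"element_weights": weights} if weights else {}
        return synthetic.gen_genome(
            synthetic.GenomeSpec(n_scaffolds=n, seed=seed, **kwargs)
        )[0]

    def test_zero_effect_means_zero_planted(self):
        counts, _, truth = synthetic.gen_expression(
            self._genome(), synthetic.BiasSpec(n_genes=500, effect_log2=0.0, seed=5)
        )
        assert (truth == "unbiased").all()

    def test_planted_ratio_matches_effect_size(self):
        # 2^3 = 8-fold planted female bias; Poisson counts; >=1000 planted genes
        genome = self._genome(n=250, x_only=True)
        spec = synthetic.BiasSpec(
            n_genes=1500, frac_female_biased_on_X=1.0, frac_male_biased_on_autosome=0.0,
            effect_log2=3.0, library_size=1e6, dispersion=0.0, seed=6,
        )
        counts, _, truth = synthetic.gen_expression(genome, spec)
        planted = truth.index[truth == "female_biased"]
        assert len(planted) >= 1000
        ratio = counts.loc[planted, "female_nonlactating"].sum() / counts.loc[planted, "male"].sum()
        assert ratio == pytest.approx(8.0, rel=0.05)

    def test_seeded_determinism(self):
        genome = self._genome()
        spec = synthetic.BiasSpec(n_genes=300, seed=9)
        a = synthetic.gen_expression(genome, spec)
        b = synthetic.gen_expression(genome, spec)
        assert a[0].to_csv() == b[0].to_csv()
        assert (a[2] == b[2]).all()

    def test_requesting_more_genes_than_available_fails(self):
        with pytest.raises(ValueError, match="n_genes"):
            synthetic.gen_expression(self._genome(n=5), synthetic.BiasSpec(n_genes=10_000))

    def test_overdispersion_inflates_variance(self):
        genome = self._genome(n=100, seed=10)
        base = dict(n_genes=500, effect_log2=0.0, library_size=1e6)
        poisson, _, _ = synthetic.gen_expression(genome, synthetic.BiasSpec(dispersion=0.0, seed=11, **base))
        overdisp, _, _ = synthetic.gen_expression(genome, synthetic.BiasSpec(dispersion=0.5, seed=11, **base))
        # same expected means; NB counts spread much further around them
        assert overdisp.to_numpy().var() > 1.5 * poisson.to_numpy().var()


class TestGenCodonPairs:
    def test_zero_branch_length_identical_pairs(self):
        pairs, _ = synthetic.gen_codon_pairs(
            synthetic.OmegaSpec(n_pairs=5, codons_per_pair=50, branch_length=0.0, seed=12)
        )
        assert all(p.seq_a == p.seq_b for p in pairs)

    def test_no_internal_stop_codons(self):
        pairs, _ = synthetic.gen_codon_pairs(
            synthetic.OmegaSpec(n_pairs=10, codons_per_pair=100, omega=1.0,
                                branch_length=1.0, seed=13)
        )
        for p in pairs:
            for ca, cb in p.codons():
                assert ca not in STOP_CODONS and cb not in STOP_CODONS

    def test_divergence_grows_with_branch_length(self):
        def mean_diff(bl, seed=14):
            pairs, _ = synthetic.gen_codon_pairs(
                synthetic.OmegaSpec(n_pairs=20, codons_per_pair=200, omega=1.0,
                                    branch_length=bl, seed=seed)
            )
            return np.mean([
                sum(ca != cb for ca, cb in p.codons()) for p in pairs
            ])
        diffs = [mean_diff(bl) for bl in (0.05, 0.2, 0.8)]
        assert diffs[0] < diffs[1] < diffs[2]

    def test_seeded_determinism(self):
        spec = synthetic.OmegaSpec(n_pairs=5, codons_per_pair=30, seed=15)
        a, _ = synthetic.gen_codon_pairs(spec)
        b, _ = synthetic.gen_codon_pairs(spec)
        assert [(p.seq_a, p.seq_b) for p in a] == [(p.seq_a, p.seq_b) for p in b]


class TestGenCandidateSegments:
    def test_zero_cytoplasmic_density_means_zero_polymorphisms(self):
        table, truth = synthetic.gen_candidate_segments(
            synthetic.SegmentSpec(n_segments=40, density_cytoplasmic=0.0, seed=16)
        )
        cyto = table[truth.to_numpy() == "cytoplasmic"]
        assert (cyto["n_polymorphisms"] == 0).all()

    def test_planted_density_mean_recovered(self):
        table, truth = synthetic.gen_candidate_segments(
            synthetic.SegmentSpec(n_segments=1000, density_chromosomal=12.0, seed=0)
        )
        chrom = table[truth.to_numpy() == "chromosomal_insertion"]
        density = 100.0 * chrom["n_polymorphisms"] / chrom["length_bp"]
        se = density.std() / np.sqrt(len(density))
        assert abs(density.mean() - 12.0) < 3 * se

    def test_seeded_determinism(self):
        spec = synthetic.SegmentSpec(n_segments=30, seed=18)
        a, _ = synthetic.gen_candidate_segments(spec)
        b, _ = synthetic.gen_candidate_segments(spec)
        assert a.to_csv() == b.to_csv()


class TestGenOrthogroupMatrix:
    def test_requested_patterns_satisfied(self):
        matrix, truth = synthetic.gen_orthogroup_matrix(
            {("Glossina", "universal"): 5}, seed=19
        )
        glossina = set(synthetic.DEFAULT_TAXONOMY.clades["Glossina"])
        for og in matrix.index:
            present = {sp for sp in matrix.columns if matrix.loc[og, sp] > 0}
            assert present == glossina

    def test_palpalis_universal_pattern(self):
        matrix, _ = synthetic.gen_orthogroup_matrix(
            {("Palpalis", "universal"): 3}, seed=20
        )
        for og in matrix.index:
            present = {sp for sp in matrix.columns if matrix.loc[og, sp] > 0}
            assert present == {"G_fuscipes", "G_palpalis"}

    def test_seeded_determinism(self):
        req = {("Diptera", "partial"): 10, ("Morsitans", "universal"): 4}
        a, ta = synthetic.gen_orthogroup_matrix(req, seed=21)
        b, tb = synthetic.gen_orthogroup_matrix(req, seed=21)
        assert a.to_csv() == b.to_csv() and ta.to_csv() == tb.to_csv()

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="unknown level"):
            synthetic.gen_orthogroup_matrix({("Hexapoda", "universal"): 1})
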