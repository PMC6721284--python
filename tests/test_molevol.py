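"""NG86 counting against exhaustive oracles, masking, divergence, rate groups."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from Bio.Data import CodonTable

from tsetse_compgen import molevol, synthetic
from tsetse_compgen.molevol import CodonPair

TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE = sorted(TABLE.forward_table)
STOPS = set(TABLE.stop_codons)
BASES = "ACGT"


# --- independent oracle: exhaustive per-codon enumeration -------------------

def oracle_sites(codon):
    """Site counts by direct enumeration of the 9 neighbours, stops excluded."""
    syn = nonsyn = 0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            neighbor = codon[:pos] + alt + codon[pos + 1:]
            if neighbor in STOPS:
                continue
            if TABLE.forward_table[neighbor] == TABLE.forward_table[codon]:
                syn += 1
            else:
                nonsyn += 1
    return 3 * nonsyn / (syn + nonsyn), 3 * syn / (syn + nonsyn)


def oracle_diffs(c1, c2):
    """Difference counts by enumerating every permutation of substitution order."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in permutations(positions):
        path, cur = [cur := c1], c1
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1:]
            path.append(cur)
        pathways.append(path)
    valid = [p for p in pathways if not any(c in STOPS for c in p[1:-1])]
    chosen = valid if valid else pathways
    nd = sd = 0.0
    for path in chosen:
        for a, b in zip(path, path[1:]):
            if a not in STOPS and b not in STOPS and \
               TABLE.forward_table[a] == TABLE.forward_table[b]:
                sd += 1
            else:
                nd += 1
    return nd / len(chosen), sd / len(chosen)


def oracle_ng86(pair):
    N = S = Nd = Sd = 0.0
    for ca, cb in pair.codons():
        na, sa = oracle_sites(ca)
        nb, sb = oracle_sites(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = oracle_diffs(ca, cb)
        Nd += nd
        Sd += sd
    return N, S, Nd, Sd


class TestNg86:
    def test_identical_sequences(self):
        r = molevol.ng86_dnds(CodonPair("p", "ATGGCT", "ATGGCT"))
        assert r.Nd == r.Sd == 0 and r.dN == r.dS == 0
        assert r.omega is None and "omega_undefined_dS_zero" in r.flags

    def test_single_synonymous_codon_change(self):
        # TTT -> TTC is Phe -> Phe: one synonymous difference
        r = molevol.ng86_dnds(CodonPair("p", "TTT", "TTC"))
        assert r.Nd == 0 and r.Sd == 1

    def test_single_nonsynonymous_codon_change(self):
        # ATG -> ATA is Met -> Ile
        r = molevol.ng86_dnds(CodonPair("p", "ATG", "ATA"))
        assert r.Nd == 1 and r.Sd == 0

    def test_counts_match_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(1, 30))
            a = "".join(SENSE[i] for i in rng.integers(len(SENSE), size=n))
            b = "".join(SENSE[i] for i in rng.integers(len(SENSE), size=n))
            pair = CodonPair("p", a, b)
            r = molevol.ng86_dnds(pair)
            N, S, Nd, Sd = oracle_ng86(pair)
            assert r.N_sites == pytest.approx(N, abs=1e-9)
            assert r.S_sites == pytest.approx(S, abs=1e-9)
            assert r.Nd == pytest.approx(Nd, abs=1e-9)
            assert r.Sd == pytest.approx(Sd, abs=1e-9)

    def test_symmetry_in_sequence_order(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = "".join(SENSE[i] for i in rng.integers(len(SENSE), size=20))
            b = "".join(SENSE[i] for i in rng.integers(len(SENSE), size=20))
            r1 = molevol.ng86_dnds(CodonPair("p", a, b))
            r2 = molevol.ng86_dnds(CodonPair("p", b, a))
            assert r1.Nd == pytest.approx(r2.Nd) and r1.Sd == pytest.approx(r2.Sd)
            assert r1.N_sites == pytest.approx(r2.N_sites)

    def test_agrees_with_biopython_where_conventions_coincide(self):
        """Cross-check dN/dS against Bio.Align.analysis.calculate_dn_ds.

        Restricted to codons with no stop-codon neighbours and at most two
        differences per codon pair, where the stop-handling conventions of
        the two implementations provably coincide.
        """
        from Bio.Align import Alignment
        from Bio.Align.analysis import calculate_dn_ds

        no_stop_neighbors = [
            c for c in SENSE
            if all(
                c[:i] + alt + c[i + 1:] not in STOPS
                for i in range(3) for alt in BASES
            )
        ]
        rng = np.random.default_rng(10)
        for _ in range(20):
            codons_a, codons_b = [], []
            while len(codons_a) < 60:
                ca = no_stop_neighbors[rng.integers(len(no_stop_neighbors))]
                cb = no_stop_neighbors[rng.integers(len(no_stop_neighbors))]
                if sum(x != y for x, y in zip(ca, cb)) > 2:
                    continue
                codons_a.append(ca)
                codons_b.append(cb)
            a, b = "".join(codons_a), "".join(codons_b)
            r = molevol.ng86_dnds(CodonPair("p", a, b))
            dn, ds = calculate_dn_ds(Alignment([a, b]), method="NG86")
            if r.dN is not None and r.dS is not None and ds >= 0:
                assert r.dN == pytest.approx(dn, abs=5e-5)  # biopython rounds to 4 dp
                assert r.dS == pytest.approx(ds, abs=5e-5)

    def test_saturated_correction_flagged(self):
        # every codon differs synonymously -> pS >= 3/4 territory
        a = "TTT" * 4 + "CGT" * 4
        b = "TTC" * 4 + "CGC" * 4
        r = molevol.ng86_dnds(CodonPair("p", a, b))
        assert "dS_saturated" in r.flags and r.omega is None

    def test_non_sense_codon_rejected(self):
        with pytest.raises(ValueError, match="sense codon"):
            molevol.ng86_dnds(CodonPair("p", "TAA", "ATG"))


class TestMasking:
    def test_perfect_pair_unchanged(self):
        a = "ATGGCTAAATTT" * 5
        pair = molevol.mask_alignment(CodonPair("p", a, a))
        assert pair.seq_a == a and pair.seq_b == a

    def test_mismatch_burst_masked(self):
        clean = "ATGGAC" * 10                       # 20 identical codons
        burst_a, burst_b = "TTT" * 10, "AGG" * 10   # 10 codons of 100% mismatch
        pair = molevol.mask_alignment(
            CodonPair("p", clean + burst_a + clean, clean + burst_b + clean),
            window=10, max_mismatch_density=0.5,
        )
        assert pair.seq_a == pair.seq_b  # only identical flanks survive
        assert pair.n_codons >= 30

    def test_gap_and_stop_columns_removed(self):
        a = "ATG---TAAGCT"
        b = "ATGTTTCAAGCT"
        pair = molevol.mask_alignment(CodonPair("p", a, b))
        assert pair.seq_a == "ATGGCT" and pair.seq_b == "ATGGCT"

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            molevol.mask_alignment(CodonPair("p", "ATGC", "ATGC"))

    def test_masking_never_increases_differences(self):
        pairs, _ = synthetic.gen_codon_pairs(
            synthetic.OmegaSpec(n_pairs=20, codons_per_pair=40, omega=1.0,
                                branch_length=0.5, seed=12)
        )
        for pair in pairs:
            raw = molevol.ng86_dnds(pair)
            masked = molevol.ng86_dnds(molevol.mask_alignment(pair))
            assert masked.Nd <= raw.Nd + 1e-9
            assert masked.Sd <= raw.Sd + 1e-9


class TestProteinDivergence:
    def test_identical_sequences_zero(self):
        assert molevol.protein_divergence("p", "MKV", "MKV").subs_per_100_sites == 0.0

    def test_one_difference_per_hundred(self):
        a = "A" * 100
        b = "A" * 99 + "V"
        assert molevol.protein_divergence("p", a, b).subs_per_100_sites == pytest.approx(1.0)

    def test_gaps_excluded_from_denominator(self):
        a = "A" * 90 + "-" * 10
        b = "A" * 89 + "V" + "-" * 10
        r = molevol.protein_divergence("p", a, b)
        assert r.n_sites == 90
        assert r.subs_per_100_sites == pytest.approx(100 / 90)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="no comparable"):
            molevol.protein_divergence("p", "---", "AAA")


class TestRateGroups:
    def test_planted_lower_x_omega_detected(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame(
            {
                "omega": np.concatenate([rng.gamma(2, 0.05, 200), rng.gamma(2, 0.15, 200)]),
                "x_flag": ["X"] * 200 + ["autosome"] * 200,
            }
        )
        [report] = molevol.compare_rate_groups(table)
        assert report["direction"] == "X_lower" and report["p_value"] < 0.01

    def test_null_distributions_not_flagged(self):
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(50):
            table = pd.DataFrame(
                {"omega": rng.gamma(2, 0.1, 120), "x_flag": ["X"] * 60 + ["autosome"] * 60}
            )
            [report] = molevol.compare_rate_groups(table)
            pvals.append(report["p_value"])
        assert np.mean(np.array(pvals) < 0.05) <= 0.2  # near-nominal false positive rate

    def test_empty_group_skipped_with_warning(self):
        table = pd.DataFrame({"omega": [0.1, 0.2], "x_flag": ["autosome", "autosome"]})
        [report] = molevol.compare_rate_groups(table)
        assert report["skipped"] and "empty group" in report["warning"]

    def test_bias_class_strata_reported(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(
            {
                "omega": rng.gamma(2, 0.1, 120),
                "x_flag": ["X", "autosome"] * 60,
                "bias_class": ["male_biased", "female_biased", "unbiased"] * 40,
            }
        )
        reports = molevol.compare_rate_groups(table)
        strata = {r["stratum"] for r in reports}
        assert strata == {"all_genes", "male_biased", "female_biased", "unbiased"}


class TestPlantedOmegaRecovery:
    @pytest.mark.parametrize("omega", [0.2, 1.0])
    def test_median_estimate_within_band(self, omega):
        spec = synthetic.OmegaSpec(
            n_pairs=150, codons_per_pair=300, omega=omega, branch_length=0.3, seed=16
        )
        pairs, planted = synthetic.gen_codon_pairs(spec)
        estimates = [
            r.omega for r in (molevol.ng86_dnds(p) for p in pairs) if r.omega is not None
        ]
        assert np.median(estimates) == pytest.approx(planted, rel=0.2)

    def test_omega_sets_are_ordered(self):
        lo_pairs, _ = synthetic.gen_codon_pairs(
            synthetic.OmegaSpec(n_pairs=60, codons_per_pair=200, omega=0.2, seed=17)
        )
        hi_pairs, _ = synthetic.gen_codon_pairs(
            synthetic.OmegaSpec(n_pairs=60, codons_per_pair=200, omega=1.0, seed=17)
        )
        med = lambda ps: np.median(
            [r.omega for r in map(molevol.ng86_dnds, ps) if r.omega is not None]
        )
        assert med(lo_pairs) < med(hi_pairs)
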