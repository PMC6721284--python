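"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of input the comparative analyses consume —
annotated scaffolds with noisy 1:1 ortholog calls, orthologous marker sets
with planted block structure, single-replicate count matrices with planted
sex-biased genes, codon pairs evolved at a planted ω, orthogroup matrices
with planted composition categories, and symbiont-homologous segment
summaries with planted polymorphism densities.  All generators are
deterministic for a fixed spec + seed and return the planted truth alongside
the data, so downstream stages can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotatedGenome
from .molevol import AA_OF, CodonPair, SENSE_CODONS, STOP_CODONS
from .muller import DEFAULT_ELEMENTS, DEFAULT_X_ELEMENTS
from .synteny import Marker
from .taxonomy import DEFAULT_TAXONOMY, TaxonMap

# ---------------------------------------------------------------------------
# specs


def _check(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"{field_name}: {message}")


@dataclass(frozen=True)
class GenomeSpec:
    """Scaffolds bearing genes with true element labels and noisy ortholog calls."""

    n_scaffolds: int = 300
    genes_per_scaffold: tuple[int, int] = (3, 12)
    scaffold_length_range: tuple[int, int] = (200_000, 2_000_000)
    element_labels: tuple[str, ...] = DEFAULT_ELEMENTS
    # Relative element sizes mirror fly chromosome-arm proportions
    # (E distinctly the largest arm, F the tiny dot element).
    element_weights: tuple[float, ...] = (0.17, 0.18, 0.18, 0.19, 0.25, 0.03)
    ortholog_rate: float = 0.75
    mislabel_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        _check(self.n_scaffolds > 0, "n_scaffolds", "must be positive")
        _check(0 < self.genes_per_scaffold[0] <= self.genes_per_scaffold[1],
               "genes_per_scaffold", "range must have positive lower bound")
        _check(0 < self.scaffold_length_range[0] <= self.scaffold_length_range[1],
               "scaffold_length_range", "range must have positive lower bound")
        _check(len(self.element_weights) == len(self.element_labels),
               "element_weights", "one weight per element label required")
        _check(abs(sum(self.element_weights) - 1.0) <= 1e-9,
               "element_weights", "must sum to 1")
        _check(0.0 <= self.ortholog_rate <= 1.0, "ortholog_rate", "must be in [0, 1]")
        _check(0.0 <= self.mislabel_rate <= 1.0, "mislabel_rate", "must be in [0, 1]")


@dataclass(frozen=True)
class BiasSpec:
    """Planted sex-biased expression structure for a single-replicate study."""

    n_genes: int = 2000
    frac_female_biased_on_X: float = 0.2
    frac_male_biased_on_autosome: float = 0.1
    effect_log2: float = 3.0
    library_size: float = 5e6
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        _check(self.n_genes > 0, "n_genes", "must be positive")
        _check(0.0 <= self.frac_female_biased_on_X <= 1.0,
               "frac_female_biased_on_X", "must be in [0, 1]")
        _check(0.0 <= self.frac_male_biased_on_autosome <= 1.0,
               "frac_male_biased_on_autosome", "must be in [0, 1]")
        _check(self.effect_log2 >= 0.0, "effect_log2", "must be non-negative")
        _check(self.library_size > 0, "library_size", "must be positive")
        _check(self.dispersion >= 0.0, "dispersion", "must be non-negative")


@dataclass(frozen=True)
class OmegaSpec:
    """Codon-pair simulation at a planted dN/dS."""

    n_pairs: int = 500
    codons_per_pair: int = 300
    omega: float = 0.2
    branch_length: float = 0.3  # expected proposed mutations per codon
    seed: int = 0

    def __post_init__(self):
        _check(self.n_pairs > 0, "n_pairs", "must be positive")
        _check(self.codons_per_pair >= 10, "codons_per_pair", "must be at least 10")
        _check(self.omega > 0, "omega", "must be positive")
        _check(self.branch_length >= 0, "branch_length", "must be non-negative")


@dataclass(frozen=True)
class SegmentSpec:
    """Symbiont-homologous segments with planted polymorphism densities.

    The default length range keeps the planted chromosomal density more than
    two binomial standard deviations above the 10/100 bp decision threshold
    at the minimum length, so classification is unambiguous in expectation.
    """

    n_segments: int = 200
    length_range: tuple[int, int] = (1500, 8000)
    density_chromosomal: float = 12.0  # polymorphisms per 100 bp
    density_cytoplasmic: float = 3.0
    indel_prob_chromosomal: float = 1.0  # P(at least one indel event planted)
    seed: int = 0

    def __post_init__(self):
        _check(self.n_segments > 0, "n_segments", "must be positive")
        _check(0 < self.length_range[0] <= self.length_range[1],
               "length_range", "range must have positive lower bound")
        _check(self.density_chromosomal >= 0, "density_chromosomal", "must be non-negative")
        _check(self.density_cytoplasmic >= 0, "density_cytoplasmic", "must be non-negative")
        _check(0.0 <= self.indel_prob_chromosomal <= 1.0,
               "indel_prob_chromosomal", "must be in [0, 1]")


# ---------------------------------------------------------------------------
# genome + ortholog map


def gen_genome(spec: GenomeSpec) -> tuple[AnnotatedGenome, pd.DataFrame, pd.DataFrame]:
    """Generate scaffolds, genes, and a noisy 1:1 ortholog map.

    Every gene on a scaffold shares the scaffold's true element.  A fraction
    ``ortholog_rate`` of genes get a 1:1 link to a fabricated reference gene;
    ``mislabel_rate`` of those links point to a uniformly chosen *wrong*
    element.  Returns (genome, ortholog_map, truth) where truth is the
    per-scaffold true element table.
    """
    rng = np.random.default_rng(spec.seed)
    n_el = len(spec.element_labels)
    elements = rng.choice(n_el, size=spec.n_scaffolds, p=np.asarray(spec.element_weights))

    scaffold_rows, gene_rows, ortho_rows = [], [], []
    ref_counter = 0
    for s in range(spec.n_scaffolds):
        scaffold_id = f"scf{s:05d}"
        true_element = spec.element_labels[elements[s]]
        length = int(rng.integers(spec.scaffold_length_range[0], spec.scaffold_length_range[1] + 1))
        scaffold_rows.append((scaffold_id, length, true_element))
        n_genes = int(rng.integers(spec.genes_per_scaffold[0], spec.genes_per_scaffold[1] + 1))
        gene_len = 2000
        usable = max(length - gene_len, n_genes)
        starts = np.sort(rng.choice(usable, size=n_genes, replace=False))
        for k, start in enumerate(starts):
            gene_id = f"{scaffold_id}_g{k:03d}"
            end = min(int(start) + gene_len, length)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((gene_id, scaffold_id, int(start), end, strand))
            if rng.random() < spec.ortholog_rate:
                if rng.random() < spec.mislabel_rate and n_el > 1:
                    wrong = [e for e in spec.element_labels if e != true_element]
                    ref_element = wrong[int(rng.integers(len(wrong)))]
                else:
                    ref_element = true_element
                ortho_rows.append((gene_id, f"Dmel_{ref_counter:06d}", ref_element))
                ref_counter += 1

    scaffolds = pd.DataFrame(scaffold_rows, columns=["scaffold_id", "length", "true_element"])
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "scaffold_id", "start", "end", "strand"])
    ortholog_map = pd.DataFrame(ortho_rows, columns=["gene_id", "ref_gene_id", "ref_element"])
    truth = scaffolds[["scaffold_id", "true_element"]].copy()
    return AnnotatedGenome(scaffolds, genes), ortholog_map, truth


# ---------------------------------------------------------------------------
# marker sets with planted block structure


def gen_marker_set(
    n_blocks: int,
    markers_per_block: int = 5,
    spacing: int = 50_000,
    resolution: int = 10_000,
    shuffle_singletons: int = 0,
    mergeable_singleton_pairs: int = 0,
    seed: int = 0,
) -> tuple[list[Marker], list[tuple[frozenset, bool]]]:
    """Plant HSB structure on one reference scaffold.

    Each planted block is a run of ``markers_per_block`` collinear markers on
    its own target scaffold; ``shuffle_singletons`` intruder markers each sit
    alone on a private target scaffold (exception-1 singletons);
    ``mergeable_singleton_pairs`` plants quadruples whose target order
    interleaves so that two ref-adjacent singletons closer than
    ``resolution`` merge under exception 2 while two far ones stay single.
    Truth is a list of (frozenset of marker indices, is_singleton_block).
    """
    if spacing <= 0:
        raise ValueError("spacing: must be positive")
    if markers_per_block < 2:
        raise ValueError("markers_per_block: must be at least 2")
    rng = np.random.default_rng(seed)
    gap = max(3 * resolution, 2 * spacing)
    markers: list[Marker] = []
    truth: list[tuple[frozenset, bool]] = []
    cursor = int(rng.integers(0, spacing))

    for b in range(n_blocks):
        tgt = f"tgtB{b:03d}"
        idx = []
        tpos = int(rng.integers(0, spacing))
        for _ in range(markers_per_block):
            jitter = int(rng.integers(0, max(spacing // 4, 1)))
            markers.append(Marker("chrR", cursor, tgt, tpos, "+"))
            idx.append(len(markers) - 1)
            cursor += spacing + jitter
            tpos += spacing
        truth.append((frozenset(idx), False))
        cursor += gap

    for s in range(shuffle_singletons):
        markers.append(Marker("chrR", cursor, f"tgtS{s:03d}", int(rng.integers(0, spacing)), "+"))
        truth.append((frozenset({len(markers) - 1}), True))
        cursor += gap

    for q in range(mergeable_singleton_pairs):
        tgt = f"tgtQ{q:03d}"
        near = max(resolution // 2, 1)
        base = len(markers)
        # ref order m1 < m2 < m3 < m4; target order m3, m1, m4, m2 -> no chains
        markers.append(Marker("chrR", cursor, tgt, spacing, "+"))                   # m1
        markers.append(Marker("chrR", cursor + near, tgt, 3 * spacing, "+"))        # m2
        markers.append(Marker("chrR", cursor + 5 * resolution, tgt, 0, "+"))        # m3
        markers.append(Marker("chrR", cursor + 10 * resolution, tgt, 2 * spacing, "+"))  # m4
        truth.append((frozenset({base, base + 1}), True))  # exception-2 merge
        truth.append((frozenset({base + 2}), True))
        truth.append((frozenset({base + 3}), True))
        cursor += 10 * resolution + gap

    return markers, truth


def gen_random_markers(
    n_markers: int,
    n_tgt_scaffolds: int = 3,
    max_pos: int = 200_000,
    seed: int = 0,
) -> list[Marker]:
    """Unstructured random marker instance (for oracle-equivalence testing)."""
    rng = np.random.default_rng(seed)
    ref_pos = rng.choice(max_pos, size=n_markers, replace=False)
    markers = []
    for i in range(n_markers):
        markers.append(
            Marker(
                "chrR",
                int(ref_pos[i]),
                f"tgt{int(rng.integers(n_tgt_scaffolds)):02d}",
                int(rng.integers(max_pos)),
                "+" if rng.random() < 0.5 else "-",
            )
        )
    return markers


# ---------------------------------------------------------------------------
# expression study


def gen_expression(
    genome: AnnotatedGenome,
    spec: BiasSpec,
    x_elements: frozenset = DEFAULT_X_ELEMENTS,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Single-replicate count study with planted sex-biased genes.

    One library per condition (male, non-lactating female, lactating female).
    Planted female-biased genes (on X-linked scaffolds) have expected counts
    2**effect_log2 higher in both female libraries than in the male library;
    planted male-biased genes (autosomal) the reverse.  Counts are negative
    binomial with variance m + dispersion * m**2 (Poisson when dispersion is
    0).  Returns (counts, gene_lengths, truth labels).
    """
    if "true_element" not in genome.scaffolds.columns:
        raise ValueError("genome must carry element labels (true_element column)")
    rng = np.random.default_rng(spec.seed)
    genes = genome.genes.merge(
        genome.scaffolds[["scaffold_id", "true_element"]], on="scaffold_id"
    )
    if spec.n_genes > len(genes):
        raise ValueError(f"n_genes: requested {spec.n_genes} but genome has {len(genes)} genes")
    genes = genes.iloc[: spec.n_genes].reset_index(drop=True)
    on_x = genes["true_element"].isin(x_elements).to_numpy()

    n_female = int(round(spec.frac_female_biased_on_X * on_x.sum()))
    n_male = int(round(spec.frac_male_biased_on_autosome * (~on_x).sum()))
    labels = np.repeat("unbiased", len(genes)).astype(object)
    if spec.effect_log2 > 0:
        x_idx = np.flatnonzero(on_x)
        a_idx = np.flatnonzero(~on_x)
        labels[rng.choice(x_idx, size=n_female, replace=False)] = "female_biased"
        labels[rng.choice(a_idx, size=n_male, replace=False)] = "male_biased"

    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    base /= base.sum()
    fold = 2.0 ** spec.effect_log2
    mult = {
        "male": np.where(labels == "male_biased", fold, 1.0),
        "female_nonlactating": np.where(labels == "female_biased", fold, 1.0),
        "female_lactating": np.where(labels == "female_biased", fold, 1.0),
    }
    counts = {}
    for sample, m in mult.items():
        mean = spec.library_size * base * m
        if spec.dispersion == 0:
            counts[sample] = rng.poisson(mean)
        else:
            r = 1.0 / spec.dispersion
            counts[sample] = rng.negative_binomial(r, r / (r + mean))
    count_df = pd.DataFrame(counts, index=genes["gene_id"])
    lengths = pd.Series(
        (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"], name="length"
    )
    truth = pd.Series(labels, index=genes["gene_id"], name="bias_truth")
    return count_df, lengths, truth


# ---------------------------------------------------------------------------
# codon pairs at planted omega


_SENSE = np.array(SENSE_CODONS)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _evolve_codon(codon: str, n_events: int, omega: float, kappa: float, rng) -> str:
    """Apply proposed point mutations; nonsynonymous acceptance prob = omega."""
    for _ in range(n_events):
        pos = int(rng.integers(3))
        old = codon[pos]
        # transition with prob kappa/(kappa+2), each transversion 1/(kappa+2)
        u = rng.random() * (kappa + 2.0)
        new = _TRANSITION[old] if u < kappa else _TRANSVERSIONS[old][u - kappa < 1.0]
        cand = codon[:pos] + new + codon[pos + 1 :]
        if cand in STOP_CODONS:
            continue
        if AA_OF[cand] != AA_OF[codon] and rng.random() >= omega:
            continue
        codon = cand
    return codon


def gen_codon_pairs(spec: OmegaSpec, kappa: float = 2.0) -> tuple[list[CodonPair], float]:
    """Evolve codon-aligned pairs at a planted ω.

    Each pair starts from a random sense-codon ancestor; one copy accumulates
    Poisson(branch_length) proposed point mutations per codon with
    transition/transversion ratio ``kappa``, accepting synonymous changes
    always, nonsynonymous ones with probability ω, and rejecting stops.
    Returns (pairs, planted omega).
    """
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for p in range(spec.n_pairs):
        codons = _SENSE[rng.integers(len(_SENSE), size=spec.codons_per_pair)]
        events = rng.poisson(spec.branch_length, size=spec.codons_per_pair)
        derived = [
            _evolve_codon(c, int(k), spec.omega, kappa, rng) for c, k in zip(codons, events)
        ]
        pairs.append(CodonPair(f"pair{p:05d}", "".join(codons), "".join(derived)))
    return pairs, spec.omega


# ---------------------------------------------------------------------------
# candidate symbiont segments


def gen_candidate_segments(spec: SegmentSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Segment summary table with planted chromosomal/cytoplasmic truth.

    Half the segments are planted chromosomal insertions (polymorphisms
    binomial at ``density_chromosomal`` per 100 bp, indel events present with
    probability ``indel_prob_chromosomal``), half cytoplasmic copies
    (``density_cytoplasmic``, no indels).  All carry a homology hit.
    """
    rng = np.random.default_rng(spec.seed)
    n_chrom = spec.n_segments // 2 + spec.n_segments % 2
    rows, labels = [], []
    for i in range(spec.n_segments):
        is_chrom = i < n_chrom
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        density = spec.density_chromosomal if is_chrom else spec.density_cytoplasmic
        n_poly = int(rng.binomial(length, min(density / 100.0, 1.0)))
        if is_chrom and rng.random() < spec.indel_prob_chromosomal:
            n_indels = 1 + int(rng.poisson(1.5))
        else:
            n_indels = 0
        rows.append((f"seg{i:05d}", length, n_poly, n_indels, True, f"scf{i // 10:04d}"))
        labels.append("chromosomal_insertion" if is_chrom else "cytoplasmic")
    table = pd.DataFrame(
        rows, columns=["id", "length_bp", "n_polymorphisms", "n_indels", "homology_hit", "scaffold"]
    )
    truth = pd.Series(labels, index=table["id"], name="class_truth")
    return table, truth


# ---------------------------------------------------------------------------
# orthogroup matrices with planted composition categories


def gen_orthogroup_matrix(
    category_counts: dict[tuple[str, str], int],
    taxon_map: TaxonMap = DEFAULT_TAXONOMY,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orthogroup count matrix with planted (level, universality) categories.

    For each requested category, rows are built whose presence/absence
    pattern has exactly that smallest covering clade and coverage status.
    Categories that cannot exist under the taxonomy — partial at species
    level, or partial for a clade whose every proper subset falls inside a
    smaller named clade — raise ``ValueError``.  Returns (matrix, truth
    frame with level and universality per row).
    """
    rng = np.random.default_rng(seed)
    levels = taxon_map.named_levels()
    rows, truth_rows, og = [], [], 0
    for (level, universality), n in sorted(category_counts.items()):
        if level not in levels:
            raise ValueError(f"unknown level {level!r}")
        if universality not in ("universal", "partial"):
            raise ValueError(f"unknown universality {universality!r}")
        members = sorted(levels[level])
        for _ in range(n):
            if universality == "universal":
                present = set(members)
            else:
                present = None
                for _attempt in range(1000):
                    cand = {sp for sp in members if rng.random() < 0.7}
                    if not cand or cand == set(members):
                        continue
                    if taxon_map.smallest_covering_clade(cand)[0] == level:
                        present = cand
                        break
                if present is None:
                    raise ValueError(
                        f"category ({level}, partial) is impossible under this taxonomy"
                    )
            row = {
                sp: (1 + int(rng.poisson(0.5)) if sp in present else 0)
                for sp in taxon_map.species
            }
            rows.append(row)
            truth_rows.append((level, universality))
            og += 1
    index = [f"OG{k:05d}" for k in range(og)]
    matrix = pd.DataFrame(rows, index=index, columns=list(taxon_map.species)).fillna(0).astype(int)
    matrix.index.name = "orthogroup_id"
    truth = pd.DataFrame(truth_rows, index=index, columns=["level", "universality"])
    return matrix, truth
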