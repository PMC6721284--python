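"""End-to-end orchestration: synthetic inputs -> all analysis stages -> manifest.

A run executes stages in dependency order inside a single run directory with
one subfolder per stage.  The manifest records the tool version, a hash of
the configuration, the seed, and sha256 checksums of every stage input and
output; deterministic stages reproduce identical checksums when re-run with
the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import expression, hgt, io, molevol, muller, orthogroups, synteny, synthetic
from .taxonomy import DEFAULT_TAXONOMY

STAGE_ORDER = ("simulate", "muller", "synteny", "bias", "dnds", "rate_compare", "orthogroups", "hgt")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    x_elements: frozenset = muller.DEFAULT_X_ELEMENTS
    resolution: int = synteny.DEFAULT_RESOLUTION
    bin_width: int = synteny.DEFAULT_BIN_WIDTH
    alpha: float = 0.05
    min_informative: int = 1
    variance_threshold: float = orthogroups.DEFAULT_VARIANCE_THRESHOLD
    density_threshold: float = hgt.DEFAULT_DENSITY_THRESHOLD
    min_length: int = hgt.DEFAULT_MIN_LENGTH
    genome_spec: dict = field(default_factory=dict)
    bias_spec: dict = field(default_factory=dict)
    omega_spec: dict = field(default_factory=dict)
    segment_spec: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}")

    def describe(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["outdir"] = str(self.outdir)
        d["stages"] = list(self.stages)
        d["x_elements"] = sorted(self.x_elements)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest (also written to disk)."""
    run_dir = config.outdir
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config.describe(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stages = [s for s in STAGE_ORDER if s in config.stages]
    for stage in stages:
        stage_dir = run_dir / stage
        stage_dir.mkdir(exist_ok=True)
        runner = _STAGES[stage]
        try:
            inputs, outputs = runner(config, run_dir, stage_dir)
        except FileNotFoundError as exc:
            raise PipelineError(stage, f"missing dependency output: {exc}") from exc
        manifest["stages"][stage] = {
            "inputs": {str(p.relative_to(run_dir)): _sha256(p) for p in sorted(inputs)},
            "outputs": {str(p.relative_to(run_dir)): _sha256(p) for p in sorted(outputs)},
        }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# --- stage runners: each returns (input paths, output paths) ----------------


def _stage_simulate(config: RunConfig, run_dir: Path, d: Path):
    seed = config.seed
    gspec = synthetic.GenomeSpec(seed=seed, **config.genome_spec)
    genome, ortho, truth = synthetic.gen_genome(gspec)
    io.write_gff3(genome, d / "genes.gff3")
    io.write_tsv(genome.scaffolds[["scaffold_id", "length"]], d / "scaffold_lengths.tsv")
    io.write_tsv(ortho, d / "orthologs.tsv", {"mislabel_rate": gspec.mislabel_rate})
    io.write_tsv(truth, d / "element_truth.tsv")

    markers, hsb_truth = synthetic.gen_marker_set(
        n_blocks=8, markers_per_block=5, spacing=50_000,
        resolution=config.resolution, shuffle_singletons=4,
        mergeable_singleton_pairs=2, seed=seed,
    )
    io.write_tsv(
        pd.DataFrame([m.__dict__ for m in markers]), d / "markers.tsv",
        {"resolution": config.resolution},
    )
    ref_len = max(m.ref_pos for m in markers) + config.bin_width
    io.write_tsv(
        pd.DataFrame({"scaffold_id": ["chrR"], "length": [ref_len]}),
        d / "marker_ref_lengths.tsv",
    )

    bspec = synthetic.BiasSpec(seed=seed, **config.bias_spec)
    counts, lengths, bias_truth = synthetic.gen_expression(genome, bspec, config.x_elements)
    io.write_tsv(counts.reset_index(), d / "counts.tsv")
    io.write_tsv(lengths.reset_index(), d / "gene_lengths.tsv")
    io.write_tsv(
        pd.DataFrame({"sample": list(counts.columns), "condition": list(counts.columns)}),
        d / "samples.tsv",
    )
    io.write_tsv(bias_truth.reset_index(), d / "bias_truth.tsv")

    ospec = synthetic.OmegaSpec(
        **({"seed": seed, "n_pairs": 60, "codons_per_pair": 200} | config.omega_spec)
    )
    pairs, _ = synthetic.gen_codon_pairs(ospec)
    records = {}
    for p in pairs:
        records[f"{p.id}|a"] = p.seq_a
        records[f"{p.id}|b"] = p.seq_b
    io.write_fasta(records, d / "codon_pairs.fasta")

    matrix, og_truth = synthetic.gen_orthogroup_matrix(
        {
            ("Diptera", "universal"): 30, ("Diptera", "partial"): 25,
            ("Brachycera", "universal"): 12, ("Glossina", "universal"): 10,
            ("Morsitans", "universal"): 8, ("Palpalis", "universal"): 20,
            ("G_m_morsitans", "universal"): 5,
        },
        seed=seed,
    )
    io.write_tsv(matrix.reset_index(), d / "orthogroups.tsv")
    io.write_tsv(og_truth.reset_index(names="orthogroup_id"), d / "orthogroup_truth.tsv")

    sspec = synthetic.SegmentSpec(seed=seed, **config.segment_spec)
    segments, seg_truth = synthetic.gen_candidate_segments(sspec)
    io.write_tsv(segments, d / "segments.tsv")
    io.write_tsv(seg_truth.reset_index(), d / "segment_truth.tsv")
    return [], list(d.iterdir())


def _stage_muller(config: RunConfig, run_dir: Path, d: Path):
    sim = run_dir / "simulate"
    gff, lengths_tsv, ortho_tsv = sim / "genes.gff3", sim / "scaffold_lengths.tsv", sim / "orthologs.tsv"
    genome = io.read_gff3_genes(gff, io.read_tsv(lengths_tsv))
    ortho = io.read_tsv(ortho_tsv)
    genes = muller.assign_genes(ortho, genome.genes)
    scaffolds = muller.assign_scaffolds(genes, genome.scaffolds, config.min_informative)
    summaries = muller.summarize_elements(scaffolds, genome.genes, genome.scaffolds, ortho)
    flags = muller.x_linkage_labels(scaffolds, config.x_elements)
    prov = {"x_elements": ",".join(sorted(config.x_elements)),
            "min_informative": config.min_informative, "tie_rule": "strict majority (>50%)"}
    io.write_tsv(muller.scaffold_assignments_frame(scaffolds), d / "scaffold_assignments.tsv", prov)
    io.write_tsv(muller.element_summaries_frame(summaries), d / "element_summaries.tsv", prov)
    io.write_tsv(
        pd.DataFrame({"scaffold_id": list(flags), "x_flag": list(flags.values())}),
        d / "x_flags.tsv", prov,
    )
    return [gff, lengths_tsv, ortho_tsv], list(d.iterdir())


def _stage_synteny(config: RunConfig, run_dir: Path, d: Path):
    sim = run_dir / "simulate"
    marker_tsv, len_tsv = sim / "markers.tsv", sim / "marker_ref_lengths.tsv"
    markers = synteny.markers_from_frame(io.read_tsv(marker_tsv))
    hsbs = synteny.detect_hsbs(markers, config.resolution)
    bins = synteny.bin_syntenic_fraction(hsbs, io.read_tsv(len_tsv), config.bin_width)
    prov = {"resolution": config.resolution, "bin_width": config.bin_width,
            "orientation_strict": False, "exception2_distance": "reference genome"}
    io.write_tsv(synteny.hsbs_frame(hsbs), d / "hsbs.tsv", prov)
    bed = synteny.hsbs_frame(hsbs)[["ref_scaffold", "ref_start", "ref_end", "n_markers"]]
    bed.insert(3, "name", [f"hsb{i:04d}" for i in range(len(bed))])
    bed.to_csv(d / "hsbs.bed", sep="\t", header=False, index=False)
    io.write_tsv(synteny.bins_frame(bins), d / "syntenic_bins.tsv", prov)
    return [marker_tsv, len_tsv], list(d.iterdir())


def _stage_bias(config: RunConfig, run_dir: Path, d: Path):
    sim = run_dir / "simulate"
    counts = io.read_tsv(sim / "counts.tsv", index_col=0)
    lengths = io.read_tsv(sim / "gene_lengths.tsv", index_col=0)["length"]
    samples = io.read_tsv(sim / "samples.tsv")
    conditions = dict(zip(samples["sample"], samples["condition"]))
    tpm = expression.compute_tpm(counts, lengths)
    calls = expression.call_bias(counts, conditions, ("female_nonlactating", "male"), config.alpha)

    assignments = io.read_tsv(run_dir / "muller" / "scaffold_assignments.tsv")
    x_flags_df = io.read_tsv(run_dir / "muller" / "x_flags.tsv")
    genome = io.read_gff3_genes(sim / "genes.gff3", io.read_tsv(sim / "scaffold_lengths.tsv"))
    gene_scaffold = dict(zip(genome.genes["gene_id"], genome.genes["scaffold_id"]))
    scaffold_element = dict(zip(assignments["scaffold_id"], assignments["element"]))
    x_flags = dict(zip(x_flags_df["scaffold_id"], x_flags_df["x_flag"]))
    summaries, comparison = expression.summarize_by_element(
        calls, gene_scaffold, scaffold_element, x_flags
    )
    prov = {"alpha": config.alpha, "test": "two-library pooled proportion z-test",
            "correction": "Bonferroni over tested genes", "contrast": "female_nonlactating:male"}
    io.write_tsv(tpm.reset_index(), d / "tpm.tsv")
    io.write_tsv(expression.bias_calls_frame(calls), d / "bias_calls.tsv", prov)
    io.write_tsv(pd.DataFrame([s.__dict__ for s in summaries]), d / "element_bias.tsv", prov)
    (d / "x_vs_autosome.json").write_text(json.dumps(comparison, indent=2) + "\n")
    return [sim / "counts.tsv", sim / "gene_lengths.tsv", sim / "samples.tsv"], list(d.iterdir())


def _stage_dnds(config: RunConfig, run_dir: Path, d: Path):
    fasta = run_dir / "simulate" / "codon_pairs.fasta"
    results = []
    for pid, a, b in io.read_alignment_pairs(fasta):
        masked = molevol.mask_alignment(molevol.CodonPair(pid, a, b))
        results.append(molevol.ng86_dnds(masked))
    io.write_tsv(
        molevol.dnds_frame(results), d / "dnds.tsv",
        {"estimator": "NG86 + Jukes-Cantor", "masking": "gap/stop columns; window 10, density 0.5"},
    )
    return [fasta], list(d.iterdir())


def _stage_rate_compare(config: RunConfig, run_dir: Path, d: Path):
    dnds = io.read_tsv(run_dir / "dnds" / "dnds.tsv")
    flags = io.read_tsv(run_dir / "muller" / "x_flags.tsv")
    # demo wiring: pair i maps to scaffold i for X/autosome stratification
    usable = flags[flags["x_flag"] != "unknown"].reset_index(drop=True)
    n = min(len(dnds), len(usable))
    table = pd.DataFrame(
        {"omega": dnds["omega"][:n].to_numpy(), "x_flag": usable["x_flag"][:n].to_numpy()}
    )
    reports = molevol.compare_rate_groups(table)
    (d / "rate_comparisons.json").write_text(json.dumps(reports, indent=2) + "\n")
    return [run_dir / "dnds" / "dnds.tsv", run_dir / "muller" / "x_flags.tsv"], list(d.iterdir())


def _stage_orthogroups(config: RunConfig, run_dir: Path, d: Path):
    og_tsv = run_dir / "simulate" / "orthogroups.tsv"
    matrix = io.read_tsv(og_tsv, index_col=0)
    calls = orthogroups.classify_matrix(matrix)
    tab = orthogroups.tabulate_categories(matrix)
    candidates = orthogroups.variance_filter(matrix, threshold=config.variance_threshold)
    prov = {"variance_threshold": config.variance_threshold, "variance": "sample (ddof=1)"}
    io.write_tsv(orthogroups.calls_frame(calls), d / "composition_calls.tsv", prov)
    io.write_tsv(tab.reset_index(), d / "category_tabulation.tsv", prov)
    io.write_tsv(candidates.reset_index(), d / "expansion_candidates.tsv", prov)
    if len(candidates) >= 3:
        scores, loadings = orthogroups.family_count_pca(candidates)
        io.write_tsv(scores.reset_index(), d / "pca_scores.tsv")
        io.write_tsv(loadings.reset_index(names="species"), d / "pca_loadings.tsv")
    return [og_tsv], list(d.iterdir())


def _stage_hgt(config: RunConfig, run_dir: Path, d: Path):
    seg_tsv = run_dir / "simulate" / "segments.tsv"
    segments = hgt.segments_from_frame(io.read_tsv(seg_tsv))
    calls = hgt.classify_segments(
        segments, min_length=config.min_length, density_threshold=config.density_threshold
    )
    summary = hgt.summarize_calls(calls, segments)
    prov = {"min_length": config.min_length, "density_threshold": config.density_threshold,
            "criteria": "homology AND density AND indels (strict conjunction)"}
    io.write_tsv(hgt.calls_frame(calls), d / "segment_calls.tsv", prov)
    (d / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return [seg_tsv], list(d.iterdir())


_STAGES = {
    "simulate": _stage_simulate,
    "muller": _stage_muller,
    "synteny": _stage_synteny,
    "bias": _stage_bias,
    "dnds": _stage_dnds,
    "rate_compare": _stage_rate_compare,
    "orthogroups": _stage_orthogroups,
    "hgt": _stage_hgt,
}
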