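"""File formats: GFF3 gene annotations, FASTA, and the pipeline's TSV tables.

Coordinates are 1-based inclusive in GFF3 on disk and 0-based half-open in
memory.  All TSV outputs carry ``#`` header comments with parameter
provenance so a table is interpretable on its own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class AnnotatedGenome:
    """Scaffolds with lengths and located genes.

    ``scaffolds``: columns scaffold_id, length (bp) and, for synthetic
    genomes, true_element.  ``genes``: columns gene_id, scaffold_id, start,
    end (0-based half-open), strand.
    """

    scaffolds: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self):
        if (self.scaffolds["length"] <= 0).any():
            raise ValueError("scaffold lengths must be positive")
        merged = self.genes.merge(self.scaffolds, on="scaffold_id", how="left")
        if merged["length"].isna().any():
            bad = merged.loc[merged["length"].isna(), "gene_id"].tolist()[:5]
            raise ValueError(f"gene(s) {bad} on unknown scaffolds")
        out = (merged["start"] < 0) | (merged["end"] > merged["length"]) | (
            merged["start"] >= merged["end"]
        )
        if out.any():
            bad = merged.loc[out, "gene_id"].tolist()[:5]
            raise ValueError(f"gene(s) {bad} outside their scaffold bounds")


def write_gff3(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genome.scaffolds.itertuples():
            fh.write(f"##sequence-region {row.scaffold_id} 1 {row.length}\n")
        for g in genome.genes.itertuples():
            fh.write(
                f"{g.scaffold_id}\ttsetse_compgen\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3_genes(gff_path, scaffold_lengths: pd.DataFrame | None = None) -> AnnotatedGenome:
    """Read genes (and scaffold lengths) from GFF3.

    Lengths come from ``##sequence-region`` pragmas unless a two-column
    frame (scaffold_id, length) overrides them.
    """
    if scaffold_lengths is None:
        rows = []
        with open(gff_path) as fh:
            for line in fh:
                m = re.match(r"##sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", line)
                if m:
                    rows.append((m.group(1), int(m.group(3))))
        if not rows:
            raise ValueError(f"{gff_path}: no ##sequence-region pragmas and no lengths given")
        scaffold_lengths = pd.DataFrame(rows, columns=["scaffold_id", "length"])

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = pd.DataFrame(
        [
            (f.id, f.seqid, f.start - 1, f.end, f.strand)
            for f in db.features_of_type("gene", order_by=("seqid", "start"))
        ],
        columns=["gene_id", "scaffold_id", "start", "end", "strand"],
    )
    return AnnotatedGenome(scaffolds=scaffold_lengths.reset_index(drop=True), genes=genes)


def read_scaffold_lengths(path) -> pd.DataFrame:
    """Scaffold lengths from FASTA or a two-column TSV (scaffold_id, length)."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        rows = [(rec.id, len(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
        return pd.DataFrame(rows, columns=["scaffold_id", "length"])
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = ["scaffold_id", "length"] + list(df.columns[2:])
    return df[["scaffold_id", "length"]]


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_alignment_pairs(path) -> list[tuple[str, str, str]]:
    """FASTA of aligned pairs: records grouped by shared ``<pair_id>|...`` prefix.

    Returns (pair_id, seq_first, seq_second) triples in file order; a pair id
    with other than two records is an error.
    """
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pair_id = rec.id.split("|")[0]
        if pair_id not in groups:
            groups[pair_id] = []
            order.append(pair_id)
        groups[pair_id].append(str(rec.seq))
    for pid, seqs in groups.items():
        if len(seqs) != 2:
            raise ValueError(f"pair {pid!r} has {len(seqs)} records, expected 2")
    return [(pid, groups[pid][0], groups[pid][1]) for pid in order]


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
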