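"""Orthology-group phylogenetic profiling and the gene-family expansion screen.

Each orthology group (OG) — a cross-species gene family from gene-tree
clustering — is classified by the smallest named clade containing every
species in which it has members ("specific to" that level), and as
*universal* when every species of that clade is represented, *partial*
otherwise.  The expansion/contraction screen keeps OGs whose per-species
copy-number variance across the six Glossina exceeds a threshold (sample
variance > 2 by default), the pre-filter applied ahead of likelihood-based
family-size testing, and a PCA over the candidate count rows exposes
sub-genus-correlated expansion patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taxonomy import DEFAULT_TAXONOMY, TaxonMap

UNIVERSAL = "universal"
PARTIAL = "partial"

DEFAULT_VARIANCE_THRESHOLD = 2.0


@dataclass(frozen=True)
class CompositionCall:
    orthogroup_id: str
    level: str  # clade label or species name
    universality: str  # UNIVERSAL or PARTIAL


def classify_composition(
    row: pd.Series, taxon_map: TaxonMap = DEFAULT_TAXONOMY
) -> CompositionCall:
    """Classify one OG row (species -> gene count) by phylogenetic composition.

    The level is the smallest named clade covering all species with count
    > 0; the call is universal iff every species of that clade has count > 0.
    A single-species row is universal at species level by convention.
    """
    present = {sp for sp in taxon_map.species if row.get(sp, 0) > 0}
    if not present:
        raise ValueError(f"orthogroup {row.name!r} has no members (all-zero row)")
    level, members = taxon_map.smallest_covering_clade(present)
    universality = UNIVERSAL if present == set(members) else PARTIAL
    return CompositionCall(str(row.name), level, universality)


def classify_matrix(
    matrix: pd.DataFrame, taxon_map: TaxonMap = DEFAULT_TAXONOMY
) -> list[CompositionCall]:
    return [classify_composition(matrix.loc[og], taxon_map) for og in matrix.index]


def tabulate_categories(
    matrix: pd.DataFrame, taxon_map: TaxonMap = DEFAULT_TAXONOMY
) -> pd.DataFrame:
    """Counts of OGs and summed genes per (level, universality) category.

    The categories partition the non-zero rows exhaustively and disjointly.
    Returns a frame indexed by (level, universality) with columns
    ``n_orthogroups`` and ``n_genes``.
    """
    calls = classify_matrix(matrix, taxon_map)
    gene_totals = matrix.sum(axis=1)
    rows: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        key = (call.level, call.universality)
        cell = rows.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += int(gene_totals[call.orthogroup_id])
    index = pd.MultiIndex.from_tuples(sorted(rows), names=["level", "universality"])
    return pd.DataFrame(
        {
            "n_orthogroups": [rows[k][0] for k in index],
            "n_genes": [rows[k][1] for k in index],
        },
        index=index,
    )


def variance_filter(
    matrix: pd.DataFrame,
    taxon_map: TaxonMap = DEFAULT_TAXONOMY,
    threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> pd.DataFrame:
    """Expansion/contraction candidates: Glossina copy-number variance > threshold.

    Sample variance (divisor n-1) of the six Glossina columns, strictly
    greater than ``threshold`` to qualify.  Returns candidate rows with a
    ``variance`` column, preserving matrix order.
    """
    cols = list(taxon_map.glossina_species)
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix is missing Glossina species column(s) {missing}")
    counts = matrix[cols].to_numpy(dtype=float)
    variance = counts.var(axis=1, ddof=1)
    keep = variance > threshold
    out = matrix.loc[keep, cols].copy()
    out["variance"] = variance[keep]
    return out


def family_count_pca(
    candidates: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of candidate OG count rows (orthogroups x species).

    Rows are centred by species means and projected by SVD onto the leading
    components.  Sign convention: each component's largest-magnitude loading
    is made positive, so output is deterministic.  Returns (scores frame
    indexed like ``candidates``, loadings frame indexed by species).
    """
    species_cols = [c for c in candidates.columns if c != "variance"]
    X = candidates[species_cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 candidate rows for a PCA")
    if n_components > min(X.shape):
        raise ValueError(f"cannot extract {n_components} components from shape {X.shape}")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("all candidate rows identical: zero variance after centring")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = Vt[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    scores = Xc @ comps.T
    pc_names = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=candidates.index, columns=pc_names),
        pd.DataFrame(comps.T, index=species_cols, columns=pc_names),
    )


def calls_frame(calls: list[CompositionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "orthogroup_id": [c.orthogroup_id for c in calls],
            "level": [c.level for c in calls],
            "universality": [c.universality for c in calls],
        }
    )


def read_tree_species_counts(path, taxon_map: TaxonMap = DEFAULT_TAXONOMY) -> pd.DataFrame:
    """Read a per-tree species-count TSV (tree_id, species, n_genes) into a matrix.

    Thin adapter for the long-format output of gene-tree parsing scripts;
    species absent from a tree get count 0, and columns follow panel order.
    """
    long = pd.read_csv(path, sep="\t", comment="#")
    matrix = (
        long.pivot_table(index="tree_id", columns="species", values="n_genes", fill_value=0)
        .astype(int)
    )
    for sp in taxon_map.species:
        if sp not in matrix.columns:
            matrix[sp] = 0
    matrix.index.name = "orthogroup_id"
    return matrix[list(taxon_map.species)]
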