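"""Muller-element assignment of genes and scaffolds by 1:1 orthology.

Chromosome-arm (Muller element A-F) gene content is strongly conserved across
flies, so a fragmented assembly can be anchored to arms through 1:1 orthologs
with D. melanogaster: a gene inherits the element of its ortholog, and a
scaffold is assigned to an element when a strict majority (> 50%) of its
ortholog-bearing genes agree on a single element.  Scaffolds with a tie, a
plurality at or below 50%, or no informative gene stay unassigned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

UNASSIGNED = "unassigned"

DEFAULT_ELEMENTS = ("A", "B", "C", "D", "E", "F")
#: Elements forming the Glossina X chromosome (all species except G. brevipalpis).
DEFAULT_X_ELEMENTS = frozenset({"A", "D", "F"})


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    scaffold_id: str
    element: str  # element label or UNASSIGNED


@dataclass(frozen=True)
class ScaffoldAssignment:
    scaffold_id: str
    element: str
    votes: dict[str, int] = field(default_factory=dict)
    n_informative: int = 0
    majority_fraction: float = 0.0


@dataclass(frozen=True)
class ElementSummary:
    element: str
    n_genes: int
    cumulative_length: int
    n_one_to_one: int


def assign_genes(ortholog_map: pd.DataFrame, genes: pd.DataFrame) -> list[GeneAssignment]:
    """Assign each annotated gene the element of its 1:1 D. melanogaster ortholog.

    Parameters
    ----------
    ortholog_map
        Columns ``gene_id``, ``ref_gene_id``, ``ref_element``; one row per
        1:1 ortholog link.  A gene appearing twice violates the 1:1 contract
        and raises ``ValueError``.
    genes
        Columns ``gene_id``, ``scaffold_id`` for all annotated genes.
        Genes without an ortholog row come back with element ``unassigned``.
    """
    dup = ortholog_map["gene_id"][ortholog_map["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"gene(s) {sorted(set(dup))[:5]} appear in multiple ortholog rows (not 1:1)")
    element_of = dict(zip(ortholog_map["gene_id"], ortholog_map["ref_element"]))
    return [
        GeneAssignment(g, s, element_of.get(g, UNASSIGNED))
        for g, s in zip(genes["gene_id"], genes["scaffold_id"])
    ]


def assign_scaffolds(
    gene_assignments: list[GeneAssignment],
    scaffold_lengths: pd.DataFrame,
    min_informative: int = 1,
) -> list[ScaffoldAssignment]:
    """Majority-vote scaffolds onto elements from their genes' assignments.

    A scaffold is assigned iff the top element holds a strict majority
    (> 50%) of its informative genes and at least ``min_informative`` genes
    carry an element.  Exact 50% ties are unassigned.
    """
    known = set(scaffold_lengths["scaffold_id"])
    votes_by_scaffold: dict[str, Counter] = {s: Counter() for s in scaffold_lengths["scaffold_id"]}
    for ga in gene_assignments:
        if ga.scaffold_id not in known:
            raise ValueError(f"gene {ga.gene_id!r} references unknown scaffold {ga.scaffold_id!r}")
        if ga.element != UNASSIGNED:
            votes_by_scaffold[ga.scaffold_id][ga.element] += 1

    out = []
    for scaffold_id in scaffold_lengths["scaffold_id"]:
        votes = votes_by_scaffold[scaffold_id]
        n_inf = sum(votes.values())
        if n_inf == 0:
            out.append(ScaffoldAssignment(scaffold_id, UNASSIGNED, {}, 0, 0.0))
            continue
        # deterministic top pick: max votes, label as tie-break (ties never assign anyway)
        top_element, top_votes = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        frac = top_votes / n_inf
        element = top_element if (frac > 0.5 and n_inf >= min_informative) else UNASSIGNED
        out.append(ScaffoldAssignment(scaffold_id, element, dict(votes), n_inf, frac))
    return out


def summarize_elements(
    scaffold_assignments: list[ScaffoldAssignment],
    genes: pd.DataFrame,
    scaffold_lengths: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> list[ElementSummary]:
    """Per-element size summary over assigned scaffolds.

    For each element: the number of ALL annotated genes on scaffolds assigned
    to it, the cumulative assembled length of those scaffolds, and the number
    of 1:1 orthologs among those genes.  Unassigned scaffolds are summarised
    under the ``unassigned`` pseudo-element.
    """
    element_of_scaffold = {sa.scaffold_id: sa.element for sa in scaffold_assignments}
    length_of = dict(zip(scaffold_lengths["scaffold_id"], scaffold_lengths["length"]))
    has_ortholog = set(ortholog_map["gene_id"])

    summaries = []
    for element in tuple(elements) + (UNASSIGNED,):
        scaffolds = [s for s, e in element_of_scaffold.items() if e == element]
        in_element = genes["scaffold_id"].isin(scaffolds)
        n_genes = int(in_element.sum())
        n_one = int((in_element & genes["gene_id"].isin(has_ortholog)).sum())
        cum_len = int(sum(length_of[s] for s in scaffolds))
        summaries.append(ElementSummary(element, n_genes, cum_len, n_one))
    return summaries


def x_linkage_labels(
    scaffold_assignments: list[ScaffoldAssignment],
    x_elements: frozenset[str] = DEFAULT_X_ELEMENTS,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> dict[str, str]:
    """Flag each scaffold as ``X``, ``autosome`` or ``unknown``."""
    bad = set(x_elements) - set(elements)
    if bad:
        raise ValueError(f"unknown element label(s) in x_elements: {sorted(bad)}")
    flags = {}
    for sa in scaffold_assignments:
        if sa.element == UNASSIGNED:
            flags[sa.scaffold_id] = "unknown"
        elif sa.element in x_elements:
            flags[sa.scaffold_id] = "X"
        else:
            flags[sa.scaffold_id] = "autosome"
    return flags


def scaffold_assignments_frame(assignments: list[ScaffoldAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold_id": [a.scaffold_id for a in assignments],
            "element": [a.element for a in assignments],
            "n_informative": [a.n_informative for a in assignments],
            "majority_fraction": [a.majority_fraction for a in assignments],
        }
    )


def element_summaries_frame(summaries: list[ElementSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
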