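"""Sex- and stage-biased expression calls from single-replicate RNA-seq counts.

With one library per condition (male, non-lactating female, lactating female)
no within-group variance exists, so differential expression is assessed with
the classical two-library proportion test: a gene's count is treated as a
binomial draw from its library total, the two proportions are compared with a
pooled-variance z statistic, and the family of tests is controlled by
Bonferroni correction at alpha = 0.05.  TPM (transcripts per million) serves
as the expression proxy for reporting; the test itself runs on raw counts.

Bias direction follows the convention "male-biased = upregulated in males
relative to females".  Per-element summaries and the X-versus-autosome
contrast quantify the excess of female-biased expression on X-linked
Muller elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("male", "female_nonlactating", "female_lactating")

BIASED_UP = "biased_up"
BIASED_DOWN = "biased_down"
UNBIASED = "unbiased"


@dataclass(frozen=True)
class BiasCall:
    gene_id: str
    contrast: tuple[str, str]
    log2_ratio: float
    p_value: float
    p_adjusted: float
    bias_class: str
    tested: bool


@dataclass(frozen=True)
class ElementBiasSummary:
    element: str
    n_genes: int
    median_log2_fm: float
    frac_male_biased: float
    frac_female_biased: float


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalised counts scaled to 1e6 per sample.

    ``tpm[g, s] = 1e6 * (count[g, s] / length[g]) / sum_g'(count[g', s] / length[g'])``
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing entries for some genes in the count matrix")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        zero = list(colsum.index[colsum == 0])
        raise ValueError(f"sample(s) {zero} have all-zero counts; TPM undefined")
    return rate.div(colsum, axis=1) * 1e6


def proportion_test(x1, n1, x2, n2):
    """Two-sided two-library proportion z-test with pooled variance.

    Tests whether a gene's share of library 1 (``x1/n1``) differs from its
    share of library 2.  Vectorised over array inputs.  Degenerate cases
    (pooled proportion 0 or 1) carry no evidence and return p = 1.
    """
    x1, n1, x2, n2 = (np.asarray(a, dtype=float) for a in (x1, n1, x2, n2))
    if np.any((x1 < 0) | (x2 < 0)):
        raise ValueError("counts must be non-negative")
    if np.any((n1 <= 0) | (n2 <= 0)):
        raise ValueError("library sizes must be positive")
    if np.any(x1 > n1) or np.any(x2 > n2):
        raise ValueError("count exceeds its library size")
    p_pool = (x1 + x2) / (n1 + n2)
    var = p_pool * (1.0 - p_pool) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (x1 / n1 - x2 / n2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return p if p.shape else float(p)


def call_bias(
    counts: pd.DataFrame,
    sample_conditions: dict[str, str],
    contrast: tuple[str, str],
    alpha: float = 0.05,
    min_total_count: int = 5,
) -> list[BiasCall]:
    """Per-gene bias calls for one condition contrast.

    Genes with fewer than ``min_total_count`` summed counts across the two
    libraries are excluded from testing (and from the Bonferroni
    denominator); they are reported untested and unbiased.  ``biased_up``
    means higher relative abundance in the first condition of the contrast.
    """
    cond_a, cond_b = contrast
    samples = {c: [s for s, cc in sample_conditions.items() if cc == c] for c in contrast}
    for c in contrast:
        if not samples[c]:
            raise ValueError(f"no sample with condition {c!r}")
        if len(samples[c]) > 1:
            raise ValueError(f"multiple samples with condition {c!r}; single-replicate design expected")
    sa, sb = samples[cond_a][0], samples[cond_b][0]
    xa = counts[sa].to_numpy(dtype=float)
    xb = counts[sb].to_numpy(dtype=float)
    na, nb = xa.sum(), xb.sum()
    tested = (xa + xb) >= min_total_count
    n_tests = int(tested.sum())

    pvals = np.ones(len(counts))
    if n_tests:
        pvals[tested] = proportion_test(xa[tested], na, xb[tested], nb)
    padj = np.minimum(pvals * max(n_tests, 1), 1.0)
    # 0.5-count pseudocount keeps ratios finite for zero counts
    log2_ratio = np.log2(((xa + 0.5) / na) / ((xb + 0.5) / nb))

    calls = []
    for i, gene_id in enumerate(counts.index):
        if tested[i] and padj[i] < alpha:
            cls = BIASED_UP if log2_ratio[i] > 0 else BIASED_DOWN
        else:
            cls = UNBIASED
        calls.append(
            BiasCall(str(gene_id), (cond_a, cond_b), float(log2_ratio[i]),
                     float(pvals[i]), float(padj[i]), cls, bool(tested[i]))
        )
    return calls


def summarize_by_element(
    bias_calls: list[BiasCall],
    gene_scaffold: dict[str, str],
    scaffold_element: dict[str, str],
    x_flags: dict[str, str],
) -> tuple[list[ElementBiasSummary], dict]:
    """Element-level bias summaries plus the X-vs-autosome rank-sum contrast.

    ``bias_calls`` must come from a (female, male) contrast so that
    ``log2_ratio`` is the log2 female:male ratio (``biased_up`` = female-
    biased, ``biased_down`` = male-biased).  The comparison statistic is a
    two-sided Mann-Whitney U on per-gene log2 F:M between X-linked and
    autosomal genes.
    """
    rows = []
    for call in bias_calls:
        scaffold = gene_scaffold.get(call.gene_id)
        if scaffold is None:
            continue
        rows.append(
            (
                scaffold_element.get(scaffold, "unassigned"),
                x_flags.get(scaffold, "unknown"),
                call.log2_ratio,
                call.bias_class,
            )
        )
    df = pd.DataFrame(rows, columns=["element", "x_flag", "log2_fm", "bias_class"])

    summaries = []
    for element in sorted(set(scaffold_element.values()) | {"unassigned"}):
        sub = df[df["element"] == element]
        n = len(sub)
        summaries.append(
            ElementBiasSummary(
                element=element,
                n_genes=n,
                median_log2_fm=float(sub["log2_fm"].median()) if n else float("nan"),
                frac_male_biased=float((sub["bias_class"] == BIASED_DOWN).mean()) if n else 0.0,
                frac_female_biased=float((sub["bias_class"] == BIASED_UP).mean()) if n else 0.0,
            )
        )

    x = df.loc[df["x_flag"] == "X", "log2_fm"]
    auto = df.loc[df["x_flag"] == "autosome", "log2_fm"]
    if len(x) == 0 or len(auto) == 0:
        comparison = {
            "comparison": "X_vs_autosome",
            "skipped": True,
            "warning": "no X-flagged genes" if len(x) == 0 else "no autosomal genes",
        }
    else:
        stat, p = stats.mannwhitneyu(x, auto, alternative="two-sided")
        comparison = {
            "comparison": "X_vs_autosome",
            "skipped": False,
            "n_x": int(len(x)),
            "n_autosome": int(len(auto)),
            "median_log2_fm_x": float(x.median()),
            "median_log2_fm_autosome": float(auto.median()),
            "u_statistic": float(stat),
            "p_value": float(p),
        }
    return summaries, comparison


def enrichment_overlap(
    per_species_calls: dict[str, set[str]],
    ortholog_groups: dict[str, dict[str, str]] | None = None,
) -> dict[frozenset, int]:
    """Venn-style partition of enriched ortholog groups across species.

    ``per_species_calls`` maps species to its set of enriched gene ids.  When
    ``ortholog_groups`` is given (species -> gene_id -> group id), gene ids
    are first mapped to cross-species group ids; otherwise the gene ids are
    assumed to already be shared group ids.  Returns counts for every
    non-empty species subset (exclusive partition); the key covering all
    species is the "universal" cell.
    """
    species = sorted(per_species_calls)
    group_sets = {}
    for sp in species:
        genes = per_species_calls[sp]
        if ortholog_groups is not None:
            mapping = ortholog_groups.get(sp, {})
            group_sets[sp] = {mapping[g] for g in genes if g in mapping}
        else:
            group_sets[sp] = set(genes)
    partition: dict[frozenset, int] = {}
    all_groups = set().union(*group_sets.values()) if group_sets else set()
    for group in all_groups:
        members = frozenset(sp for sp in species if group in group_sets[sp])
        partition[members] = partition.get(members, 0) + 1
    # make every subset explicit (zero cells included) when panel is small
    if len(species) <= 10:
        for r in range(1, len(species) + 1):
            for combo in combinations(species, r):
                partition.setdefault(frozenset(combo), 0)
    return partition


def universal_count(partition: dict[frozenset, int], species: set[str]) -> int:
    """Groups enriched in every species of the panel."""
    return partition.get(frozenset(species), 0)


def bias_calls_frame(calls: list[BiasCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "contrast": [f"{c.contrast[0]}:{c.contrast[1]}" for c in calls],
            "log2_ratio": [c.log2_ratio for c in calls],
            "p_value": [c.p_value for c in calls],
            "p_adjusted": [c.p_adjusted for c in calls],
            "bias_class": [c.bias_class for c in calls],
            "tested": [c.tested for c in calls],
        }
    )
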