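"""Independent brute-force oracles shared by the unit and acceptance suites.

Everything here is coded from the definitions directly (enumeration, per-bp
counting, cumulative sort), independently of the package's implementation
paths, so agreement is evidence rather than tautology.
"""

from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(TABLE.stop_codons)
BASES = "ACGT"


def ng86_sites(codon):
    """Site counts by enumerating the 9 one-step neighbours, stops excluded."""
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


def ng86_diffs(c1, c2):
    """Difference counts by enumerating every substitution-order permutation."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in permutations(positions):
        path, cur = [c1], c1
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


def ng86_counts(pair):
    """(N, S, Nd, Sd) for a CodonPair by exhaustive per-codon enumeration."""
    N = S = Nd = Sd = 0.0
    for ca, cb in pair.codons():
        na, sa = ng86_sites(ca)
        nb, sb = ng86_sites(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = ng86_diffs(ca, cb)
        Nd += nd
        Sd += sd
    return N, S, Nd, Sd


def composition_call(present, taxon_map):
    """(level, universality) by scanning every named level for the smallest container."""
    levels = dict(taxon_map.clades)
    for sp in taxon_map.species:
        levels[sp] = frozenset({sp})
    containing = [(label, m) for label, m in levels.items() if set(present) <= m]
    label, members = min(containing, key=lambda lm: len(lm[1]))
    return label, ("universal" if set(present) == set(members) else "partial")


def binned_coverage(spans, length, width):
    """Per-bin covered fraction by literal per-bp boolean counting."""
    covered = np.zeros(length, dtype=bool)
    for s, e in spans:
        covered[s:e] = True
    out = []
    for start in range(0, length, width):
        end = min(start + width, length)
        out.append(covered[start:end].mean())
    return out


def n_statistic(lengths, fraction):
    """N50/N90 by cumulative sort from the definition."""
    ordered = sorted(lengths, reverse=True)
    total, acc = sum(ordered), 0
    for L in ordered:
        acc += L
        if acc >= fraction * total:
            return L
    raise AssertionError("unreachable for non-empty lengths")
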