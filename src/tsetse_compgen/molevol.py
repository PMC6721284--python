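"""Pairwise molecular-evolution rates: alignment masking, NG86 dN/dS,
protein divergence, and faster-X / slower-X group comparisons.

The selective pressure on a protein-coding gene is summarised by
ω = dN/dS, the ratio of nonsynonymous to synonymous substitution rates
(ω < 1 purifying, ≈ 1 neutral, > 1 positive selection).  This module
estimates ω for a pair of codon-aligned sequences with the Nei-Gojobori
(1986) counting method and a Jukes-Cantor multiple-hit correction:

* expected numbers of synonymous (S) and nonsynonymous (N) sites are the
  per-codon fractions of one-step changes that are synonymous, averaged over
  the two sequences; changes to stop codons are excluded from the mutational
  opportunity (each codon still contributes exactly 3 sites), the same stop
  convention the pathway counting uses;
* observed differences (Sd, Nd) average the per-step classifications over
  all minimal mutational pathways between each codon pair, weighting the
  pathways equally and skipping pathways that pass through a stop codon
  (falling back to all pathways in the rare case every one is blocked);
* dN and dS apply d = -3/4 ln(1 - 4p/3) to pN = Nd/N and pS = Sd/S; the
  correction saturates (is undefined) at p ≥ 3/4.

Alignment columns that are unreliable — gaps, ambiguity codes, stop codons,
or high-mismatch bursts flagged by a sliding window — are removed before
counting, mirroring the usual pre-filter applied ahead of rate estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
AA_OF = dict(_TABLE.forward_table)
_BASES = ("A", "C", "G", "T")

DEFAULT_MASK_WINDOW = 10  # codons
DEFAULT_MASK_DENSITY = 0.5  # mismatch fraction above which a window is masked


@dataclass(frozen=True)
class CodonPair:
    id: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.id}: sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.id}: length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        return [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]


@dataclass(frozen=True)
class DnDsResult:
    id: str
    n_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None  # None when the JC correction saturates
    dS: float | None
    omega: float | None  # None when dS is 0 or undefined
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DivergenceResult:
    id: str
    n_sites: int
    n_differences: int
    subs_per_100_sites: float


def _sense_codon_sites(codon: str) -> tuple[float, float]:
    """(N, S) sites of one sense codon.

    One-step changes to stop codons are excluded from the mutational
    opportunity; the remaining changes are renormalised so every codon
    contributes exactly 3 sites, split by its synonymous fraction.
    """
    syn = nonsyn = 0
    aa = AA_OF[codon]
    for i, base in enumerate(codon):
        for alt in _BASES:
            if alt == base:
                continue
            neighbor = codon[:i] + alt + codon[i + 1 :]
            if neighbor in STOP_CODONS:
                continue
            if AA_OF[neighbor] == aa:
                syn += 1
            else:
                nonsyn += 1
    total = syn + nonsyn
    return 3.0 * nonsyn / total, 3.0 * syn / total


_SITES_CACHE = {c: _sense_codon_sites(c) for c in SENSE_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) for one codon pair, averaged over minimal mutational pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in permutations(diff):
        steps, cur, through_stop = [], c1, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        (blocked if through_stop else valid).append(steps)
    pathways = valid if valid else blocked  # fall back when every pathway hits a stop
    nd = sd = 0.0
    for steps in pathways:
        for a, b in steps:
            aa_a = AA_OF.get(a)
            aa_b = AA_OF.get(b)
            if aa_a is not None and aa_a == aa_b:
                sd += 1.0
            else:
                nd += 1.0
    return nd / len(pathways), sd / len(pathways)


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(pair: CodonPair) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

    The pair must be pre-masked: every codon a sense codon (no gaps,
    ambiguity codes or stops) — see :func:`mask_alignment`.  Symmetric in
    the two sequences.
    """
    N = S = Nd = Sd = 0.0
    for ca, cb in pair.codons():
        for c in (ca, cb):
            if c not in _SITES_CACHE:
                raise ValueError(f"{pair.id}: codon {c!r} is not a sense codon; mask the alignment first")
        na, sa = _SITES_CACHE[ca]
        nb, sb = _SITES_CACHE[cb]
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = _pathway_counts(ca, cb)
        Nd += nd
        Sd += sd

    flags = []
    if pair.n_codons == 0:
        raise ValueError(f"{pair.id}: empty alignment")
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    dN = _jc_correct(pN)
    dS = _jc_correct(pS)
    if dN is None:
        flags.append("dN_saturated")
    if dS is None:
        flags.append("dS_saturated")
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    else:
        omega = None
        if dS == 0:
            flags.append("omega_undefined_dS_zero")
    return DnDsResult(pair.id, pair.n_codons, N, S, Nd, Sd, pN, pS, dN, dS, omega, tuple(flags))


def mask_alignment(
    pair: CodonPair,
    window: int = DEFAULT_MASK_WINDOW,
    max_mismatch_density: float = DEFAULT_MASK_DENSITY,
) -> CodonPair:
    """Remove unreliable codon columns from a codon-aligned pair.

    Dropped columns: any containing a gap or ambiguity character, any that is
    a stop codon in either sequence, and any falling inside a sliding window
    of ``window`` codons whose codon-mismatch density exceeds
    ``max_mismatch_density`` (computed over the surviving gap-free columns).
    Masking is symmetric in the two sequences and only removes columns, so
    downstream difference counts can only decrease.
    """
    if window < 1:
        raise ValueError("window must be at least 1 codon")
    clean_idx, clean = [], []
    for i, (ca, cb) in enumerate(pair.codons()):
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        clean_idx.append(i)
        clean.append((ca, cb))

    mismatch = np.array([ca != cb for ca, cb in clean], dtype=float)
    keep = np.ones(len(clean), dtype=bool)
    if len(clean) >= window:
        for start in range(0, len(clean) - window + 1):
            if mismatch[start : start + window].mean() > max_mismatch_density:
                keep[start : start + window] = False

    sa = "".join(ca for (ca, _), k in zip(clean, keep) if k)
    sb = "".join(cb for (_, cb), k in zip(clean, keep) if k)
    return CodonPair(pair.id, sa, sb)


def protein_divergence(id: str, aln_a: str, aln_b: str) -> DivergenceResult:
    """Substitutions per 100 aligned sites (p-distance x 100), gaps excluded."""
    if len(aln_a) != len(aln_b):
        raise ValueError(f"{id}: aligned sequences differ in length")
    pairs = [
        (a, b)
        for a, b in zip(aln_a.upper(), aln_b.upper())
        if a not in "-." and b not in "-." and a != "X" and b != "X"
    ]
    if not pairs:
        raise ValueError(f"{id}: no comparable (non-gap) sites")
    n_diff = sum(a != b for a, b in pairs)
    return DivergenceResult(id, len(pairs), n_diff, 100.0 * n_diff / len(pairs))


def compare_rate_groups(omega_table: pd.DataFrame) -> list[dict]:
    """X-versus-autosome ω comparisons, overall and within expression-bias classes.

    ``omega_table`` columns: ``omega`` (float), ``x_flag`` ("X"/"autosome"),
    and optionally ``bias_class``.  Each contrast reports group sizes,
    medians, effect direction and a two-sided Mann-Whitney U; contrasts with
    an empty group are skipped with a warning entry rather than an error.
    """
    df = omega_table.dropna(subset=["omega"])
    strata = [("all_genes", df)]
    if "bias_class" in df.columns:
        for cls in sorted(df["bias_class"].dropna().unique()):
            strata.append((str(cls), df[df["bias_class"] == cls]))

    reports = []
    for label, sub in strata:
        x = sub.loc[sub["x_flag"] == "X", "omega"].to_numpy()
        auto = sub.loc[sub["x_flag"] == "autosome", "omega"].to_numpy()
        base = {"stratum": label, "contrast": "X_vs_autosome"}
        if len(x) == 0 or len(auto) == 0:
            reports.append(
                base | {"skipped": True, "warning": "empty group: " + ("X" if len(x) == 0 else "autosome")}
            )
            continue
        u, p = stats.mannwhitneyu(x, auto, alternative="two-sided")
        med_x, med_a = float(np.median(x)), float(np.median(auto))
        direction = "X_lower" if med_x < med_a else ("X_higher" if med_x > med_a else "equal")
        reports.append(
            base
            | {
                "skipped": False,
                "n_x": int(len(x)),
                "n_autosome": int(len(auto)),
                "median_omega_x": med_x,
                "median_omega_autosome": med_a,
                "direction": direction,
                "u_statistic": float(u),
                "p_value": float(p),
            }
        )
    return reports


def dnds_frame(results: list[DnDsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in results],
            "n_codons": [r.n_codons for r in results],
            "N_sites": [r.N_sites for r in results],
            "S_sites": [r.S_sites for r in results],
            "Nd": [r.Nd for r in results],
            "Sd": [r.Sd for r in results],
            "dN": [r.dN for r in results],
            "dS": [r.dS for r in results],
            "omega": [r.omega for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
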