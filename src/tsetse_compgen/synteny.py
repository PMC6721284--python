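"""Homologous synteny block (HSB) detection and syntenic-fraction binning.

An HSB is a set of two or more consecutive orthologous markers occupying
homologous regions of two genomes such that no other block lies within the
region they border.  Two exceptions extend this rule: (1) a single marker not
belonging to any block forms a singleton block, and (2) two consecutive
singleton markers closer than the resolution threshold (10 kb by default)
merge into one block.  Block coverage along the reference is aggregated into
fixed-width bins (250 kb by default) reporting the fraction of sequence in
each bin that lies inside a block — the quantity drawn as a Circos histogram
track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_RESOLUTION = 10_000
DEFAULT_BIN_WIDTH = 250_000


@dataclass(frozen=True)
class Marker:
    ref_scaffold: str
    ref_pos: int
    tgt_scaffold: str
    tgt_pos: int
    orientation: str = "+"  # "+" or "-"


@dataclass(frozen=True)
class HSB:
    marker_ids: tuple[int, ...]  # indices into the input marker list
    ref_scaffold: str
    ref_start: int  # half-open [ref_start, ref_end)
    ref_end: int
    tgt_scaffold: str
    tgt_start: int
    tgt_end: int
    n_markers: int
    is_singleton_block: bool  # formed via exception 1 or 2


@dataclass(frozen=True)
class SyntenyBin:
    ref_scaffold: str
    bin_start: int
    bin_end: int
    syntenic_fraction: float


def _validate_markers(markers: list[Marker]) -> None:
    seen = set()
    for m in markers:
        if m.ref_pos < 0 or m.tgt_pos < 0:
            raise ValueError("marker positions must be non-negative")
        key = (m.ref_scaffold, m.ref_pos)
        if key in seen:
            raise ValueError(f"duplicate marker at reference coordinate {key}")
        seen.add(key)


def _target_ranks(markers: list[Marker], idx: list[int]) -> dict[int, int]:
    """Rank of each marker's target position within its target scaffold."""
    by_tgt: dict[str, list[int]] = {}
    for i in idx:
        by_tgt.setdefault(markers[i].tgt_scaffold, []).append(i)
    ranks = {}
    for members in by_tgt.values():
        for r, i in enumerate(sorted(members, key=lambda i: markers[i].tgt_pos)):
            ranks[i] = r
    return ranks


def _make_block(markers, member_idx, singleton: bool) -> HSB:
    ref_pos = [markers[i].ref_pos for i in member_idx]
    tgt_pos = [markers[i].tgt_pos for i in member_idx]
    return HSB(
        marker_ids=tuple(member_idx),
        ref_scaffold=markers[member_idx[0]].ref_scaffold,
        ref_start=min(ref_pos),
        ref_end=max(ref_pos) + 1,
        tgt_scaffold=markers[member_idx[0]].tgt_scaffold,
        tgt_start=min(tgt_pos),
        tgt_end=max(tgt_pos) + 1,
        n_markers=len(member_idx),
        is_singleton_block=singleton,
    )


def _runs_greedy(markers, order, ranks, orientation_strict) -> list[list[int]]:
    """Split the reference-ordered markers of one scaffold into maximal runs.

    Adjacent markers chain when their targets sit on one scaffold at adjacent
    target ranks; in strict mode the chain direction must also stay constant.
    """
    runs: list[list[int]] = []
    current = [order[0]]
    direction = 0
    for prev, cur in zip(order, order[1:]):
        a, b = markers[prev], markers[cur]
        step = ranks[cur] - ranks[prev] if a.tgt_scaffold == b.tgt_scaffold else None
        chained = step is not None and abs(step) == 1
        if chained and orientation_strict and direction != 0 and step != direction:
            chained = False
        if chained:
            current.append(cur)
            direction = step
        else:
            runs.append(current)
            current = [cur]
            direction = 0
    runs.append(current)
    return runs


def _merge_singletons(markers, runs, resolution, both_genomes) -> list[tuple[list[int], bool]]:
    """Apply the two singleton exceptions to greedy runs.

    Returns (member_indices, is_singleton_block) per final block.  Exception 2
    merges two consecutive leftover singletons closer than ``resolution`` on
    the reference (and on the target too when ``both_genomes``); merging is
    pairwise left-to-right, and requires the singletons to be adjacent in
    reference order (no multi-marker block between them).
    """
    blocks: list[tuple[list[int], bool]] = []
    i = 0
    while i < len(runs):
        run = runs[i]
        if len(run) >= 2:
            blocks.append((run, False))
            i += 1
            continue
        nxt = runs[i + 1] if i + 1 < len(runs) else None
        if nxt is not None and len(nxt) == 1:
            a, b = markers[run[0]], markers[nxt[0]]
            close_ref = abs(b.ref_pos - a.ref_pos) < resolution
            close_tgt = (
                a.tgt_scaffold == b.tgt_scaffold and abs(b.tgt_pos - a.tgt_pos) < resolution
            )
            if close_ref and (close_tgt or not both_genomes) and a.tgt_scaffold == b.tgt_scaffold:
                blocks.append((run + nxt, True))
                i += 2
                continue
        blocks.append((run, True))
        i += 1
    return blocks


def detect_hsbs(
    markers: list[Marker],
    resolution: int = DEFAULT_RESOLUTION,
    orientation_strict: bool = False,
    merge_both_genomes: bool = False,
) -> list[HSB]:
    """Build HSBs from orthologous point markers.

    Markers are sorted by reference position within each reference scaffold;
    maximal chains of target-adjacent markers (see ``_runs_greedy``) of length
    ≥ 2 become HSBs, leftovers become singleton blocks, and close singleton
    pairs merge per exception 2.  Every marker ends up in exactly one block.
    """
    if resolution < 0:
        raise ValueError("resolution must be non-negative")
    _validate_markers(markers)
    blocks: list[HSB] = []
    by_ref: dict[str, list[int]] = {}
    for i, m in enumerate(markers):
        by_ref.setdefault(m.ref_scaffold, []).append(i)
    for ref_scaffold in sorted(by_ref):
        idx = by_ref[ref_scaffold]
        order = sorted(idx, key=lambda i: markers[i].ref_pos)
        ranks = _target_ranks(markers, idx)
        runs = _runs_greedy(markers, order, ranks, orientation_strict)
        for members, singleton in _merge_singletons(markers, runs, resolution, merge_both_genomes):
            blocks.append(_make_block(markers, members, singleton))
    return blocks


def hsb_oracle(
    markers: list[Marker],
    resolution: int = DEFAULT_RESOLUTION,
    orientation_strict: bool = False,
    merge_both_genomes: bool = False,
) -> list[HSB]:
    """Brute-force HSB reference: exhaustive window enumeration (test use only).

    Enumerates every contiguous reference-order window, keeps those whose
    adjacent marker pairs all chain (and, in strict mode, share a direction),
    selects maximal windows left to right, then applies the singleton
    exceptions.  Quadratic; refuses instances above 100 markers.
    """
    if len(markers) > 100:
        raise ValueError("hsb_oracle is for instances of at most 100 markers")
    if resolution < 0:
        raise ValueError("resolution must be non-negative")
    _validate_markers(markers)

    def window_ok(order, ranks, lo, hi):  # inclusive window [lo, hi]
        steps = []
        for k in range(lo, hi):
            a, b = markers[order[k]], markers[order[k + 1]]
            if a.tgt_scaffold != b.tgt_scaffold:
                return False
            step = ranks[order[k + 1]] - ranks[order[k]]
            if abs(step) != 1:
                return False
            steps.append(step)
        if orientation_strict and len(set(steps)) > 1:
            return False
        return True

    blocks: list[HSB] = []
    by_ref: dict[str, list[int]] = {}
    for i, m in enumerate(markers):
        by_ref.setdefault(m.ref_scaffold, []).append(i)
    for ref_scaffold in sorted(by_ref):
        idx = by_ref[ref_scaffold]
        order = sorted(idx, key=lambda i: markers[i].ref_pos)
        ranks = _target_ranks(markers, idx)
        runs = []
        lo = 0
        while lo < len(order):
            hi = lo
            for cand in range(len(order) - 1, lo, -1):  # longest window starting at lo
                if window_ok(order, ranks, lo, cand):
                    hi = cand
                    break
            runs.append([order[k] for k in range(lo, hi + 1)])
            lo = hi + 1
        for members, singleton in _merge_singletons(markers, runs, resolution, merge_both_genomes):
            blocks.append(_make_block(markers, members, singleton))
    return blocks


def bin_syntenic_fraction(
    hsbs: list[HSB],
    scaffold_lengths: pd.DataFrame,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> list[SyntenyBin]:
    """Fraction of each reference bin covered by the union of HSB spans.

    Bins are 0-based and width-aligned; the last bin of a scaffold is
    normalised by its true (shorter) width.  Overlapping spans are merged
    before computing coverage.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    length_of = dict(zip(scaffold_lengths["scaffold_id"], scaffold_lengths["length"]))
    spans: dict[str, list[tuple[int, int]]] = {}
    for b in hsbs:
        L = length_of.get(b.ref_scaffold)
        if L is None:
            raise ValueError(f"HSB references unknown scaffold {b.ref_scaffold!r}")
        if b.ref_end > L:
            raise ValueError(f"HSB span [{b.ref_start},{b.ref_end}) exceeds {b.ref_scaffold!r} length {L}")
        spans.setdefault(b.ref_scaffold, []).append((b.ref_start, b.ref_end))

    bins: list[SyntenyBin] = []
    for scaffold_id in scaffold_lengths["scaffold_id"]:
        L = int(length_of[scaffold_id])
        merged: list[tuple[int, int]] = []
        for s, e in sorted(spans.get(scaffold_id, [])):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for start in range(0, L, bin_width):
            end = min(start + bin_width, L)
            covered = sum(max(0, min(e, end) - max(s, start)) for s, e in merged)
            bins.append(SyntenyBin(scaffold_id, start, end, covered / (end - start)))
    return bins


def hsbs_frame(hsbs: list[HSB]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ref_scaffold": [b.ref_scaffold for b in hsbs],
            "ref_start": [b.ref_start for b in hsbs],
            "ref_end": [b.ref_end for b in hsbs],
            "tgt_scaffold": [b.tgt_scaffold for b in hsbs],
            "tgt_start": [b.tgt_start for b in hsbs],
            "tgt_end": [b.tgt_end for b in hsbs],
            "n_markers": [b.n_markers for b in hsbs],
            "is_singleton_block": [b.is_singleton_block for b in hsbs],
        }
    )


def bins_frame(bins: list[SyntenyBin]) -> pd.DataFrame:
    return pd.DataFrame([b.__dict__ for b in bins])


def markers_from_frame(df: pd.DataFrame) -> list[Marker]:
    """Markers from a TSV-derived frame (ref_scaffold, ref_pos, tgt_scaffold, tgt_pos[, orientation])."""
    orient = df["orientation"] if "orientation" in df else np.repeat("+", len(df))
    return [
        Marker(str(rs), int(rp), str(ts), int(tp), str(o))
        for rs, rp, ts, tp, o in zip(
            df["ref_scaffold"], df["ref_pos"], df["tgt_scaffold"], df["tgt_pos"], orient
        )
    ]
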