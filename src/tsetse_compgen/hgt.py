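"""Discrimination of symbiont-derived (Wolbachia-like) sequence in a host assembly.

Candidate segments of a host genome assembly with symbiont homology fall into
three classes.  A *chromosomal insertion* — symbiont sequence horizontally
transferred into the host nuclear genome — has diverged from the extant
symbiont, so it shows a high polymorphism density against the symbiont
reference (at least 10 polymorphisms per 100 bp) *coupled with* insertion/
deletion events, and is long enough to be assembled confidently (>= 500 bp).
A *cytoplasmic* copy is near-identical to the reference (density below the
threshold).  Everything else — short or non-homologous fragments — is an
*artifact*.  The decision consumes per-segment alignment summaries; the
upstream homology search and read assembly are not re-run here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CHROMOSOMAL = "chromosomal_insertion"
CYTOPLASMIC = "cytoplasmic"
ARTIFACT = "artifact"

DEFAULT_MIN_LENGTH = 500  # bp, smallest reported insertion size
DEFAULT_DENSITY_THRESHOLD = 10.0  # polymorphisms per 100 bp


@dataclass(frozen=True)
class CandidateSegment:
    id: str
    length: int
    n_polymorphisms: int
    n_indel_events: int
    homology_hit: bool
    source_scaffold: str = ""

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be positive")
        if self.n_polymorphisms < 0 or self.n_indel_events < 0:
            raise ValueError(f"segment {self.id}: counts must be non-negative")


@dataclass(frozen=True)
class SegmentCall:
    id: str
    polymorphism_density: float  # per 100 bp
    segment_class: str
    reasons: tuple[str, ...]


def polymorphism_density(segment: CandidateSegment) -> float:
    """Polymorphisms per 100 bp of segment length."""
    return 100.0 * segment.n_polymorphisms / segment.length


def classify_segment(
    segment: CandidateSegment,
    min_length: int = DEFAULT_MIN_LENGTH,
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD,
    lenient: bool = False,
) -> SegmentCall:
    """Apply the insertion/cytoplasmic/artifact decision rule to one segment.

    chromosomal_insertion  iff homology AND density >= threshold AND length
    >= min_length AND (strict default) at least one indel event; ``lenient``
    relaxes the conjunction to density OR indels.  cytoplasmic iff homology
    AND density < threshold.  artifact otherwise.  ``reasons`` records every
    criterion outcome.
    """
    density = polymorphism_density(segment)
    has_density = density >= density_threshold
    has_indels = segment.n_indel_events >= 1
    long_enough = segment.length >= min_length
    reasons = (
        f"homology={'yes' if segment.homology_hit else 'no'}",
        f"density={density:.2f}/100bp ({'>=' if has_density else '<'} {density_threshold:g})",
        f"indels={segment.n_indel_events} ({'>=1' if has_indels else '0'})",
        f"length={segment.length} ({'>=' if long_enough else '<'} {min_length})",
    )
    divergent = (has_density or has_indels) if lenient else (has_density and has_indels)
    if segment.homology_hit and divergent and long_enough:
        cls = CHROMOSOMAL
    elif segment.homology_hit and density < density_threshold:
        cls = CYTOPLASMIC
    else:
        cls = ARTIFACT
    return SegmentCall(segment.id, density, cls, reasons)


def classify_segments(segments, **kwargs) -> list[SegmentCall]:
    return [classify_segment(s, **kwargs) for s in segments]


def _n_statistic(lengths: np.ndarray, fraction: float) -> int:
    """Smallest length L such that segments of length >= L cover `fraction` of the total."""
    ordered = np.sort(lengths)[::-1]
    cum = np.cumsum(ordered)
    target = fraction * cum[-1]
    return int(ordered[np.searchsorted(cum, target)])


def summarize_calls(calls: list[SegmentCall], segments: list[CandidateSegment]) -> dict:
    """Per-class counts plus N50/N90/mean length of the insertion class."""
    length_of = {s.id: s.length for s in segments}
    counts = {cls: 0 for cls in (CHROMOSOMAL, CYTOPLASMIC, ARTIFACT)}
    insertion_lengths = []
    for call in calls:
        counts[call.segment_class] += 1
        if call.segment_class == CHROMOSOMAL:
            insertion_lengths.append(length_of[call.id])
    summary = {"n_" + cls: n for cls, n in counts.items()}
    if insertion_lengths:
        arr = np.asarray(insertion_lengths)
        summary |= {
            "insertion_n50": _n_statistic(arr, 0.5),
            "insertion_n90": _n_statistic(arr, 0.9),
            "insertion_mean_length": float(arr.mean()),
            "insertion_min_length": int(arr.min()),
            "insertion_max_length": int(arr.max()),
        }
    else:
        summary |= {
            "insertion_n50": 0,
            "insertion_n90": 0,
            "insertion_mean_length": 0.0,
            "insertion_min_length": 0,
            "insertion_max_length": 0,
        }
    return summary


def segments_from_frame(df: pd.DataFrame) -> list[CandidateSegment]:
    """Segments from a TSV-derived frame (id, length_bp, n_polymorphisms, n_indels, homology_hit[, scaffold])."""
    scaffolds = df["scaffold"] if "scaffold" in df else np.repeat("", len(df))
    return [
        CandidateSegment(str(i), int(L), int(p), int(d), bool(h), str(sc))
        for i, L, p, d, h, sc in zip(
            df["id"], df["length_bp"], df["n_polymorphisms"], df["n_indels"],
            df["homology_hit"], scaffolds,
        )
    ]


def calls_frame(calls: list[SegmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in calls],
            "polymorphism_density": [c.polymorphism_density for c in calls],
            "class": [c.segment_class for c in calls],
            "reasons": ["; ".join(c.reasons) for c in calls],
        }
    )
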