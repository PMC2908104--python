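"""Dataset-level fractionation statistics.

The central vocabulary: a peptide seen in n distinct fractions is
"n-spanned"; one seen in a single fraction is "unique".  Good focussing
means mostly unique peptides and small overlaps between neighbouring
fractions; this module quantifies both, plus how often a non-unique
peptide's spread stays within one contiguous block of adjacent fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .physchem import PeptideSummary
from .tables_io import FractionRange

__all__ = [
    "FractionStats",
    "SpanDistribution",
    "AdjacentOverlap",
    "fraction_stats",
    "span_distribution",
    "adjacent_overlaps",
    "assign_identifiers",
    "sort_peptides",
    "write_fraction_stats",
]


@dataclass(frozen=True)
class FractionStats:
    """Per-fraction counts for the histogram and box-plot panels."""

    fraction: int
    n_peptides: int
    n_unique: int
    pI_values: tuple[float, ...]
    expected_range: Optional[FractionRange] = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_unique <= self.n_peptides:
            raise ValueError("n_unique must lie in [0, n_peptides]")

    @property
    def pct_unique(self) -> Optional[float]:
        """Percent of this fraction's peptides that are 1-span; None if empty."""
        if self.n_peptides == 0:
            return None
        return 100.0 * self.n_unique / self.n_peptides


@dataclass(frozen=True)
class SpanDistribution:
    """Counts of peptides by span width, plus the headline percentages."""

    counts: Mapping[int, int]
    pct_unique_overall: float
    pct_nonunique_overall: float
    pct_contiguous_spreads: Optional[float]

    @property
    def n_peptides(self) -> int:
        return sum(self.counts.values())

    @property
    def max_span(self) -> int:
        return max(self.counts)


@dataclass(frozen=True)
class AdjacentOverlap:
    """Shared-peptide count between fractions i and i+1."""

    pair: tuple[int, int]
    shared: int
    size_left: int
    size_right: int

    def __post_init__(self) -> None:
        if self.pair[1] != self.pair[0] + 1:
            raise ValueError("overlap pairs must be adjacent fractions (i, i+1)")
        if not 0 <= self.shared <= min(self.size_left, self.size_right):
            raise ValueError(
                f"shared count {self.shared} exceeds a fraction size "
                f"({self.size_left}, {self.size_right})"
            )


def _infer_n_fractions(summaries: Sequence[PeptideSummary],
                       ranges: Optional[Sequence[FractionRange]]) -> int:
    n = max(s.fractions[-1] for s in summaries)
    if ranges:
        n = max(n, max(r.fraction for r in ranges))
    return n


def fraction_stats(
    summaries: Sequence[PeptideSummary],
    ranges: Optional[Sequence[FractionRange]] = None,
    n_fractions: Optional[int] = None,
) -> list[FractionStats]:
    """Per-fraction peptide counts, unique counts and pI collections.

    One entry per fraction 1..n_fractions; fractions with no peptides are
    retained (with zero counts) so downstream panels keep the physical
    well layout.  A peptide contributes its pI to every fraction it spans.
    """
    if not summaries:
        raise ValueError("fraction_stats needs at least one peptide summary")
    if n_fractions is None:
        n_fractions = _infer_n_fractions(summaries, ranges)
    by_range = {r.fraction: r for r in ranges} if ranges else {}
    members: dict[int, list[PeptideSummary]] = {f: [] for f in range(1, n_fractions + 1)}
    for s in summaries:
        for f in s.fractions:
            members[f].append(s)
    out = []
    for f in range(1, n_fractions + 1):
        group = members[f]
        out.append(
            FractionStats(
                fraction=f,
                n_peptides=len(group),
                n_unique=sum(1 for s in group if s.is_unique),
                pI_values=tuple(s.pI for s in group),
                expected_range=by_range.get(f),
            )
        )
    return out


def span_distribution(summaries: Sequence[PeptideSummary]) -> SpanDistribution:
    """Tally peptides by span width.

    ``pct_contiguous_spreads`` is computed over non-unique peptides only:
    the percentage whose fraction set forms one contiguous run (spread
    across adjacent fractions only, no gaps).  It is None when every
    peptide is unique.
    """
    if not summaries:
        raise ValueError("span_distribution needs at least one peptide summary")
    counts: dict[int, int] = {}
    for s in summaries:
        counts[s.n_span] = counts.get(s.n_span, 0) + 1
    total = len(summaries)
    n_unique = counts.get(1, 0)
    nonunique = [s for s in summaries if not s.is_unique]
    pct_contig = (
        100.0 * sum(1 for s in nonunique if s.is_contiguous) / len(nonunique)
        if nonunique
        else None
    )
    pct_unique = 100.0 * n_unique / total
    return SpanDistribution(
        counts=dict(sorted(counts.items())),
        pct_unique_overall=pct_unique,
        pct_nonunique_overall=100.0 - pct_unique,
        pct_contiguous_spreads=pct_contig,
    )


def adjacent_overlaps(
    summaries: Sequence[PeptideSummary], n_fractions: Optional[int] = None
) -> list[AdjacentOverlap]:
    """Distinct-peptide overlap between every adjacent fraction pair.

    Returns exactly n_fractions - 1 entries, pairs (1,2) .. (n-1,n).
    """
    if not summaries:
        raise ValueError("adjacent_overlaps needs at least one peptide summary")
    if n_fractions is None:
        n_fractions = _infer_n_fractions(summaries, None)
    if n_fractions < 2:
        raise ValueError("adjacent overlaps need at least two fractions")
    sets: dict[int, set[str]] = {f: set() for f in range(1, n_fractions + 1)}
    for s in summaries:
        for f in s.fractions:
            sets[f].add(s.sequence)
    out = []
    for f in range(1, n_fractions):
        left, right = sets[f], sets[f + 1]
        out.append(
            AdjacentOverlap(
                pair=(f, f + 1),
                shared=len(left & right),
                size_left=len(left),
                size_right=len(right),
            )
        )
    return out


def assign_identifiers(summaries: Sequence[PeptideSummary]) -> dict[str, int]:
    """Consecutive integer identifiers ordered by span width.

    The sort key is (n_span, first fraction, pI, sequence), which makes
    the numbering deterministic for a dataset and places all peptides of
    one span category in a contiguous identifier block -- the ordering the
    span-bitmap panel stacks rows by.
    """
    if not summaries:
        raise ValueError("assign_identifiers needs at least one peptide summary")
    ordered = sorted(summaries, key=lambda s: (s.n_span, s.fractions[0], s.pI, s.sequence))
    return {s.sequence: i for i, s in enumerate(ordered, start=1)}


_SORT_KEYS = {"pI": "pI", "mass": "mw", "score": "score"}


def sort_peptides(summaries: Sequence[PeptideSummary], key: str = "pI") -> list[PeptideSummary]:
    """Stable ascending sort by pI, mass or score; ties break lexicographically."""
    if key not in _SORT_KEYS:
        raise ValueError(f"sort key must be one of {sorted(_SORT_KEYS)}, got {key!r}")
    attr = _SORT_KEYS[key]
    values = [getattr(s, attr) for s in summaries]
    if any(v is None for v in values):
        raise ValueError(f"sort key {key!r} is absent on some peptides")
    return sorted(summaries, key=lambda s: (getattr(s, attr), s.sequence))


def write_fraction_stats(stats: Sequence[FractionStats], path) -> None:
    """Export the per-fraction statistics as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fraction\tn_peptides\tn_unique\tpct_unique\n")
        for s in stats:
            pct = "" if s.pct_unique is None else f"{s.pct_unique:.4f}"
            fh.write(f"{s.fraction}\t{s.n_peptides}\t{s.n_unique}\t{pct}\n")
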