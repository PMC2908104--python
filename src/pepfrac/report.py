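"""The one-page five-panel fractionation diagnostic figure.

Panels, top to bottom:

  A  box plot of peptide pI per fraction, with the expected pH ranges
     overlaid as dotted steps when supplied;
  B  histogram of the percentage of unique (1-span) peptides per fraction;
  C  span bitmap: one fixed-width cell per (peptide, fraction) membership,
     rows grouped into n-span bands, so carry-over shows up as long
     horizontal segments;
  D  area-proportional circle chain: circle area ~ peptides per fraction,
     lens area ~ peptides shared by adjacent fractions, shared counts
     printed in the lenses;
  E  segment stack: per fraction, peptides sorted by pI (or mass/score)
     drawn as centred segments, segments of the same peptide in adjacent
     fractions joined by a line whose grey level encodes the flat-charge
     range (darker = wider = poorer focussing potential).

Every panel function returns a plain data structure first; rendering is a
separate, stateless pass over those structures, so all numeric report
logic is testable without rasterising anything.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import physchem, span_analysis, tables_io, venn_geometry
from .physchem import PeptideSummary, PkaTable
from .span_analysis import AdjacentOverlap, FractionStats, SpanDistribution
from .tables_io import Dataset, FractionRange
from .venn_geometry import CircleSpec, LensSolution

__all__ = [
    "ReportSpec",
    "ReportResult",
    "span_colour_map",
    "fraction_colour_map",
    "panel_boxplot",
    "panel_unique_histogram",
    "panel_span_bitmap",
    "panel_venn_chain",
    "panel_segment_stack",
    "build_panels",
    "render_report",
]

_FORMATS = ("png", "pdf", "svg")


@dataclass(frozen=True)
class ReportSpec:
    """Rendering options for one report page."""

    output_path: str | os.PathLike
    format: str = "png"
    dpi: int = 150
    sort_key: str = "pI"
    charge_threshold: float = 0.01
    grey_scale_bounds: Optional[tuple[float, float]] = None
    max_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {self.format!r}")
        if self.charge_threshold <= 0:
            raise ValueError("charge threshold must be positive")


def span_colour_map(spans: Sequence[int]) -> dict[int, tuple]:
    """Injective n-span -> RGBA mapping, shared by panels C, D and E."""
    import matplotlib

    cmap = matplotlib.colormaps["turbo"]
    uniq = sorted(set(spans))
    if len(uniq) == 1:
        return {uniq[0]: tuple(cmap(0.15))}
    return {s: tuple(cmap(0.1 + 0.85 * i / (len(uniq) - 1))) for i, s in enumerate(uniq)}


def fraction_colour_map(n_fractions: int) -> dict[int, tuple]:
    """Injective fraction -> RGBA mapping, shared by panels C, D and E."""
    import matplotlib

    cmap = matplotlib.colormaps["viridis"]
    if n_fractions == 1:
        return {1: tuple(cmap(0.5))}
    return {
        f: tuple(cmap((f - 1) / (n_fractions - 1))) for f in range(1, n_fractions + 1)
    }


# --------------------------------------------------------------------------
# Panel data structures


@dataclass(frozen=True)
class BoxplotPanel:
    fractions: tuple[int, ...]
    pI_values: tuple[tuple[float, ...], ...]
    ranges: Optional[tuple[FractionRange, ...]]


@dataclass(frozen=True)
class UniqueHistogramPanel:
    fractions: tuple[int, ...]
    pct_unique: tuple[Optional[float], ...]


@dataclass(frozen=True)
class BitmapCell:
    fraction: int
    row: int
    n_span: int
    sequence: str


@dataclass(frozen=True)
class SpanBitmapPanel:
    cells: tuple[BitmapCell, ...]
    bands: Mapping[int, tuple[int, int]]  # n_span -> (first row, last row), rows 1-based
    n_fractions: int
    colours: Mapping[int, tuple]  # n_span -> RGBA


@dataclass(frozen=True)
class VennChainPanel:
    circles: tuple[CircleSpec, ...]
    lenses: tuple[LensSolution, ...]
    colours: Mapping[int, tuple]  # fraction -> RGBA


@dataclass(frozen=True)
class StackSegment:
    sequence: str
    fraction: int
    x_center: float
    y: float
    length: float
    value: float  # the sort-key value the length encodes


@dataclass(frozen=True)
class StackLine:
    sequence: str
    pair: tuple[int, int]
    start: tuple[float, float]
    end: tuple[float, float]
    grey: float  # 0 = light (narrow flat range) .. 1 = dark (wide)


@dataclass(frozen=True)
class SegmentStackPanel:
    segments: tuple[StackSegment, ...]
    lines: tuple[StackLine, ...]
    column_widths: Mapping[int, float]
    colours: Mapping[int, tuple]  # fraction -> RGBA
    grey_bounds: tuple[float, float]
    sort_key: str


@dataclass(frozen=True)
class ReportResult:
    """Rendered file plus every intermediate the panels were built from."""

    path: Path
    summaries: tuple[PeptideSummary, ...]
    stats: tuple[FractionStats, ...]
    distribution: SpanDistribution
    overlaps: tuple[AdjacentOverlap, ...]
    panels: Mapping[str, object]


# --------------------------------------------------------------------------
# Panel builders (pure data)


def panel_boxplot(
    stats: Sequence[FractionStats],
    ranges: Optional[Sequence[FractionRange]] = None,
) -> BoxplotPanel:
    if not stats:
        raise ValueError("panel_boxplot needs fraction statistics")
    if ranges is None:
        found = tuple(s.expected_range for s in stats if s.expected_range is not None)
        ranges = found or None
    return BoxplotPanel(
        fractions=tuple(s.fraction for s in stats),
        pI_values=tuple(s.pI_values for s in stats),
        ranges=tuple(ranges) if ranges else None,
    )


def panel_unique_histogram(stats: Sequence[FractionStats]) -> UniqueHistogramPanel:
    if not stats:
        raise ValueError("panel_unique_histogram needs fraction statistics")
    return UniqueHistogramPanel(
        fractions=tuple(s.fraction for s in stats),
        pct_unique=tuple(s.pct_unique for s in stats),
    )


def panel_span_bitmap(
    summaries: Sequence[PeptideSummary],
    identifiers: Mapping[str, int],
    n_fractions: Optional[int] = None,
) -> SpanBitmapPanel:
    """One filled cell per (peptide, fraction) membership.

    Row = the peptide's identifier; identifiers are assigned in span order,
    so each n-span category occupies a contiguous band of rows.
    """
    if not summaries:
        raise ValueError("panel_span_bitmap needs peptide summaries")
    if n_fractions is None:
        n_fractions = max(s.fractions[-1] for s in summaries)
    colours = span_colour_map([s.n_span for s in summaries])
    cells: list[BitmapCell] = []
    bands: dict[int, tuple[int, int]] = {}
    for s in summaries:
        row = identifiers[s.sequence]
        lo, hi = bands.get(s.n_span, (row, row))
        bands[s.n_span] = (min(lo, row), max(hi, row))
        for f in s.fractions:
            cells.append(BitmapCell(fraction=f, row=row, n_span=s.n_span, sequence=s.sequence))
    return SpanBitmapPanel(
        cells=tuple(cells),
        bands=dict(sorted(bands.items())),
        n_fractions=n_fractions,
        colours=colours,
    )


def panel_venn_chain(
    circles: Sequence[CircleSpec],
    lenses: Sequence[LensSolution],
    colours: Optional[Mapping[int, tuple]] = None,
) -> VennChainPanel:
    if colours is None:
        colours = fraction_colour_map(max(c.fraction for c in circles))
    return VennChainPanel(circles=tuple(circles), lenses=tuple(lenses), colours=colours)


def panel_segment_stack(
    summaries: Sequence[PeptideSummary],
    sort_key: str = "pI",
    grey_bounds: Optional[tuple[float, float]] = None,
    n_fractions: Optional[int] = None,
) -> SegmentStackPanel:
    """Columns of centred segments, one column per fraction.

    Within a column, peptides are sorted ascending by the sort key from
    top to bottom; segment length maps the key value linearly onto
    [0.2, 1.0] of the column width, and column width grows with the
    fraction's peptide count.  A line joins a peptide's segments in
    fractions i and i+1 iff the peptide was seen in both; its grey level
    maps the flat-charge range linearly onto [light, dark] over
    ``grey_bounds`` (dataset min/max by default).
    """
    if not summaries:
        raise ValueError("panel_segment_stack needs peptide summaries")
    ordered = span_analysis.sort_peptides(summaries, sort_key)
    if n_fractions is None:
        n_fractions = max(s.fractions[-1] for s in summaries)
    attr = {"pI": "pI", "mass": "mw", "score": "score"}[sort_key]
    values = [getattr(s, attr) for s in summaries]
    vmin, vmax = min(values), max(values)
    vspan = (vmax - vmin) or 1.0

    flats = [s.flat_range for s in summaries]
    if grey_bounds is None:
        grey_bounds = (min(flats), max(flats))
    glo, ghi = grey_bounds
    gspan = (ghi - glo) or 1.0

    members: dict[int, list[PeptideSummary]] = {f: [] for f in range(1, n_fractions + 1)}
    for s in ordered:
        for f in s.fractions:
            members[f].append(s)
    max_count = max(len(v) for v in members.values()) or 1
    widths = {f: 0.9 * len(v) / max_count for f, v in members.items()}

    segments: list[StackSegment] = []
    seg_index: dict[tuple[str, int], StackSegment] = {}
    for f in range(1, n_fractions + 1):
        for rank, s in enumerate(members[f]):
            v = getattr(s, attr)
            length = widths[f] * (0.2 + 0.8 * (v - vmin) / vspan)
            seg = StackSegment(
                sequence=s.sequence, fraction=f, x_center=float(f),
                y=-(rank + 1.0), length=length, value=v,
            )
            segments.append(seg)
            seg_index[(s.sequence, f)] = seg

    lines: list[StackLine] = []
    for s in summaries:
        present = set(s.fractions)
        grey = min(1.0, max(0.0, (s.flat_range - glo) / gspan))
        for f in s.fractions:
            if f + 1 in present:
                a = seg_index[(s.sequence, f)]
                b = seg_index[(s.sequence, f + 1)]
                lines.append(
                    StackLine(
                        sequence=s.sequence,
                        pair=(f, f + 1),
                        start=(a.x_center + a.length / 2.0, a.y),
                        end=(b.x_center - b.length / 2.0, b.y),
                        grey=grey,
                    )
                )
    return SegmentStackPanel(
        segments=tuple(segments),
        lines=tuple(lines),
        column_widths=widths,
        colours=fraction_colour_map(n_fractions),
        grey_bounds=grey_bounds,
        sort_key=sort_key,
    )


# --------------------------------------------------------------------------
# Rendering


def _draw_boxplot(ax, panel: BoxplotPanel) -> None:
    filled = [(f, v) for f, v in zip(panel.fractions, panel.pI_values) if v]
    if filled:
        ax.boxplot(
            [list(v) for _, v in filled],
            positions=[f for f, _ in filled],
            widths=0.6,
            whis=1.5,
            flierprops={"markersize": 2},
            medianprops={"color": "firebrick"},
        )
    if panel.ranges:
        for r in panel.ranges:
            ax.plot(
                [r.fraction - 0.5, r.fraction + 0.5], [r.ph_low, r.ph_low],
                linestyle=":", color="grey", linewidth=1.0,
            )
            ax.plot(
                [r.fraction - 0.5, r.fraction + 0.5], [r.ph_high, r.ph_high],
                linestyle=":", color="grey", linewidth=1.0,
            )
    ax.set_xlim(0.5, max(panel.fractions) + 0.5)
    ax.set_xticks(list(panel.fractions))
    ax.set_xticklabels([f"F{f}" for f in panel.fractions], fontsize=5, rotation=90)
    ax.set_ylabel("pI")
    ax.set_title("A  peptide pI per fraction (dotted: expected pH range)", fontsize=8, loc="left")


def _draw_histogram(ax, panel: UniqueHistogramPanel) -> None:
    for f, pct in zip(panel.fractions, panel.pct_unique):
        if pct is None:
            ax.bar(f, 100.0, color="none", edgecolor="lightgrey", hatch="///", width=0.8)
        else:
            ax.bar(f, pct, color="steelblue", width=0.8)
    ax.set_ylim(0, 100)
    ax.set_xlim(0.5, max(panel.fractions) + 0.5)
    ax.set_xticks(list(panel.fractions))
    ax.set_xticklabels([f"F{f}" for f in panel.fractions], fontsize=5, rotation=90)
    ax.set_ylabel("% unique")
    ax.set_title("B  unique peptides per fraction", fontsize=8, loc="left")


def _draw_bitmap(ax, panel: SpanBitmapPanel) -> None:
    for cell in panel.cells:
        ax.add_patch(
            _rect(
                cell.fraction - 0.5, cell.row - 0.45, 1.0, 0.9,
                color=panel.colours[cell.n_span],
            )
        )
    for n_span, (lo, hi) in panel.bands.items():
        ax.axhline(hi + 0.5, color="lightgrey", linewidth=0.4, zorder=0)
        ax.text(
            panel.n_fractions + 0.6, (lo + hi) / 2.0,
            "unique" if n_span == 1 else f"{n_span}-span",
            fontsize=5, va="center",
        )
    n_rows = max(c.row for c in panel.cells)
    ax.set_xlim(0.5, panel.n_fractions + 2.0)
    ax.set_ylim(0.5, n_rows + 0.5)
    ax.set_xticks(range(1, panel.n_fractions + 1))
    ax.set_xticklabels([f"F{f}" for f in range(1, panel.n_fractions + 1)],
                       fontsize=5, rotation=90)
    ax.set_yticks([])
    ax.set_ylabel("peptides by identifier")
    ax.set_title("C  fractionation pattern by n-span", fontsize=8, loc="left")


def _rect(x, y, w, h, color):
    from matplotlib.patches import Rectangle

    return Rectangle((x, y), w, h, facecolor=color, edgecolor="none", antialiased=False)


def _draw_venn(ax, panel: VennChainPanel) -> None:
    from matplotlib.patches import Arc, Circle

    max_r = max((c.radius for c in panel.circles), default=1.0) or 1.0
    for c in panel.circles:
        colour = panel.colours[c.fraction]
        if c.radius > 0:
            ax.add_patch(
                Circle((c.center_x, c.center_y), c.radius,
                       facecolor="none", edgecolor=colour, linewidth=1.2)
            )
        else:
            ax.plot([c.center_x], [c.center_y], marker="x", color=colour, markersize=4)
        ax.text(c.center_x, -1.15 * max_r, f"F{c.fraction}",
                ha="center", fontsize=6, color=colour)
        ax.text(c.center_x, 1.1 * max_r, str(c.n_peptides), ha="center", fontsize=5)
    by_fraction = {c.fraction: c for c in panel.circles}
    for lens in panel.lenses:
        if lens.pair is None or not lens.intersection_points:
            continue
        left = by_fraction[lens.pair[0]]
        right = by_fraction[lens.pair[1]]
        (x, y), _ = lens.intersection_points
        d = lens.distance
        t1 = math.degrees(math.atan2(y, x))
        t2 = math.degrees(math.atan2(y, x - d))
        ax.add_patch(
            Arc((left.center_x, left.center_y), 2 * left.radius, 2 * left.radius,
                theta1=-t1, theta2=t1, linewidth=1.6, color="black")
        )
        ax.add_patch(
            Arc((right.center_x, right.center_y), 2 * right.radius, 2 * right.radius,
                theta1=t2, theta2=360.0 - t2, linewidth=1.6, color="black")
        )
        if lens.shared:
            ax.text(left.center_x + x, 0.0, str(lens.shared),
                    ha="center", va="center", fontsize=6)
    span = panel.circles[-1].center_x + max_r
    ax.set_xlim(-1.2 * max_r, span + 0.2 * max_r)
    ax.set_ylim(-1.4 * max_r, 1.4 * max_r)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title("D  adjacent-fraction overlap (areas proportional to counts)",
                 fontsize=8, loc="left")


def _draw_stack(ax, panel: SegmentStackPanel) -> None:
    for seg in panel.segments:
        colour = panel.colours[seg.fraction]
        ax.plot(
            [seg.x_center - seg.length / 2.0, seg.x_center + seg.length / 2.0],
            [seg.y, seg.y],
            color=colour, linewidth=0.8, solid_capstyle="butt",
        )
    for line in panel.lines:
        shade = 0.85 * (1.0 - line.grey)
        ax.plot(
            [line.start[0], line.end[0]], [line.start[1], line.end[1]],
            color=(shade, shade, shade), linewidth=0.5,
        )
    n_fractions = max(panel.column_widths)
    ax.set_xlim(0.3, n_fractions + 0.7)
    ax.set_xticks(range(1, n_fractions + 1))
    ax.set_xticklabels([f"F{f}" for f in range(1, n_fractions + 1)],
                       fontsize=5, rotation=90)
    ax.set_yticks([])
    ax.set_ylabel(f"peptides sorted by {panel.sort_key}")
    ax.set_title(
        "E  per-fraction stacks (segment length ~ %s; darker join = wider flat-charge range)"
        % panel.sort_key,
        fontsize=8, loc="left",
    )


def build_panels(
    summaries: Sequence[PeptideSummary],
    stats: Sequence[FractionStats],
    overlaps: Sequence[AdjacentOverlap],
    spec: ReportSpec,
) -> dict[str, object]:
    """All five panel data structures (D and E absent when < 2 fractions)."""
    identifiers = span_analysis.assign_identifiers(summaries)
    panels: dict[str, object] = {
        "A": panel_boxplot(stats),
        "B": panel_unique_histogram(stats),
        "C": panel_span_bitmap(summaries, identifiers, n_fractions=len(stats)),
    }
    if overlaps:
        circles, lenses = venn_geometry.layout_chain(overlaps, spec.max_radius)
        panels["D"] = panel_venn_chain(circles, lenses,
                                       fraction_colour_map(len(stats)))
        panels["E"] = panel_segment_stack(
            summaries, spec.sort_key, spec.grey_scale_bounds, n_fractions=len(stats)
        )
    return panels


def render_report(
    ds: Dataset,
    spec: ReportSpec,
    pka: PkaTable = physchem.DEFAULT_PKA,
    mass_mode: str = "monoisotopic",
) -> ReportResult:
    """Run the full pipeline on a dataset and write the one-page figure.

    The output file is written atomically (rendered to a temporary file in
    the target directory, then moved into place), so a failure leaves no
    partial output behind.  Output is deterministic for a fixed dataset
    and spec.
    """
    import matplotlib

    matplotlib.rcParams["svg.fonttype"] = "none"  # keep label text extractable
    import matplotlib.pyplot as plt

    completed = tables_io.fill_missing(ds, pka, mass_mode)
    summaries = physchem.summarise(completed, pka, spec.charge_threshold)
    stats = span_analysis.fraction_stats(summaries, ds.ranges)
    distribution = span_analysis.span_distribution(summaries)
    n_fractions = len(stats)
    overlaps = (
        span_analysis.adjacent_overlaps(summaries, n_fractions)
        if n_fractions >= 2
        else []
    )
    panels = build_panels(summaries, stats, overlaps, spec)

    fig = plt.figure(figsize=(8.27, 11.69))
    grid = fig.add_gridspec(
        4, 2, height_ratios=[1.0, 1.6, 1.0, 1.6], hspace=0.45, wspace=0.25
    )
    _draw_boxplot(fig.add_subplot(grid[0, 0]), panels["A"])
    _draw_histogram(fig.add_subplot(grid[0, 1]), panels["B"])
    _draw_bitmap(fig.add_subplot(grid[1, :]), panels["C"])
    if "D" in panels:
        _draw_venn(fig.add_subplot(grid[2, :]), panels["D"])
        _draw_stack(fig.add_subplot(grid[3, :]), panels["E"])
    else:
        for row, label in ((2, "D"), (3, "E")):
            ax = fig.add_subplot(grid[row, :])
            ax.set_axis_off()
            ax.text(0.5, 0.5, f"panel {label} omitted: fewer than two fractions",
                    ha="center", va="center", fontsize=8)
    fig.suptitle("Peptide fractionation diagnostic report", fontsize=11)

    out = Path(spec.output_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(suffix=f".{spec.format}", dir=out.parent)
    os.close(fd)
    try:
        fig.savefig(tmp, format=spec.format, dpi=spec.dpi)
        os.replace(tmp, out)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    finally:
        plt.close(fig)
    return ReportResult(
        path=out,
        summaries=tuple(summaries),
        stats=tuple(stats),
        distribution=distribution,
        overlaps=tuple(overlaps),
        panels=panels,
    )
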