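"""Reading and writing the tab-delimited tables of the pipeline.

Two input formats: the peptide identification table (one row per
(sequence, fraction) observation, with optional estimated pI, molecular
weight and search-engine score) and the optional expected-pH-range table
(fraction, low, high).  Column names in the peptide table are remappable
via :class:`TableDialect` because search-engine exports vary.

Missing pI/MW values are completed locally from the sequence
(:func:`fill_missing`) rather than fetched from a web service, which keeps
the pipeline hermetic; user-supplied values are never overwritten.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import physchem
from .physchem import PkaTable, validate_sequence

__all__ = [
    "TableFormatError",
    "RowError",
    "TableDialect",
    "PeptideObservation",
    "FractionRange",
    "Dataset",
    "read_peptide_table",
    "read_fraction_ranges",
    "write_fraction_ranges",
    "fill_missing",
    "write_summary_table",
    "read_summary_table",
    "write_peptide_table",
]

log = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """The file as a whole is malformed (e.g. a mandatory column is absent)."""


class RowError(ValueError):
    """A single row failed parsing or validation; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping for the peptide table.

    Defaults match the package's own exports; point the fields at whatever
    your search-engine export calls them.  Unknown extra columns are ignored.
    """

    sequence: str = "sequence"
    fraction: str = "fraction"
    pI: str = "pI"
    mw: str = "mw"
    score: str = "score"


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class PeptideObservation:
    """One (sequence, fraction) identification row."""

    sequence: str
    fraction: int
    pI: Optional[float] = None
    mw: Optional[float] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.fraction < 1:
            raise ValueError(f"fraction index must be >= 1, got {self.fraction}")
        if self.pI is not None and not (0.0 < self.pI < 14.0):
            raise ValueError(f"pI must lie in (0, 14), got {self.pI}")
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"molecular weight must be positive, got {self.mw}")


@dataclass(frozen=True)
class FractionRange:
    """Expected pH sub-range of one fraction of the gradient."""

    fraction: int
    ph_low: float
    ph_high: float

    def __post_init__(self) -> None:
        if self.fraction < 1:
            raise ValueError(f"fraction index must be >= 1, got {self.fraction}")
        if not self.ph_low < self.ph_high:
            raise ValueError(
                f"fraction {self.fraction}: ph_low ({self.ph_low}) must be below "
                f"ph_high ({self.ph_high})"
            )


@dataclass(frozen=True)
class Dataset:
    """A validated set of observations plus optional expected ranges."""

    observations: tuple[PeptideObservation, ...]
    ranges: Optional[tuple[FractionRange, ...]] = None

    @property
    def n_fractions(self) -> int:
        if not self.observations:
            return 0
        return max(o.fraction for o in self.observations)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(sorted({o.sequence for o in self.observations}))


def _parse_optional_float(cell, line: int, name: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise RowError(line, f"non-numeric {name} value {text!r}") from None


def read_peptide_table(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> Dataset:
    """Load and validate a peptide identification TSV.

    Duplicate (sequence, fraction) rows collapse to one observation keeping
    the row with the maximum score (rows without a score lose ties).
    Empty cells in the optional columns mean "missing"; completion is
    deferred to :func:`fill_missing`.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for mandatory in (dialect.sequence, dialect.fraction):
        if mandatory not in frame.columns:
            raise TableFormatError(f"mandatory column {mandatory!r} missing from {path}")

    best: dict[tuple[str, int], PeptideObservation] = {}
    order: list[tuple[str, int]] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # 1-based, after the header
        record = dict(zip(frame.columns, row))
        seq = str(record[dialect.sequence]).strip().upper()
        frac_text = str(record[dialect.fraction]).strip()
        try:
            fraction = int(frac_text)
        except ValueError:
            raise RowError(line, f"non-numeric fraction value {frac_text!r}") from None
        try:
            obs = PeptideObservation(
                sequence=seq,
                fraction=fraction,
                pI=_parse_optional_float(record.get(dialect.pI), line, "pI"),
                mw=_parse_optional_float(record.get(dialect.mw), line, "mw"),
                score=_parse_optional_float(record.get(dialect.score), line, "score"),
            )
        except RowError:
            raise
        except ValueError as exc:
            raise RowError(line, str(exc)) from None
        key = (obs.sequence, obs.fraction)
        if key not in best:
            best[key] = obs
            order.append(key)
        else:
            old = best[key].score
            new = obs.score
            if (old is None and new is not None) or (
                old is not None and new is not None and new > old
            ):
                best[key] = obs
    return Dataset(observations=tuple(best[k] for k in order))


def read_fraction_ranges(path: str | Path) -> list[FractionRange]:
    """Load the expected pH range table: three columns fraction/ph_low/ph_high.

    Rows may appear in any order; the result is sorted by fraction index.
    Duplicate fraction indices and inverted bounds are rejected, and after
    sorting the lower bounds must be non-decreasing (a gradient runs one way).
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if frame.shape[1] < 3:
        raise TableFormatError(f"fraction-range table {path} needs three columns")
    ranges: list[FractionRange] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        try:
            ranges.append(FractionRange(int(row[0]), float(row[1]), float(row[2])))
        except ValueError as exc:
            raise RowError(line, str(exc)) from None
    seen = [r.fraction for r in ranges]
    dupes = {f for f in seen if seen.count(f) > 1}
    if dupes:
        raise TableFormatError(f"duplicate fraction indices in range table: {sorted(dupes)}")
    ranges.sort(key=lambda r: r.fraction)
    lows = [r.ph_low for r in ranges]
    if any(b < a for a, b in zip(lows, lows[1:])):
        raise TableFormatError("fraction pH lower bounds must be non-decreasing along the gradient")
    return ranges


def write_fraction_ranges(ranges: Sequence[FractionRange], path: str | Path) -> None:
    """Write the range table in the same TSV dialect read_fraction_ranges expects."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fraction\tph_low\tph_high\n")
        for r in sorted(ranges, key=lambda r: r.fraction):
            fh.write(f"{r.fraction}\t{r.ph_low!r}\t{r.ph_high!r}\n")


def fill_missing(
    ds: Dataset,
    pka: PkaTable = physchem.DEFAULT_PKA,
    mass_mode: str = "monoisotopic",
) -> Dataset:
    """Complete absent pI / molecular-weight values by local computation.

    User-supplied values are never overwritten; every observation of the
    same sequence receives the identical computed value, so the operation
    is idempotent.  A user-supplied pI more than 0.5 pH from the computed
    one is logged (the two may come from different pKa sets).
    """
    pi_cache: dict[str, float] = {}
    mw_cache: dict[str, float] = {}

    def computed_pi(seq: str) -> float:
        if seq not in pi_cache:
            pi_cache[seq] = physchem.isoelectric_point(seq, pka)
        return pi_cache[seq]

    def computed_mw(seq: str) -> float:
        if seq not in mw_cache:
            mw_cache[seq] = physchem.molecular_weight(seq, mass_mode)
        return mw_cache[seq]

    new_obs = []
    for obs in ds.observations:
        pI = obs.pI if obs.pI is not None else computed_pi(obs.sequence)
        mw = obs.mw if obs.mw is not None else computed_mw(obs.sequence)
        if obs.pI is not None and abs(obs.pI - computed_pi(obs.sequence)) > 0.5:
            log.warning(
                "supplied pI %.2f for %s deviates from computed %.2f by more than 0.5 pH",
                obs.pI, obs.sequence, computed_pi(obs.sequence),
            )
        if pI is obs.pI and mw is obs.mw:
            new_obs.append(obs)
        else:
            new_obs.append(replace(obs, pI=pI, mw=mw))
    return replace(ds, observations=tuple(new_obs))


_SUMMARY_COLUMNS = ["sequence", "fractions", "n_span", "pI", "mw", "score", "flat_range", "gravy"]


def write_summary_table(summaries: Sequence, path: str | Path) -> None:
    """Export one row per distinct peptide as TSV.

    The fractions cell is a comma-joined ascending list ("6,7,8,23,24").
    Floats are written with repr so a read-back reproduces them exactly.
    """
    if not summaries:
        raise ValueError("refusing to write an empty summary table")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            score = "" if s.score is None else repr(float(s.score))
            fh.write(
                f"{s.sequence}\t{','.join(str(f) for f in s.fractions)}\t{s.n_span}\t"
                f"{float(s.pI)!r}\t{float(s.mw)!r}\t{score}\t"
                f"{float(s.flat_range)!r}\t{float(s.gravy)!r}\n"
            )


def read_summary_table(path: str | Path) -> list:
    """Read back a summary TSV written by :func:`write_summary_table`."""
    from .physchem import PeptideSummary

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"summary table {path} lacks columns {missing}")
    out = []
    for row in frame.itertuples(index=False):
        rec = dict(zip(frame.columns, row))
        out.append(
            PeptideSummary(
                sequence=rec["sequence"],
                fractions=tuple(int(f) for f in rec["fractions"].split(",")),
                pI=float(rec["pI"]),
                mw=float(rec["mw"]),
                score=float(rec["score"]) if rec["score"].strip() else None,
                flat_range=float(rec["flat_range"]),
                gravy=float(rec["gravy"]),
            )
        )
    return out


def write_peptide_table(ds: Dataset, path: str | Path) -> None:
    """Write observations in the default peptide-table dialect (round-trippable)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sequence\tfraction\tpI\tmw\tscore\n")
        for o in ds.observations:
            cells = [
                o.sequence,
                str(o.fraction),
                "" if o.pI is None else repr(float(o.pI)),
                "" if o.mw is None else repr(float(o.mw)),
                "" if o.score is None else repr(float(o.score)),
            ]
            fh.write("\t".join(cells) + "\n")
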