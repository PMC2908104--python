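"""Peptide charge physicochemistry.

Net charge as a function of pH is modelled with the Henderson-Hasselbalch
equation, summing over the free N-terminus, the free C-terminus and every
ionizable side chain (D, E, C, Y, H, K, R):

    Q(pH) = sum_basic 1 / (1 + 10**(pH - pKa))
          - sum_acidic 1 / (1 + 10**(pKa - pH))

Basic groups are the N-terminus, H, K and R; acidic groups the C-terminus,
D, E, C and Y.  From this single function the module derives the titration
curve on the fixed pH 1-14 grid (0.1 steps, 131 points), the isoelectric
point (the root of Q), and the flat-charge range -- the length of the pH
interval over which |Q| stays within a small threshold, which predicts how
poorly a peptide focusses in an immobilised pH gradient.

The pKa values are a model choice, not physical constants: the shipped
default is the EMBOSS free-amino-acid set and can be replaced wholesale
via :meth:`PkaTable.from_file`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "PH_GRID",
    "KYTE_DOOLITTLE",
    "PkaTable",
    "TitrationCurve",
    "PeptideSummary",
    "validate_sequence",
    "net_charge",
    "titration_curve",
    "isoelectric_point",
    "flat_range",
    "molecular_weight",
    "gravy",
    "summarise",
]

#: The twenty standard one-letter residue codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Fixed titration grid: pH 1.0, 1.1, ..., 14.0 (131 points).
PH_GRID = np.round(np.arange(10, 141) / 10.0, 1)
PH_GRID.setflags(write=False)

#: Kyte-Doolittle hydropathy scale (dimensionless, per residue).
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

_EMBOSS_SIDE_PKA: Mapping[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
}

_BASIC_RESIDUES = frozenset("HKR")
_ACIDIC_RESIDUES = frozenset("CDEY")


def validate_sequence(sequence: str) -> str:
    """Return ``sequence`` if it is a non-empty plain one-letter string.

    Raises ``ValueError`` naming the first illegal character otherwise.
    Modified-residue annotations are deliberately rejected; sequences must
    already be stripped to the 20 standard residues.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    for ch in sequence:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"illegal residue character {ch!r} in sequence {sequence!r}")
    return sequence


@dataclass(frozen=True)
class PkaTable:
    """Acid dissociation constants for the charge model.

    ``ionize_cysteine`` controls whether C contributes an acidic group;
    switch it off for carbamidomethylated (alkylated) samples where the
    thiol is blocked.
    """

    pka_nterm: float = 8.6
    pka_cterm: float = 3.6
    pka_side: Mapping[str, float] = field(default_factory=lambda: dict(_EMBOSS_SIDE_PKA))
    ionize_cysteine: bool = True

    def __post_init__(self) -> None:
        values = [self.pka_nterm, self.pka_cterm, *self.pka_side.values()]
        for v in values:
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa value {v} outside the open interval (0, 14)")
        missing = set(_EMBOSS_SIDE_PKA) - set(self.pka_side)
        if missing:
            raise ValueError(f"pka_side is missing ionizable residues: {sorted(missing)}")

    @property
    def basic_residues(self) -> frozenset[str]:
        return _BASIC_RESIDUES

    @property
    def acidic_residues(self) -> frozenset[str]:
        if self.ionize_cysteine:
            return _ACIDIC_RESIDUES
        return _ACIDIC_RESIDUES - {"C"}

    def groups(self, sequence: str) -> tuple[np.ndarray, np.ndarray]:
        """pKa arrays of the (basic, acidic) groups of ``sequence``.

        Multiplicity matters: each occurrence of an ionizable residue
        contributes one group; the free termini always contribute one each.
        """
        validate_sequence(sequence)
        counts = Counter(sequence)
        basic = [self.pka_nterm]
        acidic = [self.pka_cterm]
        for res in self.basic_residues:
            basic.extend([self.pka_side[res]] * counts.get(res, 0))
        for res in self.acidic_residues:
            acidic.extend([self.pka_side[res]] * counts.get(res, 0))
        return np.asarray(basic, dtype=float), np.asarray(acidic, dtype=float)

    @classmethod
    def from_file(cls, path: str | Path) -> "PkaTable":
        """Load a table from a YAML/JSON key-value file.

        Recognised keys: ``nterm``, ``cterm``, the seven one-letter
        ionizable residue codes, and ``ionize_cysteine``.  Keys that are
        omitted keep their default value.
        """
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"pKa config {path} must be a key-value mapping")
        side = dict(_EMBOSS_SIDE_PKA)
        kwargs: dict = {}
        for key, value in raw.items():
            key = str(key)
            if key == "nterm":
                kwargs["pka_nterm"] = float(value)
            elif key == "cterm":
                kwargs["pka_cterm"] = float(value)
            elif key == "ionize_cysteine":
                kwargs["ionize_cysteine"] = bool(value)
            elif key.upper() in side:
                side[key.upper()] = float(value)
            else:
                raise ValueError(f"unknown pKa config key {key!r}")
        return cls(pka_side=side, **kwargs)


#: Module-wide default charge model.
DEFAULT_PKA = PkaTable()


def _charge_of_groups(ph: np.ndarray, basic: np.ndarray, acidic: np.ndarray) -> np.ndarray:
    ph = np.atleast_1d(np.asarray(ph, dtype=float))
    pos = (1.0 / (1.0 + 10.0 ** (ph[:, None] - basic[None, :]))).sum(axis=1)
    neg = (1.0 / (1.0 + 10.0 ** (acidic[None, :] - ph[:, None]))).sum(axis=1)
    return pos - neg


def net_charge(sequence: str, ph: float, pka: PkaTable = DEFAULT_PKA) -> float:
    """Net charge of ``sequence`` at ``ph``, in elementary-charge units."""
    basic, acidic = pka.groups(sequence)
    return float(_charge_of_groups(np.array([ph]), basic, acidic)[0])


@dataclass(frozen=True)
class TitrationCurve:
    """Net charge sampled on the fixed pH 1-14 grid (0.1 steps)."""

    ph_grid: np.ndarray
    charge: np.ndarray

    def __post_init__(self) -> None:
        if self.ph_grid.shape != (131,) or self.charge.shape != (131,):
            raise ValueError("titration curve must have exactly 131 grid points")


def titration_curve(sequence: str, pka: PkaTable = DEFAULT_PKA) -> TitrationCurve:
    """Net charge of ``sequence`` on the 131-point pH grid.

    The curve is non-increasing in pH: raising pH only deprotonates.
    """
    basic, acidic = pka.groups(sequence)
    charge = _charge_of_groups(PH_GRID, basic, acidic)
    charge.setflags(write=False)
    return TitrationCurve(ph_grid=PH_GRID, charge=charge)


def isoelectric_point(sequence: str, pka: PkaTable = DEFAULT_PKA, tol: float = 1e-4) -> float:
    """The pH at which the net charge of ``sequence`` is zero.

    Solved by bisection on the continuous (not gridded) charge function
    over (0, 14).  Q is strictly positive at pH 0 (the basic groups are
    protonated) and strictly negative at pH 14, and monotone non-increasing,
    so the bracket always holds.  The bisection runs to a width of
    ``min(tol, 1e-11)`` pH so that the returned root also satisfies
    ``|Q(pI)| < 1e-6`` for any realistic number of ionizable groups.
    """
    basic, acidic = pka.groups(sequence)

    def q(ph: float) -> float:
        return float(_charge_of_groups(np.array([ph]), basic, acidic)[0])

    lo, hi = 0.0, 14.0
    width = min(tol, 1e-11)
    while hi - lo > width:
        mid = 0.5 * (lo + hi)
        if q(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def flat_range(curve: TitrationCurve, threshold: float = 0.01) -> float:
    """Length (pH units) of the grid region where ``|charge| <= threshold``.

    Uses the grid-count convention: 0.1 times the number of qualifying
    points of the 131-point curve.  A threshold that admits every point
    therefore yields 13.1, not 13.0.  Wide flat ranges flag peptides that
    focus poorly because their charge barely responds to pH near the pI.
    """
    if threshold <= 0:
        raise ValueError("flat-range threshold must be positive")
    count = int(np.count_nonzero(np.abs(curve.charge) <= threshold))
    return count / 10.0


def molecular_weight(sequence: str, mode: str = "monoisotopic") -> float:
    """Peptide mass in daltons (residue masses plus one water)."""
    validate_sequence(sequence)
    if mode not in ("monoisotopic", "average"):
        raise ValueError(f"mass mode must be 'monoisotopic' or 'average', got {mode!r}")
    from pyteomics import mass as _mass

    return float(_mass.calculate_mass(sequence=sequence, average=(mode == "average")))


def gravy(sequence: str, scale: Mapping[str, float] = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathy: mean per-residue scale value."""
    validate_sequence(sequence)
    return float(sum(scale[ch] for ch in sequence) / len(sequence))


def _runs(fractions: Sequence[int]) -> tuple[int, ...]:
    """Lengths of maximal runs of consecutive indices in a sorted sequence."""
    runs: list[int] = []
    for i, f in enumerate(fractions):
        if i and f == fractions[i - 1] + 1:
            runs[-1] += 1
        else:
            runs.append(1)
    return tuple(runs)


@dataclass(frozen=True)
class PeptideSummary:
    """One distinct peptide with its fraction footprint and physchem parameters.

    ``n_span`` is the number of distinct fractions the peptide was seen in
    ("unique" means n_span == 1); ``runs`` decomposes the fraction set into
    maximal contiguous stretches.
    """

    sequence: str
    fractions: tuple[int, ...]
    pI: float
    mw: float
    score: float | None
    flat_range: float
    gravy: float

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("a peptide summary needs at least one fraction")
        if list(self.fractions) != sorted(set(self.fractions)):
            raise ValueError("fractions must be strictly increasing")

    @property
    def n_span(self) -> int:
        return len(self.fractions)

    @property
    def runs(self) -> tuple[int, ...]:
        return _runs(self.fractions)

    @property
    def is_unique(self) -> bool:
        return self.n_span == 1

    @property
    def is_contiguous(self) -> bool:
        return len(self.runs) == 1


def summarise(dataset, pka: PkaTable = DEFAULT_PKA, threshold: float = 0.01) -> list[PeptideSummary]:
    """Collapse a completed dataset into one summary per distinct sequence.

    Requires every observation to carry pI and mw (run
    :func:`pepfrac.tables_io.fill_missing` first).  The score is the best
    over the peptide's observations; pI/mw are taken from the best-scoring
    observation.  The flat-charge range and GRAVY are computed here, once
    per sequence.
    """
    if not dataset.observations:
        raise ValueError("cannot summarise an empty dataset")
    by_seq: dict[str, list] = {}
    for obs in dataset.observations:
        by_seq.setdefault(obs.sequence, []).append(obs)

    summaries: list[PeptideSummary] = []
    for seq in sorted(by_seq):
        group = by_seq[seq]
        missing = [o for o in group if o.pI is None or o.mw is None]
        if missing:
            raise ValueError(
                f"observation of {seq!r} lacks pI/mw; run fill_missing before summarise"
            )
        best = max(group, key=lambda o: (-math.inf if o.score is None else o.score))
        scores = [o.score for o in group if o.score is not None]
        fr = flat_range(titration_curve(seq, pka), threshold)
        summaries.append(
            PeptideSummary(
                sequence=seq,
                fractions=tuple(sorted({o.fraction for o in group})),
                pI=best.pI,
                mw=best.mw,
                score=max(scores) if scores else None,
                flat_range=fr,
                gravy=gravy(seq),
            )
        )
    return summaries
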