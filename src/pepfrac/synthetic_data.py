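"""Reproducible synthetic fractionation datasets.

No public peptide-level identification dataset accompanies the focussing
experiment this package diagnoses, so test data are generated: random
proteins are digested in silico with trypsin, and each peptide is
deposited into the wells of a simulated pH 3-10 gradient.

The carry-over model is deliberately simple and is a test harness, not a
physical model of electrophoresis: a peptide's apparent pI is its computed
pI plus Gaussian noise, and it is observed in every fraction whose pH
interval intersects the window

    [apparent_pI - w, apparent_pI + w],   w = spread_alpha * flat_range / 2.

This encodes the mechanism the tool exists to expose -- peptides with flat
charge-vs-pH curves around their pI focus poorly and bleed into
neighbouring fractions -- so pipeline-level tests can check that the
statistics recover it.  Peptides whose window misses the gradient entirely
accumulate in the nearest end well, as they do in the physical device.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import physchem
from .physchem import PkaTable
from .tables_io import Dataset, FractionRange, PeptideObservation

__all__ = [
    "SimConfig",
    "GroundTruth",
    "random_proteins",
    "tryptic_digest",
    "fraction_edges",
    "simulate_fractionation",
    "simulate_dataset",
]

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated fractionation run.

    Defaults emulate a 24-well pH 3-10 run: ``spread_alpha`` couples the
    flat-charge-range parameter to carry-over width (0 = perfect
    focussing), ``noise_sigma`` is the pH error between computed and
    apparent pI.
    """

    n_proteins: int = 50
    n_fractions: int = 24
    ph_low: float = 3.0
    ph_high: float = 10.0
    spread_alpha: float = 0.5
    noise_sigma: float = 0.1
    seed: int = 0
    length_range: tuple[int, int] = (150, 400)
    missed_cleavages: int = 0
    min_peptide_length: int = 6
    score_range: tuple[float, float] = (20.0, 100.0)

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("need at least two fractions")
        if self.spread_alpha < 0 or self.noise_sigma < 0:
            raise ValueError("spread_alpha and noise_sigma must be non-negative")
        if not self.ph_low < self.ph_high:
            raise ValueError("ph_low must be below ph_high")


@dataclass(frozen=True)
class GroundTruth:
    """Per-peptide generative record kept for recovery tests."""

    sequence: str
    true_pI: float
    apparent_pI: float
    flat_range: float
    half_width: float
    fractions: tuple[int, ...]


def random_proteins(
    n: int,
    length_range: tuple[int, int] = (150, 400),
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Uniform-residue random protein sequences, reproducible under seed."""
    if n < 1:
        raise ValueError("need at least one protein")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    return ["".join(rng.choice(_RESIDUES, size=L)) for L in lengths]


def _cleavage_fragments(protein: str) -> list[str]:
    """Zero-missed-cleavage tryptic fragments: cut after K/R, not before P."""
    physchem.validate_sequence(protein)
    cuts = [0]
    for i, ch in enumerate(protein[:-1]):
        if ch in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    return [protein[a:b] for a, b in zip(cuts, cuts[1:])]


def tryptic_digest(
    protein: str, missed_cleavages: int = 0, min_length: int = 6
) -> list[str]:
    """In-silico trypsin digest (cleave C-terminal to K/R except before P).

    With m missed cleavages every join of up to m+1 consecutive fragments
    is included.  Peptides shorter than ``min_length`` are filtered from
    the returned set; pass ``min_length=0`` to keep everything (the
    zero-missed-cleavage fragments then concatenate back to the protein).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    frags = _cleavage_fragments(protein)
    peptides: list[str] = []
    for m in range(missed_cleavages + 1):
        for i in range(len(frags) - m):
            peptides.append("".join(frags[i : i + m + 1]))
    return [p for p in peptides if len(p) >= min_length]


def fraction_edges(cfg: SimConfig) -> np.ndarray:
    """Even partition of [ph_low, ph_high] into n_fractions intervals."""
    return np.linspace(cfg.ph_low, cfg.ph_high, cfg.n_fractions + 1)


def expected_ranges(cfg: SimConfig) -> list[FractionRange]:
    edges = fraction_edges(cfg)
    return [
        FractionRange(i + 1, float(edges[i]), float(edges[i + 1]))
        for i in range(cfg.n_fractions)
    ]


def _window_fractions(a: float, b: float, edges: np.ndarray) -> tuple[int, ...]:
    """1-based fractions whose pH interval meets [a, b]; empty if off-gradient.

    A zero-width window (a == b) resolves by half-open membership so a
    point lands in exactly one fraction; a positive window uses open
    interval overlap, so touching an edge alone does not spread a peptide.
    """
    n = len(edges) - 1
    if a == b:
        if a < edges[0] or a > edges[-1]:
            return ()
        idx = int(np.searchsorted(edges, a, side="right")) - 1
        return (min(max(idx, 0), n - 1) + 1,)
    hits = [i + 1 for i in range(n) if edges[i] < b and a < edges[i + 1]]
    return tuple(hits)


def simulate_fractionation(
    peptides: Sequence[str],
    cfg: SimConfig,
    pka: PkaTable = physchem.DEFAULT_PKA,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Dataset, list[GroundTruth]]:
    """Deposit peptides into fractions under the pI-window carry-over model.

    Returns the observation dataset (with true pI/mw left blank so the
    pipeline's completion step is exercised downstream) and the per-peptide
    ground truth for recovery tests.  Duplicate input sequences are
    collapsed; scores are drawn uniformly per observation.
    """
    if not peptides:
        raise ValueError("simulate_fractionation needs at least one peptide")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    edges = fraction_edges(cfg)
    distinct = list(dict.fromkeys(peptides))

    pI_cache: dict[str, tuple[float, float]] = {}
    observations: list[PeptideObservation] = []
    truths: list[GroundTruth] = []
    for seq in distinct:
        if seq not in pI_cache:
            pi = physchem.isoelectric_point(seq, pka)
            fr = physchem.flat_range(physchem.titration_curve(seq, pka))
            pI_cache[seq] = (pi, fr)
        pi, fr = pI_cache[seq]
        apparent = pi + (rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 0.0)
        w = cfg.spread_alpha * fr / 2.0
        hits = _window_fractions(apparent - w, apparent + w, edges)
        if not hits:
            # off-gradient: accumulate in the nearest end well
            hits = (1,) if apparent < edges[0] else (cfg.n_fractions,)
        for f in hits:
            score = float(rng.uniform(*cfg.score_range))
            observations.append(PeptideObservation(sequence=seq, fraction=f, score=score))
        truths.append(
            GroundTruth(
                sequence=seq,
                true_pI=pi,
                apparent_pI=apparent,
                flat_range=fr,
                half_width=w,
                fractions=hits,
            )
        )
    ds = Dataset(observations=tuple(observations), ranges=tuple(expected_ranges(cfg)))
    return ds, truths


def simulate_dataset(
    cfg: SimConfig, pka: PkaTable = physchem.DEFAULT_PKA
) -> tuple[Dataset, list[GroundTruth]]:
    """End-to-end convenience: proteins -> tryptic peptides -> fractionation."""
    rng = np.random.default_rng(cfg.seed)
    proteins = random_proteins(cfg.n_proteins, cfg.length_range, rng)
    peptides: list[str] = []
    for p in proteins:
        peptides.extend(tryptic_digest(p, cfg.missed_cleavages, cfg.min_peptide_length))
    return simulate_fractionation(peptides, cfg, pka, rng)
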