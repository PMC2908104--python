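import numpy as np
import pytest

from pepfrac.physchem import PeptideSummary
from pepfrac.tables_io import Dataset, PeptideObservation

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_summary(sequence, fractions, pI=7.0, mw=1000.0, score=50.0,
                 flat_range=0.1, gravy=0.0):
    """Build a PeptideSummary with placeholder physchem values."""
    return PeptideSummary(
        sequence=sequence, fractions=tuple(sorted(fractions)),
        pI=pI, mw=mw, score=score, flat_range=flat_range, gravy=gravy,
    )


def random_peptides(n, rng, min_len=5, max_len=30):
    lengths = rng.integers(min_len, max_len + 1, size=n)
    letters = np.array(list(ALPHABET))
    return ["".join(rng.choice(letters, size=L)) for L in lengths]


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_dataset():
    """Three peptides over three fractions with everything supplied."""
    obs = (
        PeptideObservation("PEPTIDEK", 1, pI=4.2, mw=900.0, score=40.0),
        PeptideObservation("PEPTIDEK", 2, pI=4.2, mw=900.0, score=55.0),
        PeptideObservation("ACDKGGR", 1, pI=5.9, mw=700.0, score=60.0),
        PeptideObservation("HHKWR", 3, pI=10.5, mw=760.0, score=30.0),
    )
    return Dataset(observations=obs)


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, header, rows):
        path = tmp_path / name
        lines = ["\t".join(header)] + ["\t".join(str(c) for c in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
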