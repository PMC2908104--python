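"""Charge model, pI, flat-charge range, mass and hydropathy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepfrac import physchem
from pepfrac.physchem import (
    DEFAULT_PKA,
    KYTE_DOOLITTLE,
    PH_GRID,
    PkaTable,
    flat_range,
    gravy,
    isoelectric_point,
    molecular_weight,
    net_charge,
    summarise,
    titration_curve,
)
from pepfrac.tables_io import Dataset, PeptideObservation

from conftest import ALPHABET, make_summary, random_peptides

peptides = st.text(alphabet=ALPHABET, min_size=1, max_size=30)


class TestNetCharge:
    def test_glycine_at_ph1_matches_two_term_hand_evaluation(self):
        # Only the two termini ionize: Q = 1/(1+10^(1-pKa_N)) - 1/(1+10^(pKa_C-1))
        expected = 1.0 / (1.0 + 10.0 ** (1.0 - DEFAULT_PKA.pka_nterm)) \
            - 1.0 / (1.0 + 10.0 ** (DEFAULT_PKA.pka_cterm - 1.0))
        assert net_charge("G", 1.0) == pytest.approx(expected, abs=1e-12)

    def test_group_contributes_half_charge_at_its_pka(self):
        # At pH = pKa(N-term) the N-terminus contributes exactly +0.5.
        q = net_charge("G", DEFAULT_PKA.pka_nterm)
        acid = 1.0 / (1.0 + 10.0 ** (DEFAULT_PKA.pka_cterm - DEFAULT_PKA.pka_nterm))
        assert q == pytest.approx(0.5 - acid, abs=1e-12)

    @pytest.mark.parametrize("ph", [2.0, 5.0, 7.0, 9.0, 12.0])
    def test_polylysine_more_positive_than_polyaspartate(self, ph):
        assert net_charge("KKKKK", ph) > net_charge("DDDDD", ph)

    def test_rejects_illegal_residue(self):
        with pytest.raises(ValueError, match="illegal residue"):
            net_charge("PEPTIDEX1", 7.0)

    def test_bounded_by_group_counts(self):
        # DDK: basic groups = {Nterm, K}, acidic = {Cterm, D, D}
        for ph in np.linspace(0.5, 13.5, 27):
            q = net_charge("DDK", ph)
            assert -3.0 <= q <= 2.0


class TestTitrationCurve:
    def test_grid_is_ph_1_to_14_in_tenths(self):
        curve = titration_curve("GAS")
        assert curve.ph_grid.shape == (131,)
        assert curve.ph_grid[0] == 1.0
        assert curve.ph_grid[-1] == 14.0
        assert np.allclose(np.diff(curve.ph_grid), 0.1)

    def test_matches_pointwise_net_charge(self):
        curve = titration_curve("G")
        for ph, q in zip(curve.ph_grid[::13], curve.charge[::13]):
            assert q == pytest.approx(net_charge("G", float(ph)), abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seq=peptides)
    def test_curve_non_increasing_and_endpoints_ordered(self, seq):
        curve = titration_curve(seq)
        assert np.all(np.diff(curve.charge) <= 1e-12)
        assert curve.charge[0] > curve.charge[-1]


class TestIsoelectricPoint:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seq=peptides)
    def test_charge_vanishes_at_pi(self, seq):
        pi = isoelectric_point(seq)
        assert abs(net_charge(seq, pi)) < 1e-6

    def test_acidic_peptide_has_lower_pi_than_basic(self):
        assert isoelectric_point("DDDDD") < isoelectric_point("KKKKK")

    def test_agrees_with_brute_force_grid_argmin(self, rng):
        grid = np.arange(0.0, 14.0005, 0.001)
        for seq in random_peptides(40, rng):
            basic, acidic = DEFAULT_PKA.groups(seq)
            q = (1 / (1 + 10 ** (grid[:, None] - basic))).sum(1) \
                - (1 / (1 + 10 ** (acidic - grid[:, None]))).sum(1)
            brute = grid[np.argmin(np.abs(q))]
            assert isoelectric_point(seq) == pytest.approx(brute, abs=0.01)

    def test_adding_basic_residue_never_lowers_pi(self, rng):
        for seq in random_peptides(10, rng):
            pi = isoelectric_point(seq)
            assert isoelectric_point(seq + "K") >= pi - 1e-9
            assert isoelectric_point(seq + "D") <= pi + 1e-9


class TestFlatRange:
    def test_saturating_threshold_gives_13_1(self):
        curve = titration_curve("GASP")
        assert flat_range(curve, threshold=1e3) == 13.1

    def test_equals_grid_count_for_basic_peptide(self):
        curve = titration_curve("KKKKR")
        expected = sum(1 for q in curve.charge if abs(q) <= 0.01) / 10.0
        assert flat_range(curve, 0.01) == expected

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seq=peptides, threshold=st.floats(1e-4, 2.0))
    def test_equals_independent_count_and_monotone(self, seq, threshold):
        curve = titration_curve(seq)
        count = int(np.sum(np.abs(np.asarray(curve.charge)) <= threshold))
        assert flat_range(curve, threshold) == count / 10.0
        assert flat_range(curve, threshold * 2) >= flat_range(curve, threshold)

    def test_rejects_nonpositive_threshold(self):
        curve = titration_curve("GAS")
        with pytest.raises(ValueError):
            flat_range(curve, 0.0)


class TestMolecularWeight:
    def test_glycine_monoisotopic_from_elemental_composition(self):
        # Glycine free amino acid is C2 H5 N O2
        masses = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196}
        expected = 2 * masses["C"] + 5 * masses["H"] + masses["N"] + 2 * masses["O"]
        assert molecular_weight("G") == pytest.approx(expected, abs=1e-4)

    def test_appending_glycine_adds_residue_mass(self, rng):
        glycine_residue = molecular_weight("GG") - molecular_weight("G")
        for seq in random_peptides(5, rng):
            assert molecular_weight(seq + "G") - molecular_weight(seq) == pytest.approx(
                glycine_residue, abs=1e-9
            )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seq=peptides)
    def test_monoisotopic_below_average(self, seq):
        assert molecular_weight(seq, "monoisotopic") < molecular_weight(seq, "average")

    def test_agrees_with_biopython(self, rng):
        from Bio.SeqUtils import molecular_weight as bio_mw

        for seq in random_peptides(10, rng):
            assert molecular_weight(seq) == pytest.approx(
                bio_mw(seq, seq_type="protein", monoisotopic=True), rel=1e-5
            )

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError):
            molecular_weight("G", "nominal")


class TestGravy:
    @pytest.mark.parametrize("res", list(ALPHABET))
    def test_homopolymer_equals_scale_value(self, res):
        assert gravy(res * 7) == pytest.approx(KYTE_DOOLITTLE[res], abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seq=peptides)
    def test_reversal_invariant_and_matches_lookup_mean(self, seq):
        assert gravy(seq) == pytest.approx(gravy(seq[::-1]), abs=1e-12)
        assert gravy(seq) == pytest.approx(
            sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq), abs=1e-12
        )

    def test_agrees_with_biopython_protparam(self, rng):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        for seq in random_peptides(10, rng):
            assert gravy(seq) == pytest.approx(ProteinAnalysis(seq).gravy(), abs=1e-9)


class TestPkaTable:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            PkaTable(pka_nterm=15.0)

    def test_cysteine_switch_changes_acidic_groups(self):
        free = PkaTable(ionize_cysteine=True)
        blocked = PkaTable(ionize_cysteine=False)
        assert "C" in free.acidic_residues
        assert "C" not in blocked.acidic_residues
        # Alkylated cysteines no longer pull charge down at high pH.
        assert net_charge("CCCK", 10.0, blocked) > net_charge("CCCK", 10.0, free)

    def test_from_file_overrides_and_validates(self, tmp_path):
        cfg = tmp_path / "pka.yaml"
        cfg.write_text("nterm: 9.0\nK: 10.0\nionize_cysteine: false\n")
        table = PkaTable.from_file(cfg)
        assert table.pka_nterm == 9.0
        assert table.pka_side["K"] == 10.0
        assert not table.ionize_cysteine
        cfg.write_text("bogus_key: 1.0\n")
        with pytest.raises(ValueError, match="bogus_key"):
            PkaTable.from_file(cfg)


class TestSummarise:
    def _dataset(self, spec):
        obs = []
        for seq, fracs in spec.items():
            for f in fracs:
                obs.append(PeptideObservation(seq, f, pI=5.0, mw=800.0, score=float(f)))
        return Dataset(observations=tuple(obs))

    def test_single_fraction_peptide_is_unique(self):
        [s] = summarise(self._dataset({"GGK": [5]}))
        assert s.n_span == 1 and s.runs == (1,) and s.is_unique

    def test_gapped_twelve_span_decomposes_into_runs(self):
        fractions = list(range(6, 16)) + [23, 24]
        [s] = summarise(self._dataset({"VADIGLAAWGR": fractions}))
        assert s.n_span == 12
        assert s.runs == (10, 2)
        assert not s.is_contiguous

    def test_contiguous_three_span(self):
        [s] = summarise(self._dataset({"GGK": [2, 3, 4]}))
        assert s.n_span == 3 and s.runs == (3,) and s.is_contiguous

    def test_score_is_best_over_observations(self, tiny_dataset):
        summaries = {s.sequence: s for s in summarise(tiny_dataset)}
        assert summaries["PEPTIDEK"].score == 55.0

    def test_runs_sum_to_span(self, rng):
        for _ in range(20):
            fracs = sorted(rng.choice(24, size=rng.integers(1, 9), replace=False) + 1)
            [s] = summarise(self._dataset({"GGK": list(fracs)}))
            assert sum(s.runs) == s.n_span == len(fracs)

    def test_requires_completed_dataset(self):
        ds = Dataset(observations=(PeptideObservation("GGK", 1),))
        with pytest.raises(ValueError, match="fill_missing"):
            summarise(ds)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            summarise(Dataset(observations=()))
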