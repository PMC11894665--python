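"""Fragment prediction, USI/ProForma round trips, peak matching, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfoscan import (
    Modification,
    PsmRecord,
    SpectrumInterpretation,
    Usi,
    alternative_interpretations,
    build_usi,
    compare_hypotheses,
    match_peaks,
    original_interpretation,
    parse_proforma,
    parse_usi,
    theoretical_fragments,
)
from sulfoscan.constants import (
    MODIFICATION_MASSES,
    PHOSPHO_MASS,
    PROTON_MASS,
    RESIDUE_MASSES,
    SULFO_PHOSPHO_DELTA,
    WATER_MASS,
)
from sulfoscan.simulate import generate_spectrum


def interp(seq, mods, charge=2):
    return SpectrumInterpretation(seq, tuple(mods), charge)


def sulfo(pos, res="Y"):
    return Modification(pos, res, "Sulfo", MODIFICATION_MASSES["Sulfo"])


def phospho(pos, res="Y"):
    return Modification(pos, res, "Phospho", MODIFICATION_MASSES["Phospho"])


class TestFragments:
    def test_labile_sulfo_fragments_match_unmodified(self):
        frag = {
            (t, i, z): mz for t, i, z, mz in theoretical_fragments(interp("AY", [sulfo(2)]))
        }
        y1_expected = RESIDUE_MASSES["Y"] + WATER_MASS + PROTON_MASS
        assert frag[("y", 1, 1)] == pytest.approx(y1_expected, abs=1e-6)
        bare = {
            (t, i, z): mz for t, i, z, mz in theoretical_fragments(interp("AY", []))
        }
        assert frag == pytest.approx(bare)

    def test_retained_phospho_shifts_spanning_fragments(self):
        frag = {
            (t, i, z): mz
            for t, i, z, mz in theoretical_fragments(interp("AY", [phospho(2)]))
        }
        y1_expected = RESIDUE_MASSES["Y"] + WATER_MASS + PROTON_MASS + PHOSPHO_MASS
        assert frag[("y", 1, 1)] == pytest.approx(y1_expected, abs=1e-6)
        # b1 does not span the site: unshifted
        assert frag[("b", 1, 1)] == pytest.approx(
            RESIDUE_MASSES["A"] + PROTON_MASS, abs=1e-6
        )

    def test_precursor_mass_delta_is_constant(self):
        s = interp("PEPTYDEK", [sulfo(5)])
        p = interp("PEPTYDEK", [phospho(5)])
        assert p.precursor_neutral_mass() - s.precursor_neutral_mass() == pytest.approx(
            SULFO_PHOSPHO_DELTA
        )
        assert p.precursor_mz() - s.precursor_mz() == pytest.approx(
            SULFO_PHOSPHO_DELTA / 2
        )

    def test_nonspanning_fragments_identical_between_hypotheses(self):
        s = theoretical_fragments(interp("PEPTYDEK", [sulfo(5)]))
        p = theoretical_fragments(interp("PEPTYDEK", [phospho(5)]))
        for (t1, i1, z1, mz1), (t2, i2, z2, mz2) in zip(s, p):
            spans = (t1 == "b" and i1 >= 5) or (t1 == "y" and i1 > 3)
            if spans:
                assert mz2 - mz1 == pytest.approx(PHOSPHO_MASS / z1, abs=1e-9)
            else:
                assert mz1 == mz2

    def test_fragment_charges_capped(self):
        zs = {z for _, _, z, _ in theoretical_fragments(interp("PEPTYDEK", [], charge=3))}
        assert zs == {1, 2}
        zs1 = {z for _, _, z, _ in theoretical_fragments(interp("PEPTYDEK", [], charge=1))}
        assert zs1 == {1}


class TestMatchPeaks:
    def test_most_intense_within_tolerance_wins(self):
        theo = [("b", 1, 1, 100.00)]
        ann = match_peaks([(100.02, 80.0), (99.98, 100.0)], theo, 0.05, 2)
        assert ann.matches[0][4] == 99.98

    def test_tie_broken_by_mz_closeness(self):
        theo = [("b", 1, 1, 100.00)]
        ann = match_peaks([(100.03, 50.0), (99.99, 50.0)], theo, 0.05, 2)
        assert ann.matches[0][4] == 99.99

    def test_outside_tolerance_no_match(self):
        ann = match_peaks([(100.06, 50.0)], [("b", 1, 1, 100.00)], 0.05, 2)
        assert ann.matches == []
        assert ann.tic_fraction_annotated == 0.0

    def test_empty_peak_list(self):
        ann = match_peaks([], [("b", 1, 1, 100.0)], 0.05, 2)
        assert ann.matches == [] and ann.tic_fraction_annotated == 0.0

    def test_order_invariance(self):
        theo = theoretical_fragments(interp("PEPTYDEK", [phospho(5)]))
        peaks = generate_spectrum(interp("PEPTYDEK", [phospho(5)]), "retained", seed=1)
        shuffled = list(peaks)
        np.random.default_rng(0).shuffle(shuffled)
        a = match_peaks(peaks, theo, 0.05, 8)
        b = match_peaks(shuffled, theo, 0.05, 8)
        assert a.tic_fraction_annotated == b.tic_fraction_annotated
        assert sorted(a.matches) == sorted(b.matches)

    def test_noiseless_self_consistency(self):
        si = interp("SAYDEGHK", [sulfo(3)])
        peaks = generate_spectrum(si, "full-neutral-loss", noise_fraction=0.0, seed=0)
        ann = match_peaks(peaks, theoretical_fragments(si), 0.05, 8)
        assert ann.tic_fraction_annotated == pytest.approx(1.0)
        assert ann.residues_supported == pytest.approx(1.0)


class TestVerdicts:
    def _pair(self):
        return interp("SAYDEGHK", [sulfo(3)]), interp("SAYDEGHK", [phospho(3)])

    def test_full_neutral_loss_spectrum_favors_sulfo(self):
        si, pi = self._pair()
        peaks = generate_spectrum(si, "full-neutral-loss", noise_fraction=0.05, seed=3)
        assert compare_hypotheses(peaks, si, pi).verdict == "sulfo-favored"

    def test_retained_spectrum_favors_phospho(self):
        si, pi = self._pair()
        peaks = generate_spectrum(pi, "retained", noise_fraction=0.05, seed=4)
        assert compare_hypotheses(peaks, si, pi).verdict == "phospho-favored"

    def test_no_peaks_inconclusive(self):
        si, pi = self._pair()
        assert compare_hypotheses([], si, pi).verdict == "inconclusive"

    def test_mismatched_hypotheses_rejected(self):
        si, _ = self._pair()
        with pytest.raises(ValueError):
            compare_hypotheses([], si, interp("SAYDEGHR", [phospho(3)]))


class TestAlternativeInterpretations:
    def _psm(self, seq, mods, charge=2):
        return PsmRecord("PXD1", "D", "E", "r1", 9, seq, mods, charge, 0.0, 0.001)

    def test_py_rewritten_to_sulfo(self):
        psm = self._psm("VHNDAQSFDYDHDAFLGAEEAK", [phospho(7, "S"), phospho(10, "Y")])
        (alt,) = alternative_interpretations(psm)
        assert alt.proforma == "VHNDAQS[Phospho]FDY{Sulfo}DHDAFLGAEEAK"

    def test_pt_moved_to_lowest_index_tyrosine(self):
        # phospho originally parked on a threonine; the rewrite removes it
        # and sulfates the tyrosine
        psm = self._psm("ELEHNAEETYGENDK", [phospho(9, "T")])
        (alt,) = alternative_interpretations(psm)
        names = {(m.position, m.name) for m in alt.modifications}
        assert names == {(10, "Sulfo")}

    def test_double_sulfation_variant_emitted(self):
        psm = self._psm("AYDYEK", [phospho(2), phospho(4)])
        alts = alternative_interpretations(psm)
        assert len(alts) == 2
        n_sulfo = [sum(m.name == "Sulfo" for m in a.modifications) for a in alts]
        assert n_sulfo == [1, 2]

    def test_deamidated_refused(self):
        psm = self._psm(
            "ANYSDK",
            [phospho(3), Modification(2, "N", "Deamidated")],
        )
        with pytest.raises(ValueError, match="not assessed"):
            alternative_interpretations(psm)

    def test_no_tyrosine_refused(self):
        psm = self._psm("ASDSDK", [phospho(2, "S")])
        with pytest.raises(ValueError, match="no tyrosine"):
            alternative_interpretations(psm)

    def test_seeded_random_strategy_reproducible(self):
        psm = self._psm("TYAYEK", [phospho(1, "T")])
        a = alternative_interpretations(psm, strategy="seeded-random", seed=5)
        b = alternative_interpretations(psm, strategy="seeded-random", seed=5)
        assert a == b


class TestUsi:
    def _psm(self):
        return PsmRecord(
            "PXD000561",
            "D",
            "E",
            "Adult_Frontalcortex_bRP_Elite_85_f09",
            17555,
            "VHNDAQSFDYDHDAFLGAEEAK",
            [phospho(7, "S"), phospho(10, "Y")],
            2,
            0.0,
            0.001,
        )

    def test_original_usi_golden_string(self):
        psm = self._psm()
        usi = build_usi(psm, original_interpretation(psm))
        assert usi == (
            "mzspec:PXD000561:Adult_Frontalcortex_bRP_Elite_85_f09:scan:17555:"
            "VHNDAQS[Phospho]FDY[Phospho]DHDAFLGAEEAK/2"
        )

    def test_sulfo_alternative_differs_only_in_tag(self):
        psm = self._psm()
        orig = build_usi(psm, original_interpretation(psm))
        (alt,) = alternative_interpretations(psm)
        assert build_usi(psm, alt) == orig.replace("Y[Phospho]", "Y{Sulfo}")

    def test_parse_serialize_round_trip(self):
        psm = self._psm()
        u = Usi(psm.collection_id, psm.run_id, psm.scan_number, original_interpretation(psm))
        assert parse_usi(u.serialize()) == u

    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=15),
        charge=st.integers(1, 4),
        scan=st.integers(1, 10_000_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_round_trip_random_fixtures(self, seq, charge, scan):
        mods = []
        if "Y" in seq:
            pos = seq.index("Y") + 1
            mods.append(sulfo(pos))
        u = Usi("PXD1", "run_01", scan, SpectrumInterpretation(seq, tuple(mods), charge))
        assert parse_usi(u.serialize()) == u

    def test_proforma_round_trip_with_nterm_mod(self):
        i = interp("AYK", [Modification(0, "", "Carbamidomethyl"), sulfo(2)])
        seq, mods = parse_proforma(i.proforma)
        assert seq == "AYK"
        assert SpectrumInterpretation(seq, mods, 2).proforma == i.proforma

    def test_missing_identifier_is_error(self):
        psm = self._psm()
        psm.collection_id = ""
        with pytest.raises(ValueError, match="collection_id"):
            build_usi(psm, original_interpretation(psm))
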