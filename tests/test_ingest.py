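"""PSM table reading, FDR filtering, recalibration, phospho filtering."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfoscan import (
    Modification,
    PsmRecord,
    filter_fdr,
    filter_phospho,
    read_psm_table,
    recalibrate,
    write_psm_table,
)
from sulfoscan.ingest import PsmTableError, parse_mods


def make_psm(**kw) -> PsmRecord:
    defaults = dict(
        collection_id="PXD1",
        dataset_id="DS1",
        experiment_id="E1",
        run_id="r1",
        scan_number=1,
        peptide_sequence="PEPSYR",
        modifications=[],
        charge=2,
        mass_error_raw=0.0,
        q_value=0.001,
    )
    defaults.update(kw)
    return PsmRecord(**defaults)


class TestParsing:
    def test_mod_string_round_trip_on_doubly_phosphorylated_peptide(self):
        mods = parse_mods("7-S-Phospho;10-Y-Phospho")
        assert [(m.position, m.residue, m.name) for m in mods] == [
            (7, "S", "Phospho"),
            (10, "Y", "Phospho"),
        ]
        # consistent with the sequence it belongs to
        make_psm(peptide_sequence="VHNDAQSFDYDHDAFLGAEEAK", modifications=mods)

    def test_empty_mod_string_means_unmodified(self):
        assert parse_mods("") == []

    def test_mod_names_normalized_case_insensitively(self):
        assert parse_mods("1-P-phospho")[0].name == "Phospho"
        assert parse_mods("1-P-NotARealMod")[0].name == "NotARealMod"

    def test_residue_sequence_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            make_psm(modifications=[Modification(1, "S", "Phospho")])


class TestReadWrite:
    def test_empty_file_with_valid_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_psm_table([], p)
        assert read_psm_table(p) == []

    def test_write_read_identity(self, tmp_path):
        records = [
            make_psm(scan_number=i + 1, mass_error_raw=0.001 * i, q_value=0.001 * i)
            for i in range(3)
        ]
        records[1].modifications = parse_mods("5-Y-Phospho")
        records[1].peptide_sequence = "PEPSYR"
        p = tmp_path / "psms.tsv"
        write_psm_table(records, p)
        back = read_psm_table(p)
        assert len(back) == 3
        for a, b in zip(records, back):
            assert a.peptide_sequence == b.peptide_sequence
            assert a.mass_error_raw == b.mass_error_raw
            assert a.q_value == b.q_value
            assert a.modifications == b.modifications

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("collection_id\tsequence\nA\tPEPK\n")
        with pytest.raises(PsmTableError, match="missing required columns"):
            read_psm_table(p)

    def test_bad_rows_collected_not_fatal(self, tmp_path):
        good = make_psm()
        p = tmp_path / "psms.tsv"
        write_psm_table([good, good, good], p)
        text = p.read_text().splitlines()
        text[2] = text[2].replace("PEPSYR", "PEP1YR")  # invalid residue
        p.write_text("\n".join(text) + "\n")
        assert len(read_psm_table(p)) == 2

    def test_dialect_column_remapping(self, tmp_path):
        p = tmp_path / "renamed.tsv"
        write_psm_table([make_psm()], p)
        p.write_text(p.read_text().replace("sequence", "Peptide", 1))
        assert read_psm_table(p, dialect={"sequence": "Peptide"})[0].peptide_sequence == "PEPSYR"


class TestFdrFilter:
    def test_strict_inequality_at_threshold(self):
        records = [make_psm(q_value=q) for q in (0.005, 0.01, 0.02)]
        kept = filter_fdr(records, 0.01)
        assert [r.q_value for r in kept] == [0.005]

    def test_threshold_one_keeps_all_below_one(self):
        records = [make_psm(q_value=q) for q in (0.0, 0.5, 0.999)]
        assert len(filter_fdr(records, 1.0)) == 3

    def test_empty_input(self):
        assert filter_fdr([]) == []

    @given(
        qs=st.lists(st.floats(0, 1), max_size=30),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, qs, t1, t2):
        records = [make_psm(q_value=q) for q in qs]
        lo, hi = sorted([t1, t2])
        kept_lo = {id(r) for r in filter_fdr(records, lo)}
        kept_hi = {id(r) for r in filter_fdr(records, hi)}
        assert kept_lo <= kept_hi


class TestRecalibration:
    def test_median_subtraction_single_run(self):
        recs = [make_psm(mass_error_raw=e) for e in (0.001, 0.003, 0.002)]
        out = recalibrate(recs)
        assert [r.mass_error_calibrated for r in out] == pytest.approx(
            [-0.001, 0.001, 0.0]
        )

    def test_per_run_offsets_cancel(self):
        base = [0.0001, -0.0003, 0.0008, 0.0002, -0.0005]
        recs = [
            make_psm(run_id="A", mass_error_raw=e + 0.004) for e in base
        ] + [make_psm(run_id="B", mass_error_raw=e - 0.006) for e in base]
        out = recalibrate(recs)
        a = [r.mass_error_calibrated for r in out if r.run_id == "A"]
        b = [r.mass_error_calibrated for r in out if r.run_id == "B"]
        assert a == pytest.approx(b)

    def test_singleton_run_gets_zero(self):
        (out,) = recalibrate([make_psm(mass_error_raw=0.007)])
        assert out.mass_error_calibrated == 0.0

    def test_idempotent_and_difference_preserving(self):
        rng = np.random.default_rng(0)
        recs = [
            make_psm(run_id=f"r{i % 3}", mass_error_raw=float(e))
            for i, e in enumerate(rng.normal(0, 0.003, 30))
        ]
        once = recalibrate(recs)
        twice = recalibrate(
            [
                make_psm(run_id=r.run_id, mass_error_raw=r.mass_error_calibrated)
                for r in once
            ]
        )
        for r1, r2 in zip(once, twice):
            assert r2.mass_error_calibrated == pytest.approx(
                r1.mass_error_calibrated, abs=1e-12
            )
        # within-run differences preserved exactly
        for run in ("r0", "r1", "r2"):
            raws = [r.mass_error_raw for r in recs if r.run_id == run]
            cals = [r.mass_error_calibrated for r in once if r.run_id == run]
            assert np.diff(raws) == pytest.approx(np.diff(cals), abs=1e-12)

    def test_per_run_median_of_calibrated_errors_is_zero(self, default_build):
        """On the synthetic build with Uniform(-0.01, 0.01) run offsets, the
        per-run median of calibrated errors is 0 to within 1e-12."""
        out = recalibrate(default_build.psms)
        by_run = {}
        for r in out:
            by_run.setdefault(r.run_id, []).append(r.mass_error_calibrated)
        for run, vals in by_run.items():
            assert abs(statistics.median(vals)) < 1e-12, run


class TestPhosphoFilter:
    @pytest.mark.parametrize(
        "mods,kept",
        [
            ("1-M-Oxidation", False),
            ("5-Y-Phospho", True),
            ("4-S-Phospho", True),
            ("3-T-Phospho", True),
            ("", False),
        ],
    )
    def test_rule(self, mods, kept):
        r = make_psm(peptide_sequence="MSTSYK", modifications=parse_mods(mods))
        assert (len(filter_phospho([r])) == 1) is kept

    def test_phospho_on_nonstandard_residue_dropped(self):
        r = make_psm(
            peptide_sequence="MHSTYK",
            modifications=[Modification(2, "H", "Phospho")],
        )
        assert filter_phospho([r]) == []
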