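import math

import pytest

from proteoquant.errors import DuplicateEntryError, FormatError, UnknownProteinError
from proteoquant.psm_io import (
    PSM,
    average_mass_kda,
    filter_psms,
    infer_proteins,
    read_fasta_db,
    read_psm_table,
    write_psm_table,
)

from conftest import make_psm, make_record


class TestReadFastaDb:
    def test_single_glycine_record_mass(self, tmp_path):
        """Average residue mass of G plus one water: (57.05 + 18.02)/1000 kDa."""
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">P1 tiny\nG\n")
        (record,) = read_fasta_db(fasta)
        assert record.protein_id == "P1"
        assert record.molecular_mass_kDa == pytest.approx(0.07507, rel=1e-3)

    def test_empty_file_gives_empty_list(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text("")
        assert read_fasta_db(fasta) == []

    def test_duplicate_header_is_error_naming_id(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">P1\nGG\n>P1\nAA\n")
        with pytest.raises(DuplicateEntryError, match="P1"):
            read_fasta_db(fasta)

    def test_non_amino_acid_character_reports_position(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">P1\nGAB\n")
        with pytest.raises(FormatError, match="position 3"):
            read_fasta_db(fasta)

    def test_mass_scales_with_sequence(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">P1\nGGGG\n>P2\nGG\n")
        p1, p2 = read_fasta_db(fasta)
        # four vs two residues: residue masses add, water counted once
        assert p1.molecular_mass_kDa > p2.molecular_mass_kDa
        assert p1.molecular_mass_kDa - p2.molecular_mass_kDa == pytest.approx(
            2 * 0.05705, rel=1e-3
        )


class TestReadPsmTable:
    HEADER = "spectrum_id\tpeptide\tprotein_ids\tlog_expectation\tconfidence"

    def test_intensity_row_parsed(self, tmp_path):
        table = tmp_path / "psms.tsv"
        table.write_text(
            self.HEADER + "\ti114\ti115\ti116\ti117\n"
            "s1\tPEPTIDEK\tP1\t-3.0\t0.9995\t100\t100\t200\t200\n"
        )
        (psm,) = read_psm_table(table)
        assert psm.reporter_intensities == {"114": 100, "115": 100, "116": 200, "117": 200}

    def test_multiple_protein_ids_split_on_semicolon(self, tmp_path):
        table = tmp_path / "psms.tsv"
        table.write_text(self.HEADER + "\ns1\tPEPK\tCthe_0423;Cthe_0101\t-2\t0.999\n")
        (psm,) = read_psm_table(table)
        assert psm.protein_ids == ("Cthe_0423", "Cthe_0101")
        assert psm.is_shared

    def test_missing_mandatory_column_named(self, tmp_path):
        table = tmp_path / "psms.tsv"
        table.write_text("spectrum_id\tprotein_ids\tlog_expectation\tconfidence\ns\tP\t-2\t1\n")
        with pytest.raises(FormatError, match="peptide"):
            read_psm_table(table)

    def test_blank_intensity_cell_becomes_zero(self, tmp_path):
        table = tmp_path / "psms.tsv"
        table.write_text(
            self.HEADER + "\ti114\ti115\ti116\ti117\n" "s1\tPEPK\tP1\t-2\t\t\t50\t60\t70\n"
        )
        (psm,) = read_psm_table(table)
        assert psm.reporter_intensities["114"] == 0.0
        assert psm.confidence is None

    def test_non_numeric_intensity_reports_row(self, tmp_path):
        table = tmp_path / "psms.tsv"
        table.write_text(
            self.HEADER + "\ti114\ti115\ti116\ti117\n" "s1\tPEPK\tP1\t-2\t1\toops\t1\t1\t1\n"
        )
        with pytest.raises(FormatError, match="row 1"):
            read_psm_table(table)

    def test_missing_intensity_columns_mean_no_reporters(self, tmp_path):
        table = tmp_path / "psms.tsv"
        table.write_text(self.HEADER + "\ns1\tPEPK\tP1\t-2\t0.999\n")
        (psm,) = read_psm_table(table)
        assert psm.reporter_intensities is None

    def test_roundtrip_through_writer(self, tmp_path, small_simulation):
        _, _, _, psms = small_simulation
        path = tmp_path / "out.tsv"
        write_psm_table(psms[:50], path)
        back = read_psm_table(path)
        assert len(back) == 50
        assert back[3].peptide == psms[3].peptide
        for channel in ("114", "115", "116", "117"):
            assert back[3].reporter_intensities[channel] == pytest.approx(
                psms[3].reporter_intensities[channel]
            )


class TestFilterPsms:
    @pytest.mark.parametrize(
        "log_e,kept",
        [(-2.0, True), (-1.5, False), (-1.4, False), (-1.6, True)],
    )
    def test_strict_threshold(self, log_e, kept):
        psms = [make_psm(log_expectation=log_e)]
        assert (len(filter_psms(psms)) == 1) is kept

    def test_empty_input(self):
        assert filter_psms([]) == []

    def test_idempotent_and_order_preserving(self, small_simulation):
        _, _, _, psms = small_simulation
        once = filter_psms(psms)
        assert filter_psms(once) == once
        indices = [psms.index(p) for p in once[:20]]
        assert indices == sorted(indices)


class TestInferProteins:
    def records(self):
        return [make_record("P1"), make_record("P2")]

    def test_single_peptide_not_detected_despite_many_spectra(self):
        psms = [make_psm(f"s{i}", "AAAK", ("P1",)) for i in range(10)]
        assert infer_proteins(psms, self.records()) == []

    def test_two_peptides_detected_with_spectral_count(self):
        psms = [
            make_psm("s1", "AAAK", ("P1",)),
            make_psm("s2", "AAAK", ("P1",)),
            make_psm("s3", "CCCK", ("P1",)),
        ]
        (d,) = infer_proteins(psms, self.records())
        assert d.spectral_count == 3
        assert d.n_distinct_peptides == 2
        assert not d.shared_only

    def test_shared_peptide_counts_toward_both_proteins(self):
        """Three-peptide toy: one shared, one unique each; brute-force
        enumeration of the grouping rule says both detected with the shared
        spectrum counted twice."""
        psms = [
            make_psm("s1", "SHAREDK", ("P1", "P2")),
            make_psm("s2", "UNIQAK", ("P1",)),
            make_psm("s3", "UNIQBK", ("P2",)),
        ]
        detected = infer_proteins(psms, self.records())
        assert [d.protein_id for d in detected] == ["P1", "P2"]
        assert all(d.spectral_count == 2 for d in detected)
        assert all(not d.shared_only for d in detected)

    def test_unique_only_policy_drops_shared_spectra(self):
        psms = [
            make_psm("s1", "SHAREDK", ("P1", "P2")),
            make_psm("s2", "UNIQAK", ("P1",)),
            make_psm("s3", "UNIQBK", ("P1",)),
        ]
        detected = infer_proteins(psms, self.records(), shared_policy="unique-only")
        (d,) = detected
        assert d.protein_id == "P1"
        assert d.spectral_count == 2

    def test_confidence_threshold_uses_best_member(self):
        psms = [
            make_psm("s1", "AAAK", ("P1",), confidence=0.9),
            make_psm("s2", "CCCK", ("P1",), confidence=0.9995),
        ]
        assert len(infer_proteins(psms, self.records())) == 1
        low = [
            make_psm("s1", "AAAK", ("P1",), confidence=0.9),
            make_psm("s2", "CCCK", ("P1",), confidence=0.99),
        ]
        assert infer_proteins(low, self.records()) == []

    def test_unknown_protein_reference_is_error(self):
        psms = [make_psm("s1", "AAAK", ("P9",))]
        with pytest.raises(UnknownProteinError, match="P9"):
            infer_proteins(psms, self.records())

    def test_permutation_invariance_and_unique_conservation(self, small_simulation):
        _, records, _, psms = small_simulation
        forward = infer_proteins(psms, records)
        backward = infer_proteins(list(reversed(psms)), records)
        assert [(d.protein_id, d.spectral_count) for d in forward] == [
            (d.protein_id, d.spectral_count) for d in backward
        ]
        # conservation: unique-peptide spectra are counted exactly once
        unique_psms = [p for p in psms if not p.is_shared]
        unique_counts = sum(
            sum(1 for p in d.member_psms if not p.is_shared) for d in forward
        )
        detected_ids = {d.protein_id for d in forward}
        expected = sum(1 for p in unique_psms if p.protein_ids[0] in detected_ids)
        assert unique_counts == expected


class TestPSMValidation:
    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError, match="empty peptide"):
            PSM("s1", "", ("P1",), -2.0)

    def test_partial_reporter_map_rejected(self):
        with pytest.raises(ValueError, match="missing channels"):
            PSM("s1", "PEPK", ("P1",), -2.0, reporter_intensities={"114": 1.0})

    def test_record_mass_consistency_enforced(self):
        with pytest.raises(ValueError, match="disagrees"):
            make_record("P1").__class__(
                protein_id="P1", sequence="GGG", molecular_mass_kDa=99.0
            )
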