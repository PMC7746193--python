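import math

import pytest

from waldscan import (
    CodingSequence,
    Domain,
    ProteinAnnotation,
    VariantRecord,
    classify_snv,
    column_position_map,
    read_cds_fasta,
    read_msa,
    read_score_matrix,
    read_variant_table,
    slice_by_domain,
)
from waldscan.core import (
    FormatError,
    ScoreMatrix,
    write_cds_fasta,
    write_msa,
    write_score_matrix,
    write_variant_table,
)

from _oracles import SENSE_CODONS, classify_oracle


class TestClassifySnv:
    def test_agrees_with_brute_force_on_all_sense_codons(self):
        for codon in SENSE_CODONS:
            for offset in range(3):
                for alt in "ACGT":
                    if alt == codon[offset]:
                        continue
                    assert classify_snv(codon, offset, alt) == classify_oracle(
                        codon, offset, alt
                    ), (codon, offset, alt)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            classify_snv("TAA", 0, "C")

    def test_same_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            classify_snv("ATG", 0, "A")


class TestAnnotation:
    def test_domain_length(self):
        dom = Domain("phos", 146, 337)
        assert dom.length == 192

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ProteinAnnotation(
                "p", 100, (Domain("a", 1, 50), Domain("b", 50, 80))
            )

    def test_domain_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            ProteinAnnotation("p", 100, (Domain("a", 90, 101),))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            Domain("a", 10, 5)


class TestReadMsa:
    def test_two_record_identity_fixture(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">ref\nACDE\n>other\nACDE\n")
        aln = read_msa(path, "ref")
        assert aln.n_columns == 4
        assert aln.ids == ("ref", "other")

    def test_ragged_alignment_is_format_error(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">ref\nACDE\n>other\nACDEF\n")
        with pytest.raises(FormatError):
            read_msa(path, "ref")

    def test_missing_reference_is_lookup_error(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nACDE\n>b\nACDE\n")
        with pytest.raises(KeyError):
            read_msa(path, "ref")

    def test_illegal_symbol_is_alphabet_error(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">ref\nAC1E\n>b\nACDE\n")
        with pytest.raises(FormatError):
            read_msa(path, "ref")

    def test_generated_msa_round_trips(self, tmp_path, default_dataset):
        aln = default_dataset.alignment
        path = tmp_path / "msa.fasta"
        write_msa(aln, path)
        again = read_msa(path, aln.reference_id)
        assert again == aln
        first = path.read_bytes()
        write_msa(again, path)
        assert path.read_bytes() == first


class TestColumnPositionMap:
    def test_gapless_identity(self, aln_factory):
        aln = aln_factory(["ACD", "ACD"])
        assert column_position_map(aln) == {1: 1, 2: 2, 3: 3}

    def test_gap_skipping(self, aln_factory):
        aln = aln_factory(["A-C", "AAC"])
        assert column_position_map(aln) == {1: 1, 3: 2}

    def test_all_gap_reference(self, aln_factory):
        aln = aln_factory(["---", "AAC"])
        assert column_position_map(aln) == {}

    def test_mapped_positions_strictly_increasing(self, default_dataset):
        mapping = column_position_map(default_dataset.alignment)
        values = [mapping[c] for c in sorted(mapping)]
        assert values == sorted(set(values))
        assert len(values) == default_dataset.alignment.reference_length


class TestCodingSequence:
    def test_codon_indexing(self):
        cds = CodingSequence("ATGGCTTGG")
        assert cds.codon(1) == "ATG"
        assert cds.codon(3) == "TGG"
        assert cds.protein == "MAW"

    def test_internal_stop_rejected(self):
        with pytest.raises(FormatError, match="stop"):
            CodingSequence("ATGTAAGCT")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(FormatError):
            CodingSequence("ATGA")

    def test_fasta_round_trip(self, tmp_path, default_dataset):
        path = tmp_path / "cds.fasta"
        write_cds_fasta(default_dataset.cds, path)
        assert read_cds_fasta(path) == default_dataset.cds


class TestReadVariantTable:
    HEADER = "cds_pos\tref_nt\talt_nt\tallele_count\thom_count\n"

    def test_consequence_from_codon_table(self, tmp_path):
        cds = CodingSequence("ATGGCT")
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER + "1\tA\tG\t5\t0\n")
        table = read_variant_table(path, cds)
        assert len(table) == 1
        record = table.records[0]
        assert record.consequence == "missense"  # ATG -> GTG, Met -> Val
        assert record.protein_pos == 1

    def test_empty_table(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER)
        table = read_variant_table(path, CodingSequence("ATGGCT"))
        assert len(table) == 0
        assert table.n_rejected == 0

    def test_ref_mismatch_rejected_with_count(self, tmp_path):
        cds = CodingSequence("ATGGCT")
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER + "1\tC\tG\t5\t0\n1\tA\tG\t5\t0\n")
        table = read_variant_table(path, cds)
        assert len(table) == 1
        assert table.n_rejected == 1

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("cds_pos\tref_nt\talt_nt\tallele_count\n1\tA\tG\t5\n")
        with pytest.raises(FormatError, match="hom_count"):
            read_variant_table(path, CodingSequence("ATGGCT"))

    def test_non_numeric_count_is_parse_error(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER + "1\tA\tG\tmany\t0\n")
        with pytest.raises(FormatError):
            read_variant_table(path, CodingSequence("ATGGCT"))

    def test_multiallelic_site_kept_as_separate_records(self, tmp_path):
        cds = CodingSequence("ATGGCT")
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER + "1\tA\tG\t5\t0\n1\tA\tC\t2\t0\n")
        table = read_variant_table(path, cds)
        assert len(table) == 2

    def test_round_trip(self, tmp_path, default_dataset):
        path = tmp_path / "v.tsv"
        write_variant_table(default_dataset.variants, path)
        table = read_variant_table(path, default_dataset.cds)
        assert table.records == default_dataset.variants.records


class TestVariantRecord:
    def test_hom_count_cannot_exceed_allele_count(self):
        with pytest.raises(ValueError):
            VariantRecord(1, "A", "G", "missense", 1, 1, 2)


class TestScoreMatrix:
    def test_constant_matrix_means(self, tmp_path):
        protein = "MAW"
        header = "pos\t" + "\t".join("ACDEFGHIKLMNPQRSTVWY") + "\n"
        rows = []
        for pos, ref_aa in enumerate(protein, start=1):
            cells = ["NA" if aa == ref_aa else "50.0" for aa in "ACDEFGHIKLMNPQRSTVWY"]
            rows.append(f"{pos}\t" + "\t".join(cells) + "\n")
        path = tmp_path / "s.tsv"
        path.write_text(header + "".join(rows))
        matrix = read_score_matrix(path, protein)
        assert matrix.position_means() == {1: 50.0, 2: 50.0, 3: 50.0}

    def test_out_of_range_score_rejected(self, tmp_path):
        protein = "M"
        header = "pos\t" + "\t".join("ACDEFGHIKLMNPQRSTVWY") + "\n"
        cells = ["NA" if aa == "M" else "101" for aa in "ACDEFGHIKLMNPQRSTVWY"]
        path = tmp_path / "s.tsv"
        path.write_text(header + "1\t" + "\t".join(cells) + "\n")
        with pytest.raises(ValueError):
            read_score_matrix(path, protein)

    def test_row_count_mismatch_is_consistency_error(self, tmp_path, default_dataset):
        path = tmp_path / "s.tsv"
        write_score_matrix(default_dataset.matrix, path)
        from waldscan.core import ConsistencyError

        with pytest.raises(ConsistencyError):
            read_score_matrix(path, default_dataset.protein + "A")

    def test_generated_matrix_round_trips(self, tmp_path, default_dataset):
        path = tmp_path / "s.tsv"
        write_score_matrix(default_dataset.matrix, path)
        matrix = read_score_matrix(path, default_dataset.protein)
        assert matrix.scores == dict(default_dataset.matrix.scores)
        first = path.read_bytes()
        write_score_matrix(matrix, path)
        assert path.read_bytes() == first

    def test_wrong_entry_count_rejected(self):
        from waldscan.core import ConsistencyError

        with pytest.raises(ConsistencyError):
            ScoreMatrix("p", {1: {"A": 50.0}})


class TestSliceByDomain:
    def test_phosphatase_domain_has_192_positions(self):
        series = {pos: float(pos) for pos in range(1, 522)}
        sliced = slice_by_domain(series, Domain("phos", 146, 337), 521)
        assert len(sliced) == 192

    def test_kinase_domain_has_181_positions(self):
        series = {pos: float(pos) for pos in range(1, 522)}
        sliced = slice_by_domain(series, Domain("kin", 341, 521), 521)
        assert len(sliced) == 181

    def test_single_residue_slice(self):
        series = {pos: float(pos) for pos in range(1, 11)}
        sliced = slice_by_domain(series, Domain("d", 5, 5))
        assert list(sliced.index) == [5]
        assert sliced.loc[5] == 5.0

    def test_out_of_bounds_domain_raises(self):
        series = {pos: float(pos) for pos in range(1, 11)}
        with pytest.raises(IndexError):
            slice_by_domain(series, Domain("d", 5, 15), protein_length=10)

    def test_missing_positions_dropped(self):
        series = {1: 1.0, 3: 3.0, 4: 4.0}
        sliced = slice_by_domain(series, Domain("d", 1, 3))
        assert list(sliced.index) == [1, 3]
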