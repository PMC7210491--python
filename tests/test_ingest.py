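"""Parsing and restructuring: HGVS grammar, vocabularies, blocks, batch ETL."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnrs import (
    KeyManager,
    ParseError,
    SchemaError,
    etl_batch,
    normalize_allele_frequency,
    normalize_pathogenicity,
    parse_cnv_block,
    parse_fusion_block,
    parse_hgvs,
    parse_variant_block,
    restructure,
)
from cnrs.ingest import RAW_FIELDS, RawReportRecord


class TestHgvs:
    @pytest.mark.parametrize(
        "raw,level,kind,start,end,ref,alt",
        [
            ("c.2573T>G", "c", "substitution", 2573, None, "T", "G"),
            ("c.35G>T", "c", "substitution", 35, None, "G", "T"),
            ("c.376-1G>A", "c", "substitution", 376, None, "G", "A"),
            ("c.2235_2249del", "c", "deletion", 2235, 2249, "", ""),
            ("c.5266dup", "c", "duplication", 5266, None, "", ""),
            ("c.2310_2311insGGT", "c", "insertion", 2310, 2311, "", "GGT"),
            ("c.235_237delinsAA", "c", "delins", 235, 237, "", "AA"),
            ("p.Leu858Arg", "p", "substitution", 858, None, "Leu", "Arg"),
            ("p.Arg213Ter", "p", "substitution", 213, None, "Arg", "Ter"),
            ("p.Glu1257GlyfsTer9", "p", "frameshift", 1257, None, "Glu", ""),
            ("p.Glu746_Ala750del", "p", "deletion", 746, 750, "Glu", ""),
            ("p.Tyr772_Ala775dup", "p", "duplication", 772, 775, "Tyr", ""),
        ],
    )
    def test_supported_kinds(self, raw, level, kind, start, end, ref, alt):
        d = parse_hgvs(raw)
        assert (d.level, d.kind, d.position_start, d.position_end) == (level, kind, start, end)
        assert (d.ref_allele, d.alt_allele) == (ref, alt)
        assert d.raw == raw

    @pytest.mark.parametrize("raw", ["g.12345A>T", "m.100A>G", "12345A>T", ""])
    def test_unsupported_prefixes_rejected(self, raw):
        with pytest.raises(ParseError):
            parse_hgvs(raw)

    def test_lenient_mode_preserves_unrecognized(self):
        d = parse_hgvs("c.oddball99", strict=False)
        assert d.kind == "other" and d.raw == "c.oddball99"
        with pytest.raises(ParseError):
            parse_hgvs("c.oddball99", strict=True)

    @given(
        pos=st.integers(min_value=1, max_value=99999),
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
    )
    @settings(max_examples=50, deadline=None)
    def test_substitution_grammar_roundtrip(self, pos, ref, alt):
        d = parse_hgvs(f"c.{pos}{ref}>{alt}")
        assert d.kind == "substitution"
        assert (d.position_start, d.ref_allele, d.alt_allele) == (pos, ref, alt)


class TestVocabularies:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("Pathogenic", "pathogenic"),
            ("VUS", "uncertain_significance"),
            ("uncertain significance", "uncertain_significance"),
            ("likely  pathogenic", "likely_pathogenic"),
            ("Likely Benign", "likely_benign"),
            ("BENIGN", "benign"),
        ],
    )
    def test_pathogenicity_synonyms(self, term, expected):
        assert normalize_pathogenicity(term) == expected

    def test_unknown_term_strict_vs_lenient(self):
        with pytest.raises(ParseError):
            normalize_pathogenicity("weird tier")
        assert normalize_pathogenicity("weird tier", strict=False) == "uncertain_significance"
        with pytest.raises(ParseError):
            normalize_pathogenicity("")

    @pytest.mark.parametrize(
        "text,expected",
        [("35%", 0.35), ("0.35", 0.35), ("35.0 %", 0.35), ("1", 1.0), ("87", 0.87)],
    )
    def test_allele_frequency_forms(self, text, expected):
        assert normalize_allele_frequency(text) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_allele_frequency_fraction_identity(self, value):
        assert normalize_allele_frequency(repr(value)) == value


VARIANT_LINE = (
    "EGFR; exon 21; c.2573T>G; p.Leu858Arg; NM_005228; 35%; missense; "
    "pathogenic; erlotinib sensitivity"
)
FUSION_LINE = "ALK; chr2; p23.2; 29447000; intron 19; chr2:29447000; −; 12; 8; 20; 0"
CNV_LINE = "EGFR; chr7:55086714-55324313; 0.001; 6; 8; 0.75; 1; 8; 6"


class TestBlocks:
    def test_variant_line_field_mapping(self, panel):
        (rec,) = parse_variant_block(VARIANT_LINE, panel)
        assert rec.gene_name == "EGFR"
        assert rec.exon_id == "exon 21"
        assert rec.dna_change == "c.2573T>G"
        assert rec.protein_change == "p.Leu858Arg"
        assert rec.allele_frequency == pytest.approx(0.35)
        assert rec.variant_effect == "missense"
        assert rec.pathogeny == "pathogenic"
        assert rec.variant_type_code == "snv"

    def test_indel_discriminator(self, panel):
        line = "EGFR; exon 19; c.2235_2249del; p.Glu746_Ala750del; NM_005228; 22%; inframe_indel; pathogenic; "
        (rec,) = parse_variant_block(line, panel)
        assert rec.variant_type_code == "indel"

    def test_empty_blocks_yield_no_records(self, panel):
        assert parse_variant_block("", panel) == []
        assert parse_cnv_block("", panel) == []
        assert parse_fusion_block("\n  \n", panel) == []

    def test_off_panel_gene_strict_vs_lenient(self, panel):
        line = VARIANT_LINE.replace("EGFR", "XYZ99")
        with pytest.raises(ParseError):
            parse_variant_block(line, panel, strict=True)
        assert parse_variant_block(line, panel, strict=False) == []

    def test_duplicate_lines_collapse_to_first(self, panel):
        two = VARIANT_LINE + "\n" + VARIANT_LINE.replace("35%", "40%")
        records = parse_variant_block(two, panel)
        assert len(records) == 1
        assert records[0].allele_frequency == pytest.approx(0.35)

    def test_malformed_line_cites_line_number(self, panel):
        with pytest.raises(ParseError, match="line 2"):
            parse_variant_block(VARIANT_LINE + "\nEGFR; too; few", panel)

    def test_fusion_line_with_unicode_minus(self, panel):
        (rec,) = parse_fusion_block(FUSION_LINE, panel)
        assert rec.gene_strand == "-"
        assert rec.break_point == 29447000
        assert (rec.span_read, rec.split_read, rec.total_read) == (12, 8, 20)

    def test_cnv_line_and_invariant(self, panel):
        (rec,) = parse_cnv_block(CNV_LINE, panel)
        assert rec.region_ratio == pytest.approx(0.75)
        bad = "EGFR; chr7:1-2; 0.001; 5; 4; 1.25; 1; 8; 4"
        with pytest.raises(ParseError):
            parse_cnv_block(bad, panel)


def _raw_record(**overrides):
    data = {f: "" for f in RAW_FIELDS}
    data.update(
        pathology_no="SP00000001",
        patient_no="PT00000001",
        order_date="2018-01-02",
        report_date="2018-01-16",
        cancer_type="lung",
        sample_type="FFPE",
        qc_overall="pass",
        sequencer_model="NextSeq 550",
        panel_name="OncoPanel",
        panel_version="v2",
        pathologist_name="Pathologist A, MD",
        pathologist_license="L-12345",
        ordering_department="Pulmonology",
        snv_indel_block=VARIANT_LINE + "\nKRAS; exon 2; c.35G>T; p.Gly12Val; NM_033360; 12%; missense; pathogenic; ",
        fusion_block=FUSION_LINE,
        cnv_block=CNV_LINE,
        report_status="final",
    )
    data.update(overrides)
    return RawReportRecord.from_row(data)


class TestRestructure:
    def test_fixture_counts_and_discards(self, panel):
        km = KeyManager(seed=3)
        audit = []
        report = restructure(_raw_record(), panel, km, audit_log=audit)
        assert (len(report.variants), len(report.fusions), len(report.cnvs)) == (2, 1, 1)
        # discarded raw fields reach the audit log only
        assert audit[0]["pathologist_license"] == "L-12345"
        assert "L-12345" not in report.model_dump_json()

    def test_no_raw_identifiers_in_output(self, panel):
        km = KeyManager(seed=3)
        report = restructure(_raw_record(), panel, km)
        blob = report.model_dump_json()
        assert "PT00000001" not in blob
        assert "SP00000001" not in blob

    def test_child_keys_linked(self, panel):
        km = KeyManager(seed=3)
        report = restructure(_raw_record(), panel, km)
        rk = report.path_lab.report_key
        assert all(r.report_key == rk for r in report.variants + report.fusions + report.cnvs)
        assert len({r.record_key for r in report.variants + report.fusions + report.cnvs}) == 4

    def test_qc_fail_structured_but_flagged(self, panel):
        km = KeyManager(seed=3)
        report = restructure(_raw_record(qc_overall="fail"), panel, km)
        assert report.path_lab.qc_result == "fail"
        assert report.context["qc_flag"] == "qc_fail"

    def test_date_inversion_rejected(self, panel):
        km = KeyManager(seed=3)
        with pytest.raises(SchemaError):
            restructure(_raw_record(report_date="2017-12-01"), panel, km)

    def test_wrong_field_count_rejected(self):
        with pytest.raises(SchemaError):
            RawReportRecord.from_row(["a"] * 27)
        with pytest.raises(SchemaError):
            RawReportRecord.from_row(["a"] * 29)
        assert len(RAW_FIELDS) == 28


class TestEtlBatch:
    def test_lenient_accounting_conserves_rows(self, panel):
        rows = [_raw_record().to_row() for _ in range(9)]
        bad = _raw_record().to_row()
        bad["report_date"] = "2017-01-01"  # precedes order date
        rows.insert(4, bad)
        frame = pd.DataFrame(rows)
        km = KeyManager(seed=3)
        reports, log = etl_batch(frame, panel, km, mode="lenient")
        assert log.rows_in == 10
        assert log.reports_out == len(reports) == 9
        assert len(log.failures) == 1
        assert log.conserved

    def test_strict_mode_aborts_on_malformed_row(self, panel):
        bad = _raw_record().to_row()
        bad["report_date"] = "2017-01-01"
        km = KeyManager(seed=3)
        with pytest.raises(SchemaError):
            etl_batch(pd.DataFrame([bad]), panel, km, mode="strict")

    def test_empty_table_with_header(self, panel, tmp_path):
        f = tmp_path / "raw.tsv"
        f.write_text("\t".join(RAW_FIELDS) + "\n")
        reports, log = etl_batch(f, panel, KeyManager(seed=3), mode="strict")
        assert reports == [] and log.rows_in == 0 and log.conserved

    def test_missing_header_rejected(self, panel, tmp_path):
        f = tmp_path / "raw.tsv"
        f.write_text("a\tb\n1\t2\n")
        with pytest.raises(SchemaError):
            etl_batch(f, panel, KeyManager(seed=3))
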