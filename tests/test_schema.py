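"""Data-model invariants: panel registry, entity ledger, completeness checker."""

import pytest

from cnrs import (
    SchemaError,
    check_iso_completeness,
    count_schema_entities,
    count_schema_tables,
    load_panel,
    schema_export,
)
from cnrs.schema import (
    ISO_OPTIONAL_CATEGORIES,
    ISO_REQUIRED_CATEGORIES,
    PAPER_NAMED_ENTITIES,
    STRUCTURAL_ENTITIES,
    table_entities,
)

from conftest import EGFR_L858R, make_report


class TestPanelRegistry:
    def test_default_panel_counts(self, panel):
        assert len(panel) == 91
        assert len(panel.genes) == 88
        assert len(panel.category_genes("mandatory")) == 14
        assert len(panel.category_genes("additional")) == 74
        assert panel.category_genes("fusion") == {"ALK", "ROS1", "RET"}

    def test_fusion_genes_duplicate_other_categories(self, panel):
        # fusion-category entries repeat symbols already on the panel
        others = panel.category_genes("mandatory") | panel.category_genes("additional")
        assert panel.category_genes("fusion") <= others
        assert "ALK" in panel.category_genes("mandatory")

    def test_minimal_panel_file(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("gene_symbol\tcategory\nTP53\tmandatory\n")
        p = load_panel(f)
        assert len(p) == 1 and "TP53" in p

    @pytest.mark.parametrize(
        "body",
        [
            "gene_symbol\tcategory\nTP53\toptional\n",  # unknown category
            "gene_symbol\tcategory\nTP53\tmandatory\nTP53\tmandatory\n",  # dup pair
            "",  # empty file
            "gene_symbol\tcategory\n",  # header only
        ],
    )
    def test_invalid_panel_files_rejected(self, tmp_path, body):
        f = tmp_path / "p.tsv"
        f.write_text(body)
        with pytest.raises(SchemaError):
            load_panel(f)


class TestEntityLedger:
    def test_four_tables_49_entities(self):
        assert count_schema_tables() == 4
        assert count_schema_entities() == 49
        assert count_schema_entities(paper_named_only=True) == 38

    def test_named_attribute_counts_per_table(self):
        assert [len(PAPER_NAMED_ENTITIES[t]) for t in
                ("path_lab", "variant_summary", "fusion_variant", "cnv")] == [9, 9, 11, 9]

    def test_structural_entities_by_name(self):
        assert STRUCTURAL_ENTITIES == {
            "path_lab": ("report_key", "alt_subject_key", "cancer_type_code", "panel_id"),
            "variant_summary": ("record_key", "report_key", "variant_type_code"),
            "fusion_variant": ("record_key", "report_key"),
            "cnv": ("record_key", "report_key"),
        }

    def test_models_carry_exactly_the_ledger_columns(self):
        from cnrs.schema import TABLE_MODELS

        for name, model in TABLE_MODELS.items():
            assert tuple(model.model_fields) == table_entities(name)

    def test_schema_export_is_consistent(self):
        doc = schema_export()
        assert doc["table_count"] == 4
        assert sum(len(cols) for cols in doc["tables"].values()) == doc["entity_count"] == 49
        qc = next(c for c in doc["tables"]["path_lab"] if c["entity"] == "qc_result")
        assert qc["vocabulary"] == ["pass", "conditional_pass", "fail"]


class TestIsoCompleteness:
    def test_fully_populated_report_is_complete(self):
        report = make_report(variants=[EGFR_L858R])
        result = check_iso_completeness(report)
        assert result.missing_required == []
        assert tuple(result.required_present) == ISO_REQUIRED_CATEGORIES
        assert tuple(result.optional_present) == ISO_OPTIONAL_CATEGORIES

    def test_empty_treatment_and_references_flagged(self):
        report = make_report(
            variants=[EGFR_L858R], recommended_treatment="", references_text=""
        )
        result = check_iso_completeness(report)
        assert "recommended_treatment" in result.missing_required
        assert result.optional_present["references"] is False

    def test_missing_reporter_flags_performing_laboratory(self):
        report = make_report(variants=[EGFR_L858R], reporter="")
        assert "performing_laboratory" in check_iso_completeness(report).missing_required

    def test_no_findings_without_negative_flag_is_incomplete(self):
        report = make_report(context={"negative_findings": ""})
        assert "genetic_variations" in check_iso_completeness(report).missing_required
        flagged = make_report(context={"negative_findings": "negative"})
        assert "genetic_variations" not in check_iso_completeness(flagged).missing_required

    def test_monotone_adding_fields_never_removes_presence(self):
        sparse = make_report(
            recommended_treatment="", references_text="", reporter="",
            context={"ordering_physician": "", "addendum": "", "reference_genome": ""},
        )
        rich = make_report(variants=[EGFR_L858R])
        before = check_iso_completeness(sparse)
        after = check_iso_completeness(rich)
        for cat, present in before.required_present.items():
            assert not present or after.required_present[cat]
        for cat, present in before.optional_present.items():
            assert not present or after.optional_present[cat]


class TestRecordInvariants:
    def test_report_date_before_order_date_rejected(self):
        with pytest.raises(Exception):
            make_report(report_date="2017-01-01")

    def test_fusion_read_and_locus_consistency(self):
        from conftest import ALK_FUSION

        bad = dict(ALK_FUSION, total_read=5)
        with pytest.raises(Exception):
            make_report(fusions=[bad])
        bad = dict(ALK_FUSION, locus="chr3:29447000")
        with pytest.raises(Exception):
            make_report(fusions=[bad])

    def test_cnv_gain_and_ratio_consistency(self):
        from conftest import EGFR_CNV

        with pytest.raises(Exception):
            make_report(cnvs=[dict(EGFR_CNV, gain_region=9)])
        with pytest.raises(Exception):
            make_report(cnvs=[dict(EGFR_CNV, region_ratio=0.5)])

    def test_child_report_keys_must_match(self):
        from cnrs import StructuredReport, VariantSummaryRecord

        report = make_report(variants=[EGFR_L858R])
        stray = VariantSummaryRecord(**EGFR_L858R, report_key="NCC-OTHERKEY222A")
        with pytest.raises(Exception):
            StructuredReport(
                path_lab=report.path_lab, variants=[stray], fusions=[], cnvs=[]
            )
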