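"""Warehouse queries: cohort selection, frequency counting, clinical linkage."""

import datetime as dt

import pandas as pd
import pytest

from cnrs import (
    ClinicalRecord,
    CnrsError,
    CohortFilter,
    Warehouse,
    export_dataset,
)
from cnrs.errors import LeakError

from conftest import ALK_FUSION, EGFR_CNV, EGFR_L858R, make_report


def _small_store(panel):
    """Five hand-built patients with known findings (brute-force oracle below)."""
    tp53 = dict(EGFR_L858R, gene_name="TP53", dna_change="c.524G>A",
                protein_change="p.Arg175His", clinical_relevance="")
    reports = [
        make_report("NCC-AAAAAAAAAA2A", variants=[EGFR_L858R, tp53],
                    alt_subject_key="NCP-P1AAAAAAAAAA", identifiers="NCC-AAAAAAAAAA2A"),
        make_report("NCC-BBBBBBBBBB2A", variants=[tp53],
                    alt_subject_key="NCP-P2AAAAAAAAAA", cancer_type_code="ovarian"),
        make_report("NCC-CCCCCCCCCC2A", variants=[dict(tp53, allele_frequency=0.2),
                                                  dict(tp53, dna_change="c.743G>A")],
                    alt_subject_key="NCP-P3AAAAAAAAAA", cancer_type_code="ovarian"),
        make_report("NCC-DDDDDDDDDD2A", fusions=[ALK_FUSION],
                    alt_subject_key="NCP-P4AAAAAAAAAA"),
        make_report("NCC-EEEEEEEEEE2A", cnvs=[EGFR_CNV],
                    alt_subject_key="NCP-P5AAAAAAAAAA", cancer_type_code="breast"),
    ]
    clinical = [
        ClinicalRecord(alt_patient_key="NCP-P1AAAAAAAAAA", domain="diagnosis",
                       attributes={"icd10": "C34"}, event_date=dt.date(2017, 1, 1)),
        ClinicalRecord(alt_patient_key="NCP-P1AAAAAAAAAA", domain="death",
                       attributes={}, event_date=dt.date(2017, 1, 31)),
        ClinicalRecord(alt_patient_key="NCP-P2AAAAAAAAAA", domain="diagnosis",
                       attributes={"icd10": "C56"}, event_date=dt.date(2017, 6, 1)),
    ]
    return Warehouse(panel=panel).load(reports, clinical), reports


class TestLoad:
    def test_counts(self, panel):
        wh, _ = _small_store(panel)
        c = wh.counts()
        assert c["path_lab"] == 5 and c["variant_summary"] == 5
        assert c["fusion_variant"] == 1 and c["cnv"] == 1 and c["clinical"] == 3

    def test_duplicate_report_key_rejected(self, panel):
        r = make_report("NCC-AAAAAAAAAA2A", variants=[EGFR_L858R])
        with pytest.raises(CnrsError):
            Warehouse(panel=panel).load([r, r])

    def test_genomic_only_store_valid(self, panel):
        wh = Warehouse(panel=panel).load([make_report(variants=[EGFR_L858R])])
        assert wh.counts()["clinical"] == 0

    def test_raw_id_pattern_refused(self, panel):
        bad = make_report(variants=[dict(EGFR_L858R, clinical_relevance="see PT00118899")])
        with pytest.raises(LeakError):
            Warehouse(panel=panel).load([bad])

    def test_persists_to_sqlite(self, panel, tmp_path):
        import sqlite3

        db = tmp_path / "crdw.db"
        _, reports = _small_store(panel)
        Warehouse(path=db, panel=panel).load(reports)
        with sqlite3.connect(db) as conn:
            n = conn.execute("select count(*) from path_lab").fetchone()[0]
        assert n == 5


class TestQueryCohort:
    def test_empty_filter_returns_everyone(self, panel):
        wh, _ = _small_store(panel)
        assert len(wh.query_cohort(CohortFilter())) == 5

    def test_brute_force_equivalence(self, panel):
        wh, reports = _small_store(panel)
        filt = CohortFilter(genes={"TP53"}, cancer_types={"ovarian"})
        expected = {
            r.path_lab.alt_subject_key
            for r in reports
            if r.path_lab.cancer_type_code == "ovarian"
            and any(v.gene_name == "TP53" for v in r.variants)
        }
        assert set(wh.query_cohort(filt).patients) == expected

    def test_variant_kind_clause(self, panel):
        wh, _ = _small_store(panel)
        assert wh.query_cohort(CohortFilter(variant_types={"fusion"})).patients == [
            "NCP-P4AAAAAAAAAA"
        ]
        assert wh.query_cohort(
            CohortFilter(genes={"EGFR"}, variant_types={"cnv"})
        ).patients == ["NCP-P5AAAAAAAAAA"]

    def test_conjunction_narrows(self, panel):
        wh, _ = _small_store(panel)
        broad = set(wh.query_cohort(CohortFilter(genes={"TP53"})).patients)
        narrow = set(
            wh.query_cohort(CohortFilter(genes={"TP53"}, cancer_types={"ovarian"})).patients
        )
        assert narrow <= broad

    def test_unknown_gene_rejected(self, panel):
        wh, _ = _small_store(panel)
        with pytest.raises(CnrsError, match="XYZ99"):
            wh.query_cohort(CohortFilter(genes={"XYZ99"}))

    def test_deterministic_ordering(self, panel):
        wh, _ = _small_store(panel)
        rows = wh.query_cohort(CohortFilter()).patients
        assert rows == sorted(rows)


class TestMutationFrequency:
    def test_brute_force_tally_small_store(self, panel):
        wh, reports = _small_store(panel)
        table = wh.mutation_frequency(stratify_by_cancer=True)
        # independent per-patient, per-gene tally over the report objects
        tally: dict[tuple[str, str], set[str]] = {}
        strata_members: dict[str, set[str]] = {}
        for r in reports:
            patient = r.path_lab.alt_subject_key
            for stratum in ("all", r.path_lab.cancer_type_code):
                strata_members.setdefault(stratum, set()).add(patient)
                for v in r.variants:  # point mutations only
                    tally.setdefault((stratum, v.gene_name), set()).add(patient)
        for (stratum, gene), patients in tally.items():
            row = table.lookup(stratum, gene)
            assert row["n_patients_with_mutation"] == len(patients)
            assert row["n_patients_in_stratum"] == len(strata_members[stratum])
            assert row["fraction"] == pytest.approx(
                len(patients) / len(strata_members[stratum])
            )

    def test_patient_counted_once_despite_two_variants(self, panel):
        wh, _ = _small_store(panel)
        # patient P3 has two TP53 variants but counts once
        assert wh.mutation_frequency().lookup("ovarian", "TP53")[
            "n_patients_with_mutation"
        ] == 2

    def test_fusions_and_cnvs_excluded_from_point_mutations(self, panel):
        wh, _ = _small_store(panel)
        table = wh.mutation_frequency()
        assert "ALK" not in set(table.frame["gene"])
        counts = wh.finding_counts()
        assert counts == {
            "point_mutation_records": 5, "fusion_records": 1, "cnv_records": 1
        }

    def test_empty_store(self, panel):
        wh = Warehouse(panel=panel).load([])
        assert wh.mutation_frequency().frame.empty


class TestLinkClinical:
    def test_left_join_keeps_patients_without_domain(self, panel):
        wh, _ = _small_store(panel)
        cohort = wh.query_cohort(CohortFilter())
        ds = wh.link_clinical(cohort, {"diagnosis", "death"})
        assert len(ds) == 5
        assert (ds["death_date"] != "").sum() == 1

    def test_survival_days_arithmetic(self, panel):
        wh, _ = _small_store(panel)
        ds = wh.link_clinical(wh.query_cohort(CohortFilter()), {"diagnosis", "death"})
        row = ds[ds["alt_patient_key"] == "NCP-P1AAAAAAAAAA"].iloc[0]
        assert row["survival_days"] == 30  # 2017-01-01 to 2017-01-31

    def test_no_domains_gives_genomic_columns_only(self, panel):
        wh, _ = _small_store(panel)
        ds = wh.link_clinical(wh.query_cohort(CohortFilter()), set())
        assert set(ds.columns) == {
            "alt_patient_key", "cancer_type_code", "report_key", "mutated_genes"
        }

    def test_unknown_domain_rejected(self, panel):
        wh, _ = _small_store(panel)
        with pytest.raises(CnrsError):
            wh.link_clinical(wh.query_cohort(CohortFilter()), {"horoscope"})


class TestExport:
    def test_csv_roundtrip(self, panel, tmp_path):
        wh, _ = _small_store(panel)
        ds = wh.link_clinical(wh.query_cohort(CohortFilter()), {"diagnosis"})
        path = export_dataset(ds, tmp_path / "out.csv")
        back = pd.read_csv(path, dtype=str, keep_default_na=False)
        assert len(back) == len(ds)
        assert list(back.columns) == list(ds.columns)
        assert (tmp_path / "out.csv.dict.json").exists()

    def test_leak_injection_blocks_export(self, tmp_path):
        ds = pd.DataFrame({"note": ["fine", "raw id PT00118899 leaked"]})
        with pytest.raises(LeakError):
            export_dataset(ds, tmp_path / "out.csv")

    def test_empty_needs_flag_and_format_check(self, tmp_path):
        empty = pd.DataFrame(columns=["a"])
        with pytest.raises(CnrsError):
            export_dataset(empty, tmp_path / "x.csv")
        export_dataset(empty, tmp_path / "x.csv", allow_empty=True)
        with pytest.raises(CnrsError):
            export_dataset(pd.DataFrame({"a": [1]}), tmp_path / "x.parquet", format="parquet")
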