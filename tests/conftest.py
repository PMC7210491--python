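import datetime as dt

import pytest

from cnrs import (
    CnvRecord,
    FusionVariantRecord,
    KeyManager,
    PathLabInfo,
    StructuredReport,
    VariantSummaryRecord,
    Warehouse,
    clinical_records_from_frames,
    default_ncc_spec,
    etl_batch,
    generate_cohort,
    load_default_panel,
)


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged study cohort, generated once per session."""
    return generate_cohort(default_ncc_spec(seed=11))


@pytest.fixture(scope="session")
def pipeline(panel, default_cohort):
    """Full run over the default cohort: key manager, reports, warehouse."""
    km = KeyManager(credential="test-credential", seed=11)
    reports, log = etl_batch(default_cohort.raw_table, panel, km, mode="strict")
    clinical = clinical_records_from_frames(km.scrub_and_link(default_cohort.clinical))
    wh = Warehouse(panel=panel).load(reports, clinical)
    return {"keys": km, "reports": reports, "log": log, "warehouse": wh}


def make_report(
    report_key="NCC-TESTKEYAA22A",
    variants=(),
    fusions=(),
    cnvs=(),
    context=None,
    **path_overrides,
):
    """Hand-built structured report for unit tests."""
    path = dict(
        identifiers=report_key,
        test_order_date=dt.date(2018, 1, 2),
        qc_result="pass",
        sample_type="FFPE",
        report_date=dt.date(2018, 1, 16),
        reporter="Pathologist A, MD",
        sequencer_type="NextSeq 550",
        recommended_treatment="EGFR TKI",
        references_text="PMID:25741868",
        report_key=report_key,
        alt_subject_key="NCP-TESTSUBJAA2A",
        cancer_type_code="lung",
        panel_id="OncoPanel v2",
    )
    path.update(path_overrides)
    ctx = {
        "ordering_physician": "Dr. F (oncology)",
        "reference_genome": "GRCh37",
        "addendum": "reviewed",
        "negative_findings": "",
    }
    if context is not None:
        ctx.update(context)
    return StructuredReport(
        path_lab=PathLabInfo(**path),
        variants=[VariantSummaryRecord(**v, report_key=report_key) for v in variants],
        fusions=[FusionVariantRecord(**f, report_key=report_key) for f in fusions],
        cnvs=[CnvRecord(**c, report_key=report_key) for c in cnvs],
        context=ctx,
    )


EGFR_L858R = dict(
    gene_name="EGFR",
    exon_id="exon 21",
    dna_change="c.2573T>G",
    protein_change="p.Leu858Arg",
    variant_info="NM_005228",
    allele_frequency=0.35,
    variant_effect="missense",
    pathogeny="pathogenic",
    clinical_relevance="erlotinib sensitivity",
)

ALK_FUSION = dict(
    gene_name="ALK",
    chromosome="chr2",
    cytoband="p23.2",
    break_point=29447000,
    transcript_part="intron 19",
    locus="chr2:29447000",
    gene_strand="-",
    span_read=12,
    split_read=8,
    total_read=20,
    distance=0,
)

EGFR_CNV = dict(
    gene_name="EGFR",
    locus="chr7:55086714-55324313",
    p_value=0.001,
    gain_region=6,
    total_region=8,
    region_ratio=0.75,
    gene_count=1,
    region_count=8,
    significant_region_count=6,
)
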