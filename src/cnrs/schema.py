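"""Standardized data model for structured clinical panel-sequencing reports.

A single flat EHR report row is restructured into four relational tables:

* pathologic & laboratory information (one row per report),
* variant summary (SNV/indel findings),
* gene fusion findings,
* copy-number variation findings.

The module defines those four record types with their controlled
vocabularies, the gene-panel registry (91 entries, 88 unique genes), an
auditable ledger of every column entity, and a completeness checker for the
ISO/TS 20428 required/optional report categories.
"""

from __future__ import annotations

import datetime as _dt
import json
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Literal, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import SchemaError

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

QC_RESULTS = ("pass", "conditional_pass", "fail")
SAMPLE_TYPES = ("FFPE", "fresh_frozen", "blood", "other")
VARIANT_EFFECTS = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice",
    "synonymous",
    "other",
)
# ACMG-style five-tier classification.
PATHOGENY_TIERS = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain_significance",
    "likely_benign",
    "benign",
)
VARIANT_TYPE_CODES = ("snv", "indel")
PANEL_CATEGORIES = ("mandatory", "additional", "fusion")
CANCER_TYPES = (
    "lung",
    "ovarian",
    "breast",
    "malignant_melanoma",
    "colon",
    "stomach",
    "liver",
    "thyroid",
    "kidney",
    "brain",
    "prostate",
    "other",
)
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
STRANDS = ("+", "-")

QcResult = Literal["pass", "conditional_pass", "fail"]
SampleType = Literal["FFPE", "fresh_frozen", "blood", "other"]
VariantEffect = Literal[
    "missense", "nonsense", "frameshift", "inframe_indel", "splice", "synonymous", "other"
]
PathogenyTier = Literal[
    "pathogenic", "likely_pathogenic", "uncertain_significance", "likely_benign", "benign"
]
VariantTypeCode = Literal["snv", "indel"]
PanelCategory = Literal["mandatory", "additional", "fusion"]
Strand = Literal["+", "-"]


# ---------------------------------------------------------------------------
# Panel registry
# ---------------------------------------------------------------------------


class PanelEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    gene_symbol: str
    category: PanelCategory

    @field_validator("gene_symbol")
    @classmethod
    def _symbol_shape(cls, v: str) -> str:
        v = v.strip()
        if not v or not v.isalnum() or v != v.upper():
            raise ValueError(f"gene symbol must be uppercase alphanumeric, got {v!r}")
        return v


class PanelDefinition(BaseModel):
    """The registered gene panel: mandatory, additional and fusion categories.

    Fusion-category genes duplicate symbols already present elsewhere in the
    panel, so the entry count exceeds the unique-gene count.
    """

    entries: list[PanelEntry]

    @model_validator(mode="after")
    def _unique_within_category(self) -> "PanelDefinition":
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.gene_symbol, e.category)
            if key in seen:
                raise ValueError(f"duplicate panel entry {key}")
            seen.add(key)
        return self

    @property
    def genes(self) -> frozenset[str]:
        """All unique gene symbols on the panel."""
        return frozenset(e.gene_symbol for e in self.entries)

    def category_genes(self, category: str) -> frozenset[str]:
        return frozenset(e.gene_symbol for e in self.entries if e.category == category)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.entries)


def load_panel(source: str | Path) -> PanelDefinition:
    """Load a panel from a two-column delimited table (gene_symbol, category).

    The delimiter is sniffed from the header (tab or comma). Unknown
    categories and duplicate (symbol, category) pairs are rejected.
    """
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise SchemaError(f"panel file {path} is empty")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"gene_symbol", "category"} - set(frame.columns)
    if missing:
        raise SchemaError(f"panel file lacks required columns: {sorted(missing)}")
    if frame.empty:
        raise SchemaError(f"panel file {path} has a header but no entries")
    entries = []
    for _, row in frame.iterrows():
        cat = str(row["category"]).strip()
        if cat not in PANEL_CATEGORIES:
            raise SchemaError(
                f"unknown panel category {cat!r} (allowed: {PANEL_CATEGORIES})"
            )
        entries.append(PanelEntry(gene_symbol=str(row["gene_symbol"]), category=cat))
    try:
        return PanelDefinition(entries=entries)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def load_default_panel() -> PanelDefinition:
    """The packaged 91-entry cancer panel (14 mandatory, 74 additional, 3 fusion)."""
    with resources.as_file(
        resources.files("cnrs.data").joinpath("panel_genes.tsv")
    ) as path:
        return load_panel(path)


# ---------------------------------------------------------------------------
# The four standardized tables
# ---------------------------------------------------------------------------


class PathLabInfo(BaseModel):
    """Pathologic and laboratory information — one row per sequencing report."""

    # report-level attributes
    identifiers: str  # pseudonymized report accession
    test_order_date: _dt.date
    qc_result: QcResult
    sample_type: SampleType
    report_date: _dt.date
    reporter: str
    sequencer_type: str
    recommended_treatment: str = ""
    references_text: str = ""
    # structural / linkage attributes
    report_key: str
    alt_subject_key: str
    cancer_type_code: Literal[CANCER_TYPES]  # type: ignore[valid-type]
    panel_id: str

    @model_validator(mode="after")
    def _dates_ordered(self) -> "PathLabInfo":
        if self.report_date < self.test_order_date:
            raise ValueError(
                f"report_date {self.report_date} precedes test_order_date "
                f"{self.test_order_date}"
            )
        return self


class VariantSummaryRecord(BaseModel):
    """A single SNV or small-indel finding."""

    gene_name: str
    exon_id: str = ""
    dna_change: str
    protein_change: str = ""
    variant_info: str = ""
    allele_frequency: float = Field(ge=0.0, le=1.0)
    variant_effect: VariantEffect
    pathogeny: PathogenyTier
    clinical_relevance: str = ""
    record_key: str = ""
    report_key: str = ""
    variant_type_code: VariantTypeCode = "snv"


class FusionVariantRecord(BaseModel):
    """A gene-fusion finding with its breakpoint and read-support evidence."""

    gene_name: str
    chromosome: Literal[CHROMOSOMES]  # type: ignore[valid-type]
    cytoband: str = ""
    break_point: int = Field(ge=1)
    transcript_part: str = ""
    locus: str  # "chr:pos", 1-based
    gene_strand: Strand
    span_read: int = Field(ge=0)
    split_read: int = Field(ge=0)
    total_read: int = Field(ge=0)
    distance: int = Field(ge=0)
    record_key: str = ""
    report_key: str = ""

    @model_validator(mode="after")
    def _consistent(self) -> "FusionVariantRecord":
        if self.total_read < self.span_read or self.total_read < self.split_read:
            raise ValueError(
                f"total_read {self.total_read} < span_read {self.span_read} "
                f"or split_read {self.split_read}"
            )
        chrom = self.locus.split(":", 1)[0]
        if chrom != self.chromosome:
            raise ValueError(
                f"locus chromosome {chrom!r} does not match chromosome field "
                f"{self.chromosome!r}"
            )
        return self


class CnvRecord(BaseModel):
    """A copy-number variation finding over a genomic region."""

    gene_name: str
    locus: str  # "chr:start-end", 1-based inclusive
    p_value: float = Field(ge=0.0, le=1.0)
    gain_region: int = Field(ge=0)
    total_region: int = Field(ge=1)
    region_ratio: float = Field(ge=0.0)
    gene_count: int = Field(ge=0)
    region_count: int = Field(ge=0)
    significant_region_count: int = Field(ge=0)
    record_key: str = ""
    report_key: str = ""

    @model_validator(mode="after")
    def _consistent(self) -> "CnvRecord":
        if self.gain_region > self.total_region:
            raise ValueError(
                f"gain_region {self.gain_region} > total_region {self.total_region}"
            )
        if self.significant_region_count > self.region_count:
            raise ValueError("significant_region_count exceeds region_count")
        expected = self.gain_region / self.total_region
        if abs(self.region_ratio - expected) > 1e-9:
            raise ValueError(
                f"region_ratio {self.region_ratio} != gain/total {expected}"
            )
        return self


class StructuredReport(BaseModel):
    """The standardized bundle: one path/lab row plus its finding records.

    ``context`` carries source-report fields that the four tables do not
    model (ordering physician, addendum, reference genome, negative-findings
    flag, history passthrough) so the completeness checker can evaluate the
    categories they feed. It is not part of the entity ledger.
    """

    path_lab: PathLabInfo
    variants: list[VariantSummaryRecord] = Field(default_factory=list)
    fusions: list[FusionVariantRecord] = Field(default_factory=list)
    cnvs: list[CnvRecord] = Field(default_factory=list)
    context: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _keys_linked(self) -> "StructuredReport":
        rk = self.path_lab.report_key
        for rec in (*self.variants, *self.fusions, *self.cnvs):
            if rec.report_key != rk:
                raise ValueError(
                    f"child report_key {rec.report_key!r} != path_lab.report_key {rk!r}"
                )
        return self


# ---------------------------------------------------------------------------
# Entity ledger — every column of the four tables, by name
# ---------------------------------------------------------------------------

PAPER_NAMED_ENTITIES: dict[str, tuple[str, ...]] = {
    "path_lab": (
        "identifiers",
        "test_order_date",
        "qc_result",
        "sample_type",
        "report_date",
        "reporter",
        "sequencer_type",
        "recommended_treatment",
        "references_text",
    ),
    "variant_summary": (
        "gene_name",
        "exon_id",
        "dna_change",
        "protein_change",
        "variant_info",
        "allele_frequency",
        "variant_effect",
        "pathogeny",
        "clinical_relevance",
    ),
    "fusion_variant": (
        "gene_name",
        "chromosome",
        "cytoband",
        "break_point",
        "transcript_part",
        "locus",
        "gene_strand",
        "span_read",
        "split_read",
        "total_read",
        "distance",
    ),
    "cnv": (
        "gene_name",
        "locus",
        "p_value",
        "gain_region",
        "total_region",
        "region_ratio",
        "gene_count",
        "region_count",
        "significant_region_count",
    ),
}

# Linkage keys and type discriminators required to realize the four-table
# relational decomposition.
STRUCTURAL_ENTITIES: dict[str, tuple[str, ...]] = {
    "path_lab": ("report_key", "alt_subject_key", "cancer_type_code", "panel_id"),
    "variant_summary": ("record_key", "report_key", "variant_type_code"),
    "fusion_variant": ("record_key", "report_key"),
    "cnv": ("record_key", "report_key"),
}

TABLE_MODELS: dict[str, type[BaseModel]] = {
    "path_lab": PathLabInfo,
    "variant_summary": VariantSummaryRecord,
    "fusion_variant": FusionVariantRecord,
    "cnv": CnvRecord,
}


def count_schema_tables() -> int:
    return len(TABLE_MODELS)


def count_schema_entities(paper_named_only: bool = False) -> int:
    """Number of column entities across the four table definitions."""
    n = sum(len(v) for v in PAPER_NAMED_ENTITIES.values())
    if not paper_named_only:
        n += sum(len(v) for v in STRUCTURAL_ENTITIES.values())
    return n


def table_entities(table: str) -> tuple[str, ...]:
    return PAPER_NAMED_ENTITIES[table] + STRUCTURAL_ENTITIES[table]


_SEMANTIC_TYPES: dict[str, str] = {
    "test_order_date": "date",
    "report_date": "date",
    "allele_frequency": "fraction",
    "p_value": "fraction",
    "region_ratio": "ratio",
    "break_point": "genomic_position_1based",
    "locus": "genomic_locus_1based",
    "span_read": "count",
    "split_read": "count",
    "total_read": "count",
    "distance": "base_pairs",
    "gain_region": "count",
    "total_region": "count",
    "gene_count": "count",
    "region_count": "count",
    "significant_region_count": "count",
}

_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "qc_result": QC_RESULTS,
    "sample_type": SAMPLE_TYPES,
    "variant_effect": VARIANT_EFFECTS,
    "pathogeny": PATHOGENY_TIERS,
    "variant_type_code": VARIANT_TYPE_CODES,
    "cancer_type_code": CANCER_TYPES,
    "chromosome": CHROMOSOMES,
    "gene_strand": STRANDS,
}


def schema_export() -> dict[str, Any]:
    """Machine-readable description of the four tables for downstream validation."""
    tables = {}
    for name in TABLE_MODELS:
        cols = []
        for entity in table_entities(name):
            col: dict[str, Any] = {
                "entity": entity,
                "semantic_type": _SEMANTIC_TYPES.get(entity, "text"),
                "structural": entity in STRUCTURAL_ENTITIES[name],
            }
            if entity in _VOCABULARIES:
                col["semantic_type"] = "vocabulary"
                col["vocabulary"] = list(_VOCABULARIES[entity])
            cols.append(col)
        tables[name] = cols
    return {
        "tables": tables,
        "table_count": count_schema_tables(),
        "entity_count": count_schema_entities(),
    }


def write_schema_export(path: str | Path) -> None:
    Path(path).write_text(json.dumps(schema_export(), indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# ISO/TS 20428 completeness checker
# ---------------------------------------------------------------------------

ISO_REQUIRED_CATEGORIES = (
    "clinical_sequencing_orders",
    "subject_of_care",
    "authorized_orderer",
    "performing_laboratory",
    "diseases_and_phenotypes",
    "biomaterial",
    "genetic_variations",
    "variant_classification",
    "recommended_treatment",
    "addendum",
)

ISO_OPTIONAL_CATEGORIES = (
    "medical_history",
    "family_history",
    "reference_genome_version",
    "racial_genomic_information",
    "genetic_variation",
    "detailed_sequencing_information",
    "references",
)


class IsoCompleteness(BaseModel):
    """Presence/absence of the 10 required and 7 optional report categories."""

    required_present: dict[str, bool]
    optional_present: dict[str, bool]
    missing_required: list[str]

    @model_validator(mode="after")
    def _category_names(self) -> "IsoCompleteness":
        if tuple(self.required_present) != ISO_REQUIRED_CATEGORIES:
            raise ValueError("required category names/order do not match the standard")
        if tuple(self.optional_present) != ISO_OPTIONAL_CATEGORIES:
            raise ValueError("optional category names/order do not match the standard")
        return self

    @property
    def complete(self) -> bool:
        return not self.missing_required


def check_iso_completeness(report: StructuredReport) -> IsoCompleteness:
    """Evaluate the report against the standard's required/optional categories.

    Each category is judged by a fixed mapping onto report fields (see the
    methods note): a category is present iff every mapped field is nonempty.
    The check never raises — an incomplete report yields a result listing
    the missing required categories.
    """
    pl = report.path_lab
    ctx = report.context
    has_findings = bool(report.variants or report.fusions or report.cnvs)
    negative_flagged = ctx.get("negative_findings", "").strip().lower() in (
        "1",
        "true",
        "yes",
        "no findings",
        "negative",
    )

    required = {
        "clinical_sequencing_orders": pl.test_order_date is not None,
        "subject_of_care": bool(pl.alt_subject_key) and bool(pl.cancer_type_code),
        "authorized_orderer": bool(ctx.get("ordering_physician", "").strip()),
        "performing_laboratory": bool(pl.reporter.strip()) and bool(pl.sequencer_type.strip()),
        "diseases_and_phenotypes": bool(pl.cancer_type_code),
        "biomaterial": bool(pl.sample_type),
        "genetic_variations": has_findings or negative_flagged,
        "variant_classification": all(bool(v.pathogeny) for v in report.variants),
        "recommended_treatment": bool(pl.recommended_treatment.strip()),
        "addendum": bool(ctx.get("addendum", "").strip()),
    }
    optional = {
        "medical_history": bool(ctx.get("medical_history", "").strip()),
        "family_history": bool(ctx.get("family_history", "").strip()),
        "reference_genome_version": bool(ctx.get("reference_genome", "").strip()),
        "racial_genomic_information": bool(ctx.get("racial_genomic_information", "").strip()),
        "genetic_variation": any(bool(v.variant_info.strip()) for v in report.variants),
        "detailed_sequencing_information": bool(pl.panel_id.strip())
        and bool(pl.sequencer_type.strip()),
        "references": bool(pl.references_text.strip()),
    }
    missing = [c for c in ISO_REQUIRED_CATEGORIES if not required[c]]
    return IsoCompleteness(
        required_present=required, optional_present=optional, missing_required=missing
    )
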