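"""Render a structured report as the standardized three-section document.

The document mirrors the standardized result-viewer layout: (1) basic test
information, (2) sequencing methods and related information, (3) variants
with reporting results. Output is machine-readable JSON (lossless) or a
human-readable markdown/plain-text document; a completeness footer states
which required report categories are missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

from .errors import CnrsError
from .schema import StructuredReport, check_iso_completeness

SECTION_BASIC = "Basic Test Information"
SECTION_METHODS = "Sequencing Methods and Related Information"
SECTION_VARIANTS = "Variants and Reporting Results"

RenderFormat = Literal["json", "markdown", "text"]


@dataclass
class RenderedReport:
    section_basic: str
    section_methods: str
    section_variants: str
    format: str
    document: str

    @property
    def sections(self) -> tuple[str, str, str]:
        return (self.section_basic, self.section_methods, self.section_variants)


def _table(headers: list[str], rows: list[list[str]]) -> str:
    """A minimal fixed-pipe markdown table."""
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def render_report(report: StructuredReport, format: str = "markdown") -> RenderedReport:
    """Render a structured report in the requested format.

    JSON output round-trips losslessly through the report model; markdown
    and text list every finding exactly once and state a negative result
    explicitly when there are no findings.
    """
    if format not in ("json", "markdown", "text"):
        raise CnrsError(f"unsupported render format {format!r}")

    pl = report.path_lab
    completeness = check_iso_completeness(report)

    if format == "json":
        doc = report.model_dump_json(indent=2)
        return RenderedReport(
            section_basic=SECTION_BASIC,
            section_methods=SECTION_METHODS,
            section_variants=SECTION_VARIANTS,
            format=format,
            document=doc,
        )

    basic = [
        f"- Report accession: {pl.identifiers}",
        f"- Subject key: {pl.alt_subject_key}",
        f"- Cancer type: {pl.cancer_type_code}",
        f"- Test ordered: {pl.test_order_date.isoformat()}",
        f"- Report issued: {pl.report_date.isoformat()}",
        f"- Sample type: {pl.sample_type}",
        f"- QC result: {pl.qc_result}",
        f"- Reporter: {pl.reporter}",
    ]
    methods = [
        f"- Sequencer: {pl.sequencer_type}",
        f"- Panel: {pl.panel_id}",
        f"- Reference genome: {report.context.get('reference_genome', 'not stated')}",
        f"- Tumor cell percentage: {report.context.get('tumor_cell_percentage', 'not stated')}",
    ]

    variant_parts: list[str] = []
    if report.variants:
        variant_parts.append("### Point mutations (SNV/indel)\n")
        variant_parts.append(
            _table(
                ["Gene", "Exon", "DNA change", "Protein change", "VAF",
                 "Effect", "Pathogenicity", "Clinical relevance"],
                [
                    [v.gene_name, v.exon_id, v.dna_change, v.protein_change,
                     f"{v.allele_frequency:.1%}", v.variant_effect, v.pathogeny,
                     v.clinical_relevance]
                    for v in report.variants
                ],
            )
        )
    if report.fusions:
        variant_parts.append("\n### Gene fusions\n")
        variant_parts.append(
            _table(
                ["Gene", "Locus", "Cytoband", "Strand", "Span", "Split", "Total"],
                [
                    [f.gene_name, f.locus, f.cytoband, f.gene_strand,
                     f.span_read, f.split_read, f.total_read]
                    for f in report.fusions
                ],
            )
        )
    if report.cnvs:
        variant_parts.append("\n### Copy number variations\n")
        variant_parts.append(
            _table(
                ["Gene", "Locus", "P value", "Gain/Total", "Ratio"],
                [
                    [c.gene_name, c.locus, c.p_value,
                     f"{c.gain_region}/{c.total_region}", f"{c.region_ratio:.3f}"]
                    for c in report.cnvs
                ],
            )
        )
    if not variant_parts:
        variant_parts.append("No reportable variant was detected (negative result).")
    if pl.recommended_treatment:
        variant_parts.append(f"\nRecommended treatment: {pl.recommended_treatment}")

    if completeness.complete:
        footer = "Completeness: all required report categories present."
    else:
        footer = (
            "Completeness: missing required categories: "
            + ", ".join(completeness.missing_required)
        )

    if format == "markdown":
        document = "\n".join(
            [
                f"# Clinical Sequencing Report {pl.report_key}",
                "",
                f"## {SECTION_BASIC}", "", *basic, "",
                f"## {SECTION_METHODS}", "", *methods, "",
                f"## {SECTION_VARIANTS}", "", *variant_parts, "",
                "---", footer,
            ]
        )
    else:
        document = "\n".join(
            [
                f"CLINICAL SEQUENCING REPORT {pl.report_key}",
                "", SECTION_BASIC.upper(), *[b.lstrip("- ") for b in basic],
                "", SECTION_METHODS.upper(), *[m.lstrip("- ") for m in methods],
                "", SECTION_VARIANTS.upper(), *variant_parts,
                "", footer,
            ]
        )
    return RenderedReport(
        section_basic=SECTION_BASIC,
        section_methods=SECTION_METHODS,
        section_variants=SECTION_VARIANTS,
        format=format,
        document=document,
    )


def parse_rendered_json(document: str) -> StructuredReport:
    """Re-parse a JSON rendering back into the report model."""
    return StructuredReport.model_validate(json.loads(document))
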