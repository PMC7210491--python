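"""ETL from flat 28-attribute EHR report rows into structured reports.

The source system stores every panel-sequencing report as one row of a
single table; SNV/indel, fusion and CNV findings live inside free-text
blocks using a templated dialect (one finding per line, semicolon-delimited
positional fields). This module parses those rows, validates HGVS variant
descriptions and vocabulary terms, and restructures each row into a
:class:`~cnrs.schema.StructuredReport`, replacing the patient and pathology
identifiers with pseudonymous keys issued by the key manager.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ParseError, SchemaError
from .schema import (
    CANCER_TYPES,
    PATHOGENY_TIERS,
    CnvRecord,
    FusionVariantRecord,
    PanelDefinition,
    PathLabInfo,
    StructuredReport,
    VariantSummaryRecord,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Raw report record — the flat pre-standardization row
# ---------------------------------------------------------------------------

RAW_FIELDS: tuple[str, ...] = (
    "pathology_no",
    "patient_no",
    "order_date",
    "report_date",
    "cancer_type",
    "primary_site",
    "sample_type",
    "tumor_cell_percentage",
    "qc_dna_quantity",
    "qc_library",
    "qc_overall",
    "sequencer_model",
    "panel_name",
    "panel_version",
    "reference_genome",
    "pathologist_name",
    "pathologist_license",
    "ordering_physician",
    "ordering_department",
    "snv_indel_block",
    "fusion_block",
    "cnv_block",
    "negative_findings",
    "interpretation_comment",
    "recommended_treatment",
    "references_text",
    "addendum",
    "report_status",
)

# Fields never carried into the structured output (audit log only).
DISCARDED_RAW_FIELDS: tuple[str, ...] = ("pathologist_license", "ordering_department")


class RawReportRecord(BaseModel):
    """One flat EHR report row with exactly 28 attributes."""

    model_config = {"extra": "forbid"}

    pathology_no: str
    patient_no: str
    order_date: str
    report_date: str
    cancer_type: str
    primary_site: str = ""
    sample_type: str = ""
    tumor_cell_percentage: str = ""
    qc_dna_quantity: str = ""
    qc_library: str = ""
    qc_overall: str = ""
    sequencer_model: str = ""
    panel_name: str = ""
    panel_version: str = ""
    reference_genome: str = ""
    pathologist_name: str = ""
    pathologist_license: str = ""
    ordering_physician: str = ""
    ordering_department: str = ""
    snv_indel_block: str = ""
    fusion_block: str = ""
    cnv_block: str = ""
    negative_findings: str = ""
    interpretation_comment: str = ""
    recommended_treatment: str = ""
    references_text: str = ""
    addendum: str = ""
    report_status: str = ""

    @model_validator(mode="after")
    def _nonempty_ids(self) -> "RawReportRecord":
        if not self.pathology_no.strip() or not self.patient_no.strip():
            raise ValueError("pathology_no and patient_no must be nonempty")
        return self

    @classmethod
    def from_row(cls, row: Iterable[str] | dict) -> "RawReportRecord":
        if isinstance(row, dict):
            extra = set(row) - set(RAW_FIELDS)
            missing = set(RAW_FIELDS) - set(row)
            if extra or missing:
                raise SchemaError(
                    f"raw record must have exactly the 28 attributes; "
                    f"missing={sorted(missing)} unexpected={sorted(extra)}"
                )
            data = {k: ("" if pd.isna(v) else str(v)) for k, v in row.items()}
        else:
            values = list(row)
            if len(values) != len(RAW_FIELDS):
                raise SchemaError(
                    f"raw record has {len(values)} fields, expected {len(RAW_FIELDS)}"
                )
            data = {
                k: ("" if pd.isna(v) else str(v)) for k, v in zip(RAW_FIELDS, values)
            }
        try:
            return cls(**data)
        except ValidationError as exc:
            raise SchemaError(str(exc)) from exc

    def to_row(self) -> dict[str, str]:
        return {k: getattr(self, k) for k in RAW_FIELDS}


# ---------------------------------------------------------------------------
# HGVS parsing (c. / p. descriptions)
# ---------------------------------------------------------------------------

HgvsKind = Literal[
    "substitution", "deletion", "insertion", "duplication", "delins", "frameshift", "other"
]


class HgvsDescription(BaseModel):
    """A parsed DNA- or protein-level variant description."""

    level: Literal["c", "p"]
    raw: str
    kind: HgvsKind
    position_start: int = Field(ge=1)
    position_end: int | None = None
    ref_allele: str = ""
    alt_allele: str = ""

    @model_validator(mode="after")
    def _span(self) -> "HgvsDescription":
        if self.position_end is not None and self.position_end < self.position_start:
            raise ValueError("position_end < position_start")
        return self


# c.-level grammar. Positions may carry intronic offsets (e.g. 2573+1),
# which we fold into position_start/position_end by keeping the anchor base.
_C_POS = r"(\d+)(?:[+-]\d+)?"
_C_SUB = re.compile(rf"^c\.{_C_POS}([ACGT])>([ACGT])$")
_C_RANGE = rf"{_C_POS}(?:_{_C_POS})?"
_C_DEL = re.compile(rf"^c\.{_C_RANGE}del(?:[ACGT]+)?$")
_C_DUP = re.compile(rf"^c\.{_C_RANGE}dup(?:[ACGT]+)?$")
_C_INS = re.compile(rf"^c\.{_C_POS}_{_C_POS}ins([ACGT]+)$")
_C_DELINS = re.compile(rf"^c\.{_C_RANGE}delins([ACGT]+)$")

_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter"
)
_P_SUB = re.compile(rf"^p\.\(?({_AA3})(\d+)({_AA3}|=)\)?$")
_P_FS = re.compile(rf"^p\.\(?({_AA3})(\d+)({_AA3})?fs(?:Ter\d+|\*\d+)?\)?$")
_P_DEL = re.compile(rf"^p\.\(?({_AA3})(\d+)(?:_({_AA3})(\d+))?del\)?$")
_P_DUP = re.compile(rf"^p\.\(?({_AA3})(\d+)(?:_({_AA3})(\d+))?dup\)?$")
_P_DELINS = re.compile(rf"^p\.\(?({_AA3})(\d+)(?:_({_AA3})(\d+))?delins(?:{_AA3})+\)?$")
_P_INS = re.compile(rf"^p\.\(?({_AA3})(\d+)_({_AA3})(\d+)ins(?:{_AA3})+\)?$")


def parse_hgvs(raw: str, strict: bool = True) -> HgvsDescription:
    """Parse a DNA-level ("c.") or protein-level ("p.") variant description.

    Supported kinds: substitution, deletion, insertion, duplication, delins
    and (protein level) frameshift. An unrecognized description that still
    carries a valid prefix is returned as ``kind="other"`` in lenient mode
    and rejected in strict mode. Descriptions without a c./p. prefix are
    always rejected.
    """
    raw = raw.strip()
    if not raw:
        raise ParseError("empty HGVS description")
    if not (raw.startswith("c.") or raw.startswith("p.")):
        token = raw.split(".", 1)[0]
        raise ParseError(
            f"unsupported HGVS prefix {token!r} in {raw!r} (only c. and p. accepted)"
        )
    level = raw[0]

    if level == "c":
        if m := _C_SUB.match(raw):
            return HgvsDescription(
                level="c", raw=raw, kind="substitution",
                position_start=int(m.group(1)), ref_allele=m.group(2), alt_allele=m.group(3),
            )
        for kind, pattern in (
            ("delins", _C_DELINS), ("deletion", _C_DEL),
            ("duplication", _C_DUP), ("insertion", _C_INS),
        ):
            if m := pattern.match(raw):
                start = int(m.group(1))
                end = int(m.group(2)) if m.lastindex and m.group(2) else None
                alt = ""
                if kind in ("insertion", "delins"):
                    alt = m.group(m.lastindex)
                return HgvsDescription(
                    level="c", raw=raw, kind=kind,
                    position_start=start, position_end=end, alt_allele=alt,
                )
    else:
        if m := _P_SUB.match(raw):
            return HgvsDescription(
                level="p", raw=raw, kind="substitution",
                position_start=int(m.group(2)),
                ref_allele=m.group(1), alt_allele=m.group(3),
            )
        if m := _P_FS.match(raw):
            return HgvsDescription(
                level="p", raw=raw, kind="frameshift",
                position_start=int(m.group(2)), ref_allele=m.group(1),
            )
        for kind, pattern in (
            ("delins", _P_DELINS), ("deletion", _P_DEL),
            ("duplication", _P_DUP), ("insertion", _P_INS),
        ):
            if m := pattern.match(raw):
                start = int(m.group(2))
                end = int(m.group(4)) if m.lastindex and m.lastindex >= 4 and m.group(4) else None
                return HgvsDescription(
                    level="p", raw=raw, kind=kind,
                    position_start=start, position_end=end, ref_allele=m.group(1),
                )

    if strict:
        raise ParseError(f"unrecognized HGVS description {raw!r} (strict mode)")
    pos = re.search(r"(\d+)", raw)
    return HgvsDescription(
        level=level, raw=raw, kind="other",
        position_start=int(pos.group(1)) if pos else 1,
    )


# ---------------------------------------------------------------------------
# Vocabulary normalization
# ---------------------------------------------------------------------------

_PATHOGENY_SYNONYMS: dict[str, str] = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "uncertain significance": "uncertain_significance",
    "uncertain_significance": "uncertain_significance",
    "variant of uncertain significance": "uncertain_significance",
    "vus": "uncertain_significance",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "benign": "benign",
}


def normalize_pathogenicity(term: str, strict: bool = True) -> str:
    """Map a free-text pathogenicity term onto the five-tier vocabulary.

    Matching is case-insensitive and whitespace-collapsing; in lenient mode
    an unknown term falls back to ``uncertain_significance`` with a warning.
    """
    if not term or not term.strip():
        raise ParseError("empty pathogenicity term")
    key = re.sub(r"\s+", " ", term.strip().lower())
    if key in _PATHOGENY_SYNONYMS:
        return _PATHOGENY_SYNONYMS[key]
    if strict:
        raise ParseError(f"unknown pathogenicity term {term!r}")
    logger.warning("unknown pathogenicity term %r mapped to uncertain_significance", term)
    return "uncertain_significance"


_QC_SYNONYMS = {
    "pass": "pass",
    "passed": "pass",
    "conditional pass": "conditional_pass",
    "conditional_pass": "conditional_pass",
    "fail": "fail",
    "failed": "fail",
}

_SAMPLE_SYNONYMS = {
    "ffpe": "FFPE",
    "fresh frozen": "fresh_frozen",
    "fresh_frozen": "fresh_frozen",
    "blood": "blood",
    "other": "other",
}


def _normalize_enum(term: str, table: dict[str, str], what: str, default: str) -> str:
    key = re.sub(r"\s+", " ", term.strip().lower())
    if key in table:
        return table[key]
    if not key:
        return default
    raise ParseError(f"unknown {what} {term!r}")


def normalize_allele_frequency(text: str) -> float:
    """Accept '35%', '35.0 %' or '0.35'; return a fraction in [0, 1].

    A bare value above 1 is interpreted as a percentage; a bare '1' is a
    fraction of 1.0.
    """
    t = text.strip()
    if not t:
        raise ParseError("empty allele frequency")
    percent = t.endswith("%")
    if percent:
        t = t[:-1].strip()
    try:
        value = float(t)
    except ValueError as exc:
        raise ParseError(f"unparseable allele frequency {text!r}") from exc
    if percent or value > 1.0:
        value /= 100.0
    if not 0.0 <= value <= 1.0:
        raise ParseError(f"allele frequency {text!r} outside [0, 1]")
    return value


def _variant_type_for(kind: str) -> str:
    return "snv" if kind in ("substitution", "other") else "indel"


# ---------------------------------------------------------------------------
# Free-text finding blocks
# ---------------------------------------------------------------------------


def _split_fields(line: str, n: int, line_no: int, last_free_text: bool) -> list[str]:
    parts = line.split(";", n - 1) if last_free_text else line.split(";")
    parts = [p.strip() for p in parts]
    if len(parts) != n:
        raise ParseError(
            f"expected {n} semicolon-delimited fields, found {len(parts)}: {line!r}",
            line_no=line_no,
        )
    return parts


def parse_variant_block(
    text: str, panel: PanelDefinition | None = None, strict: bool = True
) -> list[VariantSummaryRecord]:
    """Parse the SNV/indel free-text block (one finding per line).

    Field order: gene; exon; DNA change; protein change; variant info;
    allele frequency; effect; pathogeny; clinical relevance. Duplicate
    (gene, DNA change) lines collapse to the first occurrence. Genes absent
    from the panel raise in strict mode and are excluded with a warning in
    lenient mode.
    """
    records: list[VariantSummaryRecord] = []
    seen: set[tuple[str, str]] = set()
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        (
            gene, exon, dna, protein, info, vaf_text, effect, pathogeny, relevance,
        ) = _split_fields(line, 9, line_no, last_free_text=True)
        gene = gene.upper()
        if panel is not None and gene not in panel:
            msg = f"gene {gene!r} is not on the panel"
            if strict:
                raise ParseError(msg, line_no=line_no)
            logger.warning("%s (line %d) — finding excluded", msg, line_no)
            continue
        if (gene, dna) in seen:
            logger.warning(
                "duplicate finding %s %s at line %d collapsed to first occurrence",
                gene, dna, line_no,
            )
            continue
        seen.add((gene, dna))
        try:
            desc = parse_hgvs(dna, strict=strict)
            if protein:
                parse_hgvs(protein, strict=strict)
            record = VariantSummaryRecord(
                gene_name=gene,
                exon_id=exon,
                dna_change=dna,
                protein_change=protein,
                variant_info=info,
                allele_frequency=normalize_allele_frequency(vaf_text),
                variant_effect=effect if effect else "other",
                pathogeny=normalize_pathogenicity(pathogeny, strict=strict),
                clinical_relevance=relevance,
                variant_type_code=_variant_type_for(desc.kind),
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"invalid variant line: {exc}", line_no=line_no) from exc
        records.append(record)
    return records


def parse_fusion_block(
    text: str, panel: PanelDefinition | None = None, strict: bool = True
) -> list[FusionVariantRecord]:
    """Parse the gene-fusion block: gene; chromosome; cytoband; break;
    transcript part; locus; strand; span read; split read; total read;
    distance."""
    records: list[FusionVariantRecord] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_fields(line, 11, line_no, last_free_text=False)
        (
            gene, chromosome, cytoband, break_point, transcript_part,
            locus, strand, span, split, total, distance,
        ) = fields
        gene = gene.upper()
        if panel is not None and gene not in panel:
            msg = f"gene {gene!r} is not on the panel"
            if strict:
                raise ParseError(msg, line_no=line_no)
            logger.warning("%s (line %d) — finding excluded", msg, line_no)
            continue
        # U+2212 minus is accepted for the reverse strand.
        strand = strand.replace("−", "-")
        try:
            record = FusionVariantRecord(
                gene_name=gene,
                chromosome=chromosome,
                cytoband=cytoband,
                break_point=int(break_point),
                transcript_part=transcript_part,
                locus=locus,
                gene_strand=strand,
                span_read=int(span),
                split_read=int(split),
                total_read=int(total),
                distance=int(distance),
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"invalid fusion line: {exc}", line_no=line_no) from exc
        records.append(record)
    return records


def parse_cnv_block(
    text: str, panel: PanelDefinition | None = None, strict: bool = True
) -> list[CnvRecord]:
    """Parse the CNV block: gene; locus; P value; gain region; total region;
    region ratio; gene count; region count; significant region count."""
    records: list[CnvRecord] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_fields(line, 9, line_no, last_free_text=False)
        (
            gene, locus, p_value, gain, total, ratio, gene_count, region_count, sig_count,
        ) = fields
        gene = gene.upper()
        if panel is not None and gene not in panel:
            msg = f"gene {gene!r} is not on the panel"
            if strict:
                raise ParseError(msg, line_no=line_no)
            logger.warning("%s (line %d) — finding excluded", msg, line_no)
            continue
        try:
            record = CnvRecord(
                gene_name=gene,
                locus=locus,
                p_value=float(p_value),
                gain_region=int(gain),
                total_region=int(total),
                region_ratio=float(ratio),
                gene_count=int(gene_count),
                region_count=int(region_count),
                significant_region_count=int(sig_count),
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"invalid CNV line: {exc}", line_no=line_no) from exc
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Restructuring — one raw row to one structured report
# ---------------------------------------------------------------------------

_CANCER_SYNONYMS = {c: c for c in CANCER_TYPES}
_CANCER_SYNONYMS.update({"melanoma": "malignant_melanoma", "malignant melanoma": "malignant_melanoma"})


def _normalize_cancer_type(term: str) -> str:
    key = re.sub(r"\s+", " ", term.strip().lower())
    if key in _CANCER_SYNONYMS:
        return _CANCER_SYNONYMS[key]
    return "other"


def restructure(
    raw: RawReportRecord,
    panel: PanelDefinition,
    keymap_handle,
    strict: bool = True,
    report_key: str | None = None,
    audit_log: list | None = None,
) -> StructuredReport:
    """Restructure one raw EHR row into the four-table standardized bundle.

    Patient and pathology identifiers are consumed by the key manager
    (``keymap_handle`` must expose ``register(patient_no, pathology_no)`` and
    ``patient_key(patient_no)``) and never appear in the output; fields with
    no standardized home are either carried in ``context`` for the
    completeness checker or routed to the audit log (license numbers,
    department codes). A QC failure does not block structuring — the report
    is flagged in ``context['qc_flag']``.
    """
    alt_id = keymap_handle.register(raw.patient_no, raw.pathology_no)
    alt_subject = keymap_handle.patient_key(raw.patient_no)
    if report_key is None:
        report_key = alt_id

    if audit_log is not None:
        audit_log.append(
            {f: getattr(raw, f) for f in ("pathology_no", *DISCARDED_RAW_FIELDS)}
        )

    qc = _normalize_enum(raw.qc_overall, _QC_SYNONYMS, "QC result", default="pass")
    sample = _normalize_enum(raw.sample_type, _SAMPLE_SYNONYMS, "sample type", default="other")
    panel_id = " ".join(p for p in (raw.panel_name, raw.panel_version) if p).strip()

    try:
        path_lab = PathLabInfo(
            identifiers=alt_id,
            test_order_date=raw.order_date,
            qc_result=qc,
            sample_type=sample,
            report_date=raw.report_date,
            reporter=raw.pathologist_name,
            sequencer_type=raw.sequencer_model,
            recommended_treatment=raw.recommended_treatment,
            references_text=raw.references_text,
            report_key=report_key,
            alt_subject_key=alt_subject,
            cancer_type_code=_normalize_cancer_type(raw.cancer_type),
            panel_id=panel_id,
        )
    except ValidationError as exc:
        raise SchemaError(f"invalid path/lab attributes: {exc}") from exc

    variants = parse_variant_block(raw.snv_indel_block, panel, strict=strict)
    fusions = parse_fusion_block(raw.fusion_block, panel, strict=strict)
    cnvs = parse_cnv_block(raw.cnv_block, panel, strict=strict)
    for i, rec in enumerate([*variants, *fusions, *cnvs], start=1):
        rec.report_key = report_key
        rec.record_key = f"{report_key}-{i:03d}"

    context = {
        "primary_site": raw.primary_site,
        "tumor_cell_percentage": raw.tumor_cell_percentage,
        "qc_dna_quantity": raw.qc_dna_quantity,
        "qc_library": raw.qc_library,
        "reference_genome": raw.reference_genome,
        "ordering_physician": raw.ordering_physician,
        "negative_findings": raw.negative_findings,
        "interpretation_comment": raw.interpretation_comment,
        "addendum": raw.addendum,
        "report_status": raw.report_status,
    }
    if qc == "fail":
        context["qc_flag"] = "qc_fail"
        logger.warning("report %s structured with failed QC", report_key)

    report = StructuredReport(
        path_lab=path_lab, variants=variants, fusions=fusions, cnvs=cnvs, context=context
    )

    leaked = scan_for_identifiers(report, [raw.patient_no, raw.pathology_no])
    if leaked:
        raise SchemaError(f"raw identifiers leaked into structured output: {leaked}")
    return report


def scan_for_identifiers(obj, identifiers: Iterable[str]) -> list[str]:
    """Return the subset of ``identifiers`` occurring as substrings anywhere
    in the JSON serialization of ``obj``."""
    if isinstance(obj, BaseModel):
        blob = obj.model_dump_json()
    else:
        blob = str(obj)
    return [i for i in identifiers if i and i in blob]


# ---------------------------------------------------------------------------
# Batch ETL
# ---------------------------------------------------------------------------


@dataclass
class IngestLog:
    """Per-batch accounting: every input row is a report out or a logged failure."""

    rows_in: int = 0
    reports_out: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)

    @property
    def conserved(self) -> bool:
        return self.rows_in == self.reports_out + len(self.failures)

    def summary(self) -> dict:
        return {
            "rows_in": self.rows_in,
            "reports_out": self.reports_out,
            "failures": len(self.failures),
        }


def etl_batch(
    raw_table: str | Path | pd.DataFrame,
    panel: PanelDefinition,
    keymap_handle,
    mode: str = "strict",
    delimiter: str = "\t",
) -> tuple[list[StructuredReport], IngestLog]:
    """Run the restructuring ETL over a delimited raw-report table.

    In strict mode the first malformed row aborts the batch; in lenient mode
    failures are logged and the remaining rows continue. The log satisfies
    ``rows_in == reports_out + failures``.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    strict = mode == "strict"
    if isinstance(raw_table, (str, Path)):
        frame = pd.read_csv(raw_table, sep=delimiter, dtype=str, keep_default_na=False)
    else:
        frame = raw_table.astype(str)
    missing = set(RAW_FIELDS) - set(frame.columns)
    if missing:
        raise SchemaError(f"raw table header lacks columns: {sorted(missing)}")

    log = IngestLog(rows_in=len(frame))
    reports: list[StructuredReport] = []
    for idx, row in frame.iterrows():
        try:
            raw = RawReportRecord.from_row(row[list(RAW_FIELDS)].to_dict())
            report = restructure(raw, panel, keymap_handle, strict=strict, audit_log=log.audit)
            reports.append(report)
            log.reports_out += 1
        except Exception as exc:  # noqa: BLE001 — per-row accounting
            if strict:
                raise
            log.failures.append((int(idx), str(exc)))
            logger.warning("row %s failed ingest: %s", idx, exc)
    return reports, log
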