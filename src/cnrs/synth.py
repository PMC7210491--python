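"""Synthetic EHR cohort generator and raw-report renderer.

Emulates the feed the pipeline ingests in production: a flat 28-column
report table plus clinical tables (diagnosis, surgery, death) keyed by raw
patient identifiers. Generation is *exact-count allocation*, not sampling —
every marginal in the :class:`CohortSpec` (cancer-type sizes, per-gene ×
per-stratum mutated-patient counts) is reproduced exactly, so downstream
cohort fractions carry no sampling error. The packaged default spec
(:func:`default_ncc_spec`) transcribes the study cohort: 367 reports across
11 cancer types with the published per-gene mutation counts pinned;
unpinned cells are filled by a seeded deterministic shuffle.

Raw patient/pathology accessions are drawn from a digits-only alphabet
({0,1,8,9}) that is disjoint from the base-32 pseudonym alphabet, which
makes substring leak-scans unambiguous.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import InfeasibleSpecError, SchemaError
from .ingest import RAW_FIELDS, RawReportRecord, normalize_allele_frequency
from .schema import PATHOGENY_TIERS, StructuredReport

STUDY_START = _dt.date(2017, 4, 1)
STUDY_END = _dt.date(2019, 2, 28)

_ID_DIGITS = "0189"  # disjoint from the base-32 pseudonym alphabet


def _encode_id(prefix: str, index: int, width: int = 8) -> str:
    digits = []
    for _ in range(width):
        digits.append(_ID_DIGITS[index % 4])
        index //= 4
    return prefix + "".join(reversed(digits))


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------


class CohortSpec(BaseModel):
    """Marginals the generated cohort must reproduce exactly.

    ``gene_mutation_counts`` maps stratum -> gene -> number of patients with
    a point mutation in that gene; the stratum ``"all"`` pins a cohort-wide
    count, which must be achievable given (and never below) the pinned
    per-stratum counts for the same gene.
    """

    cancer_type_counts: dict[str, int]
    gene_mutation_counts: dict[str, dict[str, int]] = Field(default_factory=dict)
    pathogeny_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "pathogenic": 0.45,
            "likely_pathogenic": 0.30,
            "uncertain_significance": 0.25,
        }
    )
    fusion_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    cnv_rate: float = Field(default=0.08, ge=0.0, le=1.0)
    death_rate: float = Field(default=0.20, ge=0.0, le=1.0)
    surgery_rate: float = Field(default=0.30, ge=0.0, le=1.0)
    seed: int = 7

    @property
    def total(self) -> int:
        return sum(self.cancer_type_counts.values())

    @model_validator(mode="after")
    def _basic_shape(self) -> "CohortSpec":
        if any(n < 0 for n in self.cancer_type_counts.values()):
            raise ValueError("cancer-type counts must be nonnegative")
        unknown_tiers = set(self.pathogeny_mix) - set(PATHOGENY_TIERS)
        if unknown_tiers:
            raise ValueError(f"unknown pathogenicity tiers in mix: {sorted(unknown_tiers)}")
        for stratum in self.gene_mutation_counts:
            if stratum != "all" and stratum not in self.cancer_type_counts:
                raise ValueError(f"gene counts reference unknown stratum {stratum!r}")
        return self

    def check_feasible(self) -> None:
        """Raise :class:`InfeasibleSpecError` if any count cannot be planted."""
        for stratum, genes in self.gene_mutation_counts.items():
            if stratum == "all":
                continue
            size = self.cancer_type_counts[stratum]
            for gene, n in genes.items():
                if n > size:
                    raise InfeasibleSpecError(
                        f"({stratum}, {gene}) = {n} exceeds stratum size {size}"
                    )
        all_counts = self.gene_mutation_counts.get("all", {})
        for gene, all_n in all_counts.items():
            pinned = {
                s: g[gene]
                for s, g in self.gene_mutation_counts.items()
                if s != "all" and gene in g
            }
            pinned_sum = sum(pinned.values())
            if all_n < pinned_sum:
                raise InfeasibleSpecError(
                    f"gene {gene}: overall count {all_n} < sum of pinned strata {pinned_sum}"
                )
            free_capacity = sum(
                size for s, size in self.cancer_type_counts.items() if s not in pinned
            )
            if all_n - pinned_sum > free_capacity:
                raise InfeasibleSpecError(
                    f"gene {gene}: overall count {all_n} cannot fit remaining strata"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls(**yaml.safe_load(text))
        return cls(**json.loads(text))


def default_ncc_spec(seed: int = 7) -> CohortSpec:
    """The packaged default cohort: 367 reports across 11 cancer types.

    Cancer-type sizes and the per-gene mutated-patient counts below are the
    published cohort marginals; additional genes round the distribution out
    to roughly the 12 most frequently mutated, and their counts are this
    generator's own (unpinned) choices.
    """
    return CohortSpec(
        cancer_type_counts={
            "lung": 249,
            "ovarian": 70,
            "breast": 8,
            "malignant_melanoma": 7,
            "colon": 7,
            "stomach": 7,
            "liver": 6,
            "thyroid": 5,
            "kidney": 5,
            "brain": 2,
            "prostate": 1,
        },
        gene_mutation_counts={
            "all": {
                "TP53": 167,
                "EGFR": 56,
                "KRAS": 34,
                "BRCA1": 21,
                "CDKN2A": 15,
                "PIK3CA": 14,
                "BRAF": 13,
                "MET": 12,
                "STK11": 11,
                "PTEN": 10,
                "ATM": 9,
                "NRAS": 8,
            },
            "lung": {"TP53": 120, "EGFR": 51, "KRAS": 27},
            "ovarian": {"TP53": 39, "BRCA1": 9, "PIK3CA": 5},
            "breast": {"TP53": 3, "PIK3CA": 3, "BRCA2": 3},
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exemplar variant details
# ---------------------------------------------------------------------------


def _load_exemplars() -> dict[str, list[dict[str, str]]]:
    with resources.as_file(
        resources.files("cnrs.data").joinpath("variant_exemplars.tsv")
    ) as path:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table: dict[str, list[dict[str, str]]] = {}
    for _, row in frame.iterrows():
        table.setdefault(row["gene_symbol"], []).append(row.to_dict())
    return table


_FUSION_LOCI = {
    "ALK": ("chr2", "p23.2", 29447000, "intron 19"),
    "ROS1": ("chr6", "q22.1", 117645000, "intron 33"),
    "RET": ("chr10", "q11.21", 43612000, "intron 11"),
}

_CNV_LOCI = {
    "EGFR": ("chr7", 55086714, 55324313),
    "MET": ("chr7", 116312444, 116438440),
    "ERBB2": ("chr17", 37844167, 37886679),
    "MYC": ("chr8", 128748315, 128753680),
    "CDK4": ("chr12", 58141510, 58149796),
    "FGFR1": ("chr8", 38268656, 38326352),
}

_ICD10 = {
    "lung": "C34",
    "ovarian": "C56",
    "breast": "C50",
    "malignant_melanoma": "C43",
    "colon": "C18",
    "stomach": "C16",
    "liver": "C22",
    "thyroid": "C73",
    "kidney": "C64",
    "brain": "C71",
    "prostate": "C61",
    "other": "C80",
}

_DEPARTMENTS = {
    "lung": "Pulmonology",
    "ovarian": "Gynecologic Oncology",
    "breast": "Breast Surgery",
    "malignant_melanoma": "Dermatology",
    "colon": "Colorectal Surgery",
    "stomach": "Gastroenterology",
    "liver": "Hepatology",
    "thyroid": "Endocrinology",
    "kidney": "Urology",
    "brain": "Neurosurgery",
    "prostate": "Urology",
    "other": "Oncology",
}

_THERAPY_HINTS = {
    ("EGFR", "c.2573T>G"): "EGFR TKI sensitivity (erlotinib/gefitinib)",
    ("EGFR", "c.2235_2249del"): "EGFR TKI sensitivity (erlotinib/gefitinib)",
    ("EGFR", "c.2369C>T"): "EGFR T790M - consider osimertinib",
    ("BRAF", "c.1799T>A"): "BRAF/MEK inhibitor candidate",
    ("BRCA1", "c.3770_3771del"): "PARP inhibitor candidate",
    ("BRCA1", "c.5266dup"): "PARP inhibitor candidate",
    ("BRCA2", "c.5946del"): "PARP inhibitor candidate",
}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Generated EHR-style tables plus the planted ground truth."""

    raw_table: pd.DataFrame  # 28 columns, one row per report
    clinical: dict[str, pd.DataFrame]  # domain -> (patient_no, event_date, attributes)
    ledger: pd.DataFrame  # every planted finding
    patients: pd.DataFrame  # patient_no, pathology_no, cancer_type
    spec: CohortSpec

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = {}
        targets = {"raw_reports": self.raw_table, "ground_truth": self.ledger,
                   "patients": self.patients}
        targets.update({f"clinical_{k}": v for k, v in self.clinical.items()})
        for name, frame in targets.items():
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            written[name] = path
        return written


def _allocate_unpinned(spec: CohortSpec, rng: random.Random) -> dict[str, dict[str, int]]:
    """Resolve per-stratum mutated-patient counts for every gene.

    Pinned per-stratum counts are kept verbatim; the remainder of any
    cohort-wide count is distributed over the unpinned strata by a seeded
    shuffle of capacity slots (exact totals, deterministic per seed).
    """
    spec.check_feasible()
    per_stratum: dict[str, dict[str, int]] = {
        s: dict(g) for s, g in spec.gene_mutation_counts.items() if s != "all"
    }
    for gene, all_n in sorted(spec.gene_mutation_counts.get("all", {}).items()):
        pinned = {s for s, g in per_stratum.items() if gene in g}
        remainder = all_n - sum(per_stratum[s][gene] for s in pinned)
        slots: list[str] = []
        for stratum, size in spec.cancer_type_counts.items():
            if stratum not in pinned:
                slots.extend([stratum] * size)
        rng.shuffle(slots)
        for stratum in slots[:remainder]:
            per_stratum.setdefault(stratum, {})
            per_stratum[stratum][gene] = per_stratum[stratum].get(gene, 0) + 1
    return per_stratum


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate the raw report table, clinical tables and ground-truth ledger.

    Identical specs (including seed) produce identical tables.
    """
    if spec is None:
        spec = default_ncc_spec()
    spec.check_feasible()
    rng = random.Random(spec.seed)
    exemplars = _load_exemplars()

    # patients, in stratum order
    patient_rows = []
    stratum_patients: dict[str, list[str]] = {}
    idx = 0
    for cancer_type, size in spec.cancer_type_counts.items():
        members = []
        for _ in range(size):
            patient_no = _encode_id("PT", idx)
            pathology_no = _encode_id("SP", idx)
            patient_rows.append(
                {"patient_no": patient_no, "pathology_no": pathology_no,
                 "cancer_type": cancer_type}
            )
            members.append(patient_no)
            idx += 1
        stratum_patients[cancer_type] = members
    patients = pd.DataFrame(patient_rows)
    patient_info = {r["patient_no"]: r for r in patient_rows}
    total = len(patient_rows)

    # plant point mutations
    per_stratum = _allocate_unpinned(spec, rng)
    tiers = sorted(spec.pathogeny_mix)
    weights = [spec.pathogeny_mix[t] for t in tiers]
    variant_plan: dict[str, list[dict]] = {p: [] for p in patient_info}
    ledger_rows = []
    for stratum in spec.cancer_type_counts:
        for gene, n in sorted(per_stratum.get(stratum, {}).items()):
            carriers = rng.sample(stratum_patients[stratum], n)
            for patient_no in carriers:
                if gene in exemplars:
                    ex = rng.choice(exemplars[gene])
                else:
                    pos = rng.randint(100, 3000)
                    ref, alt = rng.sample("ACGT", 2)
                    ex = {
                        "exon_id": f"exon {rng.randint(2, 20)}",
                        "dna_change": f"c.{pos}{ref}>{alt}",
                        "protein_change": "",
                        "transcript": "NM_000000",
                        "variant_effect": "missense",
                    }
                vaf_pct = round(rng.uniform(5.0, 60.0), 1)
                pathogeny = rng.choices(tiers, weights=weights, k=1)[0]
                relevance = _THERAPY_HINTS.get((gene, ex["dna_change"]), "")
                finding = {
                    "gene": gene,
                    "exon_id": ex["exon_id"],
                    "dna_change": ex["dna_change"],
                    "protein_change": ex["protein_change"],
                    "variant_info": ex["transcript"],
                    "vaf_text": f"{vaf_pct}%",
                    "variant_effect": ex["variant_effect"],
                    "pathogeny": pathogeny,
                    "clinical_relevance": relevance,
                }
                variant_plan[patient_no].append(finding)
                ledger_rows.append(
                    {
                        "patient_no": patient_no,
                        "pathology_no": patient_info[patient_no]["pathology_no"],
                        "cancer_type": stratum,
                        "kind": "point_mutation",
                        "gene": gene,
                        "detail": ex["dna_change"],
                        "pathogeny": pathogeny,
                        "allele_frequency": normalize_allele_frequency(f"{vaf_pct}%"),
                    }
                )

    # fusions and CNVs at configured rates (exact counts)
    all_patients = list(patient_info)
    fusion_plan: dict[str, list[dict]] = {p: [] for p in all_patients}
    for patient_no in rng.sample(all_patients, round(spec.fusion_rate * total)):
        gene = rng.choice(sorted(_FUSION_LOCI))
        chrom, band, base, part = _FUSION_LOCI[gene]
        bp = base + rng.randint(-5000, 5000)
        span, split = rng.randint(3, 25), rng.randint(3, 25)
        fusion_plan[patient_no].append(
            {
                "gene": gene, "chromosome": chrom, "cytoband": band,
                "break_point": bp, "transcript_part": part,
                "locus": f"{chrom}:{bp}", "strand": rng.choice("+-"),
                "span": span, "split": split,
                "total": span + split + rng.randint(0, 10),
                "distance": rng.randint(0, 5000),
            }
        )
        ledger_rows.append(
            {
                "patient_no": patient_no,
                "pathology_no": patient_info[patient_no]["pathology_no"],
                "cancer_type": patient_info[patient_no]["cancer_type"],
                "kind": "fusion", "gene": gene, "detail": f"{chrom}:{bp}",
                "pathogeny": "", "allele_frequency": "",
            }
        )

    cnv_plan: dict[str, list[dict]] = {p: [] for p in all_patients}
    for patient_no in rng.sample(all_patients, round(spec.cnv_rate * total)):
        gene = rng.choice(sorted(_CNV_LOCI))
        chrom, start, end = _CNV_LOCI[gene]
        gain = rng.randint(1, 15)
        total_region = gain + rng.randint(0, 10)
        cnv_plan[patient_no].append(
            {
                "gene": gene, "locus": f"{chrom}:{start}-{end}",
                "p_value": round(rng.uniform(0.0001, 0.05), 4),
                "gain": gain, "total_region": total_region,
                "ratio": gain / total_region,
                "gene_count": 1, "region_count": total_region,
                "sig_count": min(gain, total_region),
            }
        )
        ledger_rows.append(
            {
                "patient_no": patient_no,
                "pathology_no": patient_info[patient_no]["pathology_no"],
                "cancer_type": patient_info[patient_no]["cancer_type"],
                "kind": "cnv", "gene": gene, "detail": f"{chrom}:{start}-{end}",
                "pathogeny": "", "allele_frequency": "",
            }
        )

    # raw report rows
    span_days = (STUDY_END - STUDY_START).days
    raw_rows = []
    for i, row in enumerate(patient_rows):
        patient_no, pathology_no, ct = (
            row["patient_no"], row["pathology_no"], row["cancer_type"]
        )
        order_date = STUDY_START + _dt.timedelta(days=(i * span_days) // max(total, 1))
        report_date = order_date + _dt.timedelta(days=rng.randint(7, 21))
        variants = variant_plan[patient_no]
        fusions = fusion_plan[patient_no]
        cnvs = cnv_plan[patient_no]
        has_findings = bool(variants or fusions or cnvs)
        therapies = [v["clinical_relevance"] for v in variants if v["clinical_relevance"]]
        raw_rows.append(
            {
                "pathology_no": pathology_no,
                "patient_no": patient_no,
                "order_date": order_date.isoformat(),
                "report_date": report_date.isoformat(),
                "cancer_type": ct,
                "primary_site": ct,
                "sample_type": "FFPE" if rng.random() < 0.9 else "fresh_frozen",
                "tumor_cell_percentage": str(rng.randint(20, 90)),
                "qc_dna_quantity": f"{rng.randint(50, 400)} ng",
                "qc_library": "pass",
                "qc_overall": "pass" if rng.random() < 0.95 else "conditional pass",
                "sequencer_model": "NextSeq 550",
                "panel_name": "OncoPanel",
                "panel_version": "v2",
                "reference_genome": "GRCh37",
                "pathologist_name": f"Pathologist {rng.choice('ABCDE')}, MD",
                "pathologist_license": f"L-{rng.randint(10000, 99999)}",
                "ordering_physician": f"Dr. {rng.choice('FGHIJ')} (oncology)",
                "ordering_department": _DEPARTMENTS[ct],
                "snv_indel_block": "\n".join(_render_variant_line(v) for v in variants),
                "fusion_block": "\n".join(_render_fusion_line(f) for f in fusions),
                "cnv_block": "\n".join(_render_cnv_line(c) for c in cnvs),
                "negative_findings": "" if has_findings else "negative",
                "interpretation_comment": (
                    "Findings consistent with the clinical diagnosis."
                    if has_findings
                    else "No reportable variant detected."
                ),
                "recommended_treatment": "; ".join(dict.fromkeys(therapies)),
                "references_text": "PMID:25741868" if variants else "",
                "addendum": "",
                "report_status": "final",
            }
        )
    raw_table = pd.DataFrame(raw_rows, columns=list(RAW_FIELDS))

    # clinical tables (raw-keyed; the honest broker scrubs them later)
    diagnosis_rows, surgery_rows, death_rows = [], [], []
    order_dates = {r["pathology_no"]: r["order_date"] for r in raw_rows}
    diag_dates = {}
    for row in patient_rows:
        order = _dt.date.fromisoformat(order_dates[row["pathology_no"]])
        diag = order - _dt.timedelta(days=rng.randint(3, 30))
        diag_dates[row["patient_no"]] = diag
        diagnosis_rows.append(
            {
                "patient_no": row["patient_no"],
                "event_date": diag.isoformat(),
                "attributes": json.dumps(
                    {"cancer_type": row["cancer_type"], "icd10": _ICD10[row["cancer_type"]]},
                    sort_keys=True,
                ),
            }
        )
    for patient_no in rng.sample(all_patients, round(spec.surgery_rate * total)):
        surgery_rows.append(
            {
                "patient_no": patient_no,
                "event_date": (
                    diag_dates[patient_no] + _dt.timedelta(days=rng.randint(7, 90))
                ).isoformat(),
                "attributes": json.dumps({"procedure": "resection"}, sort_keys=True),
            }
        )
    for patient_no in rng.sample(all_patients, round(spec.death_rate * total)):
        death_rows.append(
            {
                "patient_no": patient_no,
                "event_date": (
                    diag_dates[patient_no] + _dt.timedelta(days=rng.randint(60, 600))
                ).isoformat(),
                "attributes": json.dumps({"cause": "disease"}, sort_keys=True),
            }
        )
    clinical = {
        "diagnosis": pd.DataFrame(diagnosis_rows),
        "surgery": pd.DataFrame(surgery_rows).sort_values("patient_no").reset_index(drop=True)
        if surgery_rows
        else pd.DataFrame(columns=["patient_no", "event_date", "attributes"]),
        "death": pd.DataFrame(death_rows).sort_values("patient_no").reset_index(drop=True)
        if death_rows
        else pd.DataFrame(columns=["patient_no", "event_date", "attributes"]),
    }

    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "patient_no", "pathology_no", "cancer_type", "kind", "gene",
            "detail", "pathogeny", "allele_frequency",
        ],
    )
    return SyntheticCohort(
        raw_table=raw_table, clinical=clinical, ledger=ledger, patients=patients, spec=spec
    )


# ---------------------------------------------------------------------------
# Block-dialect rendering (inverse of the ingest parsers)
# ---------------------------------------------------------------------------


def _render_variant_line(v: dict) -> str:
    return "; ".join(
        [
            v["gene"], v["exon_id"], v["dna_change"], v["protein_change"],
            v["variant_info"], v["vaf_text"], v["variant_effect"],
            v["pathogeny"], v["clinical_relevance"],
        ]
    )


def _render_fusion_line(f: dict) -> str:
    return "; ".join(
        str(x)
        for x in [
            f["gene"], f["chromosome"], f["cytoband"], f["break_point"],
            f["transcript_part"], f["locus"], f["strand"],
            f["span"], f["split"], f["total"], f["distance"],
        ]
    )


def _render_cnv_line(c: dict) -> str:
    return "; ".join(
        str(x)
        for x in [
            c["gene"], c["locus"], repr(c["p_value"]), c["gain"], c["total_region"],
            repr(c["ratio"]), c["gene_count"], c["region_count"], c["sig_count"],
        ]
    )


def render_raw_report(
    report: StructuredReport, identifiers: tuple[str, str]
) -> RawReportRecord:
    """Render a structured report back into the flat 28-attribute row.

    Inverse of the ingest restructuring for every attribute the four tables
    model; context passthrough fields are restored from ``report.context``.
    ``identifiers`` supplies the raw (patient_no, pathology_no) pair, which
    a structured report deliberately no longer carries.
    """
    patient_no, pathology_no = identifiers
    pl = report.path_lab
    ctx = report.context

    parts = pl.panel_id.rsplit(" ", 1)
    if len(parts) == 2 and parts[1][:1].lower() == "v":
        panel_name, panel_version = parts
    else:
        panel_name, panel_version = pl.panel_id, ""

    variant_lines = [
        _render_variant_line(
            {
                "gene": v.gene_name, "exon_id": v.exon_id, "dna_change": v.dna_change,
                "protein_change": v.protein_change, "variant_info": v.variant_info,
                "vaf_text": repr(v.allele_frequency), "variant_effect": v.variant_effect,
                "pathogeny": v.pathogeny, "clinical_relevance": v.clinical_relevance,
            }
        )
        for v in report.variants
    ]
    fusion_lines = [
        _render_fusion_line(
            {
                "gene": f.gene_name, "chromosome": f.chromosome, "cytoband": f.cytoband,
                "break_point": f.break_point, "transcript_part": f.transcript_part,
                "locus": f.locus, "strand": f.gene_strand,
                "span": f.span_read, "split": f.split_read, "total": f.total_read,
                "distance": f.distance,
            }
        )
        for f in report.fusions
    ]
    cnv_lines = [
        _render_cnv_line(
            {
                "gene": c.gene_name, "locus": c.locus, "p_value": c.p_value,
                "gain": c.gain_region, "total_region": c.total_region,
                "ratio": c.region_ratio, "gene_count": c.gene_count,
                "region_count": c.region_count, "sig_count": c.significant_region_count,
            }
        )
        for c in report.cnvs
    ]
    has_findings = bool(report.variants or report.fusions or report.cnvs)

    return RawReportRecord(
        pathology_no=pathology_no,
        patient_no=patient_no,
        order_date=pl.test_order_date.isoformat(),
        report_date=pl.report_date.isoformat(),
        cancer_type=pl.cancer_type_code,
        primary_site=ctx.get("primary_site", ""),
        sample_type=pl.sample_type,
        tumor_cell_percentage=ctx.get("tumor_cell_percentage", ""),
        qc_dna_quantity=ctx.get("qc_dna_quantity", ""),
        qc_library=ctx.get("qc_library", ""),
        qc_overall=pl.qc_result,
        sequencer_model=pl.sequencer_type,
        panel_name=panel_name,
        panel_version=panel_version,
        reference_genome=ctx.get("reference_genome", ""),
        pathologist_name=pl.reporter,
        pathologist_license="",
        ordering_physician=ctx.get("ordering_physician", ""),
        ordering_department="",
        snv_indel_block="\n".join(variant_lines),
        fusion_block="\n".join(fusion_lines),
        cnv_block="\n".join(cnv_lines),
        negative_findings=ctx.get("negative_findings", "" if has_findings else "negative"),
        interpretation_comment=ctx.get("interpretation_comment", ""),
        recommended_treatment=pl.recommended_treatment,
        references_text=pl.references_text,
        addendum=ctx.get("addendum", ""),
        report_status=ctx.get("report_status", "final"),
    )


def clinical_records_from_frames(
    scrubbed: dict[str, pd.DataFrame],
) -> list:
    """Convert scrubbed clinical frames (alt_patient_key, event_date,
    attributes) into :class:`~cnrs.warehouse.ClinicalRecord` rows."""
    from .warehouse import ClinicalRecord

    records = []
    for domain, frame in scrubbed.items():
        if frame.empty:
            continue
        for _, row in frame.iterrows():
            attrs = row.get("attributes", "") or "{}"
            records.append(
                ClinicalRecord(
                    alt_patient_key=row["alt_patient_key"],
                    domain=domain,
                    attributes=json.loads(attrs),
                    event_date=_dt.date.fromisoformat(str(row["event_date"])),
                )
            )
    return records
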