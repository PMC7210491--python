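"""Deidentified research warehouse: structured genomic tables joined with
clinical records, queryable for cohorts and per-gene mutation frequencies.

All rows are keyed by alternative (pseudonymous) keys; the loader refuses
input that matches the raw-identifier pattern, and every export is scanned
again before it reaches disk. Mutation frequency uses *patient-level*
counting — a patient with two findings in the same gene counts once — which
is the convention needed to reproduce per-gene cohort fractions. The
frequency statistic covers point mutations (the SNV/indel variant-summary
table) only; fusion and CNV findings are reported as separate counts.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import CnrsError, LeakError, SchemaError
from .pseudonymize import scan_frame_for_ids
from .schema import (
    PATHOGENY_TIERS,
    PanelDefinition,
    StructuredReport,
    load_default_panel,
)

# Raw patient/pathology accessions use a digits-only suffix alphabet that
# never occurs in base-32 pseudonyms, so a regexp scan is unambiguous.
RAW_ID_PATTERN = re.compile(r"(?:PT|SP)[0189]{6,}")

CLINICAL_DOMAINS = (
    "diagnosis",
    "surgery",
    "chemotherapy",
    "medication",
    "laboratory",
    "followup",
    "death",
    "demographics",
)

VARIANT_KIND_FILTERS = ("snv", "indel", "fusion", "cnv")


class ClinicalRecord(BaseModel):
    """One clinical event for a patient, keyed by the alternative patient key."""

    alt_patient_key: str
    domain: Literal[CLINICAL_DOMAINS]  # type: ignore[valid-type]
    attributes: dict[str, str] = Field(default_factory=dict)
    event_date: _dt.date


class CohortFilter(BaseModel):
    """Conjunctive cohort selection; an empty set places no constraint."""

    genes: set[str] = Field(default_factory=set)
    variant_types: set[str] = Field(default_factory=set)
    pathogeny_tiers: set[str] = Field(default_factory=set)
    cancer_types: set[str] = Field(default_factory=set)
    date_range: Optional[tuple[_dt.date, _dt.date]] = None

    @field_validator("variant_types")
    @classmethod
    def _known_kinds(cls, v: set[str]) -> set[str]:
        unknown = v - set(VARIANT_KIND_FILTERS)
        if unknown:
            raise ValueError(f"unknown variant types: {sorted(unknown)}")
        return v

    @field_validator("pathogeny_tiers")
    @classmethod
    def _known_tiers(cls, v: set[str]) -> set[str]:
        unknown = v - set(PATHOGENY_TIERS)
        if unknown:
            raise ValueError(f"unknown pathogenicity tiers: {sorted(unknown)}")
        return v

    @property
    def has_finding_clause(self) -> bool:
        return bool(self.genes or self.variant_types or self.pathogeny_tiers)


@dataclass
class CohortResult:
    """Patient-level query result (alternative keys only)."""

    rows: pd.DataFrame  # alt_patient_key, cancer_type_code, report_key
    filter: CohortFilter

    @property
    def patients(self) -> list[str]:
        return list(self.rows["alt_patient_key"])

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class FrequencyTable:
    """Per-gene patient counts and fractions, overall and per cancer type."""

    frame: pd.DataFrame  # stratum, gene, n_patients_with_mutation, n_patients_in_stratum, fraction

    def lookup(self, stratum: str, gene: str) -> dict:
        hit = self.frame[(self.frame["stratum"] == stratum) & (self.frame["gene"] == gene)]
        if hit.empty:
            raise KeyError(f"no frequency row for stratum={stratum!r} gene={gene!r}")
        return hit.iloc[0].to_dict()

    def fraction(self, stratum: str, gene: str) -> float:
        return float(self.lookup(stratum, gene)["fraction"])


class Warehouse:
    """The research data store backing cohort and frequency queries.

    Tables live in memory as DataFrames and are mirrored into a single-file
    SQLite database when ``path`` is given (":memory:" keeps everything
    transient, which is what the tests use).
    """

    def __init__(self, path: str | Path = ":memory:", panel: PanelDefinition | None = None):
        self.path = str(path)
        self.panel = panel if panel is not None else load_default_panel()
        self._frames: dict[str, pd.DataFrame] = {}
        self._loaded = False

    # -- loading -------------------------------------------------------------

    def load(
        self,
        reports: Iterable[StructuredReport],
        clinical: Iterable[ClinicalRecord] = (),
    ) -> "Warehouse":
        reports = list(reports)
        clinical = list(clinical)

        path_rows, var_rows, fus_rows, cnv_rows = [], [], [], []
        seen_keys: set[str] = set()
        for r in reports:
            if r.path_lab.report_key in seen_keys:
                raise CnrsError(f"duplicate report_key {r.path_lab.report_key!r}")
            seen_keys.add(r.path_lab.report_key)
            path_rows.append(r.path_lab.model_dump())
            var_rows += [v.model_dump() for v in r.variants]
            fus_rows += [f.model_dump() for f in r.fusions]
            cnv_rows += [c.model_dump() for c in r.cnvs]

        from .schema import table_entities

        frames = {
            "path_lab": pd.DataFrame(path_rows, columns=list(table_entities("path_lab"))),
            "variant_summary": pd.DataFrame(
                var_rows, columns=list(table_entities("variant_summary"))
            ),
            "fusion_variant": pd.DataFrame(
                fus_rows, columns=list(table_entities("fusion_variant"))
            ),
            "cnv": pd.DataFrame(cnv_rows, columns=list(table_entities("cnv"))),
            "clinical": pd.DataFrame(
                [
                    {
                        "alt_patient_key": c.alt_patient_key,
                        "domain": c.domain,
                        "event_date": c.event_date.isoformat(),
                        "attributes": json.dumps(c.attributes, sort_keys=True),
                    }
                    for c in clinical
                ],
                columns=["alt_patient_key", "domain", "event_date", "attributes"],
            ),
        }

        death = [c for c in clinical if c.domain == "death"]
        if len({c.alt_patient_key for c in death}) != len(death):
            raise SchemaError("more than one death record for a patient")

        for name, frame in frames.items():
            leaks = (
                [] if frame.empty
                else sorted(
                    {
                        m.group(0)
                        for cell in frame.astype(str).to_numpy().ravel()
                        for m in RAW_ID_PATTERN.finditer(cell)
                    }
                )
            )
            if leaks:
                raise LeakError(
                    f"load refused: raw-identifier pattern in table {name!r}: {leaks[:5]}"
                )

        self._frames = frames
        self._loaded = True
        if self.path != ":memory:":
            self._persist()
        return self

    def _persist(self) -> None:
        with sqlite3.connect(self.path) as conn:
            for name, frame in self._frames.items():
                out = frame.copy()
                for col in out.columns:
                    if out[col].map(lambda x: isinstance(x, (_dt.date, _dt.datetime))).any():
                        out[col] = out[col].astype(str)
                out.to_sql(name, conn, if_exists="replace", index=False)

    def table(self, name: str) -> pd.DataFrame:
        self._require_loaded()
        return self._frames[name].copy()

    def counts(self) -> dict[str, int]:
        self._require_loaded()
        return {name: len(frame) for name, frame in self._frames.items()}

    def _require_loaded(self) -> None:
        if not self._loaded:
            raise CnrsError("warehouse not loaded")

    # -- findings helper ------------------------------------------------------

    def _findings(self) -> pd.DataFrame:
        """All findings as (report_key, gene, kind, pathogeny) rows."""
        parts = []
        var = self._frames["variant_summary"]
        if not var.empty:
            parts.append(
                var[["report_key", "gene_name", "variant_type_code", "pathogeny"]].rename(
                    columns={"gene_name": "gene", "variant_type_code": "kind"}
                )
            )
        for name, kind in (("fusion_variant", "fusion"), ("cnv", "cnv")):
            frame = self._frames[name]
            if not frame.empty:
                part = frame[["report_key", "gene_name"]].rename(columns={"gene_name": "gene"})
                part["kind"] = kind
                part["pathogeny"] = None
                parts.append(part)
        if not parts:
            return pd.DataFrame(columns=["report_key", "gene", "kind", "pathogeny"])
        return pd.concat(parts, ignore_index=True)

    # -- queries --------------------------------------------------------------

    def query_cohort(self, filter: CohortFilter) -> CohortResult:
        """Patients with at least one report satisfying every filter clause.

        Clauses combine conjunctively; within a set, membership is
        disjunctive. Finding-level clauses (genes, variant kinds,
        pathogenicity tiers) must all be satisfied by a single finding.
        Ordering is deterministic (by alternative patient key).
        """
        self._require_loaded()
        unknown = filter.genes - self.panel.genes
        if unknown:
            raise CnrsError(f"unknown gene symbol(s) in filter: {sorted(unknown)}")

        reports = self._frames["path_lab"]
        if reports.empty:
            return CohortResult(
                rows=pd.DataFrame(columns=["alt_patient_key", "cancer_type_code", "report_key"]),
                filter=filter,
            )
        mask = pd.Series(True, index=reports.index)
        if filter.cancer_types:
            mask &= reports["cancer_type_code"].isin(filter.cancer_types)
        if filter.date_range is not None:
            lo, hi = filter.date_range
            dates = pd.to_datetime(reports["report_date"].astype(str))
            mask &= (dates >= pd.Timestamp(lo)) & (dates <= pd.Timestamp(hi))

        if filter.has_finding_clause:
            findings = self._findings()
            fmask = pd.Series(True, index=findings.index)
            if filter.genes:
                fmask &= findings["gene"].isin(filter.genes)
            if filter.variant_types:
                fmask &= findings["kind"].isin(filter.variant_types)
            if filter.pathogeny_tiers:
                fmask &= findings["pathogeny"].isin(filter.pathogeny_tiers)
            qualifying = set(findings.loc[fmask, "report_key"])
            mask &= reports["report_key"].isin(qualifying)

        hits = reports.loc[mask, ["alt_subject_key", "cancer_type_code", "report_key"]]
        hits = hits.sort_values(["alt_subject_key", "report_key"])
        # patient-level: first qualifying report supplies the stratum
        rows = (
            hits.groupby("alt_subject_key", as_index=False)
            .first()
            .rename(columns={"alt_subject_key": "alt_patient_key"})
            .sort_values("alt_patient_key")
            .reset_index(drop=True)
        )
        return CohortResult(rows=rows, filter=filter)

    def mutation_frequency(self, stratify_by_cancer: bool = True) -> FrequencyTable:
        """Per-gene fraction of patients carrying a point mutation.

        Point mutations are the SNV/indel variant-summary findings; fusions
        and CNVs are excluded (see :meth:`finding_counts`). Denominators are
        patients per stratum; numerators count each patient once per gene.
        """
        self._require_loaded()
        reports = self._frames["path_lab"]
        variants = self._frames["variant_summary"]
        if reports.empty:
            return FrequencyTable(
                frame=pd.DataFrame(
                    columns=[
                        "stratum", "gene",
                        "n_patients_with_mutation", "n_patients_in_stratum", "fraction",
                    ]
                )
            )
        patient_stratum = reports[["alt_subject_key", "cancer_type_code", "report_key"]]
        if variants.empty:
            joined = pd.DataFrame(columns=["alt_subject_key", "cancer_type_code", "gene_name"])
        else:
            joined = variants[["report_key", "gene_name"]].merge(
                patient_stratum, on="report_key", how="left"
            )

        rows = []
        strata: list[tuple[str, pd.DataFrame, int]] = []
        n_all = patient_stratum["alt_subject_key"].nunique()
        strata.append(("all", joined, n_all))
        if stratify_by_cancer:
            for ct, denom_grp in patient_stratum.groupby("cancer_type_code"):
                sub = joined[joined["cancer_type_code"] == ct]
                strata.append((str(ct), sub, denom_grp["alt_subject_key"].nunique()))

        for stratum, sub, denom in strata:
            if sub.empty or denom == 0:
                continue
            counts = sub.groupby("gene_name")["alt_subject_key"].nunique()
            for gene, n in counts.sort_index().items():
                rows.append(
                    {
                        "stratum": stratum,
                        "gene": gene,
                        "n_patients_with_mutation": int(n),
                        "n_patients_in_stratum": int(denom),
                        "fraction": int(n) / int(denom),
                    }
                )
        return FrequencyTable(frame=pd.DataFrame(rows))

    def finding_counts(self) -> dict[str, int]:
        """Separate totals for point-mutation, fusion and CNV findings."""
        self._require_loaded()
        return {
            "point_mutation_records": len(self._frames["variant_summary"]),
            "fusion_records": len(self._frames["fusion_variant"]),
            "cnv_records": len(self._frames["cnv"]),
        }

    # -- clinical linkage ------------------------------------------------------

    def link_clinical(self, cohort: CohortResult, domains: set[str]) -> pd.DataFrame:
        """Left-join clinical domains onto a cohort, one row per patient.

        Patients lacking a domain keep their row with empty columns. When
        both diagnosis and death dates are present, ``survival_days`` (death
        minus diagnosis, integer days) is derived.
        """
        self._require_loaded()
        unknown = set(domains) - set(CLINICAL_DOMAINS)
        if unknown:
            raise CnrsError(f"unknown clinical domain(s): {sorted(unknown)}")
        dataset = cohort.rows.copy()

        variants = self._frames["variant_summary"]
        reports = self._frames["path_lab"]
        if not variants.empty:
            genes = (
                variants.merge(
                    reports[["report_key", "alt_subject_key"]], on="report_key"
                )
                .groupby("alt_subject_key")["gene_name"]
                .apply(lambda g: ",".join(sorted(set(g))))
            )
            dataset["mutated_genes"] = (
                dataset["alt_patient_key"].map(genes).fillna("")
            )
        else:
            dataset["mutated_genes"] = ""

        clinical = self._frames["clinical"]
        for domain in sorted(domains):
            sub = clinical[clinical["domain"] == domain] if not clinical.empty else clinical
            if sub is None or sub.empty:
                dataset[f"{domain}_date"] = ""
                dataset[f"{domain}_attributes"] = ""
                continue
            first = (
                sub.sort_values("event_date")
                .groupby("alt_patient_key", as_index=True)
                .first()
            )
            dataset[f"{domain}_date"] = (
                dataset["alt_patient_key"].map(first["event_date"]).fillna("")
            )
            dataset[f"{domain}_attributes"] = (
                dataset["alt_patient_key"].map(first["attributes"]).fillna("")
            )

        if {"diagnosis", "death"} <= set(domains):
            def _days(row) -> object:
                if row["diagnosis_date"] and row["death_date"]:
                    d0 = _dt.date.fromisoformat(row["diagnosis_date"])
                    d1 = _dt.date.fromisoformat(row["death_date"])
                    return (d1 - d0).days
                return pd.NA

            dataset["survival_days"] = dataset.apply(_days, axis=1)
        return dataset


# -- export --------------------------------------------------------------------


def export_dataset(
    dataset: pd.DataFrame,
    path: str | Path,
    format: str = "csv",
    allow_empty: bool = False,
) -> Path:
    """Write an analysis dataset with a JSON data-dictionary sidecar.

    The frame is scanned for the raw-identifier pattern first; any hit
    blocks the export.
    """
    if dataset.empty and not allow_empty:
        raise CnrsError("refusing to export an empty dataset (pass allow_empty=True)")
    if format not in ("csv", "tsv", "json"):
        raise CnrsError(f"unsupported export format {format!r}")

    if not dataset.empty:
        leaks = sorted(
            {
                m.group(0)
                for cell in dataset.astype(str).to_numpy().ravel()
                for m in RAW_ID_PATTERN.finditer(cell)
            }
        )
        if leaks:
            raise LeakError(f"export blocked: raw-identifier pattern found: {leaks[:5]}")

    path = Path(path)
    if format == "csv":
        dataset.to_csv(path, index=False)
    elif format == "tsv":
        dataset.to_csv(path, index=False, sep="\t")
    else:
        dataset.to_json(path, orient="records", indent=2)

    sidecar = path.with_suffix(path.suffix + ".dict.json")
    sidecar.write_text(
        json.dumps(
            {
                "columns": [
                    {"name": c, "dtype": str(dataset[c].dtype)} for c in dataset.columns
                ],
                "rows": len(dataset),
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    return path
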