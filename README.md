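# cnrs — clinical NGS report structuring and research warehouse

`cnrs` is a pipeline for turning semi-structured clinical cancer-panel
sequencing reports — the kind stored as one flat 28-attribute row per report
in a hospital EHR, with findings buried in free-text blocks — into a
standardized, deidentified, queryable research store. It is aimed at
translational-research informatics teams who need to build mutation-defined
cohorts joined with clinical data (diagnosis, surgery, death) without ever
exposing patient identifiers.

The pipeline has five stages:

1. **Structuring** (`cnrs.ingest`): each raw row is restructured into four
   relational tables — pathologic/laboratory information (9 named
   attributes), variant summary (9), gene fusion (11) and copy-number
   variation (9) — 38 named attributes plus 11 linkage/discriminator
   columns, 49 column entities in all. DNA- and protein-level variant
   descriptions are validated against an HGVS-style grammar
   (`c.2573T>G`, `p.Leu858Arg`, deletions, duplications, frameshifts), and
   vocabulary fields (pathogenicity tiers, QC results, sample types) are
   normalized to closed vocabularies. A completeness checker evaluates each
   structured report against the 10 required and 7 optional ISO/TS 20428
   report categories.
2. **Pseudonymization** (`cnrs.pseudonymize`): an honest-broker key manager
   issues a random alternative ID per report and a patient alternative key
   per patient, strips raw identifier columns from staged tables, and is the
   only component able to reverse the mapping (credential required).
   Pseudonyms share no substring of length ≥ 4 with the identifiers they
   replace, and every downstream export is substring-scanned before it
   reaches disk.
3. **Warehouse** (`cnrs.warehouse`): structured genomic tables and clinical
   records keyed by alternative keys; supports conjunctive cohort filters
   (genes × variant kinds × pathogenicity × cancer types × dates), clinical
   left-joins with survival-day derivation, and a per-gene mutation
   frequency table. Frequencies use **patient-level counting** — a patient
   with two TP53 variants counts once — over point mutations (SNV/indel)
   only; fusions and CNVs are separate statistics.
4. **Synthetic cohort** (`cnrs.synth`): an exact-count generator that emits
   EHR-style raw tables whose marginals match a `CohortSpec` precisely. The
   packaged default reproduces a 367-report pan-cancer cohort (249 lung,
   70 ovarian, 8 breast, …) with pinned per-gene mutated-patient counts
   (e.g. TP53 167 overall / 120 lung / 39 ovarian).
5. **Rendering** (`cnrs.viewer`): a structured report rendered as the
   standardized three-section document (basic test information; sequencing
   methods; variants with reporting results) in JSON, markdown or text.

The gene panel is a registry of 91 entries over 88 unique genes
(14 mandatory, 74 additional, 3 fusion genes that duplicate symbols already
on the panel).

## Worked example

```python
from cnrs import (CohortFilter, KeyManager, Warehouse,
                  clinical_records_from_frames, default_ncc_spec, etl_batch,
                  generate_cohort, load_default_panel)

panel = load_default_panel()
cohort = generate_cohort(default_ncc_spec(seed=7))      # 367 raw EHR rows
keys = KeyManager(credential="example", seed=7)          # honest broker
reports, log = etl_batch(cohort.raw_table, panel, keys)  # structure + pseudonymize
clinical = clinical_records_from_frames(keys.scrub_and_link(cohort.clinical))
wh = Warehouse(panel=panel).load(reports, clinical)

print(log.summary())
print(len(wh.query_cohort(CohortFilter(cancer_types={"lung"}))), "lung patients")
freq = wh.mutation_frequency()
row = freq.lookup("all", "TP53")
print(f"TP53: {row['n_patients_with_mutation']}/{row['n_patients_in_stratum']}"
      f" = {row['fraction']:.1%}")
```

prints

```
{'rows_in': 367, 'reports_out': 367, 'failures': 0}
249 lung patients
TP53: 167/367 = 45.5%
```

i.e. all 367 raw rows were structured without failure, the lung cohort
contains 249 patients, and 45.5% of patients carry a TP53 point mutation —
exact by construction, because generation plants counts rather than sampling
rates, and the pipeline conserves them end to end.

A CLI wraps the same functions: `cnrs run` executes the full pipeline;
`cnrs synth`, `cnrs ingest`, `cnrs keys register|export-audit`, `cnrs query`,
`cnrs freq`, `cnrs render` and `cnrs schema-export` expose the stages
individually (`cnrs --help`).

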