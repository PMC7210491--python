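# Methods

## The data model

A clinical panel-sequencing report arrives as one flat row of 28 attributes
(identifiers, dates, QC fields, sequencing metadata, three free-text finding
blocks, interpretive text). The pipeline restructures it into four tables:

| table | named attributes | structural columns |
|---|---|---|
| path_lab | identifiers, test_order_date, qc_result, sample_type, report_date, reporter, sequencer_type, recommended_treatment, references_text (9) | report_key, alt_subject_key, cancer_type_code, panel_id (4) |
| variant_summary | gene_name, exon_id, dna_change, protein_change, variant_info, allele_frequency, variant_effect, pathogeny, clinical_relevance (9) | record_key, report_key, variant_type_code (3) |
| fusion_variant | gene_name, chromosome, cytoband, break_point, transcript_part, locus, gene_strand, span_read, split_read, total_read, distance (11) | record_key, report_key (2) |
| cnv | gene_name, locus, p_value, gain_region, total_region, region_ratio, gene_count, region_count, significant_region_count (9) | record_key, report_key (2) |

38 named + 11 structural = 49 column entities. The structural columns are
the minimum needed to realize the decomposition relationally: surrogate and
linkage keys, a pseudonymous subject key, the cancer-type stratum and a
variant-type discriminator. The exact ledger is pinned by test, by name.

Conventions: dates are ISO 8601; genomic coordinates are 1-based inclusive
(HGVS convention); strand is stored as ASCII `+`/`-`, with the typographic
minus (U+2212) accepted on input. Pathogenicity is a closed five-tier
(ACMG-style) vocabulary — pathogenic, likely_pathogenic,
uncertain_significance, likely_benign, benign — even though routine reports
mostly use the top three; the lower tiers cost nothing and avoid a lossy
remap. The cancer-type vocabulary covers the eleven types in the reference
cohort plus `other`. Allele frequencies are fractions in [0, 1]; a parsed
value carrying `%` or exceeding 1 is divided by 100, and a bare `1` is
treated as a fraction of 1.0.

### ISO/TS 20428 category mapping

The standard names 10 required and 7 optional report categories but does not
prescribe a field-level mapping, so the checker uses a fixed one: a category
is present iff every mapped field is nonempty.

Required: clinical_sequencing_orders ← test_order_date; subject_of_care ←
alt_subject_key + cancer_type_code; authorized_orderer ← ordering physician
(context); performing_laboratory ← reporter + sequencer_type;
diseases_and_phenotypes ← cancer_type_code; biomaterial ← sample_type;
genetic_variations ← any finding, or an explicit negative-findings flag;
variant_classification ← pathogeny on every variant; recommended_treatment ←
recommended_treatment; addendum ← addendum (context).

Optional: medical_history, family_history, racial_genomic_information ←
passthrough context text (absent by default); reference_genome_version ←
reference genome (context); genetic_variation ← variant_info on ≥ 1 variant;
detailed_sequencing_information ← panel_id + sequencer_type; references ←
references_text.

Fields the four tables do not model (ordering physician, addendum,
reference genome, the negative-findings flag, interpretation comments)
travel in a `context` dict on the structured report. It exists solely so the
completeness checker can evaluate their categories; it is not part of the
49-entity ledger, and license numbers and department codes are dropped to
the audit log instead. The checker is monotone: populating a field can only
move categories from absent to present.

## Parsing

Finding blocks use a templated dialect — one finding per line,
semicolon-delimited positional fields in table order (9 fields for
SNV/indel, 11 for fusion, 9 for CNV; the trailing free-text field of the
variant line may itself contain semicolons). This emulates templated
free-text entry; genuinely unconstrained prose is out of scope.

The HGVS grammar is a purpose-built regex parser covering substitution,
deletion, insertion, duplication, delins and protein-level frameshift at the
`c.` and `p.` levels, with intronic offsets folded onto their anchor base.
Descriptions with any other prefix (`g.`, `m.`, bare strings) are always
rejected; a `c.`/`p.`-prefixed description the grammar does not recognize is
an error in strict mode and `kind=other` (raw preserved) in lenient mode.
The DNA-change kind drives the snv/indel discriminator: substitutions are
SNVs, everything else an indel.

Strict vs lenient is one pipeline-wide flag (default strict). Lenient mode:
off-panel genes are excluded with a warning, unknown pathogenicity terms
fall back to uncertain_significance, malformed rows are logged and skipped
without aborting the batch. Duplicate variant lines (same gene + DNA change)
within a report collapse to the first with a warning in both modes. Batch
accounting always satisfies rows_in = reports_out + failures.

## Pseudonymization

Alternative IDs are `NCC-` + 10 characters of RFC-4648 base-32 + one
checksum character (weighted sum mod 32); patient alternative keys use the
`NCP-` prefix. Two levels exist because a per-report pseudonym alone cannot
link a patient's reports inside the warehouse, while a per-patient key alone
would make report accessions guessable; the keystore holds both. Issuance is
idempotent per (patient, pathology) pair and injective overall; a candidate
token is regenerated if it collides or shares any substring of length ≥ 4
with the identifiers it replaces. Tokens come from a seedable generator —
OS entropy by default, an explicit seed for reproducible fixtures.

The at-rest keystore is a JSON envelope whose payload is XORed with a
PBKDF2-HMAC-SHA256-derived keystream, with a salted passphrase hash for
verification, written mode 0600. This is obfuscation plus access control,
deliberately not a formal encryption claim; the package's privacy contract
is substring-unlinkability, enforced by scanning: `scrub_and_link` refuses
unregistered identifiers and re-scans its own output, the warehouse loader
refuses anything matching the raw-accession pattern, and `export_dataset`
scans again before writing.

## Warehouse semantics

Cohort membership is patient-level: a patient is selected iff at least one
of their reports satisfies **all** filter clauses (conjunction across
clauses, disjunction within a set; the finding-level clauses — genes,
variant kinds, pathogenicity tiers — must be met by a single finding). The
qualifying report supplies the stratum. Ordering is deterministic by
alternative patient key.

`mutation_frequency` counts *patients, not variant records*, per (stratum,
gene), over the variant-summary table only — fusion and CNV findings are
excluded from the statistic and exposed as separate counts. Both choices are
required for per-gene cohort fractions of the usual form (n carriers /
stratum size) to be well defined. Denominators are patients per stratum.

Clinical linkage is a left join (patients without a domain keep empty
columns); when diagnosis and death dates are both present,
`survival_days = death − diagnosis` in integer days. Storage is in-memory
DataFrames mirrored to a single-file SQLite database on request.

## The synthetic cohort generator

The generator emulates the EHR feed: a 28-column raw report table plus
diagnosis/surgery/death tables keyed by raw patient IDs, with every marginal
in the spec reproduced **exactly** (allocation, not Bernoulli sampling), so
downstream fractions carry no sampling error. The default spec encodes the
reference cohort: 367 reports (249 lung, 70 ovarian, 8 breast, 7 melanoma,
7 colon, 7 stomach, 6 liver, 5 thyroid, 5 kidney, 2 brain, 1 prostate) and
the pinned per-gene mutated-patient counts TP53 167 (120 lung, 39 ovarian,
3 breast), EGFR 56 (51 lung), KRAS 34 (27 lung), BRCA1 21 (9 ovarian),
PIK3CA (5 ovarian, 3 breast) and BRCA2 (3 breast). Eight further genes
(CDKN2A, BRAF, MET, STK11, PTEN, ATM, NRAS, and cohort-wide totals for
PIK3CA) carry unpinned counts of 8–15 chosen once to round the distribution
out to roughly the twelve most frequently mutated genes of such a cohort;
no test or acceptance value depends on them.

Allocation: pinned per-stratum cells are kept verbatim; the remainder of a
cohort-wide count is distributed over the *unpinned* strata by a seeded
shuffle of per-stratum capacity slots (exact totals, deterministic per
seed); carriers within a stratum are then drawn by seeded sampling.
Feasibility (cell ≤ stratum size; overall ≥ pinned sum and ≤ pinned sum +
free capacity) is checked before any generation.

Variant details come from a small curated exemplar table of recurrent,
realistic per-gene variants (hotspot substitutions, known founder
frameshifts); genes without exemplars get a synthetic generic substitution.
VAFs are uniform on [5%, 60%] (one-decimal percent); pathogenicity is drawn
from a 45/30/25 pathogenic / likely-pathogenic / VUS mix. Fusions (ALK,
ROS1, RET at canonical breakpoint regions) are planted in 5% of patients and
CNVs in 8% — ballpark rates for a pan-cancer panel cohort, configurable in
the spec. Every patient gets a diagnosis record; 30% get surgery and 20% a
death record for linkage tests. Report dates spread deterministically over a
23-month accrual window. Raw accessions are `PT`/`SP` plus eight digits from
{0, 1, 8, 9} — an alphabet disjoint from base-32 pseudonyms — so substring
leak-scans cannot produce coincidental hits. Identical specs (including
seed) yield byte-identical output; a ground-truth ledger records every
planted finding for oracle tests.

What the generator does **not** emulate: mutational signatures,
co-occurrence and mutual-exclusivity structure, multi-report patients,
messy real-world free text (typos, layout drift), or missingness patterns.
Passing tests therefore demonstrate correctness of the structuring,
pseudonymization and counting machinery under clean templated input — not
robustness to arbitrary EHR prose.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 367-report cohort end to end
(a few seconds) plus small hand-built stores (≤ 50 patients) wherever a
brute-force oracle is compared. CNV `region_ratio` must equal
gain/total within 1e-9; frequencies are exact rational counts formatted to
one decimal percent at reporting time. Ties in duplicate-variant collapse
keep the first occurrence. Degenerate inputs: empty blocks yield empty
finding lists; an empty batch with a valid header yields zero reports; an
empty warehouse yields an empty frequency table rather than an error.

## Known limitations

- The 28-attribute raw layout and the block dialect are this package's
  reconstruction of a templated hospital report; real exports will need a
  column-mapping shim in front of `etl_batch`.
- The completeness checker's category→field mapping is one defensible
  reading of the standard's categories, not a certified conformance test.
- The keystore protects against casual inspection and accidental linkage,
  not against a determined attacker with file access.
- Frequencies assume one report per patient gives the intended denominator;
  with multi-report patients the patient-level counting still holds, but
  stratum assignment follows the qualifying report and conflicts are only
  logged.
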