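# Methods

## Dimensional model

The warehouse is a star schema with a single fact table (`aliquot_fact`)
at the grain of one analyte measured on one aliquot, and four dimension
tables (person, sample, analyte, source). Surrogate integer keys are
assigned by the store and never reused; external identifiers are stored
verbatim — no transform is applied at storage time, so any later linkage
decision is reviewable against the original strings. Natural keys make
loads idempotent: a person is `(project, person_id_ext)`, an analyte is
`(analyte_name, assay_family)`, a source is `(file_name, file_hash)` —
re-uploading an identical file is rejected outright, naming the prior
upload date. A fact is unique on
`(aliquot_id_ext, analyte_key, source_key, stim)`: the same aliquot
re-tested in a second kit lot arrives via a different source and is kept
as a distinct fact, never deduplicated.

Persistence is a single SQLite file (or `":memory:"`), chosen over a
client–server RDBMS so a whole warehouse is one portable, testable
artifact. Foreign-key enforcement is on; `integrity_report()`
additionally recomputes orphan counts by full scan rather than trusting
the constraint machinery.

Person attributes are modeled as time-invariant. Age is stored as
age-at-enrollment in years and banded deterministically into decades
(`<20`, `20-29`, …, `80+`) so the cube can segregate by age band with a
concrete, testable rule. Kit lot is an attribute of the source (one lot
per batch file), the simplest placement consistent with lot appearing as
a cube level. Vocabulary-controlled fields accept the sentinel
`"unknown"`, which is a real member in the cube rather than a null.

## Ingestion

Batch sheets use one canonical wide dialect (CSV or first-worksheet
XLSX): two header rows (analyte names, then units per analyte), an ID
column, an optional `stim` column for phospho-flow, one readout cell per
analyte. Lab-native exports must be pre-converted; one documented dialect
beats guessing several undocumented ones. Cell grammar: plain number →
`in_range`; `<x` → `below_loq` keeping `x` as the readout; `>x` →
`above_loq`; blank → no fact. Anything else is a format error carrying
1-based row/column coordinates. Units are stamped verbatim from the
column header onto every fact. Tissue (from the upload-time source
attributes) is stamped per fact; a time-point hint at upload is advisory
only — time points live on samples, and metadata wins on conflict.

Metadata sheets are free-form (records in rows, attributes in columns).
A column mapping assigns sheet columns to warehouse attributes; person
attributes activate only when a person-ID column is mapped, sample
attributes (time ordinals) only with a sample-ID column. Vocabulary
resolution is case-folded and whitespace-trimmed exact matching plus
explicit incoming→valid maps; there is no fuzzy matching, and a load with
any unresolved value is rejected listing the offenders — no silent
coercion. Gender, ethnicity and condition vocabularies are global;
response, treatment and time-point labels are project-scoped. The seed
vocabularies shipped are editable defaults, not a claim about any
particular site's lists. Batch results and metadata may load in either
order.

On reload, an incoming `"unknown"`/empty value never overwrites known
stored metadata (merge semantics); reloading an identical sheet reports
zero created and zero changed.

## Identifier linkage

A link session snapshots the currently-unmapped children (distinct
aliquot IDs, or samples without a person) and all candidate parents, as
*working strings* initialized to the verbatim IDs. Transforms — phrase
removal (every occurrence) and an optional case-fold — apply per side,
are recorded in order, and are replayable, which is the invariant the
audit trail rests on. Matching is exact equality of working strings and
case-sensitive by default, since lab IDs can legitimately differ only by
case; whether the historical interactive tools matched case-insensitively
is unknown, so the default here is documented rather than claimed
faithful. "Map equals" proposes a pair only when a child's working
string matches exactly one parent; collisions are surfaced as ambiguous
and never auto-resolved. Commit is atomic — all proposed pairs or none —
aborts if any child was mapped concurrently, and writes an audit record
containing the transforms and pairs.

## Cube semantics

Aggregation denormalizes the fact table once per store state (cached,
invalidated by a mutation counter) into one string column per level.
Conventions:

* null time ordinals and blank source fields → `"(unspecified)"`;
* facts with no sample link (or samples with no person) → `"(unmapped)"`
  under person/time levels, so integrity gaps are visible in the cube;
* all members are strings; time ordinals render as their integer text.

Roll-up subtotals are produced at every prefix depth of each axis with
`"(all)"` padding. **Units** is the exception: when not explicitly placed
on an axis it is appended as an implicit finest row grouping, and in
either case it is excluded from roll-up — so no cell, including
subtotals, ever pools facts with different units strings. A consequence
is that "grand totals" are per units value, which is the meaningful
quantity (a sum of MFI and pg/ml counts would be arithmetic on
incommensurables; N subtotals per units are still additive).

Measures: N, arithmetic mean, median (mean of the two central order
statistics for even N — a convention, stated rather than inherited),
min, max; sd is the sample standard deviation (n−1, null for N<2) and
cv = sd/mean (null when the mean is 0); sd and cv are extensions beyond
the original measure set. Empty cells have N=0 and null for everything
else. Lot is an ordinary level: a query that does not display it pools
across lots, and the per-lot view is one drill-down away.

Drill-through reapplies the query's filters plus the cell's concrete
members and returns the contributing rows with person/sample/source
context; its row count equals the cell's N by construction, and
re-aggregating the detail reproduces the cell's statistics bit-exact
(same values, same order, same reduction).

Queries are structured JSON-serializable objects; no MDX-style query
language is implemented. Pivot exports are lossless: CSV with nested
column headers flattened by `"/"` and a `|measure` suffix (members
containing those characters would need escaping; none of the shipped
vocabularies do), and JSON validated against the shipped
`pivot_schema.json`. A filter naming a member absent from the store's
domain is a query error rather than silently empty.

## Synthetic cohort

The generator emulates a vaccination-response monitoring design: `n`
healthy participants (default 434), sampled at study days 0, 7 and 28;
a 51-analyte bead panel run in two kit lots with a fraction of samples
(default 15%) re-tested on the second lot; a 4-plex
electrochemiluminescence panel (IL-1β, IL-6, IL-8, TNF); and phospho-flow
with seven cytokine stimulations plus an unstimulated baseline, read out
as pSTAT1/3/5 MFI.

Readouts for analyte *a* on a sample from person *p* in lot *l* are

    y = B_a · L_l · F_a^[p is female] · exp(ε),   ε ~ N(0, σ²)

with per-analyte baselines `B_a` drawn log-uniformly (500–20000 for
MFI-like values — arbitrary but seed-fixed; no claim of matching real
instrument magnitudes), lot factors `L` = 1.0 / 1.25, and planted
female/male folds `F_a` (defaults: ENA-78 1.35, GM-CSF 1.30, Leptin 1.60,
PDGF-BB 1.40; 1.0 elsewhere). Log-normal noise (σ = 0.3 on the log scale)
was chosen because MFI-like readouts are positive and right-skewed. With
these defaults the standard error of a per-analyte log fold estimate is
≈ 0.3·√(2/651) ≈ 0.017 pooled (≈ 0.025 per lot), so the 20% screen
threshold sits many standard errors from both the null analytes and the
planted ones — the screen is expected to recover the planted set almost
always, and the test battery requires ≥95 of 100 seeds. About 1% of bead
cells are marked below the limit of quantification. An optional coupling
parameter (default off) makes females — the higher serum IL-6 group —
show reduced pSTAT1 induction under IL-6 stimulation, emulating a
cross-assay relationship.

Aliquot IDs are decorated with a lab-style prefix/suffix (`HIMC-…_A` by
default) whose removal phrases are declared in the manifest, so the
linkage workflow has real work to do and a known answer. Metadata sheets
deliberately carry unharmonized terminology ("M"/"F", mixed-case
ethnicity) to exercise vocabulary mapping. The manifest records the full
parameterization, the true folds, and noise-free expected means per
analyte × gender × lot.

What the generator does **not** emulate: plate/batch effects beyond the
single lot factor, calibration curves (facts arrive as already-computed
readouts), missingness structure, longitudinal within-person correlation
(visits are independent draws), or realistic absolute concentrations.
Passing tests therefore demonstrate the correctness of the warehouse,
linkage and cube machinery under a known truth — not robustness to the
full messiness of real laboratory data, in particular not to batch
effects that would require normalization before cross-experiment
comparison.

## Problem sizes and determinism

The random-query oracle battery uses 20 stores of up to 1000 facts with
50 queries checked cell-by-cell against an independent flat
filter-group-aggregate reference (built from CSV table exports and stdlib
statistics, deliberately off the engine's code path). Roll-up,
drill-through and closure checks run on the full default cohort
(~113k facts); the 100-seed screen study regenerates the bead-assay
family per seed through the complete ingest-link-query pipeline on an
in-memory store. Every stochastic component — generator, oracle
batteries, property tests — is seeded; identical study specifications
produce byte-identical files, and identical store+query pairs produce
byte-identical exports (no timestamps inside exported artifacts; load
timestamps live in the source dimension and audit log only).

## Known limitations

* Single-writer embedded store; no concurrency or web service.
* One batch-sheet dialect; instrument-native exports need pre-conversion.
* No statistical testing, normalization or charting — the intended
  hand-off is table export to external analysis tools.
* Cross-assay analyte identity (IL-6 by bead vs electrochemiluminescence)
  is by name match at query time; analytes are scoped per assay family in
  the dimension table.
* `"(all)"` and `"(unmapped)"` are reserved member names; external data
  using them literally would collide.
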