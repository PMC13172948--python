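# Methods

## The screening problem

Spontaneous reporting databases collect voluntary reports of suspected
adverse drug reactions. Disproportionality analysis asks, for a drug
(here: a cannabis-derived-product exposure group) and an event (a
MedDRA-style preferred term, PT), whether the pair is co-reported more
often than expected if drug and event were independent across the
database. The unit of analysis throughout is the **deduplicated
report**: a report contributes at most once to any cell of any 2×2
table, regardless of repeated drug mentions or repeated PT listings.

## Deduplication and calendar anchoring

Cases accumulate follow-up versions across quarterly files. The pipeline
keeps every non-date field from the most recent version — highest
`caseversion`, ties broken by latest receipt date and then lexicographic
`primaryid` (deterministic, with a warning) — and anchors the report on
the earliest receipt quarter across its versions. Field-level merging
across versions is deliberately **not** performed: the whole record wins
from the latest version. This whole-record rule is the simplest policy
consistent with "most recent update linked to the initial report date"
and is the main sensitivity knob a re-analysis might turn. Reports with
no reaction PT are dropped (with a logged count); they cannot enter any
contingency table.

Age arrives as (value, unit) pairs; conversion to years uses
DEC×10, YR×1, MON÷12, WK÷52.1775, DY÷365.25, HR÷8766 (365.25-day years,
chosen for explicitness over locale conventions). Negative or
unparseable values become missing with a warning — data rows never
raise.

## Exposure definition

Candidate terms are surfaced by fourteen case-insensitive substring
queries over normalized verbatim drug names (normalization: uppercase,
collapse whitespace runs, strip edge punctuation; no stemming).
Substring search is intentionally high-sensitivity; specificity comes
from the curated term→group mapping, which assigns each normalized term
to one of the seven exposure groups or excludes it. Discovered terms
missing from the mapping go to a review queue (fatal only in strict
mode), mirroring the iterative curation such inventories require.

Two deliberate choices:

- **THC/CBD is a term-level group.** A report containing one THC term
  and one CBD term in separate drug entries gets {THC, CBD}, not
  THC/CBD; only explicit combination strings map to THC/CBD.
- **Mapping tables may contain terms outside the query closure** (e.g. a
  brand spelling that no query matches). These are accepted with a
  warning rather than rejected, since a curator may add synonyms the
  queries can never surface; they simply cannot appear in a discovered
  inventory.

Reports join a group through mentions in **any** role; within a group,
the reported role is resolved by the priority PS > SS > I > C.

## Descriptive stratification

Age bins are left-closed at 13, 18, 36, 55, 70; sex, role and
reporter-region (Canada / United States / Europe / Other / Missing, with
a configurable Europe code list) complete the Table-1 layout. Missing is
always its own category. Percentages use the group's report total as the
denominator, and a report in several groups contributes to each group's
column. Outcome rows are the documented exception to column
conservation: a report may carry several outcome codes, so outcome
counts can exceed the group total and are not renormalized.

## Disproportionality estimators

For exposed group reports (a with the PT, b without) and comparator
reports (c, d), with N = a+b+c+d and E = (a+b)(a+c)/N:

- **ROR** = ad/bc; 95% CI `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`.
- **PRR** = [a/(a+b)]/[c/(c+d)]; 95% CI
  `exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`.
- **IC** (BCPNN information component), gamma-Poisson shrinkage form:
  a ~ Poisson(μ) with prior μ ~ Gamma(½, rate 1/(2E)) (prior mean E)
  gives posterior μ ~ Gamma(a+½, 1+1/(2E)). The point estimate
  IC = log₂((a+½)/(E+½)) is exactly log₂ of the posterior mean over E,
  and the 95% credible bounds are log₂ of posterior quantiles over E.
  The closed-form lower-bound approximation
  IC₀₂₅ ≈ IC − 3.3(a+½)^(−1/2) − 2.4(a+½)^(−1) is provided both as a
  fast cross-check (it agrees with the exact quantile within 0.25 bits
  for a ≥ 10 over 0.1 ≤ a/E ≤ 10) and as an optional flagging rule.
  The gamma form is the default because it gives exact quantiles and
  matches current practice; the approximation variant exists because
  older BCPNN implementations used moment expansions.

Signals: ROR/PRR flag when the CI lower bound exceeds 1; IC flags when
IC₀₂₅ > 0. Flags are stored alongside the estimates and re-derivable
from the bounds.

Numerical and degenerate-input policy:

- Zero cells leave ROR/PRR **undefined** (NaN markers, never
  exceptions); the optional Haldane +0.5 correction must be requested
  explicitly — defaults never manufacture estimates. Undefined estimates
  never flag.
- The default comparator is *all other reports* (other CDP groups
  included); an exclude-all-CDP policy is available as a sensitivity
  analysis, since either reading of a full-database comparator is
  defensible.
- `min_count` defaults to 1 (hypothesis-free: no a-priori event list);
  the observed count is reported so users can post-filter.
- No multiple-testing adjustment is applied; the number of estimated
  pairs is recorded in the output metadata for downstream use. The IC's
  shrinkage is the built-in small-count control.
- An empty exposure margin is an error; an empty stratum in subgroup
  analysis is a warning and a skipped stratum.

A property worth noting: IC is **not** strictly increasing in a for
arbitrary tables (both margins grow with a; at a=3, b=c=d=1 and a=4,
b=c=d=1 the IC is exactly log₂(21/19) in both cases). Monotonicity
holds in the surveillance regime N ≫ a², which is where screening
operates; the test suite asserts exactly that and freezes the
counterexample.

## Subgroup (indication) stratification

Reports of the screened group are split by whether a mention of the
group's own terms carries an indication PT from the given set (e.g. the
seizure-like indication); comparator reports are split by whether any of
their mentions does. Screening then runs independently within each
stratum, which is how indication-driven signals (events that are really
features of the treated condition) are separated from
indication-independent ones.

## Reporting artefacts

Ranked tables keep IC-flagged signals ordered by IC₀₂₅ descending, ties
broken by (a descending, PT ascending). Sector maps place the union of a
SOC's observed PTs in alphabetical order by PT name, identically for
both compared groups; each cell carries IC₀₂₅, with *absent* (PT never
observed for the group, NaN) kept distinct from *observed but no signal*
(IC₀₂₅ ≤ 0). The numeric matrix is the tested artefact; rendering is
cosmetic. The pipeline driver stamps every run with a config hash, the
seed and the package version; identical configs reproduce identical
artefacts byte-for-byte.

## Synthetic data generator

The generator emulates the features of real spontaneous-report streams
that the pipeline must survive, with all randomness flowing from one
root seed through named substreams (so identical configurations yield
byte-identical bundles, and partial artefacts are reproducible):

- **Event model.** Within a report of group g, PT e occurs independently
  with probability min(1, π_e·ρ_{ g,e }), where π_e is the background PT
  probability and ρ comes from the planted-signal list (ρ = 1
  otherwise). Background probabilities are log-spaced over
  3×10⁻⁵–0.04 across 100 PTs by default — a few common events and a
  long rare tail, the shape real PT frequency spectra take. Reports with
  no event are redrawn wholesale (rejection), which conditions on ≥ 1
  reaction without distorting relative PT rates or group-independence
  under the null. Planted signals may be **indication-linked**: the
  multiplier applies only to reports whose CDP mention carries the
  seizure-like indication, enabling subgroup-contrast experiments.
- **Nomenclature.** Each group draws verbatim terms from a canonical
  pool (brand, chemical and informal variants); a configurable fraction
  (default 15%) receives a single-character perturbation that never
  touches the query substring anchoring the term, so every emitted
  string — misspelled or not — remains discoverable by the query list.
- **Duplication.** A configurable fraction of cases (default 10%) is
  emitted as 2–3 versions across quarters with `primaryid` =
  caseid·10+version; later versions mutate only non-key fields (fill a
  missing age, add an outcome), so deduplication correctness is
  observable against the manifest.
- **Reporting profiles.** Age, sex, role and country distributions
  differ by exposure group (the pharmaceutical CBD group is paediatric
  and primary-suspect-heavy with US dominance; herbal groups skew to
  adult males in secondary-suspect/concomitant roles; the oromucosal
  spray group is European and concomitant-heavy). These profiles are
  qualitative: they shape realistic contrasts in the descriptive tables
  without being calibrated to any external counts, since group-specific
  reporting-bias magnitudes are not quantified anywhere.
- **Default scale.** Group weights total ≈ 21% of reports, proportioned
  like the relative sizes of real CDP report groups (the largest being
  the generic-cannabis and pharmaceutical-CBD groups); defaults for
  missingness are 30% (age), 10% (sex), 4% (country).

The generator writes the same '$'-delimited quarterly dialect the reader
ingests, and returns alongside the reports a truth object: the planted
table, the per-case exposure labels, the emitted-term→group mapping
(the curated-mapping analogue a reviewer would have produced), and a
run manifest of aggregate counts.

**What passing synthetic tests does and does not show.** The generator
gives exact ground truth for deduplication, exposure assignment,
counting and estimator behaviour, and realistic null/alternative
calibration for the flags. It does not model reporting delay, free-text
narratives, correlated events within syndromes, masking/competition
between signals, secular reporting trends, or the real distribution of
verbatim-name pathology (it perturbs one character; real data contain
compound strings, concatenated ingredient lists and free text). Results
on synthetic data therefore validate the machinery, not the
epidemiology of any real database.

## Study-condition sizes

The packaged analyses run at: null calibration, three seeds × 200 000
reports (all ρ = 1); signal recovery, three seeds × 120 000 reports with
four planted pairs (ρ = 4–8, expected counts ≥ 12); pipeline integrity,
one 20 000-report universe round-tripped through files; subgroup
contrast, 120 000 reports with two groups (80% vs 8% seizure-indication
rates, three indication-linked seizure signals planted for the
pharmaceutical group only). These sizes give well-populated supported
(E ≥ 5) and sparse (a < 5) strata while keeping a full run around a
minute.

## The full-scale inventory table

`cdpsignal.inventory_fixture` generates a synthetic 1204-term mapping
table whose per-group composition matches the published CDP inventory
(CBD 339, Cannabis 319, THC 244, Epidiolex 14, 44 excluded); the split
of the remaining 244 retained terms across Rx THC, Sativex and THC/CBD
is an invented allocation, as those counts are not published. The terms
themselves are deterministic brand/formulation variants, not the real
inventory — the table exercises `summarize_inventory` and the
query-closure validation at realistic scale.

## Known limitations

- Whole-record (not field-level) version merging; see above.
- Exposure misclassification from the term-level THC/CBD rule and from
  curation itself is inherited by design, as in any manual inventory.
- The comparator-policy ambiguity (other CDP groups in or out of the
  comparator) is exposed as a switch rather than resolved.
- Disproportionality output is hypothesis-generating only; flags are
  reporting associations, not causal or comparative-safety claims.
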