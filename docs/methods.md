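# Methods

## Problem setting

A public clinical-trial registry stores one XML document per study. The
fields that identify what a study is about are heterogeneous: submitters
type free-text *condition* strings (sometimes MeSH headings, sometimes not),
and an indexing algorithm at the registry adds controlled MeSH headings in a
separate *condition_browse* field. Neither field names a clinical specialty.
trialtax builds specialty cohorts from these fields through a reviewed
term taxonomy, and attaches a measured error rate to the result.

## Registry ETL

**Escape sanitization.** Raw registry text may embed the five XML-reserved
characters; `sanitize_text` replaces them with the standard character
references (`&amp;`, `&lt;`, `&gt;`, `&quot;`, `&apos;`), ampersand first.
The function is intentionally not idempotent — applying it to already
escaped text double-escapes — so it is applied exactly once, before
embedding text in XML.

**Study-design grammar.** The *Study Design* element is a single string of
`Name: Value` segments separated by `", "`. The grammar used here: split at
`", "` only where the following token looks like a `Name:` header; a
masking value may end in a parenthesized role list (Participant,
Investigator, Outcome Assessor, Caregiver; "Subject" and "Outcomes
Assessor" are normalized) and may contain several masking levels separated
by `";"`, each emitted as its own component. Unrecognized component names
are kept verbatim with `recognized=False`; segments without a colon are
flagged and skipped. The parse result therefore carries both the component
list and the flagged segments, so no input token is silently lost.

**Dates and ages.** The registration date defaults to the
`firstreceived_date` element and is configurable, because the registry
dialect has changed over time and the analysis cutoff ("registered after
September 27, 2007", the FDAAA anniversary) depends on which date field is
meant. Eligibility ages are normalized to years (months ÷ 12, weeks ÷ 52,
days ÷ 365); `N/A` is missing, and missing is distinct from any numeric
value.

**Completeness.** `completeness_by_year` reports, per registration year,
the fraction of studies with a non-null value for a declared queryable
element. Years with no dated studies are omitted; the fraction is invariant
under input order.

## Thesaurus model

Tree numbers are verbatim strings matching `letter digits ("." digits)*`,
depth 1–12. The hierarchy is defined purely by string prefix over the
*loaded* identifiers: parents absent from the input file are not
synthesized, they simply do not participate (and consequently cannot be
flagged). Terms are matched case-insensitively with collapsed whitespace;
display capitalization is preserved separately. Descendant queries use a
bisect over the sorted id list (prefix-contiguity of sorted strings), and
are cross-checked in the tests against a brute-force prefix scan.

## Annotation semantics

A tag attaches to a (tree number, specialty) pair and is strictly Y or N.
Three derived notions matter downstream:

- **Term summary** — pool the tags on all of a term's tree numbers:
  uniform Y → Y, uniform N → N, mixed → A. A term with no tags at all is
  *untagged*, which is a distinct state from N (it decides Group 4 vs
  Group 5) and is never defaulted.
- **Hierarchy consistency** — a *parent* is any annotated id with at least
  one annotated descendant; it is flagged when any annotated descendant
  carries the opposite tag. The headline rate is flagged parents over
  parents checked. Flags are never auto-corrected: an accept-list of
  already-reviewed parents suppresses re-flagging while still counting the
  parent as checked, mirroring a review-and-confirm workflow. Whether the
  denominator is specialty-specific or pooled is a choice of input: pass
  one specialty's annotations for the former, the union for the latter.
- **Free-text eligibility** — submitted condition terms are normalized
  (lowercase, collapsed whitespace, trailing punctuation stripped —
  configurable at the call site via pre-normalized input) and counted once
  per qualifying study; qualifying means interventional and registered
  strictly after the cutoff date. The default threshold is 5 studies.

Dual review resolves to the common label on agreement and to the third
reviewer's label otherwise; a disagreement without adjudication is an
error, because an unadjudicated disagreement has no defined truth.

## Classification rules

Per specialty, a study's terms (submitted conditions, browse terms, or
their union — the union is the multiset concatenation, so single-source
runs compose exactly) are resolved to summary tags; unresolvable terms are
counted as unannotated. Groups are assigned in order: any Y → 1; else any
A → 2; else all-N with nothing unannotated and at least one term → 3; else
any N → 4; else 5. Reading Group 3 as requiring at least one term and zero
unannotated terms makes Groups 3 and 4 disjoint and exhaustive ahead of
Group 5; a study with no terms at all is Unclassified, not "all N
vacuously". Labels are fixed: 1 → Y, 2 → Ambiguous, 3–4 → N,
5 → Unclassified. Keyword-field terms do not participate in term-based
classification.

Pediatrics is a direct eligibility rule (maximum age present and ≤ 18
years). Genomics is a keyword search ("gene", "genomic", "DNA" by default,
configurable) over conditions, intervention terms, keywords and title,
case-insensitive on word boundaries so that "gene" never fires inside
"generalized"; observational studies are eligible for genomics.

## Validation statistics

`build_confusion` tallies (manual, algorithm) label pairs into the twelve
cells A–L. Metric denominators are frozen in the report schema:
manual-margin rates (`fp_among_manual_N`, `fn_among_manual_Y`) use full
manual row totals; algorithm-margin rates, the algorithm prevalence and the
overall error exclude the Ambiguous and Unclassified columns; the
ambiguous/unclassified fractions are over the grand total. Any zero
denominator yields an explicit undefined marker rather than an exception.
Values are exact ratios internally; rounding to one decimal happens only in
`rounded()`/report output. Note that with these definitions the cardiology
worked example gives an overall error of 39/948 = 4.1%.

Reviewer disagreement is the raw fraction of studies on which a batch's two
reviewers differed; the pooled rate is Σn/ΣN, i.e. the batch-size-weighted
mean. No chance-corrected agreement statistic (kappa) or confidence
interval is computed. Review sampling is without replacement under an
explicit seed; the last batch may be short if the batch size does not
divide the sample size.

`compare_sources` re-runs classification under each term source against the
same manual labels and reports per-metric absolute differences between the
browse-only and condition-only runs.

## Synthetic data: what it emulates, and what it does not

The generator is fully determined by `SynthConfig.seed` (independent
sub-streams are derived per component, so regenerating any artifact is
byte-identical across runs). Defaults: 500 studies over 2003–2010, 82%
interventional, three specialties at 10% prevalence, a 4-category ×
branching-3 × depth-3 thesaurus with ~10% multi-tree terms, 10% reviewer
flip probability, and planted algorithm error of 2% false positives / 20%
false negatives — the scale of the validation study the statistics module
is built to reproduce.

Design choices worth knowing:

- **Disjoint specialty subtrees.** Each top-level node is planted Y for at
  most one specialty. This makes the per-study truth table exact (a study
  is in a specialty iff it carries one of that specialty's Y terms) and
  gives the zero-error pipeline a provably diagonal contingency table.
  Real MeSH specialty footprints overlap; tests passing here therefore say
  nothing about cross-specialty leakage in real data.
- **Simplified browse indexer.** The condition_browse emulator implements
  exact normalized matching of condition text against thesaurus headings
  plus exclusion of headings above a document-frequency quantile (very
  common terms are not indexed). The real indexing algorithm's weighting,
  lexical variants and score cutoff are unpublished and not modeled; browse
  terms here are always a subset of matched condition text, which real
  browse terms are not.
- **Noise vocabulary.** Free-text noise terms come from a fixed nonsense
  lexicon guaranteed (by a marker token) never to collide with generated
  headings, so "unannotated term" behavior is exercised deliberately.
- **Annotation inconsistency** flips each non-top id's tag independently
  with the configured rate, giving closed-form expectations for direct
  parent–child mismatch fractions (binomially checked in the tests).
- **Reviewer error** flips each reviewer's label independently; the
  adjudicator returns the truth. A double flip produces a silent wrong
  manual label — realistic, and the reason the planted-rate recovery
  experiment runs with reviewer flips off, so that the manual margin is a
  clean oracle for the planted algorithm error.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on generated data:
cohorts of 120–500 studies, thesauri of ~150–340 tree numbers, 20-seed
replications at n = 1000 for parameter recovery, and exhaustive
enumeration of all 341 tag profiles up to four terms for rule conformance.
Recovery checks use a ±3 binomial-standard-error band with a 19/20-seed
success requirement. All randomness flows from explicit integer seeds kept
below 2^31; there are no hidden global RNG dependencies.

## Known limitations

- Thesaurus subsetting (which categories/depths enter annotation) is left
  to configuration; no opinionated default subset is shipped.
- Investigation-specific inclusion/exclusion criteria are a hook
  (`classify_cohort(exclusion=...)`) with no defaults.
- No MeSH entry-term/synonym expansion: term matching is exact after
  normalization.
- The genomics and pediatrics selectors are not validated by the
  contingency-table machinery here; they are deterministic rules.
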