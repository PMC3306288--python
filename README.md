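# trialtax

Tools for turning a clinical-trial registry dump (ClinicalTrials.gov-style
public XML) into analysis-ready tables, classifying each study into clinical
specialties through a MeSH-based taxonomy, and quantifying how often that
automated classification disagrees with expert manual review.

**Who it is for.** Research-policy analysts and registry curators who need
specialty-level cohorts (cardiology trials, oncology trials, ...) out of a
registry that was built for record lookup, not aggregate analysis — and who
need an honest error rate attached to any cohort built by rules.

## What it does

1. **Registry ETL** (`trialtax.registry_etl`) — parses registry XML into
   normalized study records; decomposes the concatenated *Study Design*
   string into named components (allocation, masking with per-role lists,
   primary purpose, ...); replaces XML-reserved characters with character
   references; computes per-year field-completeness trends.
2. **MeSH thesaurus** (`trialtax.mesh_thesaurus`) — terms attached to
   dot-delimited tree numbers (`C19.700.355`); hierarchy is pure string
   prefix: the parent of a node is the node minus its last segment, and
   descendants are all loaded ids extending it. One term may sit in several
   trees at once.
3. **Annotation management** (`trialtax.annotation`) — per-(tree number,
   specialty) Y/N tags from clinical reviewers; per-term summaries
   (all-Y → Y, all-N → N, mixed → A for ambiguous); hierarchical-consistency
   validation (a parent's tag should match every annotated descendant;
   mismatches are flagged, never auto-corrected); frequency-based selection
   of free-text condition terms for review (≥ 5 qualifying studies); and
   two-reviewer adjudication.
4. **Specialty classifier** (`trialtax.specialty_classifier`) — the
   five-group rule: any Y term → Group 1 (label Y); else any A → Group 2
   (Ambiguous); else all terms annotated N → Group 3; else any N → Group 4
   (Groups 3–4 pool to label N); else Group 5 (Unclassified). Plus
   dedicated selectors for pediatrics (maximum age ≤ 18 years) and genomics
   (word-boundary keyword search over conditions, interventions, keywords,
   title).
5. **Validation statistics** (`trialtax.validation_stats`) — a
   manual-review × algorithm contingency table (cells A–L), false-positive
   and false-negative rates against both margins, reviewer-disagreement
   summaries, seeded review sampling, and a side-by-side comparison of term
   sources (submitted conditions vs NLM-generated browse terms).
6. **Synthetic data** (`trialtax.synthetic_data`) — seeded generators for
   miniature thesauri, cohorts with planted specialty truth, annotation
   sets with controlled inconsistency, and reviews with controlled error,
   so the whole pipeline is testable and calibratable offline.

## The error model

With manual review as truth, cell `C` (manual N, algorithm Y) counts false
positives and cell `B` (manual Y, algorithm N) counts false negatives:

```
FP among manual-N  = C / (C + D + I + J)
FP among algo-Y    = C / (A + C + E)
FN among manual-Y  = B / (A + B + G + H)
FN among algo-N    = B / (B + D + F)
```

Algorithm-margin percentages exclude the Ambiguous and Unclassified columns
from the denominator; manual-Unknown studies never enter an error numerator.

## Worked example

```python
from trialtax import (ConfusionTable, misclassification_metrics,
                      disagreement_summary)

table = ConfusionTable(A=72, B=21, G=0, H=2, C=18, D=836, I=1, J=49,
                       E=0, F=1, K=0, L=0)          # 1000 reviewed studies
print(misclassification_metrics(table).rounded())
print(disagreement_summary([("1&2", 12, 200), ("1&3", 20, 400),
                            ("4&5", 18, 200), ("6&7", 18, 200)]
                           ).formatted_pooled())
```

prints

```
{'pct_specialty_manual': 9.5, 'pct_specialty_algorithm': 9.5,
 'fp_among_manual_N': 2.0, 'fp_among_algo_Y': 20.0,
 'fn_among_manual_Y': 22.1, 'fn_among_algo_N': 2.4,
 'overall_incorrect': 4.1, 'overall_ambiguous': 0.1,
 'overall_unclassified': 5.1}
68/1,000 (6.8%)
```

i.e. 9.5% of the reviewed sample is in the specialty by either route, but
one in five algorithm-Y studies is a false positive and 22.1% of true
specialty studies are missed — while the two human reviewers themselves
disagreed on 6.8% of studies.

## Command line

```bash
trialtax simulate --seed 4 --n-studies 200 --out world/
trialtax ingest --xml-dir world/xml --out-dir tables/
trialtax annotate-check --annotations world/annotations.csv \
    --thesaurus world/thesaurus.tsv --specialty cardiology
trialtax classify --xml-dir world/xml --annotations world/annotations.csv \
    --thesaurus world/thesaurus.tsv --specialty cardiology --out assign.csv
trialtax validate --assignments assign.csv --manual manual.csv \
    --specialty cardiology --out report/
```

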