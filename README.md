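# phenotext

Dictionary-based phenotype profiling from clinical free text.

Most of what clinicians observe about a patient never reaches structured
codes: it stays in narrative reports. `phenotext` mines such notes to build
phenotype profiles for groups of patients — in particular small rare-disease
cohorts sitting inside a large clinical data warehouse — and is aimed at
clinical-data-warehouse engineers and rare-disease researchers who want an
auditable, rule-based baseline rather than a learned NER model.

The pipeline:

1. **Lexicon filtering** — a phenotype dictionary (term → concept id, CUI-like)
   is restricted to terms of 3–80 characters with a phenotype-like semantic
   type (*Sign or Symptom*, *Disease or Syndrome*, *Finding*, …).
2. **Extraction** — exact, case- and punctuation-insensitive matching of
   lexicon terms on normalized token sequences (greedy longest match, never
   across sentence boundaries), with character offsets back into the raw text.
3. **Context classification** — ConText-style trigger rules decide, per
   mention, whether it is *negated* ("absence de diabète") and whether the
   *experiencer* is the patient or a family member ("la mère a de l'asthme").
4. **Cohort metrics** — only qualifying mentions (not negated, patient
   context) count. For a concept *c* in a cohort:

   * frequency(c) = (# cohort patients with ≥ 1 qualifying mention of *c*) / |cohort|
   * TF-IDF(c) = (N_c / N_tot) · log₁₀(P_tot / P_c)

   with N_c the qualifying mention count of *c* in the cohort, N_tot the
   cohort's total qualifying mention count, P_tot the number of warehouse
   patients and P_c the number of warehouse patients carrying *c*. Frequency
   estimates phenotype prevalence; TF-IDF surfaces concepts *specific* to the
   cohort relative to the whole warehouse.
5. **Evaluation** — ranked top-K lists are scored by truncated-list average
   precision (AP) against expert relevance judgments, with mean average
   precision (MAP) across cohorts, and compared to a reference phenotype set
   by exact-or-broader coverage (a reference concept counts if extracted
   exactly or if it is a hierarchy ancestor of an extracted concept).

A synthetic-corpus generator (`phenotext.synth`) produces full input bundles —
documents, lexicon, triggers, cohort, judgments, reference set — with known
ground truth, so the entire pipeline is testable without licensed
terminologies or patient data.

## Worked example

The TF-IDF of a concept with 649 qualifying cohort mentions out of 18,538, in
a warehouse of 446,481 patients of whom 2,233 carry the concept:

```python
>>> from phenotext import tfidf_score
>>> round(tfidf_score(n_c=649, n_tot=18_538, p_tot=446_481, p_c=2_233), 3)
0.081
```

And a frequency of 150 positive patients in a 209-patient cohort is
150/209 ≈ 71.8%.

End to end on a synthetic warehouse (30 cohort patients, 300 background
patients):

```bash
phenotext synth   --out demo --seed 7 --cohort-patients 30 --background-patients 300
phenotext extract --lexicon demo/lexicon.tsv --triggers demo/triggers.tsv \
                  --documents demo/documents.jsonl --out demo/mentions.tsv \
                  --context-table demo/context.json
phenotext rank    --mentions demo/mentions.tsv --cohort demo/cohort.txt \
                  --lexicon demo/lexicon.tsv --out demo/rankings.tsv
phenotext evaluate --rankings demo/rankings.tsv --judgments demo/judgments.tsv \
                  --reference demo/reference.tsv --hierarchy demo/hierarchy.tsv \
                  --out demo/report.tsv
```

which extracts 1,180 mentions and prints rankings whose head is

```
metric  concept_id  preferred_label       n_patients  frequency  n_mentions  tfidf
freq    C0001       Stéréotypies          21          0.700000   32          0.162310
freq    C0004       Épilepsie             17          0.566667   32          0.146648
freq    C0005       Retard de croissance  16          0.533333   22          0.120642
```

— the concept planted at 70% cohort prevalence is recovered at 21/30 = 70%,
and its TF-IDF of 0.162 = (32/197)·log₁₀(P_tot/P_c) reflects how rare it is in
the background. The evaluation step then reports

```
cohort_id  n_relevant_freq  n_relevant_tfidf  ...  ap_freq   ap_tfidf  coverage
cohort     10               10                ...  0.966667  1.0       1.0
MAP (frequency ranking): 0.9667
MAP (TF-IDF ranking):    1.0000
```

meaning all ten disease-associated concepts were judged relevant, nearly all
ranked ahead of the background concepts (AP), and every reference phenotype
was covered exactly or by a broader ancestor.

## File formats

All interchange formats are plain text (UTF-8): documents as JSONL
(`patient_id`, `doc_id`, `text`), lexicon / triggers / mentions / warehouse
stats / rankings / judgments / reference / hierarchy as headered TSV, cohorts
as one patient id per line. See the module docstrings for column details, and
`docs/methods.md` for the method's assumptions and design choices.
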