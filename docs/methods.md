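# Methods

## Scope and model

`phenotext` implements rule-based phenotype profiling for patient cohorts
from free-text clinical notes. It assumes a pre-extracted phenotype lexicon
(surface term → concept id, with semantic types), so no terminology licenses
are needed at run time, and it deliberately uses *exact* dictionary matching
after normalization: no word reordering ("renal acute injury" does not match
"acute renal injury"), no fuzzy matching, no machine-learned recognition.
Synonyms in the lexicon are the only mechanism for surface variation. This
trades recall for full auditability — every mention can be traced to a
lexicon row and a character span.

## Text normalization

Tokens are maximal runs of Unicode-alphanumeric characters, lowercased; every
run of non-alphanumeric characters is a single separator. Offsets are kept in
code points, 0-based half-open, so `text[start:end]` always recovers the raw
matched surface. Sentences split on `.`, `!`, `?`, `;` and newline — a
deliberately naive rule, because clinical notes rarely carry reliable
sentence structure and a transparent splitter keeps negation scopes
auditable. Diacritics are preserved by default (accented letters are
alphanumeric, so punctuation-insensitivity does not touch them); a
`strip_diacritics` switch folds them via NFD-decomposition for corpora with
inconsistent accent usage, and must then be applied to documents, lexicon and
triggers alike (all three funnel through the same normalizer).

## Lexicon filtering

Two filters, applied at load time rather than match time:

* term length within [3, 80] characters inclusive, measured on the raw
  surface term (an accented letter counts as one character);
* semantic type within a 10-type phenotype allow-list (Sign or Symptom,
  Disease or Syndrome, Finding, Pathologic Function, Congenital Abnormality,
  Physiologic Function, Anatomical Abnormality, Neoplastic Process, Acquired
  Abnormality, Mental or Behavioral Dysfunction).

A concept carrying several semantic types is retained if *any* of its types
is allowed (the lexicon TSV has one row per term-type pair to keep this
observable). The language column is informational; no language filtering is
performed.

## Matching and context classification

Matching scans each sentence left to right with greedy longest-match on
normalized token sequences; after a match the scan resumes past it, so
mentions never overlap and an embedded sub-term ("croissance" inside "retard
de croissance") is never double-counted. Equal-length candidates at the same
position tie-break by ascending concept id.

Context classification follows the ConText family of algorithms with two
attributes, set independently (all four combinations occur):

* `negated` — the mention falls in the scope of a negation trigger;
* `experiencer` — `family` if in the scope of a family-history trigger,
  else `patient`.

A trigger's scope runs in its direction(s) within the same sentence, up to
`max_scope_tokens` (default 10) tokens, stopping before a scope terminator
(default `mais`, `sauf`, `but`). Trigger phrases are matched with the same
normalization and longest-match rule; tokens inside a matched trigger phrase
are not eligible as concept mentions (a disease word inside a cue phrase is
read as part of the cue). A mention is "in scope" if any of its tokens is.

The default French trigger inventory (negation: *pas de, absence, sans,
aucun, aucune, ni, non*; family: *mère, père, frère, sœur, cousin, cousine,
oncle, tante, familial, familiale*; all forward, scope 10) is a reasoned
reconstruction, not a canonical resource: production use should load a
curated list via the triggers TSV.

## Cohort metrics

Only qualifying mentions — not negated *and* patient experiencer — enter the
metrics. For concept *c* and a cohort C inside a warehouse:

* frequency(c) = |{p ∈ C : ≥1 qualifying mention of c}| / |C|, an estimate of
  phenotype prevalence in the cohort;
* TF-IDF(c) = (N_c / N_tot) · log₁₀(P_tot / P_c), where N_c and N_tot are
  qualifying mention *token* counts within the cohort and P_c / P_tot are
  patient counts over the **whole warehouse**, not the cohort. The
  warehouse-wide reading is the only one under which the inverse-document-
  frequency term can down-weight ubiquitous findings; with cohort-level
  patient counts the formula's worked magnitudes are not reproducible.
  The logarithm base is 10 by default — the value the published worked
  magnitudes imply — with `log_base` as an explicit override.

P_tot defaults to the number of patients with at least one qualifying
extracted concept when stats are computed from a mention stream; an explicit
`total_patients` (e.g. the full warehouse census) can be supplied instead,
since both readings are defensible. Rankings are computed over all concepts
present in the cohort index, ties broken by ascending concept id, then
truncated to the top K (default 50); both metrics and both ranks are reported
for every listed concept. Metrics are stored at full precision; files carry
six decimals; display rounding happens only in reports.

The context table tallies *all* mentions (no qualifying filter) into the 2×2
experiencer × negation grid and derives the family share of all mentions and
the not-negated share among patient-context mentions.

## Evaluation

Average precision uses the truncated-list convention: AP = Σ
precision@k over relevant ranks k, divided by the number of relevant items
*in the judged list*. The total number of relevant phenotypes for a disease
is unknowable when experts judge only a top-K list, so the list-local
denominator is the honest choice; AP is undefined (an error, not 0) for a
list with no relevant item. MAP is the arithmetic mean of per-list APs and is
reported separately per ranking metric.

Reference coverage matches a reference concept if it was extracted exactly,
or if it is an ancestor — at any depth — of an extracted concept in the
supplied hierarchy (edges child → parent; validated acyclic before
traversal, via networkx). Exact matches are reported in preference to
broader ones. Semantically related but non-hierarchical pairs (hypotonia vs
muscle weakness) are deliberately *not* matched: that judgment cannot be made
by hierarchical reasoning and is out of scope.

## Synthetic data

The generator emulates the target data regime — a small cohort inside a
large warehouse — with all randomness drawn from one seeded NumPy generator
(no global state; same seed ⇒ byte-identical bundle):

* patients: 50 cohort + 1,000 background by default; documents per patient
  ~ 1 + Poisson(mean − 1), mean 3 — short-note volumes typical of pediatric
  outpatient records;
* 30 default concepts: 10 disease-like (cohort prevalence 0.15–0.70,
  background 0.002–0.03) and 20 routine findings (background up to 0.25),
  with French surface terms including accented and multi-word forms;
* each positive patient–concept pair yields 1 + Poisson(mean − 1) affirmed
  patient-context mentions (mean 1.5), each in its own filler-padded
  sentence, spread uniformly over the patient's documents;
* per document, with probability 0.10 a negated sentence and with 0.05 a
  family-history sentence is added, each mentioning a concept the patient
  does *not* have, introduced by a randomly chosen trigger of that category —
  so any leakage of non-qualifying mentions into the metrics shows up as
  prevalence inflation;
* the filler vocabulary is validated disjoint (token-level) from lexicon
  terms and trigger phrases, and planted sentences never straddle sentence
  boundaries, so extraction on clean synthetic text must recover the planted
  labels *exactly* — which the tests assert.

Noise rates reflect the observed composition of real warehouse extractions,
where family-context mentions are a few percent of the total and a quarter
to a third of patient-context mentions are negated; at these defaults the
generated corpora land in that regime. What passing tests show is therefore
correctness of the machinery (matching, scoping, counting, ranking,
scoring), not robustness to real clinical language: misspellings, novel
synonyms, uncued negations and cross-sentence discourse are all absent by
construction.

The checked-in fixture (`tests/fixtures/`) freezes one bundle at seed
7,654,321 with a manifest of SHA-256 hashes and the small expected outputs;
the ranking in the manifest was cross-checked at creation time against an
independent pandas groupby implementation of both metrics.

## Numerical and degenerate-input choices

* Frequency on an empty cohort, AP with no relevant items, TF-IDF for a
  concept missing from warehouse stats, and a cyclic hierarchy are errors;
  an empty trigger list or an empty filtered lexicon only warn.
* `P_c = P_tot` gives TF-IDF exactly 0 (log 1), not an error.
* File outputs fix float formatting (six decimals) so reruns are
  byte-identical; in-memory values stay at double precision.
* The scaled problem sizes used in tests (cohorts of 20–200, warehouses of
  50–1,000 patients, ≤ 30 concepts) keep the full suite in a few seconds
  while preserving every structural feature of the target regime.

## Known limitations

Exact matching misses reordered or inflected variants not present as lexicon
synonyms. The sentence splitter and the scope rules are deliberately simple;
uncertainty/hypothetical contexts and non-patient experiencers beyond
"family" are not modeled. Coverage comparison requires the reference set to
be pre-mapped into the extraction concept space. Grouping semantically close
concepts before prevalence estimation is out of scope.
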