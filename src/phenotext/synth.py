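"""Synthetic clinical-note corpora with known ground truth.

Real phenotype extraction runs over licensed terminologies and protected
patient text, neither of which can ship with a package. This module
generates the whole input bundle instead — lexicon, trigger list, documents
and cohort definition — while recording exactly what was planted where, so
extraction, aggregation and evaluation can all be checked against ground
truth.

The generator emulates the data regime the method targets: a small disease
cohort (tens to a couple hundred patients) inside a much larger background
warehouse, short multi-sentence notes, concepts planted per patient at
controlled prevalences, and controlled rates of negated and family-history
mentions introduced with known trigger phrases. Every planted mention sits
in its own sentence with filler words around it, the filler vocabulary is
disjoint from lexicon terms and trigger phrases, and sentence punctuation
is inserted so context scopes behave as designed. It does NOT emulate real
clinical language: no typos, no word reordering, no ambiguous cues, no
terms the lexicon lacks.

Noise mentions always use concepts the patient does *not* have, so an
extractor that fails to discard negated or family-context mentions
visibly inflates the estimated cohort frequencies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import (
    DEFAULT_TRIGGERS,
    Document,
    TriggerEntry,
    normalize_term,
    write_documents,
    write_triggers,
)
from .evaluation import write_judgments
from .terminology import DEFAULT_SEMANTIC_TYPES, Lexicon, TermEntry, filter_lexicon, write_lexicon

logger = logging.getLogger(__name__)

COHORT_ID = "cohort"

#: Synthetic parent concept used to exercise broader-than matching.
BROADER_PARENT_ID = "C9000"
BROADER_CHILD_ID = "C0001"


@dataclass(frozen=True)
class ConceptSpec:
    """One synthetic phenotype concept and how often to plant it."""

    concept_id: str
    surface_terms: tuple[str, ...]
    cohort_prevalence: float
    background_prevalence: float
    mentions_per_positive_mean: float = 1.5


def default_concept_specs() -> tuple[ConceptSpec, ...]:
    """Thirty concepts: ten enriched in the cohort (disease-like), twenty
    common in the background warehouse (pediatric routine findings)."""
    disease = [
        ("stéréotypies", 0.70, 0.002),
        ("microcéphalie", 0.55, 0.004),
        ("scoliose", 0.50, 0.015),
        ("épilepsie", 0.45, 0.02),
        ("retard de croissance", 0.40, 0.01),
        ("apraxie", 0.35, 0.003),
        ("hypotonie", 0.30, 0.01),
        ("troubles du sommeil", 0.30, 0.03),
        ("bruxisme", 0.25, 0.002),
        ("ostéoporose", 0.15, 0.005),
    ]
    common = [
        ("fièvre", 0.20, 0.25),
        ("toux", 0.15, 0.20),
        ("vomissements", 0.10, 0.15),
        ("diarrhée", 0.08, 0.12),
        ("asthme", 0.05, 0.10),
        ("otite", 0.05, 0.09),
        ("eczéma", 0.04, 0.08),
        ("anémie", 0.06, 0.07),
        ("rhinite", 0.03, 0.07),
        ("bronchiolite", 0.02, 0.06),
        ("constipation", 0.05, 0.06),
        ("angine", 0.03, 0.06),
        ("migraine", 0.04, 0.05),
        ("obésité", 0.03, 0.05),
        ("reflux gastrique", 0.04, 0.05),
        ("gastroentérite", 0.02, 0.05),
        ("allergie alimentaire", 0.02, 0.04),
        ("varicelle", 0.01, 0.03),
        ("dermatite", 0.02, 0.03),
        ("lombalgie", 0.01, 0.02),
    ]
    specs = []
    for i, (term, cp, bp) in enumerate(disease + common, start=1):
        specs.append(ConceptSpec(f"C{i:04d}", (term,), cp, bp))
    return tuple(specs)


DEFAULT_FILLER: tuple[str, ...] = (
    "le", "la", "un", "une", "examen", "clinique", "montre", "patient",
    "consultation", "jour", "suivi", "note", "observation", "bilan",
    "normal", "stable", "depuis", "mois", "controle", "evolution",
    "bonne", "etat", "general", "ce",
)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic warehouse.

    Defaults describe a scaled-down version of the target regime: a
    50-patient cohort in a 1,000-patient warehouse, about three short
    notes per patient, 10% of documents carrying a negated mention and 5%
    a family-history mention of a concept the patient does not have.
    """

    seed: int = 0
    n_cohort_patients: int = 50
    n_background_patients: int = 1000
    docs_per_patient_mean: float = 3.0
    concept_specs: tuple[ConceptSpec, ...] = field(default_factory=default_concept_specs)
    negation_noise_rate: float = 0.10
    family_noise_rate: float = 0.05
    filler_vocabulary: tuple[str, ...] = DEFAULT_FILLER
    triggers: tuple[TriggerEntry, ...] = DEFAULT_TRIGGERS

    def validate(self) -> None:
        if self.n_cohort_patients < 1 or self.n_background_patients < 0:
            raise ValueError("need >= 1 cohort patient and >= 0 background patients")
        if self.docs_per_patient_mean < 1:
            raise ValueError("docs_per_patient_mean must be >= 1")
        for r, name in ((self.negation_noise_rate, "negation_noise_rate"), (self.family_noise_rate, "family_noise_rate")):
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        term_tokens: set[str] = set()
        for cs in self.concept_specs:
            if not 0 <= cs.cohort_prevalence <= 1 or not 0 <= cs.background_prevalence <= 1:
                raise ValueError(f"{cs.concept_id}: prevalences must be in [0, 1]")
            if cs.mentions_per_positive_mean < 1:
                raise ValueError(f"{cs.concept_id}: mentions_per_positive_mean must be >= 1")
            for t in cs.surface_terms:
                term_tokens.update(normalize_term(t))
        trigger_tokens = {tok for tr in self.triggers for tok in normalize_term(tr.phrase)}
        filler_tokens = {tok for w in self.filler_vocabulary for tok in normalize_term(w)}
        clash = filler_tokens & (term_tokens | trigger_tokens)
        if clash:
            raise ValueError(f"filler vocabulary collides with lexicon/trigger tokens: {sorted(clash)}")


@dataclass
class SynthBundle:
    """A generated corpus plus everything needed to check results against it."""

    config: SynthConfig
    documents: list[Document]
    lexicon: Lexicon
    triggers: list[TriggerEntry]
    cohort_patient_ids: list[str]
    truth_mentions: pd.DataFrame  # patient_id, doc_id, concept_id, negated, experiencer
    truth_patients: pd.DataFrame  # patient_id, concept_id, in_cohort
    truth_summary: dict  # true prevalences and warehouse patient counts per concept

    def judgments(self) -> dict[str, dict[tuple[str, str], bool]]:
        """Ground-truth relevance: a concept is relevant to the cohort's
        disease iff it was planted enriched in the cohort (cohort
        prevalence at least double the background prevalence)."""
        flags = {}
        for cs in self.config.concept_specs:
            rel = cs.cohort_prevalence > 0 and cs.cohort_prevalence >= 2 * cs.background_prevalence
            flags[("freq", cs.concept_id)] = rel
            flags[("tfidf", cs.concept_id)] = rel
        return {COHORT_ID: flags}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle in the pipeline's interchange formats.

        Deterministic given the config: the same config writes
        byte-identical files every time.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fname for name, fname in [
            ("documents", "documents.jsonl"),
            ("lexicon", "lexicon.tsv"),
            ("triggers", "triggers.tsv"),
            ("cohort", "cohort.txt"),
            ("judgments", "judgments.tsv"),
            ("reference", "reference.tsv"),
            ("hierarchy", "hierarchy.tsv"),
            ("truth_mentions", "truth_mentions.tsv"),
            ("truth_patients", "truth_patients.tsv"),
            ("truth_summary", "truth_summary.json"),
        ]}
        write_documents(self.documents, paths["documents"])
        write_lexicon(self.lexicon, paths["lexicon"])
        write_triggers(self.triggers, paths["triggers"])
        paths["cohort"].write_text("".join(p + "\n" for p in self.cohort_patient_ids), encoding="utf-8")
        write_judgments(self.judgments(), paths["judgments"])
        # Reference set = the disease-associated concepts, except that the
        # first one is replaced by a synthetic broader parent reachable only
        # through the hierarchy — exercising broader-than matching.
        ref_rows = []
        for cs in self.config.concept_specs:
            if cs.cohort_prevalence > 0 and cs.cohort_prevalence >= 2 * cs.background_prevalence:
                cid = BROADER_PARENT_ID if cs.concept_id == BROADER_CHILD_ID else cs.concept_id
                ref_rows.append(("synthref", cid, cid))
        pd.DataFrame(ref_rows, columns=["ref_id", "concept_id", "label"]).to_csv(
            paths["reference"], sep="\t", index=False, lineterminator="\n")
        pd.DataFrame([(BROADER_CHILD_ID, BROADER_PARENT_ID)],
                     columns=["child_concept_id", "parent_concept_id"]).to_csv(
            paths["hierarchy"], sep="\t", index=False, lineterminator="\n")
        tm = self.truth_mentions.copy()
        tm["negated"] = tm["negated"].astype(int)
        tm.to_csv(paths["truth_mentions"], sep="\t", index=False, lineterminator="\n")
        tp = self.truth_patients.copy()
        tp["in_cohort"] = tp["in_cohort"].astype(int)
        tp.to_csv(paths["truth_patients"], sep="\t", index=False, lineterminator="\n")
        paths["truth_summary"].write_text(
            json.dumps(self.truth_summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return paths


def _make_lexicon(specs: tuple[ConceptSpec, ...]) -> Lexicon:
    stypes = sorted(DEFAULT_SEMANTIC_TYPES)
    entries = []
    for i, cs in enumerate(specs):
        label = cs.surface_terms[0].capitalize()
        for t in cs.surface_terms:
            entries.append(TermEntry(t, cs.concept_id, label, stypes[i % len(stypes)], "FRE"))
    return filter_lexicon(Lexicon(entries=entries))


def generate_corpus(cfg: SynthConfig) -> SynthBundle:
    """Generate a deterministic synthetic warehouse from one seeded RNG.

    Per patient: document count ~ 1 + Poisson(mean - 1); each concept the
    patient is positive for (Bernoulli at the cohort or background
    prevalence) contributes 1 + Poisson(mean - 1) affirmed patient-context
    mentions spread uniformly over the patient's documents, each in its own
    filler-padded sentence. Each document then carries, with the configured
    noise rates, a negated and/or a family-history sentence mentioning a
    concept the patient does NOT have, introduced by a randomly chosen
    trigger phrase of that category.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lexicon = _make_lexicon(cfg.concept_specs)
    neg_triggers = [t for t in cfg.triggers if t.category == "negation"]
    fam_triggers = [t for t in cfg.triggers if t.category == "family"]
    filler = list(cfg.filler_vocabulary)

    patients = [(f"COH{i:04d}", True) for i in range(cfg.n_cohort_patients)] + [
        (f"BKG{i:05d}", False) for i in range(cfg.n_background_patients)
    ]

    documents: list[Document] = []
    truth_rows: list[tuple[str, str, str, bool, str]] = []
    patient_rows: list[tuple[str, str, bool]] = []
    true_pc: dict[str, int] = {cs.concept_id: 0 for cs in cfg.concept_specs}

    def filler_words(lo: int, hi: int) -> list[str]:
        n = int(rng.integers(lo, hi + 1))
        return [filler[int(k)] for k in rng.integers(0, len(filler), size=n)]

    for pid, in_cohort in patients:
        positives = []
        for cs in cfg.concept_specs:
            p = cs.cohort_prevalence if in_cohort else cs.background_prevalence
            if rng.random() < p:
                positives.append(cs)
                patient_rows.append((pid, cs.concept_id, in_cohort))
                true_pc[cs.concept_id] += 1
        negatives = [cs for cs in cfg.concept_specs if cs not in positives]

        n_docs = 1 + int(rng.poisson(cfg.docs_per_patient_mean - 1))
        doc_ids = [f"{pid}-D{j:02d}" for j in range(n_docs)]
        sentences: list[list[tuple[str, tuple[str, bool, str] | None]]] = [[] for _ in range(n_docs)]

        for cs in positives:
            term = cs.surface_terms[int(rng.integers(0, len(cs.surface_terms)))]
            n_mentions = 1 + int(rng.poisson(cs.mentions_per_positive_mean - 1))
            for _ in range(n_mentions):
                d = int(rng.integers(0, n_docs))
                words = filler_words(1, 3) + [term] + filler_words(0, 2)
                sentences[d].append((" ".join(words), (cs.concept_id, False, "patient")))

        for d in range(n_docs):
            if negatives and neg_triggers and rng.random() < cfg.negation_noise_rate:
                cs = negatives[int(rng.integers(0, len(negatives)))]
                trig = neg_triggers[int(rng.integers(0, len(neg_triggers)))]
                term = cs.surface_terms[int(rng.integers(0, len(cs.surface_terms)))]
                sentences[d].append((f"{trig.phrase} {term}", (cs.concept_id, True, "patient")))
            if negatives and fam_triggers and rng.random() < cfg.family_noise_rate:
                cs = negatives[int(rng.integers(0, len(negatives)))]
                trig = fam_triggers[int(rng.integers(0, len(fam_triggers)))]
                term = cs.surface_terms[int(rng.integers(0, len(cs.surface_terms)))]
                sentences[d].append((f"{trig.phrase} {term}", (cs.concept_id, False, "family")))
            # one or two pure filler sentences so notes are not wall-to-wall findings
            for _ in range(int(rng.integers(1, 3))):
                sentences[d].append((" ".join(filler_words(3, 8)), None))

        for d, doc_id in enumerate(doc_ids):
            order = rng.permutation(len(sentences[d]))
            parts = []
            for k in order:
                sent, planted = sentences[d][k]
                parts.append(sent[0].upper() + sent[1:])
                if planted is not None:
                    truth_rows.append((pid, doc_id, planted[0], planted[1], planted[2]))
            documents.append(Document(pid, doc_id, ". ".join(parts) + "."))

    truth_mentions = pd.DataFrame(
        truth_rows, columns=["patient_id", "doc_id", "concept_id", "negated", "experiencer"]
    ).sort_values(["patient_id", "doc_id", "concept_id", "negated", "experiencer"], kind="mergesort").reset_index(drop=True)
    truth_patients = pd.DataFrame(patient_rows, columns=["patient_id", "concept_id", "in_cohort"])
    summary = {
        "n_cohort_patients": cfg.n_cohort_patients,
        "n_background_patients": cfg.n_background_patients,
        "true_cohort_prevalence": {cs.concept_id: cs.cohort_prevalence for cs in cfg.concept_specs},
        "true_background_prevalence": {cs.concept_id: cs.background_prevalence for cs in cfg.concept_specs},
        "true_patients_per_concept": true_pc,
    }
    logger.info(
        "generated %d documents for %d patients (%d cohort), %d planted mentions",
        len(documents), len(patients), cfg.n_cohort_patients, len(truth_mentions),
    )
    return SynthBundle(
        config=cfg,
        documents=documents,
        lexicon=lexicon,
        triggers=list(cfg.triggers),
        cohort_patient_ids=[p for p, c in patients if c],
        truth_mentions=truth_mentions,
        truth_patients=truth_patients,
        truth_summary=summary,
    )


#: Seed of the checked-in test fixture manifest.
FIXTURE_SEED = 7_654_321


def make_fixture_bundle(seed: int | None = None) -> SynthBundle:
    """The fixed test fixture: 50 cohort patients in a 1,000-patient
    warehouse with 30 concepts — the target regime scaled down so the full
    pipeline runs in seconds."""
    return generate_corpus(SynthConfig(seed=FIXTURE_SEED if seed is None else seed))
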