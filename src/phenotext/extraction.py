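"""Text normalization, dictionary matching and context classification.

The extraction pipeline mirrors how rule-based clinical concept extractors
work on free-text notes:

1. :func:`normalize` lowercases the text and treats every maximal run of
   non-alphanumeric characters as a single token separator, keeping
   per-token character offsets so every match can be traced back to the
   original string. Sentences are split naively on ``. ! ? ;`` and newline —
   clinical notes rarely carry reliable punctuation, and a simple splitter
   keeps trigger scopes auditable.
2. :func:`find_mentions` matches lexicon terms exactly on the normalized
   token sequence, left to right, greedy longest-match, never across a
   sentence boundary and never overlapping.
3. :func:`classify_context` applies ConText-style trigger rules to decide,
   per mention, whether it is negated ("absence de diabete") and whether it
   is about the patient or a family member ("la mere a de l'asthme").

Diacritics are preserved by default: accented letters are alphanumeric, so
"insensitive to non-alphanumeric characters" does not touch them. An
optional ``strip_diacritics`` switch folds them for corpora with
inconsistent accent usage; it must then be applied consistently to
documents, lexicon and triggers, which all funnel through the same
normalizer here.
"""

from __future__ import annotations

import csv
import json
import logging
import unicodedata
from bisect import bisect_left
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .terminology import Lexicon

logger = logging.getLogger(__name__)

#: Characters whose appearance between two tokens ends a sentence.
SENTENCE_BREAK_CHARS = frozenset(".!?;\n")

#: Tokens that terminate a trigger's scope early (ConText convention).
DEFAULT_SCOPE_TERMINATORS = frozenset({"mais", "sauf", "but"})

EXPERIENCER_PATIENT = "patient"
EXPERIENCER_FAMILY = "family"

TRIGGER_COLUMNS = ("phrase", "category", "direction", "max_scope_tokens")
MENTION_COLUMNS = (
    "patient_id", "doc_id", "concept_id", "start", "end",
    "matched_text", "negated", "experiencer",
)


@dataclass(frozen=True)
class Document:
    """One clinical note. ``text`` may be empty; identifiers may not."""

    patient_id: str
    doc_id: str
    text: str
    doc_type: str | None = None
    department: str | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id or not self.doc_id:
            raise ValueError("patient_id and doc_id must be non-empty")


@dataclass(frozen=True)
class NormalizedText:
    """Token stream with offsets back into the original text.

    ``offsets`` are 0-based half-open (start, end) pairs in Unicode code
    points; ``sentence_bounds`` are (first_token, last_token_exclusive)
    pairs partitioning the token sequence.
    """

    tokens: tuple[str, ...]
    offsets: tuple[tuple[int, int], ...]
    sentence_bounds: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TriggerEntry:
    """A negation or family-history cue phrase with its scope rule."""

    phrase: str
    category: str  # "negation" | "family"
    direction: str = "forward"  # "forward" | "backward" | "both"
    max_scope_tokens: int = 10

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("trigger phrase must be non-empty")
        if self.category not in ("negation", "family"):
            raise ValueError(f"unknown trigger category: {self.category!r}")
        if self.direction not in ("forward", "backward", "both"):
            raise ValueError(f"unknown trigger direction: {self.direction!r}")
        if self.max_scope_tokens < 1:
            raise ValueError("max_scope_tokens must be >= 1")


@dataclass(frozen=True)
class Mention:
    """One occurrence of a lexicon concept in one document."""

    patient_id: str
    doc_id: str
    concept_id: str
    start: int
    end: int
    matched_text: str
    negated: bool = False
    experiencer: str = EXPERIENCER_PATIENT

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("mention start must be < end")


# A small default French trigger inventory. The original trigger lists for
# French clinical text are not public, so these are configurable defaults,
# not a canonical resource; load your own via load_triggers() for real use.
DEFAULT_TRIGGERS: tuple[TriggerEntry, ...] = tuple(
    [TriggerEntry(p, "negation") for p in ("pas de", "absence", "sans", "aucun", "aucune", "ni", "non")]
    + [
        TriggerEntry(p, "family")
        for p in (
            "mère", "père", "frère", "sœur", "cousin", "cousine",
            "oncle", "tante", "familial", "familiale",
        )
    ]
)


def _strip_marks(s: str) -> str:
    return "".join(c for c in unicodedata.normalize("NFD", s) if not unicodedata.combining(c))


def normalize(text: str, strip_diacritics: bool = False) -> NormalizedText:
    """Tokenize ``text`` case-insensitively on runs of non-alphanumerics.

    Every maximal run of non-alphanumeric characters is one separator, so
    ``"(DIABÈTE)."`` yields the single token ``diabète``. Offsets always
    index the original string, so ``text[start:end]`` recovers the raw
    surface form of each token.
    """
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    bounds: list[tuple[int, int]] = []
    sent_start = 0
    i, n = 0, len(text)
    while i < n:
        if text[i].isalnum():
            j = i + 1
            while j < n and text[j].isalnum():
                j += 1
            tok = text[i:j].lower()
            if strip_diacritics:
                tok = _strip_marks(tok)
            tokens.append(tok)
            offsets.append((i, j))
            i = j
        else:
            if text[i] in SENTENCE_BREAK_CHARS and len(tokens) > sent_start:
                bounds.append((sent_start, len(tokens)))
                sent_start = len(tokens)
            i += 1
    if len(tokens) > sent_start:
        bounds.append((sent_start, len(tokens)))
    return NormalizedText(tuple(tokens), tuple(offsets), tuple(bounds))


def normalize_term(term: str, strip_diacritics: bool = False) -> tuple[str, ...]:
    """Normalized token tuple of a lexicon term or trigger phrase."""
    return normalize(term, strip_diacritics=strip_diacritics).tokens


class TermIndex:
    """Lexicon compiled to a token-tuple lookup for longest-match scanning.

    When two concepts share the same normalized token sequence, the lowest
    concept_id wins (deterministic tie-break).
    """

    def __init__(self, lex: Lexicon, strip_diacritics: bool = False):
        self.strip_diacritics = strip_diacritics
        table: dict[tuple[str, ...], str] = {}
        for e in lex.entries:
            toks = normalize_term(e.surface_term, strip_diacritics)
            if not toks:
                continue
            prev = table.get(toks)
            if prev is None or e.concept_id < prev:
                table[toks] = e.concept_id
        self.table = table
        self.max_tokens = max((len(t) for t in table), default=0)

    def __len__(self) -> int:
        return len(self.table)


def _scan_longest(
    tokens: Sequence[str],
    sentence_bounds: Iterable[tuple[int, int]],
    table: Mapping[tuple[str, ...], object],
    max_tokens: int,
) -> list[tuple[int, int, object]]:
    """Greedy left-to-right longest-match scan; returns (tok_start, tok_end, value).

    Matches never cross sentence bounds; after a match the scan resumes at
    the token following it, so matches never overlap.
    """
    out: list[tuple[int, int, object]] = []
    if not table:
        return out
    for s, e in sentence_bounds:
        i = s
        while i < e:
            hit = None
            for length in range(min(max_tokens, e - i), 0, -1):
                key = tuple(tokens[i : i + length])
                if key in table:
                    hit = (i, i + length, table[key])
                    break
            if hit is not None:
                out.append(hit)
                i = hit[1]
            else:
                i += 1
    return out


def find_mentions(
    doc: Document,
    lex: Lexicon | TermIndex,
    strip_diacritics: bool = False,
    _norm: NormalizedText | None = None,
) -> list[Mention]:
    """Exact dictionary matching of lexicon terms in one document.

    Matching is exact on normalized token sequences (no word reordering, no
    fuzziness), greedy longest-match at each position, non-overlapping, and
    confined to single sentences. Context flags are left at their defaults
    (affirmed, patient); :func:`classify_context` sets them.
    """
    index = lex if isinstance(lex, TermIndex) else TermIndex(lex, strip_diacritics)
    norm = _norm if _norm is not None else normalize(doc.text, strip_diacritics=index.strip_diacritics)
    mentions = []
    for ts, te, cui in _scan_longest(norm.tokens, norm.sentence_bounds, index.table, index.max_tokens):
        start = norm.offsets[ts][0]
        end = norm.offsets[te - 1][1]
        mentions.append(
            Mention(doc.patient_id, doc.doc_id, str(cui), start, end, doc.text[start:end])
        )
    return mentions


class _TriggerIndex:
    def __init__(self, triggers: Sequence[TriggerEntry], strip_diacritics: bool = False):
        table: dict[tuple[str, ...], list[TriggerEntry]] = {}
        for t in triggers:
            toks = normalize_term(t.phrase, strip_diacritics)
            if toks:
                table.setdefault(toks, []).append(t)
        self.table = table
        self.max_tokens = max((len(t) for t in table), default=0)


def classify_context(
    mentions: Sequence[Mention],
    norm: NormalizedText,
    triggers: Sequence[TriggerEntry],
    scope_terminators: Iterable[str] = DEFAULT_SCOPE_TERMINATORS,
    strip_diacritics: bool = False,
) -> list[Mention]:
    """Set ``negated`` and ``experiencer`` on mentions via trigger scopes.

    A trigger's scope runs from the trigger occurrence in its direction(s),
    within the same sentence, for at most ``max_scope_tokens`` tokens,
    stopping before the first scope-terminator token ("mais", "sauf",
    "but"). A mention is negated iff any of its tokens falls in the scope
    of a negation trigger; its experiencer is "family" iff any token falls
    in the scope of a family trigger. The two attributes are independent.

    Trigger phrases are matched with the same normalization and
    longest-match rule as concepts; mentions overlapping a trigger
    occurrence are dropped (a disease word inside a cue phrase is part of
    the cue, not a finding).
    """
    if not triggers:
        logger.warning("empty trigger list: all mentions left affirmed / patient-experiencer")
        return list(mentions)
    tindex = _TriggerIndex(triggers, strip_diacritics)
    terminators = frozenset(scope_terminators)
    occurrences = _scan_longest(norm.tokens, norm.sentence_bounds, tindex.table, tindex.max_tokens)

    negated_toks: set[int] = set()
    family_toks: set[int] = set()
    trigger_toks: set[int] = set()
    for ts, te, entries in occurrences:
        trigger_toks.update(range(ts, te))
        sent = next((b for b in norm.sentence_bounds if b[0] <= ts < b[1]), (ts, te))
        for ent in entries:  # type: ignore[union-attr]
            scope: set[int] = set()
            if ent.direction in ("forward", "both"):
                stop = min(sent[1], te + ent.max_scope_tokens)
                for k in range(te, stop):
                    if norm.tokens[k] in terminators:
                        break
                    scope.add(k)
            if ent.direction in ("backward", "both"):
                stop = max(sent[0], ts - ent.max_scope_tokens)
                for k in range(ts - 1, stop - 1, -1):
                    if norm.tokens[k] in terminators:
                        break
                    scope.add(k)
            if ent.category == "negation":
                negated_toks |= scope
            else:
                family_toks |= scope

    starts = [o[0] for o in norm.offsets]
    out: list[Mention] = []
    for m in mentions:
        t0 = bisect_left(starts, m.start)
        t1 = t0
        while t1 < len(norm.offsets) and norm.offsets[t1][1] <= m.end:
            t1 += 1
        span = range(t0, max(t1, t0 + 1))
        if any(k in trigger_toks for k in span):
            continue
        out.append(
            replace(
                m,
                negated=any(k in negated_toks for k in span),
                experiencer=EXPERIENCER_FAMILY if any(k in family_toks for k in span) else EXPERIENCER_PATIENT,
            )
        )
    return out


def extract_corpus(
    docs: Iterable[Document],
    lex: Lexicon,
    triggers: Sequence[TriggerEntry],
    scope_terminators: Iterable[str] = DEFAULT_SCOPE_TERMINATORS,
    strip_diacritics: bool = False,
    log_every: int = 10_000,
) -> Iterator[Mention]:
    """Run match + context classification over a document stream.

    Yields, per document in input order, its mentions sorted by start
    offset; equivalent to concatenating ``classify_context(find_mentions(d))``
    over the stream. Logs progress and per-category counts.
    """
    index = TermIndex(lex, strip_diacritics)
    n_docs = n_mentions = n_negated = n_family = 0
    for doc in docs:
        norm = normalize(doc.text, strip_diacritics=strip_diacritics)
        found = find_mentions(doc, index, _norm=norm)
        for m in classify_context(found, norm, triggers, scope_terminators, strip_diacritics):
            n_mentions += 1
            n_negated += m.negated
            n_family += m.experiencer == EXPERIENCER_FAMILY
            yield m
        n_docs += 1
        if log_every and n_docs % log_every == 0:
            logger.info("extracted %d documents, %d mentions so far", n_docs, n_mentions)
    logger.info(
        "extraction done: %d documents, %d mentions (%d negated, %d family-context)",
        n_docs, n_mentions, n_negated, n_family,
    )


# ---------------------------------------------------------------------------
# File formats


def read_documents(path: str | Path) -> Iterator[Document]:
    """Stream documents from JSONL (one object per line, keys patient_id,
    doc_id, text, optional doc_type/department/date). Malformed lines are
    skipped with a logged warning and counted."""
    path = Path(path)
    n_bad = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                doc = Document(
                    patient_id=str(obj["patient_id"]),
                    doc_id=str(obj["doc_id"]),
                    text=str(obj.get("text", "")),
                    doc_type=obj.get("doc_type"),
                    department=obj.get("department"),
                    date=obj.get("date"),
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                logger.warning("%s:%d: malformed document record (%s); skipped", path, lineno, exc)
                n_bad += 1
                continue
            yield doc
    if n_bad:
        logger.warning("%s: skipped %d malformed document record(s)", path, n_bad)


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in docs:
            obj = {"patient_id": d.patient_id, "doc_id": d.doc_id, "text": d.text}
            for k in ("doc_type", "department", "date"):
                v = getattr(d, k)
                if v is not None:
                    obj[k] = v
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def load_triggers(path: str | Path) -> list[TriggerEntry]:
    """Read a trigger TSV with header phrase, category, direction, max_scope_tokens."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"trigger file not found: {path}")
    out: list[TriggerEntry] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in TRIGGER_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"trigger file {path} missing column(s): {', '.join(missing)}")
        for row in reader:
            out.append(
                TriggerEntry(
                    phrase=row["phrase"].strip(),
                    category=row["category"].strip(),
                    direction=row["direction"].strip() or "forward",
                    max_scope_tokens=int(row["max_scope_tokens"] or 10),
                )
            )
    return out


def write_triggers(triggers: Iterable[TriggerEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRIGGER_COLUMNS)
        for t in triggers:
            w.writerow([t.phrase, t.category, t.direction, t.max_scope_tokens])


def write_mentions(mentions: Iterable[Mention], path: str | Path) -> int:
    """Write mentions TSV; negated encoded 0/1. Returns the row count."""
    n = 0
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MENTION_COLUMNS)
        for m in mentions:
            w.writerow(
                [m.patient_id, m.doc_id, m.concept_id, m.start, m.end,
                 m.matched_text, int(m.negated), m.experiencer]
            )
            n += 1
    return n


def read_mentions(path: str | Path) -> Iterator[Mention]:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"mentions file not found: {path}")
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in MENTION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"mentions file {path} missing column(s): {', '.join(missing)}")
        for row in reader:
            yield Mention(
                patient_id=row["patient_id"],
                doc_id=row["doc_id"],
                concept_id=row["concept_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                matched_text=row["matched_text"],
                negated=bool(int(row["negated"])),
                experiencer=row["experiencer"],
            )
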