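"""Phenotype lexicon: loading, validation and filtering.

The lexicon maps surface terms (including synonyms) to concept identifiers
(CUI-like opaque strings) with a semantic type drawn from a controlled list.
Extraction quality is driven almost entirely by what survives the two
lexicon filters applied here:

* a length window on the raw surface term (default 3..80 characters,
  inclusive), which removes abbreviations too short to be unambiguous and
  pathologically long synonym strings;
* a semantic-type allow-list restricting concepts to phenotype-like
  categories (signs, symptoms, diseases, abnormalities, ...), so that
  anatomy, procedures or chemicals never enter the mention stream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

#: Phenotype-like semantic types used as the default extraction allow-list.
DEFAULT_SEMANTIC_TYPES: frozenset[str] = frozenset(
    {
        "Sign or Symptom",
        "Disease or Syndrome",
        "Finding",
        "Pathologic Function",
        "Congenital Abnormality",
        "Physiologic Function",
        "Anatomical Abnormality",
        "Neoplastic Process",
        "Acquired Abnormality",
        "Mental or Behavioral Dysfunction",
    }
)

DEFAULT_MIN_TERM_LENGTH = 3
DEFAULT_MAX_TERM_LENGTH = 80

LEXICON_COLUMNS = ("concept_id", "surface_term", "preferred_label", "semantic_type", "language")


class LexiconError(ValueError):
    """Fatal problem with a lexicon file (missing file, missing column)."""


@dataclass(frozen=True)
class TermEntry:
    """One surface term attached to one concept.

    A concept may carry several semantic types; the lexicon file holds one
    row per (term, semantic type), so the same (surface_term, concept_id)
    pair may legitimately appear with different types before filtering.
    """

    surface_term: str
    concept_id: str
    preferred_label: str
    semantic_type: str
    language: str = ""

    def __post_init__(self) -> None:
        if not self.surface_term:
            raise ValueError("surface_term must be non-empty")
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")


@dataclass
class Lexicon:
    """A collection of term entries plus the filter parameters applied to it.

    ``allowed_semantic_types``/``min_term_length``/``max_term_length`` are
    ``None`` on a freshly loaded (unfiltered) lexicon and set by
    :func:`filter_lexicon`.
    """

    entries: list[TermEntry] = field(default_factory=list)
    allowed_semantic_types: frozenset[str] | None = None
    min_term_length: int | None = None
    max_term_length: int | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def concept_ids(self) -> set[str]:
        return {e.concept_id for e in self.entries}

    def labels(self) -> dict[str, str]:
        """concept_id -> preferred_label (first label wins; conflicts warned at load)."""
        out: dict[str, str] = {}
        for e in self.entries:
            out.setdefault(e.concept_id, e.preferred_label)
        return out


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon TSV (UTF-8, header ``concept_id  surface_term
    preferred_label  semantic_type  language``) into an unfiltered Lexicon.

    Exact duplicate (surface_term, concept_id, semantic_type) rows collapse
    to one entry. Malformed rows (wrong field count, empty term or concept)
    are skipped with a logged warning carrying the line number. A concept
    observed with two different preferred labels keeps the first and warns,
    so the concept -> label mapping stays functional.
    """
    path = Path(path)
    if not path.is_file():
        raise LexiconError(f"lexicon file not found: {path}")
    entries: list[TermEntry] = []
    seen: set[tuple[str, str, str]] = set()
    labels: dict[str, str] = {}
    n_malformed = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LexiconError(f"lexicon file is empty: {path}") from None
        missing = [c for c in LEXICON_COLUMNS if c not in header]
        if missing:
            raise LexiconError(f"lexicon {path} is missing required column(s): {', '.join(missing)}")
        col = {name: header.index(name) for name in LEXICON_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                logger.warning("%s:%d: malformed row (%d fields, expected %d); skipped", path, lineno, len(row), len(header))
                n_malformed += 1
                continue
            term = row[col["surface_term"]].strip()
            cui = row[col["concept_id"]].strip()
            if not term or not cui:
                logger.warning("%s:%d: empty surface_term or concept_id; skipped", path, lineno)
                n_malformed += 1
                continue
            stype = row[col["semantic_type"]].strip()
            label = row[col["preferred_label"]].strip()
            if cui in labels and labels[cui] != label:
                logger.warning("%s:%d: concept %s has conflicting preferred labels (%r vs %r); keeping the first", path, lineno, cui, labels[cui], label)
                label = labels[cui]
            else:
                labels.setdefault(cui, label)
            key = (term, cui, stype)
            if key in seen:
                continue
            seen.add(key)
            entries.append(TermEntry(term, cui, label, stype, row[col["language"]].strip()))
    logger.info("loaded %d lexicon entries from %s (%d malformed rows skipped)", len(entries), path, n_malformed)
    return Lexicon(entries=entries)


def filter_lexicon(
    lex: Lexicon,
    min_len: int = DEFAULT_MIN_TERM_LENGTH,
    max_len: int = DEFAULT_MAX_TERM_LENGTH,
    allowed_types: Iterable[str] = DEFAULT_SEMANTIC_TYPES,
) -> Lexicon:
    """Apply the length window and semantic-type allow-list.

    Length is measured in characters of the raw surface term (an accented
    letter counts as one character); both bounds are inclusive. A
    (surface_term, concept_id) pair is retained if ANY of its semantic-type
    rows is allowed, and collapses to a single entry afterwards.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if max_len < min_len:
        raise ValueError(f"max_len ({max_len}) must be >= min_len ({min_len})")
    allowed = frozenset(allowed_types)

    kept: list[TermEntry] = []
    kept_pairs: set[tuple[str, str]] = set()
    n_len = n_type = 0
    for e in lex.entries:
        if not (min_len <= len(e.surface_term) <= max_len):
            n_len += 1
            continue
        if e.semantic_type not in allowed:
            n_type += 1
            continue
        pair = (e.surface_term, e.concept_id)
        if pair in kept_pairs:
            continue
        kept_pairs.add(pair)
        kept.append(e)
    logger.info(
        "lexicon filter: %d entries in, %d kept (%d outside [%d, %d] chars, %d disallowed semantic type)",
        len(lex.entries), len(kept), n_len, min_len, max_len, n_type,
    )
    if not kept:
        logger.warning("lexicon filter produced an empty lexicon")
    return Lexicon(
        entries=kept,
        allowed_semantic_types=allowed,
        min_term_length=min_len,
        max_term_length=max_len,
    )


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write a lexicon back to the TSV interchange format."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LEXICON_COLUMNS)
        for e in lex.entries:
            w.writerow([e.concept_id, e.surface_term, e.preferred_label, e.semantic_type, e.language])
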