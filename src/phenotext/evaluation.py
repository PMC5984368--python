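"""Evaluation of ranked phenotype lists.

Two complementary evaluations are supported:

* **Expert relevance** — each ranked top-K list is judged item by item
  (relevant / not relevant), and summarized by truncated-list average
  precision (AP) and, across cohorts, mean average precision (MAP). AP
  here divides by the number of relevant items *in the judged list*: the
  total number of relevant phenotypes for a disease is unknowable when
  only the top-K was judged.

* **Reference coverage** — the extracted concept set is compared against a
  reference phenotype set (e.g. a rare-disease knowledge base pre-mapped
  into the same concept space). A reference concept counts as covered if
  it was extracted exactly (same identifier) or if it is an ancestor — a
  broader concept, at any depth — of some extracted concept (e.g.
  reference "Arrhythmia" covered by extracted "Cardiac flutter").
  Semantically related but non-hierarchical concepts never match.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .cohort_metrics import RankedConcept

logger = logging.getLogger(__name__)

JUDGMENT_COLUMNS = ("cohort_id", "metric", "rank", "concept_id", "relevant")


@dataclass(frozen=True)
class JudgedList:
    """One ranked, expert-judged list: (concept_id, relevant) in rank order."""

    entries: tuple[tuple[str, bool], ...]

    @classmethod
    def from_relevance(cls, flags: Iterable[bool]) -> "JudgedList":
        return cls(tuple((f"item{i}", bool(f)) for i, f in enumerate(flags, start=1)))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReferenceSet:
    """Reference phenotype concept ids for one disease, pre-mapped into the
    extraction concept space."""

    concepts: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.concepts:
            raise ValueError("reference set must be non-empty")


@dataclass
class Hierarchy:
    """Concept hierarchy as (child, parent) edges; must be acyclic."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)  # child -> parent
        return g

    def validate(self) -> nx.DiGraph:
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"concept hierarchy contains a cycle: {cycle}")
        return g


def average_precision(judged: JudgedList | Sequence[bool]) -> float:
    """Truncated-list average precision.

    AP = (sum over relevant ranks k of precision@k) / (# relevant in list).
    Raises if the list has no relevant item (AP is undefined there).
    """
    entries = judged.entries if isinstance(judged, JudgedList) else tuple(("", bool(b)) for b in judged)
    n_rel = 0
    acc = 0.0
    for k, (_, rel) in enumerate(entries, start=1):
        if rel:
            n_rel += 1
            acc += n_rel / k
    if n_rel == 0:
        raise ValueError("AP undefined: no relevant items")
    return acc / n_rel


def mean_average_precision(judged_lists: Sequence[JudgedList | Sequence[bool]]) -> float:
    """Arithmetic mean of per-list average precisions."""
    if not judged_lists:
        raise ValueError("MAP undefined: no judged lists")
    aps = []
    for i, jl in enumerate(judged_lists):
        try:
            aps.append(average_precision(jl))
        except ValueError as exc:
            raise ValueError(f"list {i}: {exc}") from exc
    return sum(aps) / len(aps)


def reference_coverage(
    ref: ReferenceSet,
    extracted: Iterable[str],
    hier: Hierarchy | None = None,
) -> tuple[int, float, list[tuple[str, str]]]:
    """Match a reference phenotype set against extracted concepts.

    Returns (n_matched, coverage, matches) where matches is a list of
    (reference_concept_id, match_kind) with match_kind "exact" or
    "broader". Exact matches take precedence; "broader" means the
    reference concept is an ancestor (any depth) of some extracted
    concept. Raises on a cyclic hierarchy before any traversal.
    """
    extracted_set = set(extracted)
    ancestors_of_extracted: set[str] = set()
    if hier is not None and hier.edges:
        g = hier.validate()
        for e in extracted_set:
            if e in g:
                # edges run child -> parent, so descendants() walks up to ancestors
                ancestors_of_extracted |= nx.descendants(g, e)
    matches: list[tuple[str, str]] = []
    for r in sorted(ref.concepts):
        if r in extracted_set:
            matches.append((r, "exact"))
        elif r in ancestors_of_extracted:
            matches.append((r, "broader"))
    return len(matches), len(matches) / len(ref.concepts), matches


# ---------------------------------------------------------------------------
# Report assembly


@dataclass
class EvaluationReport:
    per_cohort: pd.DataFrame
    map_freq: float | None
    map_tfidf: float | None

    def to_text(self) -> str:
        lines = [self.per_cohort.to_string(index=False)]
        if self.map_freq is not None:
            lines.append(f"MAP (frequency ranking): {self.map_freq:.4f}")
        if self.map_tfidf is not None:
            lines.append(f"MAP (TF-IDF ranking):    {self.map_tfidf:.4f}")
        return "\n".join(lines) + "\n"

    def to_tsv(self, path: str | Path) -> None:
        df = self.per_cohort.copy()
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].map(lambda v: f"{v:.6f}" if pd.notna(v) else "")
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def build_judged_lists(
    rankings: Mapping[str, Sequence[RankedConcept]],
    judgments: Mapping[tuple[str, str], bool],
    cohort_id: str,
) -> dict[str, JudgedList]:
    """Attach relevance flags to ranked lists for one cohort.

    ``judgments`` maps (metric, concept_id) -> relevant. A judgment whose
    concept is absent from the ranking is ignored with a warning; a ranked
    concept without a judgment is treated as not relevant.
    """
    out: dict[str, JudgedList] = {}
    for metric, ranked in rankings.items():
        ranked_ids = {rc.concept_id for rc in ranked}
        orphans = [c for (m, c) in judgments if m == metric and c not in ranked_ids]
        if orphans:
            logger.warning(
                "cohort %s / %s: %d judged concept(s) absent from the ranking, ignored: %s",
                cohort_id, metric, len(orphans), ", ".join(sorted(orphans)[:5]),
            )
        out[metric] = JudgedList(
            tuple((rc.concept_id, judgments.get((metric, rc.concept_id), False)) for rc in ranked)
        )
    return out


def evaluation_report(
    rankings: Mapping[str, Mapping[str, Sequence[RankedConcept]]],
    judgments: Mapping[str, Mapping[tuple[str, str], bool]],
    reference: Mapping[str, ReferenceSet] | None = None,
    hierarchy: Hierarchy | None = None,
) -> EvaluationReport:
    """Per-cohort evaluation table plus MAP across cohorts.

    ``rankings``: cohort_id -> {"freq": [...], "tfidf": [...]} in rank order.
    ``judgments``: cohort_id -> {(metric, concept_id): relevant}.
    ``reference``: optional cohort_id -> ReferenceSet for coverage columns.
    """
    rows = []
    aps_freq: list[float] = []
    aps_tfidf: list[float] = []
    for cohort_id in rankings:
        if cohort_id not in judgments:
            raise KeyError(f"no judgments for cohort {cohort_id!r}")
        judged = build_judged_lists(rankings[cohort_id], judgments[cohort_id], cohort_id)
        rel_sets = {
            m: {cid for cid, rel in judged[m].entries if rel} for m in ("freq", "tfidf")
        }
        row: dict = {
            "cohort_id": cohort_id,
            "n_relevant_freq": len(rel_sets["freq"]),
            "n_relevant_tfidf": len(rel_sets["tfidf"]),
            "n_relevant_union": len(rel_sets["freq"] | rel_sets["tfidf"]),
            "n_relevant_intersection": len(rel_sets["freq"] & rel_sets["tfidf"]),
            "ap_freq": average_precision(judged["freq"]),
            "ap_tfidf": average_precision(judged["tfidf"]),
        }
        aps_freq.append(row["ap_freq"])
        aps_tfidf.append(row["ap_tfidf"])
        if reference is not None and cohort_id in reference:
            extracted = {
                rc.concept_id
                for m in ("freq", "tfidf")
                for rc in rankings[cohort_id][m]
            }
            n_matched, cov, _ = reference_coverage(reference[cohort_id], extracted, hierarchy)
            row["n_reference"] = len(reference[cohort_id].concepts)
            row["n_reference_matched"] = n_matched
            row["coverage"] = cov
        rows.append(row)
    return EvaluationReport(
        per_cohort=pd.DataFrame(rows),
        map_freq=sum(aps_freq) / len(aps_freq) if aps_freq else None,
        map_tfidf=sum(aps_tfidf) / len(aps_tfidf) if aps_tfidf else None,
    )


# ---------------------------------------------------------------------------
# File formats


def load_judgments(path: str | Path) -> dict[str, dict[tuple[str, str], bool]]:
    """Judgments TSV (cohort_id, metric, rank, concept_id, relevant) ->
    cohort_id -> {(metric, concept_id): relevant}. The rank column is
    informational; ordering always comes from the ranking itself."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"judgments file not found: {path}")
    out: dict[str, dict[tuple[str, str], bool]] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in JUDGMENT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"judgments file {path} missing column(s): {', '.join(missing)}")
        for row in reader:
            metric = row["metric"].strip()
            if metric not in ("freq", "tfidf"):
                raise ValueError(f"judgments file {path}: unknown metric {metric!r}")
            out.setdefault(row["cohort_id"], {})[(metric, row["concept_id"])] = bool(int(row["relevant"]))
    return out


def write_judgments(
    judgments: Mapping[str, Mapping[tuple[str, str], bool]],
    path: str | Path,
    ranks: Mapping[tuple[str, str, str], int] | None = None,
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(JUDGMENT_COLUMNS)
        for cohort_id in sorted(judgments):
            for (metric, cid), rel in sorted(judgments[cohort_id].items()):
                rank = (ranks or {}).get((cohort_id, metric, cid), 0)
                w.writerow([cohort_id, metric, rank, cid, int(rel)])


def load_reference(path: str | Path) -> ReferenceSet:
    """Reference TSV with header ref_id, concept_id, label."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"reference file not found: {path}")
    concepts = set()
    source = ""
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            concepts.add(row["concept_id"])
            source = source or row.get("ref_id", "")
    return ReferenceSet(concepts=frozenset(concepts), source=source)


def load_hierarchy(path: str | Path) -> Hierarchy:
    """Hierarchy TSV with header child_concept_id, parent_concept_id."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"hierarchy file not found: {path}")
    edges = set()
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            edges.add((row["child_concept_id"], row["parent_concept_id"]))
    return Hierarchy(edges=edges)
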