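"""Cohort-level aggregation and ranking of extracted phenotype concepts.

Only *qualifying* mentions count here: not negated, and about the patient
rather than a family member. Two ranking metrics are computed per concept c
for a cohort of patients inside a larger warehouse:

* frequency(c) = (# cohort patients with >= 1 qualifying mention of c) / |cohort|
* TF-IDF(c)    = (N_c / N_tot) * log10(P_tot / P_c)

where N_c is the number of qualifying mention tokens of c in the cohort,
N_tot the total number of qualifying mention tokens in the cohort, P_tot
the number of patients in the whole warehouse, and P_c the number of
warehouse patients carrying concept c. Frequency estimates how prevalent a
phenotype is in the cohort; TF-IDF down-weights phenotypes common across
the entire warehouse, surfacing the cohort-specific ones.

The logarithm base defaults to 10 (``log_base`` overrides it); P_c / P_tot
deliberately refer to the whole warehouse, not the cohort — the inverse
document frequency term is meaningless otherwise.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .extraction import EXPERIENCER_FAMILY, EXPERIENCER_PATIENT, Mention

logger = logging.getLogger(__name__)

RANKING_COLUMNS = (
    "concept_id", "preferred_label", "n_patients", "frequency",
    "n_mentions", "tfidf", "rank_freq", "rank_tfidf",
)


def is_qualifying(m: Mention) -> bool:
    """Mentions that count toward frequency and TF-IDF."""
    return (not m.negated) and m.experiencer == EXPERIENCER_PATIENT


@dataclass
class CohortIndex:
    """Per-(patient, concept) qualifying-mention counts for one cohort."""

    cohort_patient_ids: frozenset[str]
    mention_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_tot(self) -> int:
        """Total qualifying mention tokens in the cohort (N_tot)."""
        return sum(self.mention_counts.values())

    def n_c(self, concept_id: str) -> int:
        """Qualifying mention tokens of one concept in the cohort (N_c)."""
        return sum(v for (_, c), v in self.mention_counts.items() if c == concept_id)

    def patients_with(self, concept_id: str) -> int:
        return sum(1 for (_, c), v in self.mention_counts.items() if c == concept_id and v > 0)

    @property
    def concept_ids(self) -> set[str]:
        return {c for (_, c), v in self.mention_counts.items() if v > 0}


@dataclass
class WarehouseStats:
    """Warehouse-wide patient totals: P_tot and per-concept P_c."""

    total_patients: int
    patients_per_concept: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_patients < 1:
            raise ValueError("total_patients must be >= 1")
        for c, p in self.patients_per_concept.items():
            if not 1 <= p <= self.total_patients:
                raise ValueError(f"patients_per_concept[{c}]={p} outside [1, {self.total_patients}]")


@dataclass(frozen=True)
class RankedConcept:
    concept_id: str
    preferred_label: str
    n_patients_in_cohort: int
    frequency: float
    n_mentions: int
    tfidf: float
    rank_freq: int
    rank_tfidf: int


@dataclass
class ContextTable:
    """2x2 mention tally: experiencer (patient/family) x negated (yes/no)."""

    counts: dict[tuple[str, bool], int] = field(
        default_factory=lambda: {
            (EXPERIENCER_FAMILY, True): 0,
            (EXPERIENCER_FAMILY, False): 0,
            (EXPERIENCER_PATIENT, True): 0,
            (EXPERIENCER_PATIENT, False): 0,
        }
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def family_share(self) -> float:
        """Fraction of all mentions attributed to family history."""
        tot = self.total
        if tot == 0:
            return 0.0
        return (self.counts[(EXPERIENCER_FAMILY, True)] + self.counts[(EXPERIENCER_FAMILY, False)]) / tot

    @property
    def patient_not_negated_share(self) -> float:
        """Among patient-context mentions, the fraction not negated."""
        pat = self.counts[(EXPERIENCER_PATIENT, True)] + self.counts[(EXPERIENCER_PATIENT, False)]
        if pat == 0:
            return 0.0
        return self.counts[(EXPERIENCER_PATIENT, False)] / pat

    def as_dict(self) -> dict:
        return {
            "family_negated": self.counts[(EXPERIENCER_FAMILY, True)],
            "family_not_negated": self.counts[(EXPERIENCER_FAMILY, False)],
            "patient_negated": self.counts[(EXPERIENCER_PATIENT, True)],
            "patient_not_negated": self.counts[(EXPERIENCER_PATIENT, False)],
            "total": self.total,
            "family_share": self.family_share,
            "patient_not_negated_share": self.patient_not_negated_share,
        }


def build_cohort_index(mentions: Iterable[Mention], cohort: Iterable[str]) -> CohortIndex:
    """Count qualifying mentions per (patient, concept) for cohort members.

    Mentions that are negated, family-context, or from patients outside the
    cohort are discarded. A cohort patient with no documents simply
    contributes zero counts.
    """
    cohort_ids = frozenset(cohort)
    counts: Counter[tuple[str, str]] = Counter()
    for m in mentions:
        if m.patient_id in cohort_ids and is_qualifying(m):
            counts[(m.patient_id, m.concept_id)] += 1
    return CohortIndex(cohort_patient_ids=cohort_ids, mention_counts=dict(counts))


def concept_frequency(index: CohortIndex, concept_id: str) -> float:
    """Fraction of cohort patients with >= 1 qualifying mention of the concept."""
    if not index.cohort_patient_ids:
        raise ValueError("empty cohort")
    return index.patients_with(concept_id) / len(index.cohort_patient_ids)


def tfidf_score(n_c: int, n_tot: int, p_tot: int, p_c: int, log_base: float = 10.0) -> float:
    """Closed-form TF-IDF: (n_c / n_tot) * log_base(p_tot / p_c)."""
    if n_tot < 1:
        raise ValueError("n_tot must be >= 1")
    if p_c < 1:
        raise ValueError("p_c must be >= 1")
    return (n_c / n_tot) * (math.log(p_tot / p_c) / math.log(log_base))


def concept_tfidf(
    index: CohortIndex,
    stats: WarehouseStats,
    concept_id: str,
    log_base: float = 10.0,
) -> float:
    """TF-IDF of one concept for the cohort against the warehouse."""
    if index.n_tot < 1:
        raise ValueError("cohort index has no qualifying mentions (N_tot = 0)")
    p_c = stats.patients_per_concept.get(concept_id)
    if p_c is None:
        raise KeyError(f"concept {concept_id!r} absent from warehouse stats: cannot compute IDF")
    return tfidf_score(index.n_c(concept_id), index.n_tot, stats.total_patients, p_c, log_base)


def rank_concepts(
    index: CohortIndex,
    stats: WarehouseStats,
    k: int = 50,
    labels: Mapping[str, str] | None = None,
    log_base: float = 10.0,
) -> tuple[list[RankedConcept], list[RankedConcept]]:
    """Top-k concept lists by descending frequency and by descending TF-IDF.

    Ranks are computed over all concepts present in the cohort index (ties
    broken by ascending concept_id), then each list is truncated to
    min(k, #distinct concepts). Every returned concept carries both metrics
    and both ranks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = labels or {}
    n_tot = index.n_tot
    per_concept_nc: Counter[str] = Counter()
    per_concept_pat: defaultdict[str, int] = defaultdict(int)
    for (pid, cid), v in index.mention_counts.items():
        if v > 0:
            per_concept_nc[cid] += v
            per_concept_pat[cid] += 1

    n_cohort = len(index.cohort_patient_ids)
    if n_cohort == 0:
        raise ValueError("empty cohort")
    rows = {}
    for cid, nc in per_concept_nc.items():
        p_c = stats.patients_per_concept.get(cid)
        if p_c is None:
            raise KeyError(f"concept {cid!r} absent from warehouse stats: cannot compute IDF")
        rows[cid] = (
            per_concept_pat[cid],
            per_concept_pat[cid] / n_cohort,
            nc,
            tfidf_score(nc, n_tot, stats.total_patients, p_c, log_base),
        )

    by_freq = sorted(rows, key=lambda c: (-rows[c][1], c))
    by_tfidf = sorted(rows, key=lambda c: (-rows[c][3], c))
    rank_f = {c: i + 1 for i, c in enumerate(by_freq)}
    rank_t = {c: i + 1 for i, c in enumerate(by_tfidf)}

    def mk(cid: str) -> RankedConcept:
        n_pat, freq, nc, tfidf = rows[cid]
        return RankedConcept(
            concept_id=cid,
            preferred_label=labels.get(cid, cid),
            n_patients_in_cohort=n_pat,
            frequency=freq,
            n_mentions=nc,
            tfidf=tfidf,
            rank_freq=rank_f[cid],
            rank_tfidf=rank_t[cid],
        )

    return [mk(c) for c in by_freq[:k]], [mk(c) for c in by_tfidf[:k]]


def context_table(mentions: Iterable[Mention]) -> ContextTable:
    """Tally ALL mentions (no qualifying filter) into the 2x2 context table."""
    t = ContextTable()
    for m in mentions:
        t.counts[(m.experiencer, m.negated)] += 1
    return t


def compute_warehouse_stats(
    mentions: Iterable[Mention],
    total_patients: int | None = None,
) -> WarehouseStats:
    """Derive P_tot / P_c from a full-corpus mention stream.

    P_c counts distinct patients with >= 1 qualifying mention of c. By
    default P_tot counts patients with at least one qualifying extracted
    concept; pass ``total_patients`` to use the full warehouse patient
    count instead (both readings are defensible; this keeps it explicit).
    """
    patients_per_concept: defaultdict[str, set[str]] = defaultdict(set)
    all_patients: set[str] = set()
    for m in mentions:
        if is_qualifying(m):
            patients_per_concept[m.concept_id].add(m.patient_id)
            all_patients.add(m.patient_id)
    p_tot = total_patients if total_patients is not None else len(all_patients)
    if p_tot < 1:
        raise ValueError("no patients with qualifying mentions; cannot build warehouse stats")
    return WarehouseStats(
        total_patients=p_tot,
        patients_per_concept={c: len(s) for c, s in patients_per_concept.items()},
    )


# ---------------------------------------------------------------------------
# File formats


def read_cohort(path: str | Path) -> set[str]:
    """Plain-text cohort file: one patient_id per line, blank lines ignored."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"cohort file not found: {path}")
    with path.open(encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_warehouse_stats(stats: WarehouseStats, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"#total_patients={stats.total_patients}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["concept_id", "n_patients"])
        for c in sorted(stats.patients_per_concept):
            w.writerow([c, stats.patients_per_concept[c]])


def read_warehouse_stats(path: str | Path) -> WarehouseStats:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"warehouse stats file not found: {path}")
    with path.open(encoding="utf-8", newline="") as fh:
        preamble = fh.readline().strip()
        if not preamble.startswith("#total_patients="):
            raise ValueError(f"{path}: expected '#total_patients=<n>' preamble, got {preamble!r}")
        total = int(preamble.split("=", 1)[1])
        reader = csv.DictReader(fh, delimiter="\t")
        ppc = {row["concept_id"]: int(row["n_patients"]) for row in reader}
    return WarehouseStats(total_patients=total, patients_per_concept=ppc)


def write_rankings(
    by_freq: list[RankedConcept],
    by_tfidf: list[RankedConcept],
    path: str | Path,
) -> None:
    """Ranking TSV with a 'metric' lead column (freq | tfidf), one block per list.

    Scores are written at fixed precision (frequency 6 dp, tfidf 6 dp) so
    reruns are byte-identical; full precision lives in the objects.
    """
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("metric",) + RANKING_COLUMNS)
        for metric, lst in (("freq", by_freq), ("tfidf", by_tfidf)):
            for rc in lst:
                w.writerow(
                    [metric, rc.concept_id, rc.preferred_label, rc.n_patients_in_cohort,
                     f"{rc.frequency:.6f}", rc.n_mentions, f"{rc.tfidf:.6f}",
                     rc.rank_freq, rc.rank_tfidf]
                )


def read_rankings(path: str | Path) -> dict[str, list[RankedConcept]]:
    """Read a ranking TSV back into {'freq': [...], 'tfidf': [...]} (rank order)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"rankings file not found: {path}")
    out: dict[str, list[RankedConcept]] = {"freq": [], "tfidf": []}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["metric"]].append(
                RankedConcept(
                    concept_id=row["concept_id"],
                    preferred_label=row["preferred_label"],
                    n_patients_in_cohort=int(row["n_patients"]),
                    frequency=float(row["frequency"]),
                    n_mentions=int(row["n_mentions"]),
                    tfidf=float(row["tfidf"]),
                    rank_freq=int(row["rank_freq"]),
                    rank_tfidf=int(row["rank_tfidf"]),
                )
            )
    return out
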