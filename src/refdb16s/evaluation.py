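"""Database performance metrics: identification power, completeness,
ambiguity, and leave-one-out taxonomic consistency.

Four complementary views of how useful a reference database is for
identifying clinical amplicon reads:

* **first named match** — the rank, within the identity-sorted hit list at
  >=98%, of the first hit carrying a full Latin binomial; lower is better.
* **completeness** — percentage of queries with *no* hit at a threshold;
  a complete database leaves few reads unmatched.
* **ambiguity** — mean number of distinct OTU labels among a query's hits
  above a threshold; an internally consistent database returns one.
* **LOOCV** — each database sequence is queried against the rest; the best
  non-self hit (with >=80% shorter-sequence coverage) should come from the
  same genus, restricted to genera with more than one database sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .hits import HitList
from .identity import DEFAULT_MIN_COVERAGE, search
from .records import Read, ReferenceRecord

__all__ = [
    "DEFAULT_THRESHOLDS",
    "LoocvResult",
    "EvaluationReport",
    "first_named_match_position",
    "completeness_curve",
    "ambiguity_curve",
    "loocv_genus",
    "classification_accuracy",
    "evaluate_database",
]

DEFAULT_THRESHOLDS = (98.0, 98.5, 99.0, 99.5)

QueryLike = Union[str, ReferenceRecord, Read]


def first_named_match_position(
    hits: HitList, min_identity: float = 98.0
) -> Optional[int]:
    """1-based rank of the first fully named subject at >= *min_identity*.

    Scans the identity-sorted hit list restricted to the threshold; returns
    None when no named subject qualifies.
    """
    rank = 0
    for h in hits:
        if h.pct_identity < min_identity:
            continue
        rank += 1
        if h.subject_named:
            return rank
    return None


def _default_search(query, db, min_identity, otu_labels=None):
    return search(query, db, min_identity, otu_labels=otu_labels)


def completeness_curve(
    queries: Sequence[QueryLike],
    db: Sequence[ReferenceRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    *,
    search_fn: Optional[Callable] = None,
) -> Dict[float, float]:
    """Percent of queries that fail to match any database sequence.

    One search per query at the lowest threshold; higher thresholds reuse
    the same hit lists, so the curve is monotone by construction.
    """
    if not queries:
        raise ValueError("completeness_curve requires queries")
    fn = search_fn or _default_search
    lowest = min(thresholds)
    hitlists = [
        fn(q, db, lowest) if db else HitList(getattr(q, "id", "query"))
        for q in queries
    ]
    out: Dict[float, float] = {}
    for t in thresholds:
        failing = sum(1 for h in hitlists if len(h.at_threshold(t)) == 0)
        out[t] = 100.0 * failing / len(queries)
    return out


def ambiguity_curve(
    queries: Sequence[QueryLike],
    db: Sequence[ReferenceRecord],
    otu_labels: Mapping[str, str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    *,
    search_fn: Optional[Callable] = None,
) -> Dict[float, Optional[float]]:
    """Mean number of distinct OTU labels among hits above each threshold.

    Labels are counted, not entries: several hits to one OTU are one answer.
    Queries with no hit at a threshold are excluded from that mean; a
    threshold where no query has a hit yields None.
    """
    fn = search_fn or _default_search
    lowest = min(thresholds)
    hitlists = [fn(q, db, lowest, otu_labels=otu_labels) for q in queries]
    out: Dict[float, Optional[float]] = {}
    for t in thresholds:
        counts = []
        for h in hitlists:
            labels = h.distinct_otu_labels(min_identity=t)
            if len(h.at_threshold(t)) > 0:
                counts.append(len(labels))
        out[t] = sum(counts) / len(counts) if counts else None
    return out


@dataclass(frozen=True)
class LoocvResult:
    eligible_n: int
    mismatch_n: int
    mismatched_ids: Tuple[str, ...] = ()

    @property
    def accuracy_pct(self) -> float:
        return classification_accuracy(self.eligible_n, self.mismatch_n)


def classification_accuracy(eligible_n: int, mismatch_n: int) -> float:
    """Successful-classification percentage: 100 * (eligible - mismatch) / eligible."""
    if eligible_n <= 0:
        raise ValueError("eligible_n must be positive")
    if not 0 <= mismatch_n <= eligible_n:
        raise ValueError("mismatch_n must be in [0, eligible_n]")
    return 100.0 * (eligible_n - mismatch_n) / eligible_n


def loocv_genus(
    db: Sequence[ReferenceRecord],
    genus_labels: Mapping[str, str],
    *,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    search_fn: Optional[Callable] = None,
) -> LoocvResult:
    """Leave-one-out cross-validation of genus-level consistency.

    Every database sequence is searched against the whole database; the
    exact self-match is ignored and the best remaining hit whose aligned
    region covers at least 80% of the shorter sequence is taken.  Exact
    duplicates under a different id are legal subjects.  Only queries from
    genera with more than one database sequence are eligible; an eligible
    query with no qualifying non-self hit counts as a mismatch.
    """
    if not db:
        raise ValueError("loocv_genus requires a database")
    genus_sizes: Dict[str, int] = {}
    for rec in db:
        g = genus_labels.get(rec.id)
        if g is not None:
            genus_sizes[g] = genus_sizes.get(g, 0) + 1

    def default_fn(query, database, min_identity, otu_labels=None):
        return search(query, database, min_identity, min_coverage=min_coverage)

    fn = search_fn or default_fn
    eligible = 0
    mismatches: List[str] = []
    for rec in db:
        g = genus_labels.get(rec.id)
        if g is None or genus_sizes.get(g, 0) < 2:
            continue
        eligible += 1
        hits = fn(rec, db, 0.0)
        best = next((h for h in hits if h.subject_id != rec.id), None)
        if best is None or genus_labels.get(best.subject_id) != g:
            mismatches.append(rec.id)
    return LoocvResult(eligible, len(mismatches), tuple(sorted(mismatches)))


@dataclass
class EvaluationReport:
    """All four metrics for one database against one query set."""

    named_match_positions: Dict[str, Optional[int]]
    completeness: Dict[float, float]
    ambiguity: Dict[float, Optional[float]]
    loocv: Optional[LoocvResult]

    def to_dict(self) -> dict:
        return {
            "named_match_positions": self.named_match_positions,
            "completeness_pct_failing": {
                str(t): v for t, v in self.completeness.items()
            },
            "ambiguity_mean_labels": {str(t): v for t, v in self.ambiguity.items()},
            "loocv": None
            if self.loocv is None
            else {
                "eligible_n": self.loocv.eligible_n,
                "mismatch_n": self.loocv.mismatch_n,
                "accuracy_pct": self.loocv.accuracy_pct,
            },
        }


def evaluate_database(
    db: Sequence[ReferenceRecord],
    queries: Sequence[QueryLike],
    otu_labels: Mapping[str, str],
    genus_labels: Optional[Mapping[str, str]] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    named_match_min_identity: float = 98.0,
) -> EvaluationReport:
    """Run all four performance metrics against one database."""
    lowest = min(thresholds)
    positions: Dict[str, Optional[int]] = {}
    hitlists = []
    for q in queries:
        h = search(q, db, lowest, otu_labels=otu_labels)
        hitlists.append(h)
        positions[h.query_id] = first_named_match_position(
            h, min_identity=named_match_min_identity
        )
    comp: Dict[float, float] = {}
    amb: Dict[float, Optional[float]] = {}
    for t in thresholds:
        failing = sum(1 for h in hitlists if len(h.at_threshold(t)) == 0)
        comp[t] = 100.0 * failing / len(queries) if queries else 0.0
        counts = [
            len(h.distinct_otu_labels(min_identity=t))
            for h in hitlists
            if len(h.at_threshold(t)) > 0
        ]
        amb[t] = sum(counts) / len(counts) if counts else None
    loocv = loocv_genus(db, genus_labels) if genus_labels else None
    return EvaluationReport(positions, comp, amb, loocv)
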