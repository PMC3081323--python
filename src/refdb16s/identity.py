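"""Pairwise percent identity and all-vs-database similarity search.

This module defines the single identity semantics every other stage uses.
Identity comes from a global alignment with free end gaps (overlap
alignment): candidate references are near-full-length, which makes this
deterministic and easy to check against an exhaustive dynamic-programming
oracle, unlike a heuristic local search.

    pct_identity = 100 * matched columns / aligned columns

where the aligned region excludes end-gap columns, internal gap columns count
as mismatches, and a non-ACGT character never matches anything (including an
identical ambiguity code).  Alignment scoring is match +1, mismatch -2,
gap -2, mirroring the megablast parameters
``-gapopen 0 -gapextend 0 -penalty -2 -reward 1``.

A hit additionally needs coverage: the aligned region must span at least 80%
of the shorter of the two sequences (``min_coverage=0.8``).  This suppresses
short spurious matches with high identity over a tiny overlap and is applied
to all searches, not only cross-validation; pass ``min_coverage=0`` to turn
it off.

The search backend is pluggable: the default aligns internally; a
:class:`TabularBackend` replays precomputed hits from a tabular search-result
file.  The identity/coverage filter and the sort contract are
backend-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, Mapping, Optional, Sequence, Union

from ._nw import encode, overlap_align
from .hits import Hit, HitList
from .records import Read, ReferenceRecord

__all__ = [
    "IdentityResult",
    "pairwise_identity",
    "search",
    "identity_matrix",
    "TabularBackend",
    "DEFAULT_MIN_COVERAGE",
]

DEFAULT_MIN_COVERAGE = 0.8

SeqLike = Union[str, ReferenceRecord, Read]


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of one pairwise comparison."""

    pct_identity: float  # in [0, 100]
    align_len: int  # columns in the aligned region (end gaps excluded)
    coverage_short: float  # align_len / min(len a, len b), capped at 1

    def passes(self, min_identity: float, min_coverage: float) -> bool:
        return (
            self.pct_identity >= min_identity
            and self.coverage_short >= min_coverage
        )


def _as_seq(x: SeqLike) -> str:
    if isinstance(x, (ReferenceRecord, Read)):
        return x.seq
    return x


def pairwise_identity(a: SeqLike, b: SeqLike) -> IdentityResult:
    """Percent identity between two nucleotide sequences.

    The pair is canonically ordered (shorter sequence first, ties broken
    lexicographically) before aligning, so the result is symmetric in its
    arguments by construction even when co-optimal alignments exist.
    """
    sa, sb = _as_seq(a), _as_seq(b)
    if not sa or not sb:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if (len(sa), sa) > (len(sb), sb):
        sa, sb = sb, sa
    matches, cols, _score = overlap_align(encode(sa), encode(sb))
    if cols == 0:
        return IdentityResult(0.0, 0, 0.0)
    pct = 100.0 * matches / cols
    cov = min(1.0, cols / min(len(sa), len(sb)))
    return IdentityResult(pct, cols, cov)


def identity_matrix(
    records: Sequence[SeqLike],
    identity_fn: Optional[Callable[[SeqLike, SeqLike], IdentityResult]] = None,
) -> Dict[frozenset, IdentityResult]:
    """All-pairs identities keyed by frozenset of indices into *records*."""
    fn = identity_fn or pairwise_identity
    out: Dict[frozenset, IdentityResult] = {}
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            out[frozenset((i, j))] = fn(records[i], records[j])
    return out


class TabularBackend:
    """Search backend replaying precomputed hits (e.g. from a BLAST run).

    Built from per-query :class:`HitList` objects as returned by
    :func:`refdb16s.io.read_hits_tabular`.  ``search`` re-applies the
    identity/coverage filter and the sort contract, so file order and
    pre-filtering of the imported hits do not matter.
    """

    def __init__(self, hitlists: Iterable[HitList]):
        self._by_query: Dict[str, HitList] = {h.query_id: h for h in hitlists}

    def __call__(self, query_id, query_seq, db):
        stored = self._by_query.get(query_id)
        if stored is None:
            return []
        lengths = {r.id: len(r.seq) for r in db}
        out = []
        for h in stored:
            if h.subject_id not in lengths:
                continue
            shorter = min(len(query_seq), lengths[h.subject_id])
            cov = min(1.0, h.align_len / shorter) if shorter else 0.0
            out.append((h.subject_id, h.pct_identity, h.align_len, cov))
        return out


def _internal_backend(query_id, query_seq, db):
    out = []
    for rec in db:
        res = pairwise_identity(query_seq, rec.seq)
        out.append((rec.id, res.pct_identity, res.align_len, res.coverage_short))
    return out


def search(
    query: SeqLike,
    db: Sequence[ReferenceRecord],
    min_identity: float = 0.0,
    *,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    otu_labels: Optional[Mapping[str, str]] = None,
    backend: Optional[Callable] = None,
    query_id: Optional[str] = None,
) -> HitList:
    """Search one query against a reference database.

    Returns every subject with ``pct_identity >= min_identity`` and
    coverage of the shorter sequence ``>= min_coverage``, ordered by the
    HitList contract (identity desc, alignment length desc, subject id asc).

    Parameters
    ----------
    query:
        Query sequence, record, or read.
    db:
        Reference records to search against.
    min_identity:
        Percent identity threshold (inclusive).
    min_coverage:
        Shorter-sequence coverage threshold (inclusive); 0 disables it.
    otu_labels:
        Optional mapping from subject id to OTU label, attached to hits.
    backend:
        Callable ``(query_id, query_seq, db) -> [(subject_id, pct, alen,
        cov), ...]``; defaults to the internal aligner.
    """
    if not db:
        raise ValueError("search requires a non-empty database")
    qseq = _as_seq(query)
    if query_id is None:
        query_id = getattr(query, "id", "query")
    named = {r.id: r.named for r in db}
    raw = (backend or _internal_backend)(query_id, qseq, db)
    hits = [
        Hit(
            subject_id=sid,
            pct_identity=pct,
            align_len=alen,
            subject_named=named.get(sid),
            subject_otu_label=(otu_labels or {}).get(sid),
        )
        for sid, pct, alen, cov in raw
        if pct >= min_identity and cov >= min_coverage
    ]
    return HitList(query_id, hits)
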