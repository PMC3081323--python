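"""Iterative refinement of a reference database against clinical reads.

One curation pass: (1) assign every read to its best database match at
>=98% identity; (2) dereplicate the unassigned reads and, for groups of more
than 25, nominate a full-length candidate from a local sequence pool (or
flag the group representative as novel when the pool has nothing suitable);
(3) after re-assignment, drop every database entry supported by fewer than
25 reads — this removes artefacts (chimeras, error-ridden reads) and
transient environmental contaminants that are not true residents of the
sampled habitat.

The expansion rule ("more than 25") and retention rule ("fewer than 25")
are deliberately asymmetric: expansion needs >= 26 reads, retention needs
>= 25.  Both thresholds are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .grouping import SimilarityGroup, greedy_group
from .identity import DEFAULT_MIN_COVERAGE, pairwise_identity, search
from .records import Read, ReferenceRecord

__all__ = [
    "ReadAssignment",
    "AssignmentTable",
    "Proposal",
    "assign_reads",
    "propose_additions",
    "frequency_filter",
    "filter_reads",
    "curate",
    "CurationResult",
]


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    subject_id: Optional[str]  # None when unassigned
    pct_identity: Optional[float]

    @property
    def assigned(self) -> bool:
        return self.subject_id is not None


@dataclass
class AssignmentTable:
    """Read-to-reference assignments plus per-reference support counts."""

    assignments: List[ReadAssignment]
    min_identity: float

    @property
    def support_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for a in self.assignments:
            if a.subject_id is not None:
                counts[a.subject_id] = counts.get(a.subject_id, 0) + 1
        return counts

    @property
    def assigned(self) -> List[ReadAssignment]:
        return [a for a in self.assignments if a.assigned]

    @property
    def unassigned_ids(self) -> List[str]:
        return [a.read_id for a in self.assignments if not a.assigned]


def assign_reads(
    reads: Sequence[Read],
    db: Sequence[ReferenceRecord],
    min_identity: float = 98.0,
    *,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    backend: Optional[Callable] = None,
) -> AssignmentTable:
    """Assign each read to its single best database match.

    The best match is the top of the hit list under the identity sort and
    tie-break contract; a read whose hit list at the threshold is empty is
    unassigned.  A read never splits support across entries.
    """
    if not db:
        raise ValueError("assign_reads requires a non-empty database")
    out: List[ReadAssignment] = []
    for read in reads:
        hits = search(
            read, db, min_identity, min_coverage=min_coverage, backend=backend
        )
        best = hits.best
        if best is None:
            out.append(ReadAssignment(read.id, None, None))
        else:
            out.append(ReadAssignment(read.id, best.subject_id, best.pct_identity))
    return AssignmentTable(out, min_identity)


@dataclass
class Proposal:
    """A database addition nominated by a group of unassigned reads."""

    group: SimilarityGroup
    representative_read_id: str
    candidate_id: Optional[str]  # pool sequence, or None when novel
    novel: bool


def propose_additions(
    unassigned_reads: Sequence[Read],
    candidate_pool: Sequence[ReferenceRecord],
    min_group_size: int = 25,
    min_identity: float = 98.0,
    group_threshold: float = 99.7,
    seed: int = 0,
) -> List[Proposal]:
    """Nominate database additions from groups of unassigned reads.

    Unassigned reads are dereplicated at 99.7%; only groups with more than
    *min_group_size* members proceed.  Pool sequences at >= *min_identity*
    to the group representative **and longer than it** are candidates,
    ranked by greatest length, then highest identity, then oral/airway
    provenance.  If the pool offers nothing, the group representative read
    itself is emitted flagged as novel.
    """
    if not unassigned_reads:
        return []
    as_records = [ReferenceRecord(id=r.id, seq=r.seq) for r in unassigned_reads]
    by_id = {r.id: r for r in as_records}
    groups = greedy_group(as_records, threshold_pct=group_threshold, seed=seed)
    proposals: List[Proposal] = []
    for group in groups:
        if len(group.member_ids) <= min_group_size:
            continue
        rep = by_id[group.representative_id]
        candidates: List[Tuple[int, float, bool, str]] = []
        for pool_rec in candidate_pool:
            if len(pool_rec.seq) <= len(rep.seq):
                continue
            res = pairwise_identity(rep, pool_rec)
            if res.pct_identity >= min_identity:
                candidates.append(
                    (
                        len(pool_rec.seq),
                        res.pct_identity,
                        pool_rec.provenance == "oral_airway",
                        pool_rec.id,
                    )
                )
        if candidates:
            candidates.sort(key=lambda c: (-c[0], -c[1], not c[2], c[3]))
            proposals.append(
                Proposal(group, rep.id, candidate_id=candidates[0][3], novel=False)
            )
        else:
            proposals.append(Proposal(group, rep.id, candidate_id=None, novel=True))
    return proposals


def frequency_filter(
    db: Sequence[ReferenceRecord],
    assignment: AssignmentTable,
    min_support: int = 25,
) -> Tuple[List[ReferenceRecord], List[Tuple[str, int]]]:
    """Drop database entries supported by fewer than *min_support* reads.

    Returns (retained records, removal log of (id, support count)).  An
    entry with exactly *min_support* supporting reads is retained.
    """
    counts = assignment.support_counts
    kept: List[ReferenceRecord] = []
    removed: List[Tuple[str, int]] = []
    for rec in db:
        n = counts.get(rec.id, 0)
        if n >= min_support:
            kept.append(rec)
        else:
            removed.append((rec.id, n))
    return kept, removed


def _primer_trim_lengths(
    seq: str, fwd: Optional[str], rev: Optional[str]
) -> Tuple[int, int]:
    """(leading, trailing) bases to trim for primers matching exactly or
    with at most one mismatch."""

    def _matches(window: str, primer: str) -> bool:
        return sum(1 for a, b in zip(window, primer) if a != b) <= 1

    lead = 0
    if fwd and len(seq) >= len(fwd) and _matches(seq[: len(fwd)], fwd):
        lead = len(fwd)
    tail = 0
    if rev and len(seq) - lead >= len(rev) and _matches(seq[-len(rev):], rev):
        tail = len(rev)
    return lead, tail


def filter_reads(
    raw_reads: Sequence[Read],
    min_len: int = 350,
    min_qual: float = 25.0,
    primers: Optional[Tuple[Optional[str], Optional[str]]] = None,
    drop_chimeras: bool = True,
) -> List[Read]:
    """Quality/length filtering of raw amplicon reads.

    Primer prefix/suffix (exact or one mismatch) is removed before testing.
    Kept reads are strictly longer than *min_len* bp with mean Phred quality
    strictly above *min_qual*; reads without qualities (FASTA input) skip
    the quality test.  Reads flagged as chimeric by an external checker are
    dropped when *drop_chimeras* is set.
    """
    fwd, rev = primers if primers else (None, None)
    kept: List[Read] = []
    for read in raw_reads:
        if drop_chimeras and read.chimera:
            continue
        lead, tail = _primer_trim_lengths(read.seq, fwd, rev)
        seq = read.seq[lead : len(read.seq) - tail]
        qual = (
            list(read.qual)[lead : len(read.seq) - tail]
            if read.qual is not None
            else None
        )
        if len(seq) <= min_len:
            continue
        if qual is not None and sum(qual) / len(qual) <= min_qual:
            continue
        kept.append(
            Read(id=read.id, seq=seq, qual=qual, chimera=read.chimera,
                 tags=dict(read.tags))
        )
    return kept


@dataclass
class CurationResult:
    """Outcome of a curation run: final database plus per-stage logs."""

    db: List[ReferenceRecord]
    assignment: AssignmentTable
    proposals: List[Proposal]
    removed: List[Tuple[str, int]]
    log: List[str] = field(default_factory=list)


def curate(
    db: Sequence[ReferenceRecord],
    reads: Sequence[Read],
    pool: Sequence[ReferenceRecord] = (),
    min_identity: float = 98.0,
    min_support: int = 25,
    min_group_size: int = 25,
    iterations: int = 1,
    seed: int = 0,
) -> CurationResult:
    """Driver loop: assign -> expand -> re-assign -> frequency-filter.

    Each iteration adds accepted pool candidates for large unmatched read
    groups, then re-assigns and filters.  Per-stage actions are logged; no
    sequence is dropped silently.
    """
    current = list(db)
    log: List[str] = []
    pool_by_id = {r.id: r for r in pool}
    assignment = assign_reads(reads, current, min_identity)
    proposals: List[Proposal] = []
    for it in range(max(1, iterations)):
        log.append(
            f"iteration {it + 1}: {len(assignment.assigned)}/{len(reads)} reads assigned"
        )
        unassigned = {a.read_id for a in assignment.assignments if not a.assigned}
        unreads = [r for r in reads if r.id in unassigned]
        proposals = propose_additions(
            unreads, pool, min_group_size=min_group_size,
            min_identity=min_identity, seed=seed,
        )
        added = 0
        current_ids = {r.id for r in current}
        for p in proposals:
            if p.candidate_id and p.candidate_id not in current_ids:
                current.append(pool_by_id[p.candidate_id])
                current_ids.add(p.candidate_id)
                added += 1
                log.append(f"iteration {it + 1}: added {p.candidate_id} from pool")
            elif p.novel:
                log.append(
                    f"iteration {it + 1}: group at {p.representative_read_id} "
                    f"flagged novel (no pool candidate)"
                )
        assignment = assign_reads(reads, current, min_identity)
        if added == 0:
            break
    filtered, removed = frequency_filter(current, assignment, min_support)
    for rid, n in removed:
        log.append(f"filter: removed {rid} (support {n} < {min_support})")
    return CurationResult(
        db=filtered,
        assignment=assignment,
        proposals=proposals,
        removed=removed,
        log=log,
    )
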