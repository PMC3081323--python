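"""Greedy dereplication of highly similar candidate sequences.

Candidate reference sets pulled from public repositories contain many
near-identical entries for the same taxon.  Dereplication collapses them:
starting from the first input sequence, a founder claims every still
ungrouped sequence within the identity threshold (default 99.7%, i.e. 0.3%
divergence — roughly the sequencing-error level over a full-length 16S
gene), then a new founder is drawn at random from the remainder and the
process repeats until nothing is left.  One representative per group is kept,
chosen by metadata quality; additional within-taxon variants are retained
only when they diverge by more than 1% from everything already kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .identity import IdentityResult, pairwise_identity
from .records import ReferenceRecord

__all__ = [
    "SimilarityGroup",
    "greedy_group",
    "select_representative",
    "representative_rank_key",
    "retain_within_taxon_variants",
]

IdentityFn = Callable[..., IdentityResult]


@dataclass
class SimilarityGroup:
    """A founder plus all members within the identity threshold of it."""

    founder_id: str
    member_ids: List[str]  # includes the founder
    representative_id: str
    threshold_pct: float


def representative_rank_key(record: ReferenceRecord):
    """Sort key implementing the representative-selection priority.

    Lexicographic: type strains first, then oral/airway provenance, then
    fewest ambiguous bases, then greatest length, then ascending id as the
    final tiebreak.  The earliest record under this key is the
    representative.
    """
    return (
        not record.is_type_strain,
        record.provenance != "oral_airway",
        record.ambiguous_frac,
        -len(record.seq),
        record.id,
    )


def select_representative(members: Sequence[ReferenceRecord]) -> str:
    """Pick the group representative by metadata quality, length and id."""
    if not members:
        raise ValueError("cannot select a representative from an empty group")
    return min(members, key=representative_rank_key).id


def greedy_group(
    records: Sequence[ReferenceRecord],
    threshold_pct: float = 99.7,
    seed: int = 0,
    identity_fn: Optional[IdentityFn] = None,
) -> List[SimilarityGroup]:
    """Greedy single-pass dereplication at an identity threshold.

    The first founder is the first input record; every later founder is
    drawn by a seeded RNG from the ungrouped remainder, mirroring the random
    choice in the original procedure while keeping default runs
    reproducible.  A founder's group contains the founder plus every *still
    ungrouped* record with identity >= threshold to it; grouped records are
    never revisited, so the output is a partition.
    """
    if not records:
        raise ValueError("greedy_group requires at least one record")
    if not 0.0 < threshold_pct <= 100.0:
        raise ValueError("threshold_pct must be in (0, 100]")
    fn = identity_fn or pairwise_identity
    rng = np.random.default_rng(seed)

    remaining = list(range(len(records)))
    groups: List[SimilarityGroup] = []
    first = True
    while remaining:
        if first:
            founder_pos = 0
            first = False
        else:
            founder_pos = int(rng.integers(len(remaining)))
        founder_idx = remaining.pop(founder_pos)
        founder = records[founder_idx]
        member_idx = [founder_idx]
        still = []
        for idx in remaining:
            if fn(founder, records[idx]).pct_identity >= threshold_pct:
                member_idx.append(idx)
            else:
                still.append(idx)
        remaining = still
        members = [records[i] for i in sorted(member_idx)]
        groups.append(
            SimilarityGroup(
                founder_id=founder.id,
                member_ids=[m.id for m in members],
                representative_id=select_representative(members),
                threshold_pct=threshold_pct,
            )
        )
    return groups


def retain_within_taxon_variants(
    members: Sequence[ReferenceRecord],
    max_identity_pct: float = 99.0,
    identity_fn: Optional[IdentityFn] = None,
) -> List[str]:
    """Keep genuinely divergent variants within one named taxon.

    The representative is always kept; walking the remaining members in
    representative-rank order, a member is added only if it is less than
    *max_identity_pct* identical (default: >1% divergent) to every member
    already retained.  Near-duplicates add nothing for a database designed
    around a 98% match threshold.
    """
    if not members:
        raise ValueError("empty taxon member list")
    fn = identity_fn or pairwise_identity
    ordered = sorted(members, key=representative_rank_key)
    retained: List[ReferenceRecord] = [ordered[0]]
    for cand in ordered[1:]:
        if all(
            fn(cand, kept).pct_identity < max_identity_pct for kept in retained
        ):
            retained.append(cand)
    return [r.id for r in retained]
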