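"""Similarity-search hit lists with a total, deterministic sort contract.

Hits are ranked on percent identity rather than e-value, because e-values are
biased by random length differences between database sequences.  The full
ordering contract is: descending percent identity, ties broken by descending
alignment length, then ascending subject id.  The contract is total, so any
permutation of the same hits yields an identical ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional

__all__ = ["Hit", "HitList"]


@dataclass(frozen=True)
class Hit:
    subject_id: str
    pct_identity: float
    align_len: int
    subject_named: Optional[bool] = None
    subject_otu_label: Optional[str] = None

    def sort_key(self):
        return (-self.pct_identity, -self.align_len, self.subject_id)


class HitList:
    """Ordered similarity-search results for one query."""

    def __init__(self, query_id: str, entries: Iterable[Hit] = ()):
        self.query_id = query_id
        self.entries: List[Hit] = sorted(entries, key=Hit.sort_key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    def __repr__(self) -> str:
        return f"HitList({self.query_id!r}, {len(self.entries)} hits)"

    @property
    def best(self) -> Optional[Hit]:
        """Top-ranked hit, or None if the list is empty."""
        return self.entries[0] if self.entries else None

    def at_threshold(self, min_identity: float) -> "HitList":
        """Hits with percent identity >= *min_identity* (order preserved)."""
        return HitList(
            self.query_id,
            [h for h in self.entries if h.pct_identity >= min_identity],
        )

    def distinct_otu_labels(self, min_identity: float = 0.0) -> set:
        """Distinct subject OTU labels among hits at or above a threshold."""
        return {
            h.subject_otu_label
            for h in self.entries
            if h.pct_identity >= min_identity and h.subject_otu_label is not None
        }
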