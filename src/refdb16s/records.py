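"""Core sequence record types shared by every stage of the pipeline.

A :class:`ReferenceRecord` is one candidate or accepted reference sequence
together with the metadata that drives representative selection (type-strain
status, provenance, sequence quality).  A :class:`Read` is one amplicon
sequencing read, optionally carrying per-base Phred qualities and a chimera
flag produced by an external checker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "PROVENANCES",
    "ReferenceRecord",
    "Read",
    "is_full_binomial",
    "filter_ambiguous",
]

PROVENANCES = ("oral_airway", "other", "unknown")

_ACGT = frozenset("ACGT")

# Tokens that mark a name as not a validly named species.
_UNNAMED_EPITHETS = {"sp", "sp.", "spp", "spp."}


def is_full_binomial(name: Optional[str]) -> bool:
    """True iff *name* is a full Latin binomial (genus plus species epithet).

    Placeholder epithets such as ``"sp."`` and labels containing
    ``"unclassified"`` do not count as named.
    """
    if not name:
        return False
    if "unclassified" in name.lower():
        return False
    tokens = name.split()
    if len(tokens) < 2:
        return False
    return tokens[1].lower() not in _UNNAMED_EPITHETS


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class ReferenceRecord:
    """One candidate/reference 16S sequence with curation metadata.

    Parameters
    ----------
    id:
        Accession string; unique within a record set.
    seq:
        Nucleotide sequence (IUPAC).  Uppercased on construction, RNA ``U``
        mapped to ``T``.
    name:
        Latin binomial if the organism is validly named, else ``None`` or a
        placeholder (``"Streptococcus sp."``).
    lineage:
        Ordered taxonomy labels, domain first, genus last.
    cultivated:
        Whether a cultivated isolate exists for this taxon.
    provenance:
        One of :data:`PROVENANCES`; ``oral_airway`` marks human oral-cavity or
        airway origin, which is favoured during representative selection.
    is_type_strain:
        Whether the sequence derives from the species type strain.
    """

    id: str
    seq: str
    name: Optional[str] = None
    lineage: tuple = ()
    cultivated: bool = False
    provenance: str = "unknown"
    is_type_strain: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.seq = _normalize_seq(self.seq)
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"record {self.id!r}: provenance {self.provenance!r} not in {PROVENANCES}"
            )
        self.lineage = tuple(self.lineage)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ambiguous_frac(self) -> float:
        """Fraction of non-ACGT bases in the sequence, in [0, 1]."""
        n = sum(1 for c in self.seq if c not in _ACGT)
        return n / len(self.seq)

    @property
    def named(self) -> bool:
        """True iff the record carries a full Latin binomial."""
        return is_full_binomial(self.name)

    @property
    def genus(self) -> Optional[str]:
        """Genus token of the name, or the last lineage label as fallback."""
        if self.name:
            return self.name.split()[0]
        return self.lineage[-1] if self.lineage else None

    def with_seq(self, seq: str) -> "ReferenceRecord":
        return replace(self, seq=seq)


@dataclass
class Read:
    """One amplicon read, with optional Phred qualities and provenance tags."""

    id: str
    seq: str
    qual: Optional[Sequence[int]] = None
    chimera: bool = False
    #: free-form provenance tags (e.g. source record id for simulated reads)
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = _normalize_seq(self.seq)
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_quality(self) -> Optional[float]:
        """Mean Phred quality over the read, or None for FASTA input."""
        if self.qual is None:
            return None
        return float(sum(self.qual)) / len(self.qual)


def filter_ambiguous(records, max_frac: float = 0.10):
    """Drop records with *max_frac* or more undetermined (non-ACGT) bases.

    The default removes sequences with >=10% ambiguous bases, the screen
    applied to candidate references before grouping.
    """
    return [r for r in records if r.ambiguous_frac < max_frac]
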