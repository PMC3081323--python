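"""Shannon-entropy variation map over a 16S multiple alignment.

Per alignment column, base frequencies are computed over A, C, G and T
only — gap characters and IUPAC ambiguity codes are excluded — and the
Shannon entropy H' = -sum p(x_i) log2 p(x_i) is reported in bits (0 for an
invariant column, 2 for a uniform one; natural log available via ``base``).
Sliding-window means locate conserved stretches suitable for primers and
hypervariable stretches suitable as informative amplicons.

Columns are 1-based alignment coordinates.  Because alignment gaps shift
positions relative to any one organism, an optional remapping onto an
ungapped reference row (e.g. an E. coli sequence included in the alignment)
is provided.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .io import Alignment

__all__ = ["VariationProfile", "column_entropy", "entropy_profile", "reference_positions"]

_BASES = "ACGT"


@dataclass
class VariationProfile:
    """Per-column entropies plus sliding-window means.

    ``entropies[j]`` is the entropy of 1-based column ``j+1``, or None where
    no A/C/G/T is present.  ``window_means`` holds one entry per full
    window: (1-based start column, window size, mean over defined columns,
    or None when the window has no defined column).
    """

    entropies: List[Optional[float]]
    window_means: List[Tuple[int, int, Optional[float]]]

    @property
    def n_cols(self) -> int:
        return len(self.entropies)


def column_entropy(column: str, base: float = 2.0) -> Optional[float]:
    """Shannon entropy of one alignment column.

    Counts A/C/G/T only; gaps and ambiguity codes are excluded from the
    base-composition probabilities rather than spread fractionally.  Returns
    None for a column with no countable base.
    """
    counts = Counter(c for c in column.upper() if c in _BASES)
    total = sum(counts.values())
    if total == 0:
        return None
    h = 0.0
    for n in counts.values():
        p = n / total
        h -= p * math.log(p, base)
    return h


def entropy_profile(
    alignment: Alignment, window_size: int = 1, base: float = 2.0
) -> VariationProfile:
    """Entropy per column plus means over sliding windows (step 1 bp).

    Windows cover *window_size* consecutive columns; the mean is taken over
    the defined (non-None) columns inside the window, and a window with no
    defined column is itself undefined.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if window_size > alignment.n_cols:
        raise ValueError(
            f"window_size {window_size} exceeds alignment width {alignment.n_cols}"
        )
    entropies = [
        column_entropy(alignment.column(j), base=base)
        for j in range(alignment.n_cols)
    ]
    window_means: List[Tuple[int, int, Optional[float]]] = []
    for start in range(alignment.n_cols - window_size + 1):
        vals = [e for e in entropies[start : start + window_size] if e is not None]
        mean = sum(vals) / len(vals) if vals else None
        window_means.append((start + 1, window_size, mean))
    return VariationProfile(entropies, window_means)


def reference_positions(alignment: Alignment, ref_id: str) -> List[Optional[int]]:
    """Map alignment columns to 1-based positions in an ungapped reference row.

    Entry ``j`` is the position of column ``j+1`` in the reference sequence,
    or None where the reference row has a gap.  This supports renumbering a
    variation profile into, e.g., E. coli coordinates.
    """
    row = alignment.row(ref_id)
    out: List[Optional[int]] = []
    pos = 0
    for c in row:
        if c == "-":
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out
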