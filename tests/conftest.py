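"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from refdb16s.identity import IdentityResult
from refdb16s.records import ReferenceRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate_exact(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly *n_subs* distinct positions (always to a new base)."""
    arr = list(seq)
    for pos in rng.choice(len(arr), size=n_subs, replace=False):
        choices = [b for b in BASES if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(3))]
    return "".join(arr)


def make_family(
    rng: np.random.Generator,
    n: int,
    length: int = 150,
    max_subs: int = 8,
    prefix: str = "R",
):
    """Records mutated from a common base by 0..max_subs substitutions."""
    base = random_seq(rng, length)
    out = []
    for i in range(n):
        k = int(rng.integers(0, max_subs + 1))
        out.append(
            ReferenceRecord(id=f"{prefix}{i:03d}", seq=mutate_exact(base, k, rng))
        )
    return out


def stub_identity(matrix):
    """Identity function backed by a {frozenset(id pair): pct} lookup.

    Self-pairs return 100.  Used to test clustering/grouping logic against
    constructed identity structures without any alignment.
    """

    def fn(a, b):
        ia = a.id if hasattr(a, "id") else a
        ib = b.id if hasattr(b, "id") else b
        if ia == ib:
            return IdentityResult(100.0, 100, 1.0)
        pct = matrix[frozenset((ia, ib))]
        return IdentityResult(pct, 100, 1.0)

    return fn


# ---------------------------------------------------------------------------
# Exhaustive overlap-alignment oracle (enumeration; tiny sequences only).
# Scoring: match +1, mismatch -2, gap -2, end gaps free; non-ACGT never
# matches.  Returns the optimal score and the set of (matches, columns)
# pairs realised by score-optimal alignments with at least one column.
# ---------------------------------------------------------------------------


def _enumerate_core(a: str, b: str):
    """All global alignments of a vs b as (score, matches, cols) triples."""
    results = []

    def walk(i, j, score, matches, cols):
        if i == len(a) and j == len(b):
            results.append((score, matches, cols))
            return
        if i < len(a) and j < len(b):
            is_match = a[i] == b[j] and a[i] in BASES
            walk(i + 1, j + 1, score + (1 if is_match else -2),
                 matches + (1 if is_match else 0), cols + 1)
        if i < len(a):
            walk(i + 1, j, score - 2, matches, cols + 1)
        if j < len(b):
            walk(i, j + 1, score - 2, matches, cols + 1)

    walk(0, 0, 0, 0, 0)
    return results


def oracle_overlap_alignment(a: str, b: str):
    """Brute-force overlap alignment by enumerating every trim + core path."""
    best_score = None
    outcomes = set()
    n, m = len(a), len(b)
    lead_trims = [(i, 0) for i in range(n + 1)] + [(0, j) for j in range(1, m + 1)]
    tail_trims = [(i, 0) for i in range(n + 1)] + [(0, j) for j in range(1, m + 1)]
    for (li, lj) in lead_trims:
        for (ti, tj) in tail_trims:
            if li + ti > n or lj + tj > m:
                continue
            core_a = a[li : n - ti]
            core_b = b[lj : m - tj]
            for score, matches, cols in _enumerate_core(core_a, core_b):
                if cols == 0:
                    continue
                if best_score is None or score > best_score:
                    best_score = score
                    outcomes = {(matches, cols)}
                elif score == best_score:
                    outcomes.add((matches, cols))
    return best_score, outcomes


def make_pair_with_identity(rng: np.random.Generator, length: int, n_subs: int):
    """A sequence pair whose overlap identity is exactly (length-n_subs)/length.

    Retries until the optimal alignment is the plain gap-free one (local
    repeats can otherwise let a paired indel beat substitutions).
    """
    from refdb16s.identity import pairwise_identity

    for _ in range(50):
        a = random_seq(rng, length)
        b = mutate_exact(a, n_subs, rng)
        res = pairwise_identity(a, b)
        if res.align_len == length:
            assert res.pct_identity == pytest.approx(
                100.0 * (length - n_subs) / length
            )
            return a, b
    raise AssertionError("could not construct a gap-free pair")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
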