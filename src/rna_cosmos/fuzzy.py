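"""Fuzzy counting: edit distances between k-mers and pseudo-count expansion.

Small structural changes shift every overlapping k-mer, so two nearly
identical structures can share few exact k-mers. Fuzzy counting softens
this by adding fractional pseudo-counts e^(-d) for k-mers within unit-cost
edit distance d (insertions, deletions, mismatches) of an observed k-mer,
by default for d <= 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .kmer_core import KmerCountVector

__all__ = [
    "NeighborTable",
    "kmer_edit_distance",
    "neighbor_table",
    "fuzzify",
    "DEFAULT_MAX_DIST",
]

#: Default edit-distance threshold for pseudo-counts.
DEFAULT_MAX_DIST = 2


@dataclass(frozen=True)
class NeighborTable:
    """Symmetric map (kmer, kmer) -> d for k-mer pairs with 1 <= d <= max_dist.

    Stored with each unordered pair under both orderings so lookups need
    no canonicalization; no self-entries.
    """

    k: int
    max_dist: int
    entries: dict[tuple[str, str], int]

    def neighbors(self, kmer: str) -> list[tuple[str, int]]:
        return [(b, d) for (a, b), d in self.entries.items() if a == kmer]


def kmer_edit_distance(a: str, b: str, max_dist: int | None = None) -> int:
    """Unit-cost Levenshtein distance by dynamic programming.

    With ``max_dist`` set, the DP abandons early once every entry of a row
    exceeds the threshold and returns ``max_dist + 1`` as a sentinel
    ("provably farther than max_dist").
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if max_dist is not None and abs(la - lb) > max_dist:
        return max_dist + 1
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (ca != b[j - 1]),  # match / mismatch
            )
        if max_dist is not None and min(cur) > max_dist:
            return max_dist + 1
        prev = cur
    return prev[lb]


def neighbor_table(
    vocabulary,
    max_dist: int = DEFAULT_MAX_DIST,
    *,
    _cache: dict | None = None,
) -> NeighborTable:
    """All unordered k-mer pairs within edit distance max_dist of each other.

    max_dist of 1 or 2 is the intended range; 3 is allowed with a warning
    because it connects too many k-mer pairs and blurs structural
    categories. An optional cache dict memoizes distances across calls
    (used by matrix runs where pair-union vocabularies overlap heavily).
    """
    vocab = list(dict.fromkeys(vocabulary))
    if not vocab:
        raise ValueError("empty vocabulary")
    if max_dist < 1:
        raise ValueError(f"max_dist must be >= 1, got {max_dist}")
    if max_dist > 2:
        warnings.warn(
            f"max_dist={max_dist} connects many k-mer pairs and blurs "
            "the distinction between structural categories",
            stacklevel=2,
        )
    k = len(vocab[0])
    entries: dict[tuple[str, str], int] = {}
    for i in range(len(vocab)):
        for j in range(i + 1, len(vocab)):
            a, b = vocab[i], vocab[j]
            key = (a, b) if a <= b else (b, a)
            if _cache is not None and key in _cache:
                d = _cache[key]
            else:
                d = kmer_edit_distance(a, b, max_dist=max_dist)
                if _cache is not None:
                    _cache[key] = d
            if 1 <= d <= max_dist:
                entries[(a, b)] = d
                entries[(b, a)] = d
    return NeighborTable(k=k, max_dist=max_dist, entries=entries)


def fuzzify(
    v: KmerCountVector, table: NeighborTable, scheme: str = "linear"
) -> KmerCountVector:
    """Add edit-distance-decayed pseudo-counts within the vector's vocabulary.

    ``linear`` (default): fuzzy[u] = sum_w counts[w] * e^(-d(u, w)) over
    vocabulary k-mers w with d <= max_dist (d(u, u) = 0, so original
    counts enter with weight 1). ``flat``: each k-mer with a positive
    count contributes a single e^(-d) pseudo-count to each neighbor,
    regardless of its count. Entries never decrease; the vocabulary and
    its order are preserved.
    """
    if scheme not in ("linear", "flat"):
        raise ValueError(f"unknown fuzzify scheme {scheme!r}")
    index = {w: i for i, w in enumerate(v.vocabulary)}
    fuzzy = v.counts.copy()
    weights = {d: math.exp(-d) for d in range(1, table.max_dist + 1)}
    for (a, b), d in table.entries.items():
        ia = index.get(a)
        ib = index.get(b)
        if ia is None or ib is None:
            continue
        if v.counts[ib] > 0:
            contribution = v.counts[ib] if scheme == "linear" else 1.0
            fuzzy[ia] += contribution * weights[d]
    return KmerCountVector(k=v.k, vocabulary=v.vocabulary, counts=fuzzy)
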