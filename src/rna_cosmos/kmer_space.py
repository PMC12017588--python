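"""The k-mer space: census of observed structural k-mers and the
edit-distance network over them.

Every structure maps to a subset of nodes in this network, where nodes are
observed unique k-mers and edges join pairs within a chosen edit distance.
Hub ranking and dominant-character node labels summarize which structural
elements dominate the space (in practice stem characters L and R).
"""

from __future__ import annotations

import warnings
from collections import Counter
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .fuzzy import kmer_edit_distance
from .kmer_core import extract_kmers
from .structure_io import StructureArray

__all__ = [
    "census",
    "possible_kmers",
    "build_network",
    "dominant_label",
    "top_hubs",
    "write_edges",
    "write_graphml",
]

#: Tie-break priority for dominant-character labels.
_LABEL_PRIORITY = "LRHMXIBE"


def census(arrays: Iterable[StructureArray], k: int) -> Counter:
    """Distinct k-mers with total occurrence counts across a dataset.

    Arrays shorter than k are skipped with a warning. The number of
    distinct k-mers observed is bounded by 8^k.
    """
    tally: Counter = Counter()
    for arr in arrays:
        if len(arr) < k:
            warnings.warn(
                f"skipping record {arr.name!r}: length {len(arr)} < k={k}",
                stacklevel=2,
            )
            continue
        tally.update(extract_kmers(arr, k))
    return tally


def possible_kmers(k: int, alphabet_size: int = 8) -> int:
    """Number of possible unique k-mers, A^k (A = 8 structural codes)."""
    return alphabet_size**k


def dominant_label(kmer: str) -> str:
    """The structural code with the highest occurrence in a k-mer.

    Ties are broken by the fixed priority L, R, H, M, X, I, B, E.
    """
    if not kmer:
        raise ValueError("empty k-mer")
    tally = Counter(kmer)
    return max(tally, key=lambda c: (tally[c], -_LABEL_PRIORITY.index(c)))


def _edges_dp(kmers: Sequence[str], max_dist: int) -> set[tuple[str, str, int]]:
    """Edge set via pairwise banded DP with early exit."""
    edges = set()
    for a, b in combinations(kmers, 2):
        d = kmer_edit_distance(a, b, max_dist=max_dist)
        if d <= max_dist:
            key = (a, b) if a <= b else (b, a)
            edges.add((key[0], key[1], d))
    return edges


def _deletion_variants(s: str, depth: int) -> set[str]:
    """All strings reachable from s by at most `depth` deletions."""
    out = {s}
    frontier = {s}
    for _ in range(depth):
        nxt = set()
        for t in frontier:
            for i in range(len(t)):
                nxt.add(t[:i] + t[i + 1 :])
        out |= nxt
        frontier = nxt
    return out


def _edges_join(kmers: Sequence[str], max_dist: int) -> set[tuple[str, str, int]]:
    """Edge set via deletion-neighborhood hash join, DP-verified.

    If lev(a, b) <= d then a and b share a string reachable by <= d
    deletions from each, so joining on deletion variants yields a complete
    candidate set; candidates are confirmed with the banded DP. Produces
    the identical edge set to the all-pairs DP.
    """
    buckets: dict[str, list[str]] = {}
    for kmer in kmers:
        for variant in _deletion_variants(kmer, max_dist):
            buckets.setdefault(variant, []).append(kmer)
    candidates: set[tuple[str, str]] = set()
    for members in buckets.values():
        if len(members) > 1:
            for a, b in combinations(sorted(set(members)), 2):
                candidates.add((a, b))
    edges = set()
    for a, b in candidates:
        d = kmer_edit_distance(a, b, max_dist=max_dist)
        if 1 <= d <= max_dist:
            edges.add((a, b, d))
    return edges


def build_network(
    kmers: Counter | dict | Iterable[str],
    max_dist: int = 2,
    *,
    strategy: str = "auto",
) -> nx.Graph:
    """Edit-distance network over unique k-mers.

    Nodes carry ``count`` (occurrences; 1 if a bare iterable was given),
    ``dominant_label`` and, once edges are added, ``degree``. Edges join
    unordered k-mer pairs with 1 <= d <= max_dist and carry ``d``.
    ``strategy`` selects the pairwise banded DP (``"dp"``), the
    deletion-neighborhood hash join (``"join"``), or size-based choice
    (``"auto"``); both produce identical edge sets.
    """
    if max_dist < 1:
        raise ValueError(f"max_dist must be >= 1, got {max_dist}")
    if isinstance(kmers, (Counter, dict)):
        counts = dict(kmers)
    else:
        counts = {k: 1 for k in kmers}
    nodes = sorted(counts)
    if strategy == "auto":
        strategy = "join" if len(nodes) > 2000 else "dp"
    if strategy == "dp":
        edges = _edges_dp(nodes, max_dist)
    elif strategy == "join":
        edges = _edges_join(nodes, max_dist)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    g = nx.Graph(max_dist=max_dist)
    for kmer in nodes:
        g.add_node(kmer, count=counts[kmer], dominant_label=dominant_label(kmer))
    for a, b, d in edges:
        g.add_edge(a, b, d=d)
    for kmer in g.nodes:
        g.nodes[kmer]["degree"] = g.degree[kmer]
    return g


def top_hubs(network: nx.Graph, n: int) -> list[str]:
    """The n k-mers with the most edges, ties broken lexicographically."""
    if n <= 0:
        return []
    ranked = sorted(network.nodes, key=lambda kmer: (-network.degree[kmer], kmer))
    return ranked[:n]


def write_edges(network: nx.Graph, path) -> None:
    """TSV edge list: kmer_a, kmer_b, d."""
    with open(path, "w") as fh:
        fh.write("kmer_a\tkmer_b\td\n")
        for a, b, data in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['d']}\n")


def write_graphml(network: nx.Graph, path) -> None:
    """GraphML with node attributes (count, dominant_label, degree)."""
    nx.write_graphml(network, path)
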