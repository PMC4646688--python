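"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by a different route than the
implementation under test: plain memoized recursion for alignment
scores, exhaustive enumeration for tree topologies and locus scans, and
dendropy's own bipartition encoding for splits.  They are deliberately
slow and simple.
"""

from __future__ import annotations

import collections
import itertools
from functools import lru_cache

import dendropy
import numpy as np

NEG = float("-inf")


def gotoh_score(q: str, r: str, sub: dict, gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score by memoized three-state recursion."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        if state == "M":
            if i == 0 or j == 0:
                return NEG
            prev = max(best(i - 1, j - 1, s) for s in "MUL")
            return prev + sub[(q[i - 1], r[j - 1])] if prev > NEG else NEG
        if state == "U":  # gap in reference
            if i == 0:
                return NEG
            return max(
                best(i - 1, j, "M") + gap_open,
                best(i - 1, j, "U") + gap_extend,
                best(i - 1, j, "L") + gap_open,
            )
        if j == 0:
            return NEG
        return max(
            best(i, j - 1, "M") + gap_open,
            best(i, j - 1, "U") + gap_open,
            best(i, j - 1, "L") + gap_extend,
        )

    score = max(best(len(q), len(r), s) for s in "MUL")
    best.cache_clear()
    return score


# ---------------------------------------------------------------------------
# Exhaustive unrooted-topology search


def enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal nodes are numbered from ``n`` upward so they never collide
    with leaf ids.
    """
    trees: list[tuple[list[tuple[int, int]], int]] = [([(0, n), (1, n), (2, n)], n + 1)]
    for leaf in range(3, n):
        nxt_trees = []
        for edges, nxt in trees:
            for i, (a, b) in enumerate(edges):
                e2 = edges[:i] + edges[i + 1 :] + [(a, nxt), (b, nxt), (leaf, nxt)]
                nxt_trees.append((e2, nxt + 1))
        trees = nxt_trees
    return [e for e, _ in trees]


def _path_matrix(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (u, v) in enumerate(pairs):
        prev: dict[int, tuple[int, int] | None] = {u: None}
        dq = collections.deque([u])
        while dq:
            x = dq.popleft()
            if x == v:
                break
            for y, eidx in adj[x]:
                if y not in prev:
                    prev[y] = (x, eidx)
                    dq.append(y)
        x = v
        while prev[x] is not None:
            p, eidx = prev[x]  # type: ignore[misc]
            A[row, eidx] = 1
            x = p
    return A


def topology_splits(edges: list[tuple[int, int]], n: int) -> frozenset[frozenset[int]]:
    """Non-trivial splits of a topology (side not containing leaf 0)."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    splits = set()
    for a, b in edges:
        # leaves on b's side when edge (a,b) is cut
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return frozenset(splits)


@lru_cache(maxsize=8)
def _topology_cache(n: int):
    tops = enumerate_topologies(n)
    A = np.array([_path_matrix(e, n) for e in tops])
    pinv = np.array([np.linalg.pinv(a) for a in A])
    splits = [topology_splits(e, n) for e in tops]
    return A, pinv, splits


def exhaustive_best_topology(d: np.ndarray) -> frozenset[frozenset[int]]:
    """Splits of the least-squares-best topology for a distance matrix.

    Scores every unrooted binary topology by the residual of its
    least-squares branch-length fit and returns the winner's splits.
    """
    n = d.shape[0]
    A, pinv, splits = _topology_cache(n)
    vec = np.array([d[i, j] for i, j in itertools.combinations(range(n), 2)])
    b = np.einsum("tij,j->ti", pinv, vec)
    resid = ((np.einsum("tij,tj->ti", A, b) - vec) ** 2).sum(axis=1)
    return splits[int(np.argmin(resid))]


def tree_distance_matrix(edges: list[tuple[int, int]], lengths: np.ndarray, n: int) -> np.ndarray:
    """Additive pairwise distances induced by a topology + branch lengths."""
    A = _path_matrix(edges, n)
    vec = A @ lengths
    d = np.zeros((n, n))
    for (i, j), v in zip(itertools.combinations(range(n), 2), vec):
        d[i, j] = d[j, i] = v
    return d


# ---------------------------------------------------------------------------
# Splits via dendropy (independent of gasp.phylogeny.bipartitions)


def dendropy_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits using dendropy's bipartition encoding."""
    tree.encode_bipartitions()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    anchor = taxa[0]
    n = len(taxa)
    out = set()
    for bp in tree.bipartition_encoding:
        mask = bp.leafset_bitmask
        side = {
            t.label
            for t in tree.taxon_namespace
            if mask & tree.taxon_namespace.taxon_bitmask(t)
        }
        if anchor in side:
            side = set(taxa) - side
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return out


# ---------------------------------------------------------------------------
# Brute-force locus scan


def brute_force_locus(genes, definition):
    """Innermost left/right marker scan by exhaustive pair enumeration.

    Returns a dict contig -> gene_id list of the innermost candidate
    (smallest index gap over all matched left/right marker pairs on
    that contig, earliest on ties); contigs with markers on one side
    only are omitted.
    """
    by_contig: dict[str, list] = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.start, g.end, g.gene_id)):
        by_contig.setdefault(g.contig, []).append(g)
    out: dict[str, list[str]] = {}
    for contig, cg in sorted(by_contig.items()):
        lefts = [i for i, g in enumerate(cg) if definition.side_of(g.gene_id) == "left"]
        rights = [i for i, g in enumerate(cg) if definition.side_of(g.gene_id) == "right"]
        best = None
        for l in lefts:
            for r in rights:
                if l == r:
                    continue
                lo, hi = min(l, r), max(l, r)
                key = (hi - lo, lo)
                if best is None or key < best[0]:
                    best = (key, [g.gene_id for g in cg[lo : hi + 1]])
        if best is not None:
            out[contig] = best[1]
    return out
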