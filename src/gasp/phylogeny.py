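"""Distance-based phylogenetics: p/Poisson distances, neighbor joining,
bootstrap support and majority-rule consensus.

This re-creates the classic PHYLIP-style distance arm of a protein
phylogeny: pairwise distances from an alignment, a neighbor-joining
tree, column-resampled bootstrap replicates (100 by default) and a
majority-rule consensus.  Two distance corrections are shipped:

* ``p-distance`` — mismatches / comparable columns (both residues
  non-gap and non-X);
* ``poisson``    — ``-ln(1 - p)``, correcting for multiple hits under a
  rate-homogeneous model.

Distances are non-negative and symmetric; the triangle inequality is
*not* guaranteed after Poisson correction.  Saturated pairs
(p >= 0.95 by default) are capped at the correction of the cap with a
warning.  All tie-breaks are lowest-index and the bootstrap uses one
seeded generator with per-replicate substreams, so runs are
bit-reproducible.  Negative NJ branch lengths are clamped to zero
(PHYLIP-compatible behaviour).

Trees are :class:`dendropy.Tree` objects; Newick I/O round-trips
topology, branch lengths, labels and integer support values (written
as internal-node labels).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from gasp.errors import InputError, NewickParseError, UndefinedDistanceError

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}
DEFAULT_SATURATION_CAP = 0.95
DEFAULT_REPLICATES = 100  # standard bootstrap protocol


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise InputError(f"matrix shape {v.shape} does not match {n} taxa")
        if not np.all(np.isfinite(v)):
            raise InputError("distances must be finite")
        if np.any(v < 0):
            raise InputError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise InputError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise InputError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


def protein_distance(
    a: str,
    b: str,
    model: str = "poisson",
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> float:
    """Pairwise distance between two aligned protein sequences.

    Columns where either sequence has a gap or X are excluded.  Raises
    :class:`UndefinedDistanceError` when no column is comparable.
    """
    if len(a) != len(b):
        raise InputError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    if model not in {"p-distance", "poisson"}:
        raise InputError(f"unknown distance model {model!r}")
    comparable = mismatches = 0
    for ca, cb in zip(a, b):
        if ca in GAP_CHARS or cb in GAP_CHARS or ca == "X" or cb == "X":
            continue
        comparable += 1
        if ca != cb:
            mismatches += 1
    if comparable == 0:
        raise UndefinedDistanceError("no comparable columns between sequences")
    p = mismatches / comparable
    if model == "p-distance":
        return p
    if p >= saturation_cap:
        warnings.warn(
            f"p-distance {p:.3f} at/above saturation cap {saturation_cap}; distance capped",
            stacklevel=2,
        )
        p = saturation_cap
    return -math.log(1.0 - p)


def distance_matrix(
    names: Sequence[str],
    sequences: Sequence[str],
    model: str = "poisson",
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> DistanceMatrix:
    """All pairwise distances of an alignment."""
    n = len(names)
    if n != len(sequences):
        raise InputError("names and sequences differ in length")
    if len(set(names)) != n:
        raise InputError("taxon names must be unique")
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = protein_distance(sequences[i], sequences[j], model, saturation_cap)
            v[i, j] = v[j, i] = d
    return DistanceMatrix(taxa=tuple(names), values=v)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining (Saitou–Nei with the Q criterion).

    Iteratively joins the pair minimising
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; ties resolve to the lowest
    index pair.  Branch lengths follow the NJ formulas, clamped at zero
    with a warning when negative.  On an additive matrix the result is
    the unique generating topology with exact branch lengths.  Requires
    at least 3 taxa; the returned tree is unrooted (trifurcating seed
    node).
    """
    n = len(m.taxa)
    if n < 3:
        raise InputError(f"neighbor joining needs >= 3 taxa, got {n}")

    tns = dendropy.TaxonNamespace([str(t) for t in m.taxa])
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for t in m.taxa:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(str(t))
        nodes.append(node)
    d = m.values.copy()

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0", stacklevel=3)
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: first minimum in row-major order
        flat = int(np.argmin(q))
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = clamp(li)
        cj.edge.length = clamp(lj)
        # distances from the new node
        dn = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        new_d = np.zeros((k - 1, k - 1))
        new_d[: k - 2, : k - 2] = d[np.ix_(keep, keep)]
        new_d[-1, : k - 2] = dn[keep]
        new_d[: k - 2, -1] = dn[keep]
        d = new_d
        nodes = [nodes[x] for x in keep] + [parent]

    # final three-point join
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    seed = tree.seed_node
    for node, length in ((a, la), (b, lb), (c, lc)):
        seed.add_child(node)
        node.edge.length = clamp(length)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, consensus, bootstrap


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the side *not*
    containing the lexicographically smallest leaf label is the
    canonical representative.  Trivial splits (single leaf / all-but-
    one) are excluded.
    """
    labels = _leaf_labels(tree)
    anchor = min(labels)
    n = len(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if anchor in side:
            side = labels - side
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return out


def majority_consensus(
    trees: Sequence[dendropy.Tree],
    threshold: float = 0.5,
) -> dendropy.Tree:
    """Majority-rule consensus: bipartitions with frequency > threshold.

    ``threshold`` must be >= 0.5 (guaranteeing pairwise compatibility);
    no greedy completion with minority bipartitions is performed.
    Internal nodes carry the bipartition frequency (percent, rounded to
    int) as label and ``support`` attribute.  All trees must share one
    leaf set.
    """
    if not trees:
        raise InputError("no trees given")
    if not 0.5 <= threshold < 1.0:
        raise InputError(f"threshold must be in [0.5, 1), got {threshold}")
    leafsets = [_leaf_labels(t) for t in trees]
    if any(ls != leafsets[0] for ls in leafsets[1:]):
        raise InputError("trees have mismatched leaf sets")
    labels = leafsets[0]

    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    total = len(trees)
    majority = {
        bp: cnt / total for bp, cnt in counts.items() if cnt / total > threshold
    }

    # Build the consensus rooted at the anchor side: each canonical
    # bipartition is a clade of the remaining leaves; >50% majorities
    # form a laminar family.
    tns = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    leaf_nodes: dict[str, dendropy.Node] = {}
    for lab in sorted(labels):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        root.add_child(node)
        leaf_nodes[lab] = node

    def clade_leafset(node: dendropy.Node) -> set[str]:
        return {l.taxon.label for l in node.leaf_iter()}

    for clade, freq in sorted(majority.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
        # find the shallowest node whose leaf set contains the clade
        host = root
        descended = True
        while descended:
            descended = False
            for child in host.child_nodes():
                if not child.is_leaf() and clade <= clade_leafset(child):
                    host = child
                    descended = True
                    break
        group = [c for c in host.child_nodes() if clade_leafset(c) <= clade]
        if not group or set().union(*(clade_leafset(c) for c in group)) != set(clade):
            continue  # incompatible with already-placed clades (threshold >= 0.5 prevents this)
        new = dendropy.Node()
        support = round(100.0 * freq)
        new.label = str(support)
        new.support = support
        for c in group:
            host.remove_child(c)
            new.add_child(c)
        host.add_child(new)
    tree.is_rooted = False
    return tree


def bootstrap_support(
    names: Sequence[str],
    sequences: Sequence[str],
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    model: str = "poisson",
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> dendropy.Tree:
    """NJ tree with bootstrap support on its internal edges.

    Alignment columns are resampled with replacement ``replicates``
    times (replicate i draws from substream i of one seeded generator);
    each replicate is rebuilt with the same distance model and NJ, and
    each internal edge of the full-data tree is annotated with the
    percentage of replicates containing its bipartition (node label and
    ``support`` attribute, integer percent).
    """
    if replicates < 1:
        raise InputError(f"replicates must be >= 1, got {replicates}")
    if len(names) < 3:
        raise InputError("need >= 3 sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise InputError("sequences must be aligned to equal length")

    full = neighbor_joining(distance_matrix(names, sequences, model, saturation_cap))
    target = bipartitions(full)
    counts = {bp: 0 for bp in target}
    streams = np.random.SeedSequence(seed).spawn(replicates)
    for rep in range(replicates):
        rng = np.random.default_rng(streams[rep])
        cols = rng.integers(0, L, size=L)
        resampled = ["".join(s[c] for c in cols) for s in sequences]
        try:
            rep_tree = neighbor_joining(
                distance_matrix(names, resampled, model, saturation_cap)
            )
        except UndefinedDistanceError:
            logger.warning("replicate %d skipped: undefined distance", rep)
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1

    anchor = min(_leaf_labels(full))
    labels = _leaf_labels(full)
    for node in full.preorder_node_iter():
        if node is full.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if anchor in side:
            side = labels - side
        bp = frozenset(side)
        if bp in counts:
            support = round(100.0 * counts[bp] / replicates)
            node.label = str(support)
            node.support = support
    return full


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a string or file path.

    Internal-node labels that parse as numbers are exposed as
    ``node.support``.  Malformed input raises
    :class:`NewickParseError` carrying the parser's position message.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = int(round(float(node.label)))
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick (supports as internal-node labels)."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s
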