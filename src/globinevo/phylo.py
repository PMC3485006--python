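"""Guide-tree machinery: protein p-distances, neighbor joining, bootstrap.

This is deliberately minimal backbone inference — the pipeline only needs a
reasonable guide tree, and a user-supplied newick tree is always accepted
everywhere a tree is an input. Distances are uncorrected p-distances;
NJ is the standard Saitou–Nei agglomeration with deterministic tie-breaking
(lowest (i, j) index pair in the Q matrix); bootstrap support is the fraction
of column-resampled replicates whose tree contains the same leaf bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import dendropy
import numpy as np

logger = logging.getLogger("globinevo")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be >= 0")


def pdistance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """p-distances: mismatches / columns where both sequences are non-gap."""
    taxa = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(alignment[t]) for t in taxa])
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != "-") & (arr[j] != "-")
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            d[i, j] = d[j, i] = (arr[i][both] != arr[j][both]).mean()
    return DistanceMatrix(taxa, d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; negative branch estimates clamped to 0.

    The returned tree is unrooted (serialized with a trifurcating root).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    ns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes.append(node)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j) pair in active-index order
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best] - 1e-12:
                    best = (i, j)
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = clamp(li)
        nodes[aj].edge.length = clamp(lj)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (ai, aj):
                continue
            d[-1, k] = d[k, -1] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (ai, aj)] + [d.shape[0] - 1]

    # join the last three around a trifurcating root
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = dendropy.Node()
    for idx, ln in ((a, 0.5 * (dab + dac - dbc)),
                    (b, 0.5 * (dab + dbc - dac)),
                    (c, 0.5 * (dac + dbc - dab))):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(ln)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class SupportedTree:
    tree: dendropy.Tree
    support: dict[frozenset, float] = field(default_factory=dict)

    def newick_with_support(self) -> str:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node is self.tree.seed_node:
                continue
            key = _bipart_key(
                {lf.taxon.label for lf in node.leaf_iter()},
                {lf.taxon.label for lf in self.tree.leaf_node_iter()},
            )
            if key in self.support:
                node.label = str(int(round(self.support[key])))
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def _bipart_key(side: set[str], all_taxa: set[str]) -> frozenset:
    """Canonical bipartition key, independent of rotation: the side not
    containing the lexicographically smallest taxon."""
    anchor = min(all_taxa)
    return frozenset(side if anchor not in side else all_taxa - side)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    all_taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if 1 < len(side) < len(all_taxa) - 1:
            out.add(_bipart_key(side, all_taxa))
    return out


def bootstrap_support(
    alignment: dict[str, str],
    tree_builder: Callable[[dict[str, str]], dendropy.Tree],
    replicates: int = 1000,
    seed: int = 0,
) -> SupportedTree:
    """Nonparametric bootstrap over alignment columns.

    Columns are resampled with replacement to the original length; the
    builder is applied per replicate and support for each internal edge of
    the builder's tree on the original alignment is the percentage of
    replicate trees containing the same leaf bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned")
    ncols = lengths.pop()
    if ncols < 2:
        raise ValueError("alignment must have >= 2 columns")
    rng = np.random.default_rng(seed)
    taxa = list(alignment)
    arr = np.array([list(alignment[t]) for t in taxa])
    reference = tree_builder(alignment)
    ref_biparts = tree_bipartitions(reference)
    counts = {bp: 0 for bp in ref_biparts}
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = {t: "".join(arr[i, cols]) for i, t in enumerate(taxa)}
        rep_biparts = tree_bipartitions(tree_builder(rep))
        for bp in ref_biparts:
            if bp in rep_biparts:
                counts[bp] += 1
    support = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    return SupportedTree(reference, support)
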