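"""Neighbor-joining phenograms with Newick serialization.

Canonical agglomerative neighbor joining (Saitou & Nei): at each step the
pair minimizing Q(i,j) = (m-2) d(i,j) - r(i) - r(j) is joined, branch lengths
follow the standard formulas, and distances to the new node are
d(u,m) = (d(i,m) + d(j,m) - d(i,j)) / 2.  On an additive distance matrix the
path-length metric of the output tree reproduces the input exactly.  Ties in
Q are broken by the lexicographically smallest pair of cluster keys (the
smallest tip label in each cluster), so the result is deterministic.
Negative branch lengths are clamped to zero with the deficit moved to the
sibling branch (configurable off), the usual convention for phenograms.

Trees are held as dendropy Trees (flagged unrooted; the serialization root is
the last join) with a deterministic 6-decimal Newick writer so that
write -> read -> write is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .ordination import DistanceMatrix

__all__ = ["PhenogramTree", "neighbor_joining", "write_newick", "read_newick"]

_NEEDS_QUOTE = set("()[]{}:;,='\" \t\n")


def _format_label(label: str) -> str:
    if label and not (_NEEDS_QUOTE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


@dataclass
class PhenogramTree:
    """Unrooted similarity tree with branch lengths and tip labels."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        """Deterministic Newick text, branch lengths at 6 decimals.

        Iterative traversal: neighbor-joining trees of ontogenetic series are
        deeply unbalanced and would overflow the recursion limit.
        """
        rendered: dict[int, str] = {}
        stack: list[tuple[dendropy.Node, bool]] = [(self.tree.seed_node, False)]
        while stack:
            node, expanded = stack.pop()
            children = node.child_nodes()
            if children and not expanded:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(children))
                continue
            if children:
                body = "(" + ",".join(rendered.pop(id(c)) for c in children) + ")"
            else:
                body = _format_label(node.taxon.label if node.taxon else "")
            if node.edge.length is not None:
                body += ":%.6f" % node.edge.length
            rendered[id(node)] = body
        return rendered[id(self.tree.seed_node)] + ";\n"

    def patristic_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Path-length (patristic) distances between tips, in `order`."""
        labels = order if order is not None else self.tip_labels
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return D

    def _edge_splits(self) -> dict[frozenset, float]:
        """Nontrivial unrooted splits with total edge length.

        Each split is keyed by the tip set on the side NOT containing the
        lexicographically smallest tip.  The two child edges of a degree-2
        serialization root describe the same unrooted edge and their lengths
        are summed.
        """
        all_tips = frozenset(self.tip_labels)
        anchor = min(all_tips)
        splits: dict[frozenset, float] = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.edge.length is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(below) < 2 or len(all_tips - below) < 2:
                continue
            key = below if anchor not in below else all_tips - below
            splits[key] = splits.get(key, 0.0) + node.edge.length
        return splits

    def splits(self) -> set[frozenset]:
        """The set of nontrivial unrooted bipartitions (canonical sides)."""
        return set(self._edge_splits())

    def deepest_split(self) -> tuple[frozenset, frozenset]:
        """The bipartition across the longest internal edge."""
        splits = self._edge_splits()
        if not splits:
            raise ValueError("tree has no internal edges")
        side = max(splits, key=lambda s: (splits[s], sorted(s)))
        return side, frozenset(self.tip_labels) - side


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = True) -> PhenogramTree:
    """Build a neighbor-joining tree from a distance matrix."""
    n0 = D.n
    if n0 < 2:
        raise ValueError("neighbor joining needs at least 2 tips")
    if len(set(D.labels)) != n0:
        raise ValueError("tip labels must be unique")
    d = D.values.astype(float).copy()

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    keys: list[str] = list(D.labels)
    for label in D.labels:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label)
        nodes.append(node)
    active = list(range(n0))

    def attach(parent: dendropy.Node, child_idx: int, length: float) -> None:
        parent.add_child(nodes[child_idx])
        nodes[child_idx].edge.length = length

    while len(active) > 2:
        m = len(active)
        dm = d[np.ix_(active, active)]
        r = dm.sum(axis=1)
        Q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = float(Q.min())
        tol = 1e-12 * max(1.0, abs(qmin))
        best = None
        for a, b in np.argwhere(Q <= qmin + tol):
            if a >= b:
                continue
            pair_key = tuple(sorted((keys[active[a]], keys[active[b]])))
            if best is None or pair_key < best[0]:
                best = (pair_key, (int(a), int(b)))
        a, b = best[1]
        i, j = active[a], active[b]
        dij = dm[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        if clamp_negative:
            if li < 0.0:
                lj, li = lj + li, 0.0
            elif lj < 0.0:
                li, lj = li + lj, 0.0
        parent = dendropy.Node()
        attach(parent, i, li)
        attach(parent, j, lj)
        others = [x for x in active if x not in (i, j)]
        d[i, others] = d[others, i] = 0.5 * (d[i, others] + d[j, others] - dij)
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    u, v = active
    duv = d[u, v]
    root = dendropy.Node()
    attach(root, u, duv / 2.0)
    attach(root, v, duv / 2.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhenogramTree(tree=tree)


def write_newick(tree: PhenogramTree) -> str:
    """Newick text for the tree (deterministic; see PhenogramTree.newick)."""
    return tree.newick()


def read_newick(text: str) -> PhenogramTree:
    """Parse Newick text into a PhenogramTree (flagged unrooted)."""
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True, suppress_internal_node_taxa=True
    )
    tree.is_rooted = False
    return PhenogramTree(tree=tree)
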