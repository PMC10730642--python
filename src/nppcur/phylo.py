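"""Distance trees, Robinson-Foulds comparison and clade associations.

The analysis contrasts trees built from the same sequences aligned under
two parameter regimes.  Tree inference here is neighbor joining on
p-distances (a deterministic stand-in adequate for contrasting regimes);
the Robinson-Foulds (RF) distance is the size of the symmetric
difference of the two trees' nontrivial bipartition (split) sets, with a
normalized variant RF / (|S1| + |S2|).  RF is computed on unrooted
topologies: a rooted input is handled by the canonical split
representation, which makes the two child edges of a degree-2 root
contribute a single split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import dendropy
import numpy as np


class PhyloNode:
    """A tree node: leaves carry a label, internal nodes carry children."""

    __slots__ = ("label", "children", "length")

    def __init__(self, label=None, children=None, length=None):
        self.label = label
        self.children = list(children) if children else []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "PhyloNode":
        return PhyloNode(
            self.label, [c.copy() for c in self.children], self.length
        )


@dataclass
class PhyloTree:
    """Leaf-labeled tree with a split-set view for RF computation."""

    root: PhyloNode

    def leaf_labels(self) -> list:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node.label)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def to_newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                lab = str(node.label)
                if any(ch in lab for ch in " \t(),:;'"):
                    lab = "'" + lab.replace("'", "''") + "'"
                body = lab
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None:
                body += f":{node.length:g}"
            return body

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )

        def convert(dnode):
            if dnode.is_leaf():
                return PhyloNode(
                    label=dnode.taxon.label if dnode.taxon else dnode.label,
                    length=dnode.edge.length,
                )
            return PhyloNode(
                children=[convert(c) for c in dnode.child_nodes()],
                length=dnode.edge.length,
            )

        return cls(convert(dtree.seed_node))


def splits(tree: PhyloTree) -> frozenset:
    """Canonical nontrivial bipartitions, one per internal edge.

    Each split is represented by its canonical side: the smaller leaf
    set, with a lexicographic tie-break at equal sizes.  Duplicate leaf
    labels are an error.
    """
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    full = frozenset(labels)
    n = len(full)
    out = set()

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 2 <= len(below) <= n - 2:
            out.add(_canonical(below, full))
        return below

    walk(tree.root)
    return frozenset(out)


def _canonical(side: frozenset, full: frozenset) -> frozenset:
    other = full - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(map(str, s))))


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """RF distance: |S1 symmetric-difference S2| over canonical splits."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return len(splits(t1) ^ splits(t2))


def normalized_rf(t1: PhyloTree, t2: PhyloTree) -> float:
    """RF scaled by the total split count; 0 when both trees are stars."""
    s1, s2 = splits(t1), splits(t2)
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    denom = len(s1) + len(s2)
    return len(s1 ^ s2) / denom if denom else 0.0


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist, labels: Sequence[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric zero-diagonal matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels (a cluster is keyed by its smallest leaf
    label), which makes the output deterministic.
    """
    D = np.asarray(dist, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")

    nodes = [PhyloNode(label=l) for l in labels]
    keys = [str(l) for l in labels]  # smallest leaf label per cluster
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        m = len(active)
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        vi = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i][j] - vi
        nodes[i].length, nodes[j].length = vi, vj
        new = PhyloNode(children=[nodes[i], nodes[j]])
        new_idx = len(nodes)
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d = 0.5 * (D[i][k] + D[j][k] - D[i][j])
            D[new_idx][k] = D[k][new_idx] = d
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    nodes[i].length = 0.5 * (D[i][j] + D[i][k] - D[j][k])
    nodes[j].length = 0.5 * (D[i][j] + D[j][k] - D[i][k])
    nodes[k].length = 0.5 * (D[i][k] + D[j][k] - D[i][j])
    order = sorted((i, j, k), key=lambda x: keys[x])
    return PhyloTree(PhyloNode(children=[nodes[x] for x in order]))


def p_distance_matrix(alignment) -> tuple[np.ndarray, list]:
    """Pairwise p-distances (mismatch fraction over gap-free column pairs)."""
    ids, rows = alignment.ids, alignment.rows
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = valid = 0
            for x, y in zip(rows[i], rows[j]):
                if x == "-" or y == "-":
                    continue
                valid += 1
                diff += x != y
            D[i][j] = D[j][i] = diff / valid if valid else 1.0
    return D, list(ids)


# ---------------------------------------------------------------------------
# clade associations


def clade_association_counts(
    tree: PhyloTree, family_labels: Dict[str, str], reference_family: str
) -> dict:
    """Per-family counts of leaves associated with a reference family.

    A leaf is associated when its sibling subtree -- the union of the
    other children attached at its parent -- contains at least one
    reference-family leaf.  Returns ``{family: (associated, total)}`` for
    every non-reference family.
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in family_labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {sorted(missing)}")

    parent: dict = {}

    def walk(node):
        for c in node.children:
            parent[id(c)] = node
            walk(c)

    walk(tree.root)

    def leafset(node):
        if node.is_leaf:
            return [node.label]
        out = []
        for c in node.children:
            out.extend(leafset(c))
        return out

    counts: dict = {}
    ref_leaves = {l for l in leaves if family_labels[l] == reference_family}

    def visit(node):
        if node.is_leaf:
            fam = family_labels[node.label]
            if fam != reference_family:
                assoc, total = counts.get(fam, (0, 0))
                p = parent.get(id(node))
                hit = False
                if p is not None:
                    sibling_leaves = [
                        l
                        for c in p.children
                        if c is not node
                        for l in leafset(c)
                    ]
                    hit = any(l in ref_leaves for l in sibling_leaves)
                counts[fam] = (assoc + int(hit), total + 1)
        for c in node.children:
            visit(c)

    visit(tree.root)
    return counts
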