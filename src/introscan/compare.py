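"""Structural comparison: tree edit distance and UPGMA clustering.

A dot-bracket structure maps losslessly to an ordered rooted tree — each
base pair an internal node (label ``P``), each unpaired base a leaf
(label ``U``), all hanging from a virtual root (``R``).  Structural
distance is the minimum-cost tree edit distance (Zhang–Shasha), by
default with unit insert/delete/relabel costs; a ``vienna`` cost scheme
(unpaired indel 1, pair indel 2, no cheap relabel) reproduces the
defaults of the classic full-structure comparison program and is used
for cross-checks against it.

UPGMA (arithmetic-average agglomeration) turns the pairwise distance
matrix into an ultrametric tree; equal-distance merges break toward the
lexicographically smallest cluster labels so the tree is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StructureTree",
    "DistanceMatrix",
    "ClusterTree",
    "tree_edit_distance",
    "pairwise_matrix",
    "upgma",
]


# ---------------------------------------------------------------------------
# structure trees

@dataclass(frozen=True)
class StructureTree:
    """Ordered rooted tree form of a dot-bracket string (full representation)."""

    label: str  # "R" (root), "P" (pair), "U" (unpaired)
    children: tuple["StructureTree", ...] = ()

    @staticmethod
    def from_dot_bracket(db: str) -> "StructureTree":
        stack: list[list] = [["R", []]]
        for i, c in enumerate(db):
            if c == "(":
                stack.append(["P", []])
            elif c == ")":
                if len(stack) < 2:
                    raise ValueError(f"unbalanced dot-bracket at position {i}")
                label, kids = stack.pop()
                stack[-1][1].append(StructureTree(label, tuple(kids)))
            elif c == ".":
                stack[-1][1].append(StructureTree("U"))
            else:
                raise ValueError(f"illegal character {c!r} at position {i}")
        if len(stack) != 1:
            raise ValueError("unbalanced dot-bracket: unclosed '('")
        label, kids = stack[0]
        return StructureTree(label, tuple(kids))

    def to_dot_bracket(self) -> str:
        out: list[str] = []

        def walk(node: "StructureTree"):
            if node.label == "U":
                out.append(".")
            elif node.label == "P":
                out.append("(")
                for ch in node.children:
                    walk(ch)
                out.append(")")
            else:
                for ch in node.children:
                    walk(ch)

        walk(self)
        return "".join(out)

    def size(self) -> int:
        return 1 + sum(ch.size() for ch in self.children)


_COSTS = {
    # indel cost per label, relabel cost for differing labels
    "unit": ({"U": 1, "P": 1, "R": 1}, 1),
    "vienna": ({"U": 1, "P": 2, "R": 1}, 1),
}


def _cost_fns(scheme: str):
    try:
        indel, relabel = _COSTS[scheme]
    except KeyError:
        raise ValueError(f"unknown cost scheme {scheme!r}") from None

    def cdel(label: str) -> int:
        return indel[label]

    def crel(a: str, b: str) -> int:
        if a == b:
            return 0
        if relabel is None:
            return indel[a] + indel[b]
        return relabel

    return cdel, crel


def tree_edit_distance(a: str, b: str, scheme: str = "unit") -> float:
    """Minimum-cost edit distance between two dot-bracket structures.

    Zhang–Shasha ordered tree edit distance on the full structure trees.
    Symmetric; zero iff the trees are identical.
    """
    ta = StructureTree.from_dot_bracket(a)
    tb = StructureTree.from_dot_bracket(b)
    cdel, crel = _cost_fns(scheme)
    return _zhang_shasha(ta, tb, cdel, crel)


def _postorder(root: StructureTree):
    """Postorder labels, leftmost-leaf indices, and keyroots (Zhang–Shasha)."""
    labels: list[str] = []
    lml: list[int] = []

    def walk(node: StructureTree) -> int:
        first_leaf = None
        for ch in node.children:
            idx = walk(ch)
            if first_leaf is None:
                first_leaf = lml[idx]
        me = len(labels)
        labels.append(node.label)
        lml.append(me if first_leaf is None else first_leaf)
        return me

    walk(root)
    n = len(labels)
    keyroots = [i for i in range(n) if i == n - 1 or all(
        lml[j] != lml[i] for j in range(i + 1, n)
    )]
    return labels, lml, keyroots


def _zhang_shasha(ta, tb, cdel, crel) -> float:
    la, lmla, kra = _postorder(ta)
    lb, lmlb, krb = _postorder(tb)
    na, nb = len(la), len(lb)
    td = np.zeros((na, nb))

    for i in kra:
        for j in krb:
            ioff, joff = lmla[i], lmlb[j]
            m, n = i - ioff + 2, j - joff + 2
            fd = np.zeros((m, n))
            for x in range(1, m):
                fd[x][0] = fd[x - 1][0] + cdel(la[ioff + x - 1])
            for y in range(1, n):
                fd[0][y] = fd[0][y - 1] + cdel(lb[joff + y - 1])
            for x in range(1, m):
                for y in range(1, n):
                    ia, jb = ioff + x - 1, joff + y - 1
                    if lmla[ia] == ioff and lmlb[jb] == joff:
                        fd[x][y] = min(
                            fd[x - 1][y] + cdel(la[ia]),
                            fd[x][y - 1] + cdel(lb[jb]),
                            fd[x - 1][y - 1] + crel(la[ia], lb[jb]),
                        )
                        td[ia][jb] = fd[x][y]
                    else:
                        px = lmla[ia] - ioff
                        py = lmlb[jb] - joff
                        fd[x][y] = min(
                            fd[x - 1][y] + cdel(la[ia]),
                            fd[x][y - 1] + cdel(lb[jb]),
                            fd[px][py] + td[ia][jb],
                        )
    return float(td[na - 1][nb - 1])


# ---------------------------------------------------------------------------
# distance matrices and UPGMA

@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        assert v.shape == (len(self.labels), len(self.labels))

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def pairwise_matrix(
    structures: Sequence[tuple[str, str]], scheme: str = "unit"
) -> DistanceMatrix:
    """All-pairs tree edit distances for labeled dot-bracket structures."""
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    labels = [lab for lab, _ in structures]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(structures)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = tree_edit_distance(structures[i][1], structures[j][1], scheme)
            values[i, j] = values[j, i] = dij
    return DistanceMatrix(tuple(labels), values)


@dataclass(frozen=True)
class ClusterTree:
    """Node of a rooted ultrametric tree; ``height`` is distance/2 units."""

    height: float
    children: tuple["ClusterTree", ...] = ()
    label: Optional[str] = None

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label is not None else []
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaf_labels())
        return out

    def to_newick(self, digits: int = 6) -> str:
        def walk(node: "ClusterTree") -> str:
            if not node.children:
                return node.label or ""
            parts = []
            for ch in node.children:
                bl = round(node.height - ch.height, digits)
                parts.append(f"{walk(ch)}:{bl:g}")
            return "(" + ",".join(parts) + ")"

        return walk(self) + ";"

    def leaf_depths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: "ClusterTree", acc: float):
            if not node.children:
                out[node.label] = acc
                return
            for ch in node.children:
                walk(ch, acc + node.height - ch.height)

        walk(self, 0.0)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol if depths else True


def upgma(m: DistanceMatrix) -> ClusterTree:
    """Arithmetic-average agglomerative clustering to an ultrametric tree.

    Cluster-to-cluster distances are size-weighted averages of member
    distances; merge heights are half the merge distance.  Equal-distance
    merges break toward the lexicographically smallest pair of cluster
    labels (a cluster is labeled by its smallest leaf).
    """
    n = len(m.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    v = np.asarray(m.values, dtype=float)
    if np.isnan(v).any() or (v < 0).any():
        raise ValueError("distance matrix must be non-negative and NaN-free")

    clusters: dict[str, tuple[ClusterTree, int]] = {
        lab: (ClusterTree(0.0, (), lab), 1) for lab in m.labels
    }
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((m.labels[i], m.labels[j]))] = float(v[i, j])

    while len(clusters) > 1:
        best_key = None
        best = None
        for key, dval in dist.items():
            a, b = sorted(key)
            cand = (dval, a, b)
            if best is None or cand < best:
                best = cand
                best_key = (a, b)
        a, b = best_key
        d_ab = best[0]
        (ta, na), (tb, nb) = clusters[a], clusters[b]
        node = ClusterTree(d_ab / 2.0, (ta, tb))
        new_label = min(a, b)
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_label, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[new_label] = (node, na + nb)

    (root, _), = clusters.values()
    return root
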