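"""Distance-based phylogeny: MSA distances, neighbor joining, Newick.

The guide tree of the kinome comparison is a Saitou–Nei neighbor-joining
tree over pairwise distances computed from the kinase-domain alignment.
Two distance methods are offered: the p-distance (mismatch fraction over
gap-free column pairs) and a scoredist-style transform of normalised
BLOSUM62 similarity.  NJ is exact on additive matrices, which is the
correctness oracle used by the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import GAP, Alignment

#: Distance assigned when normalised similarity is non-positive (saturation).
SCOREDIST_CEILING = 3.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero-diagonal, (n, n)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("non-zero diagonal")


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; branch length is the edge to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree represented with a degree-3 (or star) root node."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        names = sorted(self.leaf_names)
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def visit(node: TreeNode) -> dict[str, float]:
            if not node.children:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for c in node.children:
                sub = visit(c)
                below.append({k: v + c.length for k, v in sub.items()})
            for da, db in combinations(below, 2):
                for la, va in da.items():
                    for lb, vb in db.items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = va + vb
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        visit(self.root)
        return DistanceMatrix(ids=names, d=d)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-side canonical leaf set."""
        all_leaves = frozenset(self.leaf_names)
        splits: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> frozenset[str]:
            if not node.children:
                return frozenset([node.name])
            below = frozenset().union(*(visit(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        for c in self.root.children:
            visit(c)
        return splits


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (Robinson–Foulds) distance between topologies."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def msa_distance(msa: Alignment, method: str = "pdist") -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``pdist``: mismatch fraction over columns where neither row is gapped.
    ``scoredist_blosum62``: -ln of BLOSUM62 similarity normalised between
    the expected random score and the mean self-score of the pair, clamped
    to ``SCOREDIST_CEILING`` when the normalised similarity is non-positive.
    A pair sharing no gap-free column is an error.
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    ids = msa.ids
    n = len(ids)
    d = np.zeros((n, n))
    blosum = substitution_matrices.load("BLOSUM62") if method != "pdist" else None
    for i, j in combinations(range(n), 2):
        ri, rj = msa.rows[i][1], msa.rows[j][1]
        pairs = [
            (a, b) for a, b in zip(ri, rj) if a != GAP and b != GAP
        ]
        if not pairs:
            raise ValueError(
                f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
            )
        if method == "pdist":
            dist = sum(a != b for a, b in pairs) / len(pairs)
        elif method == "scoredist_blosum62":
            score = sum(_blosum_score(blosum, a, b) for a, b in pairs)
            self_i = sum(_blosum_score(blosum, a, a) for a, _ in pairs)
            self_j = sum(_blosum_score(blosum, b, b) for _, b in pairs)
            expected = _expected_random_score(blosum) * len(pairs)
            upper = 0.5 * (self_i + self_j)
            norm = (score - expected) / (upper - expected)
            dist = SCOREDIST_CEILING if norm <= 0 else min(
                SCOREDIST_CEILING, -math.log(norm)
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=list(ids), d=d)


def _blosum_score(blosum, a: str, b: str) -> float:
    try:
        return float(blosum[a, b])
    except (KeyError, IndexError):
        return float(blosum["X", "X"])


def _expected_random_score(blosum) -> float:
    # uniform background over the 20 standard residues
    aas = [a for a in blosum.alphabet if a in "ACDEFGHIKLMNPQRSTVWY"]
    return float(
        np.mean([[float(blosum[a, b]) for b in aas] for a in aas])
    )


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Q(i,j) = (n-2) d(i,j) - R_i - R_j with R_i = sum_k d(i,k); the
    minimal-Q pair is joined (ties broken on the lexicographically smallest
    taxon-name pair), branch lengths follow the Saitou–Nei rule, distances
    to the new node are (d(i,k)+d(j,k)-d(i,j))/2, and the final three nodes
    close the star with the closed-form three-taxon lengths.  Negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    edge, preserving the path length through the joined pair.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    labels: list[str] = list(dm.ids)
    d = dm.d.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best: tuple[float, tuple[str, str], tuple[int, int]] | None = None
        for i, j in combinations(range(n), 2):
            q = (n - 2) * d[i, j] - r[i] - r[j]
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or q < best[0] - 1e-12 or (
                abs(q - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (q, key, (i, j))
        i, j = best[2]
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        vj = d[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = vi, vj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(best[1])]

    # close the star: three-taxon closed form
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    v0 = max(0.0, 0.5 * (d01 + d02 - d12))
    v1 = max(0.0, 0.5 * (d01 + d12 - d02))
    v2 = max(0.0, 0.5 * (d02 + d12 - d01))
    for node, v in zip(nodes, (v0, v1, v2)):
        node.length = v
    return PhyloTree(root=TreeNode(children=nodes))


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi = max(0.0, vi + vj)
        vj = 0.0
    return vi, vj


def to_newick(tree: PhyloTree) -> str:
    """Serialise with branch lengths to 6 decimal places."""

    def fmt(node: TreeNode) -> str:
        if not node.children:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{node.length:.6f}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"


def read_newick(text: str) -> PhyloTree:
    """Parse the subset of Newick written by :func:`to_newick`."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            node.children.append(parse())
            while text[pos] == ",":
                pos += 1
                node.children.append(parse())
            if text[pos] != ")":
                raise ValueError(f"expected ')' at {pos}")
            pos += 1
        else:
            start = pos
            while pos < len(text) and text[pos] not in ",():":
                pos += 1
            node.name = text[start:pos]
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse()
    if pos != len(text):
        raise ValueError(f"trailing characters at {pos}")
    return PhyloTree(root=root)
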