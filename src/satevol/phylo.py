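"""Evolutionary distances (p, K2P, gamma-corrected K2P), neighbor-joining
trees and species-specificity summaries.

Distances are computed with pairwise deletion over the kept columns of a
masked alignment: any column where either row carries a gap or N is excluded
for that pair.  Saturated pairs (where the K2P logarithms are undefined) are
flagged, never raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .msa import Alignment

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


def _pair_counts(row_i: str, row_j: str) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions) under pairwise deletion."""
    n = ts = tv = 0
    for a, b in zip(row_i, row_j):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing sites, pairwise deletion.

    Returns NaN when no site is comparable.
    """
    n, ts, tv = _pair_counts(row_i, row_j)
    if n == 0:
        return math.nan
    return (ts + tv) / n


def k2p_distance(
    row_i: str, row_j: str, gamma_shape: float | None = None
) -> float:
    """Kimura two-parameter distance, optionally gamma-corrected.

    With transition fraction P and transversion fraction Q:
    ``d = -ln(1-2P-Q)/2 - ln(1-2Q)/4``; with gamma shape ``a``,
    ``d = (a/2) * [(1-2P-Q)^(-1/a) + (1-2Q)^(-1/a)/2 - 3/2]``.
    Saturated pairs (``1-2P-Q <= 0`` or ``1-2Q <= 0``) return NaN.
    """
    n, ts, tv = _pair_counts(row_i, row_j)
    if n == 0:
        return math.nan
    p_frac = ts / n
    q_frac = tv / n
    w1 = 1.0 - 2.0 * p_frac - q_frac
    w2 = 1.0 - 2.0 * q_frac
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    if gamma_shape is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    a = float(gamma_shape)
    if not (a > 0):
        raise ValueError("gamma shape must be positive")
    return (a / 2.0) * (w1 ** (-1.0 / a) + 0.5 * w2 ** (-1.0 / a) - 1.5)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair undefined flags."""

    labels: list[str]
    matrix: np.ndarray
    model: str
    undefined: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if self.undefined is None:
            self.undefined = np.isnan(self.matrix)
        self.undefined = np.asarray(self.undefined, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self) -> str:
        lines = ["\t".join(["label"] + self.labels)]
        for i, lab in enumerate(self.labels):
            cells = [
                "NA" if self.undefined[i, j] else repr(float(self.matrix[i, j]))
                for j in range(self.n)
            ]
            lines.append("\t".join([lab] + cells))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, model: str = "unknown") -> "DistanceMatrix":
        rows = [line.split("\t") for line in text.strip().split("\n")]
        labels = rows[0][1:]
        mat = np.array(
            [
                [math.nan if c == "NA" else float(c) for c in row[1:]]
                for row in rows[1:]
            ]
        )
        return cls(labels=labels, matrix=mat, model=model)


def distance_matrix(
    alignment: Alignment,
    model: str = "p",
    gamma_shape: float | None = None,
) -> DistanceMatrix:
    """All-pairs distances over an alignment's kept columns.

    ``model`` is ``"p"`` or ``"k2p"``; pass ``gamma_shape`` for the
    gamma-corrected K2P variant.  Undefined pairs are NaN and flagged.
    """
    if alignment.n_rows < 2:
        raise ValueError("need at least 2 rows")
    rows = alignment.kept_rows()
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "p":
                d = p_distance(rows[i], rows[j])
            elif model == "k2p":
                d = k2p_distance(rows[i], rows[j], gamma_shape)
            else:
                raise ValueError(f"unknown model: {model!r}")
            mat[i, j] = mat[j, i] = d
    tag = model if gamma_shape is None or model == "p" else f"k2p+g{gamma_shape}"
    return DistanceMatrix(labels=list(alignment.labels), matrix=mat, model=tag)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_inner() for c in self.children)
        return f"({inner}):{self.length:.10g}"


@dataclass
class PhyloTree:
    """Unrooted NJ tree: the root node is the trifurcating join point."""

    root: TreeNode
    clamped_branches: int = 0

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self) -> str:
        return self.root.to_newick()


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) label pair; negative branch lengths are clamped to 0 and
    counted.
    """
    if dm.n < 3:
        raise ValueError("need at least 3 labels for NJ")
    if dm.undefined.any() and np.isnan(dm.matrix[~np.eye(dm.n, dtype=bool)]).any():
        raise ValueError("matrix contains undefined pairs; drop or impute first")

    nodes = [TreeNode(name=lab) for lab in dm.labels]
    labels = list(dm.labels)
    d = dm.matrix.astype(float).copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            logger.debug("clamped negative branch length %g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key = tuple(sorted((labels[i], labels[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and key < best[2]
                ):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        d_ij = d[i, j]
        li = 0.5 * d_ij + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d_ij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new_node = TreeNode(children=[child_i, child_j])
        new_label = f"({min(labels[i], labels[j])}+{max(labels[i], labels[j])})"

        new_d = 0.5 * (d[i] + d[j] - d_ij)
        keep = [k for k in range(r) if k not in (i, j)]
        nd = np.zeros((r - 1, r - 1))
        nd[: r - 2, : r - 2] = d[np.ix_(keep, keep)]
        nd[r - 2, : r - 2] = nd[: r - 2, r - 2] = new_d[keep]
        d = nd
        nodes = [nodes[k] for k in keep] + [new_node]
        labels = [labels[k] for k in keep] + [new_label]

    # final trifurcation via the three-point formulas
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length = clamp(la)
    b.length = clamp(lb)
    c.length = clamp(lc)
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root, clamped_branches=clamped)


def species_cluster_index(
    tree: PhyloTree,
    species: dict[str, str],
    purity: float = 0.90,
) -> float:
    """Fraction of leaves sitting in species-pure parts of the tree.

    Every split side of the unrooted tree is a candidate cluster; sides
    whose dominant species accounts for at least ``purity`` of members are
    chosen greedily (largest first, disjoint).  Leaves in chosen clusters of
    size >= 2 count toward the index, so the result is 1.0 when every
    species is monophyletic (with >= 2 members) and near the permutation
    expectation for random labels.
    """
    all_leaves = tree.leaf_names()
    missing = [leaf for leaf in all_leaves if leaf not in species]
    if missing:
        raise KeyError(f"leaves without species labels: {missing[:5]}")
    universe = frozenset(all_leaves)

    def is_pure(names) -> bool:
        counts: dict[str, int] = {}
        for name in names:
            counts[species[name]] = counts.get(species[name], 0) + 1
        return max(counts.values()) / len(names) >= purity

    # candidate clusters: both sides of every edge of the unrooted tree
    candidates: list[frozenset[str]] = []

    def collect(node: TreeNode) -> frozenset:
        names = (
            frozenset([node.name])
            if node.is_leaf()
            else frozenset().union(*(collect(c) for c in node.children))
        )
        if node is not tree.root:
            for side in (names, universe - names):
                if side and is_pure(side):
                    candidates.append(side)
        return names

    collect(tree.root)
    candidates.sort(key=lambda s: (-len(s), sorted(s)[0]))

    covered: set[str] = set()
    good = 0
    for cand in candidates:
        if len(cand) < 2 or cand & covered:
            continue
        covered |= cand
        good += len(cand)
    return good / len(all_leaves)
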