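"""Neighbor-joining haplotype genealogies under the Kimura two-parameter model.

The K2P distance treats transitions (A<->G, C<->T) and transversions
separately: with transition proportion P and transversion proportion Q over
the compared sites,

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).

Trees are built with the Saitou-Nei neighbor-joining agglomeration, which is
exact on additive distance matrices.  Branch support is assessed by
resampling alignment columns with replacement, rebuilding the tree per
replicate, and reporting for every internal edge the percentage of replicate
trees containing the same bipartition; supports below 50 are conventionally
hidden when rendering.

Deterministic conventions (the underlying publications leave these open):
Q-criterion ties break to the lowest label-index pair; negative NJ branch
lengths are clamped to zero with the length transferred to the sister branch;
distances use pairwise gap deletion by default (switchable to complete
deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from ._util import DNA, as_pairs, check_aligned

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distance undefined: substitution saturation puts the K2P logs out of
    domain (1 - 2P - Q <= 0 or 1 - 2Q <= 0)."""


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Compared over sites where both sequences carry an unambiguous base
    (pairwise gap deletion).  Raises :class:`SaturationError` when the
    distance is undefined.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in DNA or y not in DNA:
            continue
        n += 1
        if x == y:
            continue
        if {x, y} <= _PURINES or {x, y} <= _PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise SaturationError("no comparable sites between sequences")
    p, q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair (P={p:.3f}, Q={q:.3f}): K2P distance undefined"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.labels)


def k2p_matrix(alignment, gap_mode: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P distances for an alignment.

    ``gap_mode="complete"`` first drops every column containing a non-ACGT
    character in any sequence; ``"pairwise"`` (default) compares each pair
    over its own clean sites.
    """
    pairs = as_pairs(alignment)
    check_aligned(pairs)
    if gap_mode == "complete":
        cols = [i for i in range(len(pairs[0][1]))
                if all(seq[i] in DNA for _, seq in pairs)]
        pairs = [(name, "".join(seq[i] for i in cols)) for name, seq in pairs]
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    n = len(pairs)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = k2p_distance(pairs[i][1], pairs[j][1])
    return DistanceMatrix(tuple(name for name, _ in pairs), d)


@dataclass
class TreeNode:
    """Minimal unrooted-tree node (root is a trifurcation for >= 4 taxa)."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    def internal_nodes(self) -> list["TreeNode"]:
        """Non-root internal nodes (one per internal edge of the unrooted tree)."""
        out = []
        for c in self.children:
            if not c.is_leaf:
                out.append(c)
                out.extend(c.internal_nodes())
        return out

    def newick(self, with_support: bool = False,
               min_support: float = 50.0) -> str:
        """Newick string; optional integer support labels on internal nodes,
        with values below ``min_support`` suppressed."""
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if with_support and not top and node.support is not None \
                    and node.support >= min_support:
                label = str(int(round(node.support)))
            if top:
                return f"({inner}){label};"
            return f"({inner}){label}:{node.length:.6f}"
        return fmt(self, True)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical internal-edge bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the canonical side is the
    one *not* containing the lexicographically smallest leaf name, so splits
    compare across differently rooted representations.
    """
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.internal_nodes():
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    On an additive matrix the recovered path lengths reproduce the input
    distances exactly (up to floating point).  Ties in the Q criterion break
    to the lowest (i, j) index pair; negative branch lengths are clamped to
    zero with the length moved to the sister branch.
    """
    m = len(matrix)
    if m < 3:
        raise ValueError("neighbor joining requires >= 3 labels")
    nodes = [TreeNode(name=l) for l in matrix.labels]
    d = matrix.values.copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major: lowest i, then lowest j, on exact ties
        i, j = divmod(int(np.argmin(q)), k)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        d2 = np.zeros((k - 1, k - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


@dataclass(frozen=True)
class SupportTree:
    tree: TreeNode
    supports: dict[frozenset[str], float]
    n_replicates_used: int
    n_replicates_skipped: int

    def newick(self, min_support: float = 50.0) -> str:
        return self.tree.newick(with_support=True, min_support=min_support)


def bootstrap_supports(alignment, b: int = 500, seed: Optional[int] = None,
                       gap_mode: str = "pairwise") -> SupportTree:
    """NJ tree with column-resampling bootstrap supports.

    ``b`` replicates resample alignment columns with replacement; an internal
    edge's support is the percentage of replicate trees containing the same
    bipartition.  Replicates with saturated (undefined) distances are skipped
    and the percentage denominator adjusted.  Fully deterministic for a fixed
    seed.
    """
    if b < 1:
        raise ValueError("bootstrap requires b >= 1")
    pairs = as_pairs(alignment)
    length = check_aligned(pairs)
    tree = nj_tree(k2p_matrix(pairs, gap_mode=gap_mode))
    target = bipartitions(tree)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    used = skipped = 0
    for _ in range(b):
        cols = rng.integers(0, length, size=length)
        resampled = [(name, "".join(seq[i] for i in cols)) for name, seq in pairs]
        try:
            rep = nj_tree(k2p_matrix(resampled, gap_mode=gap_mode))
        except SaturationError:
            skipped += 1
            continue
        used += 1
        for bp in bipartitions(rep):
            if bp in hits:
                hits[bp] += 1
    supports = {bp: (100.0 * h / used if used else 0.0)
                for bp, h in hits.items()}
    # annotate the tree's internal nodes
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    for node in tree.internal_nodes():
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if side in supports:
            node.support = supports[side]
    return SupportTree(tree, supports, used, skipped)
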