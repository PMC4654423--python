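"""Distances, neighbor-joining and bootstrap support.

The tree builder is a standard Saitou–Nei neighbor-joining with the
Q-criterion, deterministic lexicographic tie-breaking (by the smallest
leaf label contained in each cluster) and negative branch lengths clamped
to zero.  Distances come either from an alignment (p or Poisson-corrected
distance, pairwise gap deletion) or, for unaligned sequences, from a
k-mer profile dissimilarity.  Bootstrap support resamples alignment
columns with a seeded generator and reports the percentage of replicate
trees containing each leaf bipartition.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "pairwise_distance",
    "kmer_distance",
    "nj_tree",
    "bootstrap_support",
]


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")

    def to_tsv(self, path) -> None:
        """Phylip-square style TSV."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class _Node:
    label: str | None = None  # leaf label, None for internal
    children: list[tuple["_Node", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c, _ in self.children))


class PhyloTree:
    """Unrooted binary tree (represented with a trifurcating root)."""

    def __init__(self, root: _Node, labels: Sequence[str]):
        self.root = root
        self.labels = tuple(labels)

    # -- structure ---------------------------------------------------------
    def leaf_set(self) -> frozenset[str]:
        return self.root.leaves()

    def _normalize(self, side: frozenset[str]) -> frozenset[str]:
        ref = min(self.labels)
        return side if ref not in side else self.leaf_set() - side

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, one per internal edge."""
        out: set[frozenset[str]] = set()

        def walk(node: _Node) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = child.leaves()
                    if 1 < len(side) < len(self.labels) - 1:
                        out.add(self._normalize(side))
                    walk(child)

        walk(self.root)
        return out

    def set_supports(self, support: dict[frozenset[str], float]) -> None:
        def walk(node: _Node) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = child.leaves()
                    if 1 < len(side) < len(self.labels) - 1:
                        child.support = support.get(self._normalize(side), 0.0)
                    walk(child)

        walk(self.root)

    # -- output ------------------------------------------------------------
    def newick(self, with_support: bool = False) -> str:
        def fmt(node: _Node, length: float | None) -> str:
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                tag = ""
                if with_support and node.support is not None:
                    tag = f"{node.support:g}"
                body = f"({inner}){tag}"
            return body if length is None else f"{body}:{length:.10g}"

        return fmt(self.root, None) + ";"

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths through the tree."""
        idx = {lab: i for i, lab in enumerate(sorted(self.labels))}
        n = len(idx)
        d = np.zeros((n, n))

        def walk(node: _Node) -> dict[str, float]:
            """Distances from every leaf under ``node`` up to ``node``."""
            if node.is_leaf:
                return {node.label: 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                sub = walk(child)
                below.append({lab: dist + length for lab, dist in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i].items():
                        for lb, db in below[j].items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return DistanceMatrix(tuple(sorted(self.labels)), d)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def pairwise_distance(
    alignment: Sequence, model: str = "p"
) -> DistanceMatrix:
    """p or Poisson distance from an alignment, pairwise gap deletion.

    ``alignment`` is a sequence of records with ``id`` and ``sequence``
    attributes (equal-length gapped rows).  Columns with a gap in either
    member of a pair are excluded for that pair.
    """
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    ids = [r.id for r in alignment]
    rows = [r.sequence for r in alignment]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError("alignment rows must have equal length")
    arr = np.array([list(r) for r in rows])
    gap = (arr == "-") | (arr == ".")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            ncols = int(ok.sum())
            if ncols == 0:
                raise ValueError(
                    f"no comparable columns for pair ({ids[i]}, {ids[j]})"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / ncols
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1.0 for pair ({ids[i]}, {ids[j]}): "
                        "Poisson correction undefined"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(ids), d)


def kmer_distance(records: Sequence, k: int = 3) -> DistanceMatrix:
    """Alignment-free k-mer profile dissimilarity for unaligned sequences.

    d(a, b) = 1 - 2 * sum(min(counts)) / (n_a + n_b), zero for identical
    sequences.
    """
    ids = [r.id for r in records]
    profiles = []
    for r in records:
        s = r.sequence
        profiles.append(Counter(s[i : i + k] for i in range(len(s) - k + 1)))
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = profiles[i], profiles[j]
            shared = sum(min(c, pj[w]) for w, c in pi.items() if w in pj)
            total = sum(pi.values()) + sum(pj.values())
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / total
    return DistanceMatrix(tuple(ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion are broken by the smallest sorted pair of
    cluster labels, a cluster's label being the lexicographically smallest
    leaf it contains.  Negative branch lengths are clamped to zero with a
    log warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[_Node] = [_Node(label=lab) for lab in dm.labels]
    clabels: list[str] = list(dm.labels)
    D = dm.d.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("nj_tree: clamping negative branch length %g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            (tuple(sorted((clabels[active[i]], clabels[active[j]]))), i, j)
            for i, j in cand
            if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = _Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # distances from the new node to the remaining clusters
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        clabels.append(min(clabels[i], clabels[j]))
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = sorted(active, key=lambda x: clabels[x])
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root, dm.labels)


def bootstrap_support(
    alignment: Sequence,
    n_replicates: int = 1000,
    seed: int | None = None,
    model: str = "p",
) -> PhyloTree:
    """NJ tree on the full alignment plus bootstrap bipartition supports.

    Columns are resampled with replacement ``n_replicates`` times using a
    seeded generator; an internal edge's support is the percentage of
    replicate trees containing the same leaf bipartition.
    """
    rows = [r.sequence for r in alignment]
    length = len(rows[0])
    if length < 2:
        raise ValueError("bootstrap needs an alignment with >= 2 columns")
    tree = nj_tree(pairwise_distance(alignment, model))
    rng = np.random.default_rng(seed)
    tally: Counter[frozenset[str]] = Counter()

    class _Row:
        __slots__ = ("id", "sequence")

        def __init__(self, rid, seq):
            self.id, self.sequence = rid, seq

    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            _Row(r.id, "".join(r.sequence[c] for c in cols)) for r in alignment
        ]
        rep = nj_tree(pairwise_distance(resampled, model))
        for bip in rep.bipartitions():
            tally[bip] += 1
    support = {b: 100.0 * c / n_replicates for b, c in tally.items()}
    tree.set_supports(support)
    return tree
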