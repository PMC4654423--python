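"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (no caching, no shared code
with the package internals) so they can serve as a second route for the
quantities the package computes.
"""

from __future__ import annotations

import itertools
from math import comb, log

from Bio.Data import CodonTable

_CT = CodonTable.unambiguous_dna_by_id[1]
_STOP = set(_CT.stop_codons)


def _translate(codon: str) -> str:
    return "*" if codon in _STOP else _CT.forward_table[codon]


def ng86_oracle(pairs: list[tuple[str, str]]):
    """Plain NG86 on a list of codon pairs.

    Returns (S, N, sd, nd, ks, kn) with ks/kn = None when saturated.
    """
    S = 0.0
    for ca, cb in pairs:
        for codon in (ca, cb):
            aa = _translate(codon)
            syn = 0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1 :]
                    if alt not in _STOP and _translate(alt) == aa:
                        syn += 1
            S += syn / 3.0 / 2.0
    N = 3.0 * len(pairs) - S

    sd = nd = 0.0
    for ca, cb in pairs:
        positions = [i for i in range(3) if ca[i] != cb[i]]
        if not positions:
            continue
        tallies = []
        for order in itertools.permutations(positions):
            cur = ca
            through_stop = False
            s_steps = n_steps = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in _STOP and nxt != cb:
                    through_stop = True
                if _translate(cur) == _translate(nxt):
                    s_steps += 1
                else:
                    n_steps += 1
                cur = nxt
            tallies.append((through_stop, s_steps, n_steps))
        kept = [(s, n) for blocked, s, n in tallies if not blocked]
        if not kept:
            kept = [(s, n) for _, s, n in tallies]
        sd += sum(s for s, _ in kept) / len(kept)
        nd += sum(n for _, n in kept) / len(kept)

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * log(1.0 - 4.0 * p / 3.0)

    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    return S, N, sd, nd, jc(ps), jc(pn)


def hypergeom_tail_oracle(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for a hypergeometric draw, by direct combinatorial sums."""
    total = comb(M, n)
    hits = 0
    for x in range(k, min(K, n) + 1):
        hits += comb(K, x) * comb(M - K, n - x)
    return hits / total


def all_pairs_identity(a: str, b: str) -> float:
    """Ungapped identity over the shorter sequence (for equal-family reads)."""
    L = min(len(a), len(b))
    return sum(x == y for x, y in zip(a, b)) / L


def random_additive_tree(n: int, rng):
    """A random unrooted binary tree with rational branch lengths.

    Returns (labels, D) where D is the leaf path-length matrix, plus the
    set of non-trivial bipartitions (each frozenset excludes the smallest
    label) for topology comparison.
    """
    import numpy as np

    labels = [f"t{i:02d}" for i in range(n)]
    adj: dict[str, list[tuple[str, float]]] = {}

    def connect(a, b, l):
        adj.setdefault(a, []).append((b, l))
        adj.setdefault(b, []).append((a, l))

    def length():
        return float(rng.integers(1, 17)) / 8.0

    counter = itertools.count()

    def newnode():
        return f"_n{next(counter)}"

    connect(labels[0], labels[1], length())
    edges = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        a, b = edges[int(rng.integers(len(edges)))]
        mid = newnode()
        old = [x for x in adj[a] if x[0] == b][0][1]
        adj[a] = [x for x in adj[a] if x[0] != b]
        adj[b] = [x for x in adj[b] if x[0] != a]
        cut = max(1, int(rng.integers(1, 8))) / 8.0 * old
        connect(a, mid, cut)
        connect(b, mid, old - cut)
        connect(leaf, mid, length())
        edges.remove((a, b))
        edges += [(a, mid), (b, mid), (leaf, mid)]

    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        for j, b in enumerate(labels):
            D[i, j] = dist[b]

    # bipartitions: removing each internal edge splits the leaves
    bips = set()
    for a, b in edges:
        if a in labels or b in labels:
            continue
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if v != b and v not in seen and not (u == a and v == b):
                    if (u, v) == (a, b):
                        continue
                    seen.add(v)
                    stack.append(v)
        side = frozenset(x for x in seen if x in labels)
        if 1 < len(side) < n - 1:
            if min(labels) in side:
                side = frozenset(labels) - side
            bips.add(side)
    return labels, D, bips
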