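"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the implementation paths they check: folding is
verified by exhaustive enumeration of nested pairings, primer matching by
degenerate expansion, and neighbor-joining by path-length matrices of
randomly generated trees.
"""

from __future__ import annotations

import itertools
import random

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
          ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


def max_pairs_bruteforce(seq: str, min_loop: int = 3) -> int:
    """Maximum nested base-pair count by exhaustive recursion (n <= ~14)."""
    s = seq.upper()

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        # j unpaired
        result = best(i, j - 1)
        for k in range(i, j - min_loop):
            if (s[k], s[j]) in _PAIRS:
                result = max(result, best(i, k - 1) + best(k + 1, j - 1) + 1)
        return result

    return best(0, len(s) - 1)


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def placements_by_expansion(primer_seq: str, text: str, max_mismatch: int):
    """All (start_1based, mismatches) via brute-force degenerate expansion."""
    concrete = ["".join(p) for p in itertools.product(*(IUPAC[b] for b in primer_seq))]
    k = len(primer_seq)
    hits = {}
    for s in range(len(text) - k + 1):
        window = text[s : s + k]
        mm = min(sum(a != b for a, b in zip(c, window)) for c in concrete)
        if mm <= max_mismatch:
            hits[s + 1] = mm
    return hits


def random_additive_tree(n_taxa: int, rng: random.Random):
    """Random binary tree with positive branch lengths and its path metric.

    Returns (labels, distance_matrix, splits) where splits is the set of
    non-trivial bipartitions (as frozensets of the side not containing the
    first label).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # grow by random attachment: start with a 2-leaf tree as an edge list
    nodes = {0: labels[0], 1: labels[1]}
    edges = {(0, 1): rng.uniform(0.5, 2.0)}
    next_id = 2
    leaf_of = {0: labels[0], 1: labels[1]}
    for i in range(2, n_taxa):
        (a, b) = rng.choice(sorted(edges))
        w = edges.pop((a, b))
        split = rng.uniform(0.2, 0.8)
        mid, leaf = next_id, next_id + 1
        next_id += 2
        edges[(a, mid)] = w * split
        edges[(mid, b)] = w * (1 - split)
        edges[(mid, leaf)] = rng.uniform(0.5, 2.0)
        leaf_of[leaf] = labels[i]

    adj = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def dists_from(start):
        out = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    leaf_ids = sorted(leaf_of)
    D = [[0.0] * n_taxa for _ in range(n_taxa)]
    index = {leaf_of[lid]: i for i, lid in enumerate(leaf_ids)}
    for lid in leaf_ids:
        d = dists_from(lid)
        for mid in leaf_ids:
            D[index[leaf_of[lid]]][index[leaf_of[mid]]] = d[mid]

    # splits: removing each internal edge partitions the leaves
    splits = set()
    all_leaves = frozenset(labels)
    for (a, b) in edges:
        # leaves on the b-side of edge (a, b)
        side = set()
        stack = [(b, a)]
        while stack:
            u, parent = stack.pop()
            if u in leaf_of:
                side.add(leaf_of[u])
            for v, _ in adj[u]:
                if v != parent:
                    stack.append((v, u))
        if 1 < len(side) < n_taxa - 1:
            fs = frozenset(side)
            if labels[0] in fs:
                fs = all_leaves - fs
            splits.add(fs)
    ordered = sorted(index, key=lambda l: index[l])
    return ordered, D, splits
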