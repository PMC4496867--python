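"""Per-locus intron phylogenetics: distances, neighbor-joining, bootstrap,
and junction conservation profiles.

Trees are neighbor-joining only (Saitou-Nei agglomeration with the standard
branch-length formulas); bootstrap supports come from column resampling of
the per-locus alignment.  Introns from different loci are typically too
divergent to compare: :func:`check_comparable` refuses sets whose mean
pairwise identity falls below 20 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "LocusProfile",
    "pairwise_distances",
    "nj_tree",
    "bootstrap_support",
    "junction_consensus",
    "center_star_align",
    "group_by_locus",
    "check_comparable",
    "JC_SATURATION_CAP",
]

#: Jukes-Cantor distance assigned when p >= 0.749 (log argument nonpositive).
JC_SATURATION_CAP = 5.0
_P_SATURATION = 0.749


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray
    saturated: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape disagrees with labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("distance matrix must be non-negative")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root (trifurcation for
    >= 3 taxa).  Supports, when present, sit on internal edges in [0, 100]."""

    root: TreeNode
    taxa: tuple[str, ...]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side not containing
        the lexicographically smallest taxon.

        Internal edges of length zero are treated as unresolved (an
        all-identical alignment yields a star, not an arbitrarily resolved
        topology) and contribute no split.
        """
        all_taxa = set(self.taxa)
        anchor = min(all_taxa)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for child, length in node.children:
                side = set(child.leaves())
                if length > 0 and 1 < len(side) < len(all_taxa) - 1:
                    if anchor in side:
                        side = all_taxa - side
                    splits.add(frozenset(side))
                walk(child)

        walk(self.root)
        return splits

    def newick(self, with_support: bool = False) -> str:
        def render(node: TreeNode, length: float | None) -> str:
            if not node.children:
                s = node.label
            else:
                inner = ",".join(render(c, bl) for c, bl in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = f"{node.support:g}"
                s = f"({inner}){label}"
            if length is not None:
                s += f":{length:.6f}"
            return s

        return render(self.root, None) + ";"


@dataclass
class LocusProfile:
    """Junction conservation profile for the intron set at one locus."""

    locus: int
    member_ids: tuple[str, ...]
    pfm: np.ndarray  # shape (4, 2 * window), rows A, C, G, T
    information_content: np.ndarray  # bits per column, in [0, 2]
    window: int


def pairwise_distances(
    seqs: list[str], labels: list[str] | None = None, model: str = "p"
) -> DistanceMatrix:
    """p- or Jukes-Cantor distances with pairwise deletion of gapped columns.

    JC = -(3/4) ln(1 - (4/3) p), capped at :data:`JC_SATURATION_CAP` when
    p >= 0.749 (flagged in ``saturated``).
    """
    if model not in ("p", "JC"):
        raise ValueError("model must be 'p' or 'JC'")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    labels = list(labels) if labels is not None else [f"seq{i}" for i in range(len(seqs))]
    arr = np.array([list(s.upper()) for s in seqs])
    valid = np.isin(arr, list("ACGT"))
    n = len(seqs)
    D = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(f"no comparable columns between {labels[i]} and {labels[j]}")
            p = float((arr[i][both] != arr[j][both]).sum() / compared)
            if model == "p":
                d = p
            elif p >= _P_SATURATION:
                d = JC_SATURATION_CAP
                saturated.append((labels[i], labels[j]))
            else:
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(tuple(labels), D, tuple(saturated))


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining; deterministic, exact on additive matrices.

    Q-matrix pair selection with ties broken by the lexicographically
    smallest (min-leaf) label pair; negative branch lengths are clamped to 0.
    Two taxa yield a single edge of the given length.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in D.labels]
    reps: list[str] = list(D.labels)  # min leaf label per cluster, for ties
    d = D.matrix.astype(float).copy()
    active = list(range(n))

    if n == 2:
        root = TreeNode(children=[(nodes[0], d[0, 1] / 2), (nodes[1], d[0, 1] / 2)])
        return PhyloTree(root=root, taxa=D.labels)

    next_nodes = list(nodes)
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new = TreeNode(children=[(next_nodes[i], vi), (next_nodes[j], vj)])
        # reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (d[i, k] + d[j, k] - d[i, j]) / 2
        next_nodes[i] = new
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    va = (d[a, b] + d[a, c] - d[b, c]) / 2
    vb = (d[a, b] + d[b, c] - d[a, c]) / 2
    vc = (d[a, c] + d[b, c] - d[a, b]) / 2
    order = sorted([(reps[a], a, va), (reps[b], b, vb), (reps[c], c, vc)])
    root = TreeNode(
        children=[(next_nodes[k], max(v, 0.0)) for _, k, v in order]
    )
    return PhyloTree(root=root, taxa=D.labels)


def bootstrap_support(
    seqs: list[str],
    labels: list[str],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ point tree with bootstrap supports from column resampling.

    Support of an internal edge = percentage of replicate trees containing
    the same bipartition.  Deterministic for a fixed seed; invariant to the
    input order of taxa up to relabeling.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ncol = len(seqs[0])
    if ncol < 2:
        raise ValueError("alignment must have at least 2 columns")
    point = nj_tree(pairwise_distances(seqs, labels, model=model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    # order-independent seeding: sort rows by label before resampling
    order = np.argsort(np.array(labels))
    sorted_labels = [labels[i] for i in order]
    arr = np.array([list(seqs[i]) for i in order])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rs = ["".join(row) for row in arr[:, cols]]
        try:
            rep = nj_tree(pairwise_distances(rs, sorted_labels, model=model))
        except ValueError:  # e.g. a resample with no comparable columns
            continue
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    def annotate(node: TreeNode) -> None:
        for child, _ in node.children:
            if child.children:
                side = set(child.leaves())
                all_taxa = set(point.taxa)
                if min(all_taxa) in side:
                    side = all_taxa - side
                bp = frozenset(side)
                if bp in counts:
                    child.support = 100.0 * counts[bp] / n_reps
            annotate(child)

    annotate(point.root)
    return point


def group_by_locus(calls) -> dict[int, list]:
    """Partition intron calls by locus; every call lands in exactly one group."""
    groups: dict[int, list] = {}
    for c in calls:
        groups.setdefault(c.locus.position, []).append(c)
    return dict(sorted(groups.items()))


def junction_consensus(members, junction_window: int = 10) -> LocusProfile:
    """Position-frequency matrix over the 5' exon|intron junction columns.

    Columns are boundary-anchored: the last ``junction_window`` exon nt
    followed by the first ``junction_window`` intron nt (2 x window columns).
    Per-column information content = 2 - Shannon entropy (log2), with
    non-ACGT characters excluded from the column counts.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 members with intact junctions")
    w = junction_window
    rows = []
    ids = []
    loci = set()
    for m in members:
        if m.truncated:
            raise ValueError("truncated member has no intact junction")
        exon = m.upstream_flank[-w:].rjust(w, "-")
        intron = m.sequence[:w].ljust(w, "-")
        rows.append(exon + intron)
        ids.append(m.host_id)
        loci.add(m.locus.position)
    if len(loci) != 1:
        raise ValueError("members span multiple loci")
    bases = "ACGT"
    pfm = np.zeros((4, 2 * w))
    for row in rows:
        for col, ch in enumerate(row):
            if ch in bases:
                pfm[bases.index(ch), col] += 1
    ic = np.zeros(2 * w)
    for col in range(2 * w):
        total = pfm[:, col].sum()
        if total == 0:
            ic[col] = 0.0
            continue
        p = pfm[:, col] / total
        entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        ic[col] = 2.0 - entropy
    return LocusProfile(
        locus=loci.pop(),
        member_ids=tuple(ids),
        pfm=pfm,
        information_content=ic,
        window=w,
    )


def profile_to_tsv(profile: LocusProfile) -> str:
    lines = ["column\tA\tC\tG\tT\tIC_bits"]
    for col in range(profile.pfm.shape[1]):
        a, c, g, t = (int(x) for x in profile.pfm[:, col])
        lines.append(f"{col + 1}\t{a}\t{c}\t{g}\t{t}\t{profile.information_content[col]:.4f}")
    return "\n".join(lines) + "\n"


def _pairwise_global(a: str, b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def center_star_align(seqs: list[str]) -> list[str]:
    """Center-star progressive alignment (adequate for high-identity sets).

    The center is the sequence maximising summed pairwise alignment score;
    the others are merged onto it with the once-a-gap-always-a-gap rule.
    Divergent sets should be aligned with a real MSA tool instead.
    """
    if len(seqs) == 1:
        return list(seqs)
    if len({len(s) for s in seqs}) == 1 and len(set(seqs)) == 1:
        return list(seqs)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    n = len(seqs)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(seqs[i], seqs[j])
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))
    master = seqs[center]  # center with accumulated gaps
    aligned: dict[int, str] = {center: master}
    for i in range(n):
        if i == center:
            continue
        a_center, a_other = _pairwise_global(_degap(master), seqs[i])
        # re-project existing master gaps onto the new pairwise alignment
        merged_center, merged_other, others_pad = _merge(master, a_center, a_other)
        master = merged_center
        for k in aligned:
            aligned[k] = others_pad(aligned[k])
        aligned[i] = merged_other
    width = len(master)
    return [aligned[i].ljust(width, "-") for i in range(n)]


def _degap(s: str) -> str:
    return s.replace("-", "")


def _merge(master: str, a_center: str, a_other: str):
    """Merge a new center/other pairwise alignment into the gapped master.

    Returns the new master, the other sequence padded to it, and a function
    that pads any previously aligned row to the new master.
    """
    out_master = []
    out_other = []
    ops = []  # per output column: 'M' from master column, 'I' new gap column
    mi = 0  # index into master
    pi = 0  # index into a_center / a_other
    while mi < len(master) or pi < len(a_center):
        if mi < len(master) and master[mi] == "-":
            out_master.append("-")
            out_other.append("-")
            ops.append("M")
            mi += 1
        elif pi < len(a_center) and a_center[pi] == "-":
            out_master.append("-")
            out_other.append(a_other[pi])
            ops.append("I")
            pi += 1
        else:
            out_master.append(master[mi])
            out_other.append(a_other[pi])
            ops.append("M")
            mi += 1
            pi += 1

    def pad(row: str) -> str:
        res = []
        ri = 0
        for op in ops:
            if op == "M":
                res.append(row[ri])
                ri += 1
            else:
                res.append("-")
        return "".join(res)

    return "".join(out_master), "".join(out_other), pad


def mean_pairwise_identity(aligned: list[str]) -> float:
    """Mean fraction of identical residues over pairwise-comparable columns."""
    n = len(aligned)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(s.upper()) for s in aligned])
    valid = np.isin(arr, list("ACGT"))
    idents = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if both.sum() == 0:
                idents.append(0.0)
                continue
            idents.append(float((arr[i][both] == arr[j][both]).mean()))
    return float(np.mean(idents))


def check_comparable(aligned: list[str], min_identity: float = 0.20) -> float:
    """Refuse phylogenetic comparison of sets below ``min_identity``."""
    ident = mean_pairwise_identity(aligned)
    if ident < min_identity:
        raise ValueError(
            f"sequences too divergent for phylogenetic comparison "
            f"(mean identity {ident:.1%} < {min_identity:.0%})"
        )
    return ident
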