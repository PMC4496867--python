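"""Classify intron calls into four categories.

Categories (decided in this fixed order):

1. ``PRU`` — truncated calls (one junction missing);
2. ``HE``  — a qualifying ORF (>= 50 aa by default) whose peptide carries at
   least one LAGLIDADG-style motif copy (homing endonuclease);
3. ``HP``  — short (< 50 nt) introns folding into a hairpin (paired fraction
   >= 0.5) while maintaining a bulge-helix-bulge (BHB) junction motif;
4. ``REMNANT`` — intact junctions but no qualifying ORF;
5. ``PRU`` — anything left (uncharacterized, e.g. an ORF without a motif).

Folding uses base-pair maximisation (Nussinov) rather than free-energy
minimisation; the BHB search is a constrained duplex scan over the junction
windows (see :func:`detect_bhb`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .detection import IntronCall

__all__ = [
    "OrfHit",
    "MotifScan",
    "BHBMotif",
    "IntronClassification",
    "find_orfs",
    "scan_laglidadg",
    "nussinov_fold",
    "detect_bhb",
    "classify_intron",
    "gc_summary",
    "ClassifyParams",
]

_DNA = set("ACGT")
START_CODONS = ("ATG", "GTG", "TTG")

#: Permissive LAGLIDADG-style motif pattern: nine positions, each a residue
#: class; a window matches when at most one position disagrees.  Packaged as
#: an auditable in-repo fixture in place of a profile-HMM search.
LAGLIDADG_PATTERN: tuple[frozenset[str], ...] = tuple(
    frozenset(s)
    for s in ("LIVMFA", "LIVMFA", "GAS", "LIVMF", "LIVMF", "D", "GAS", "DE", "G")
)
LAGLIDADG_MAX_MISMATCH = 1

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
          ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame on the intron (1-based inclusive nt span)."""

    start: int
    end: int
    strand: str
    peptide: str
    length_aa: int


@dataclass(frozen=True)
class MotifScan:
    """LAGLIDADG motif census of one peptide.

    One copy implies the homodimeric enzyme form, two copies the monomeric
    (single-chain) form; counts are capped at 2.
    """

    count: int
    positions: tuple[tuple[int, int], ...]
    form: str  # none | homodimer | monomer


@dataclass(frozen=True)
class BHBMotif:
    """Bulge-helix-bulge junction motif.

    ``excision_sites`` are the two exon/intron boundary offsets within the
    junction windows (one per bulge) where splicing is hypothesised to cut.
    """

    helix_len: int
    bulge5_len: int
    bulge3_len: int
    excision_sites: tuple[int, int]
    score: float


@dataclass(frozen=True)
class IntronClassification:
    category: str  # HE | HP | REMNANT | PRU
    motif_scan: MotifScan | None
    orf: OrfHit | None
    hairpin: tuple[int, float] | None  # (pairs, paired_fraction)
    bhb: BHBMotif | None
    gc: float


@dataclass(frozen=True)
class ClassifyParams:
    min_orf_aa: int = 50
    genetic_table: int = 11
    hp_max_len: int = 50
    hp_min_paired_fraction: float = 0.5
    bhb_window: int = 12
    min_helix: int = 4
    max_bulge_gap: int = 4
    fold_max_len: int = 200


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs(seq: str, min_aa: int = 50, table: int = 11) -> list[OrfHit]:
    """All ORFs >= ``min_aa`` on both strands, sorted by length descending.

    Within each stop-delimited segment of each reading frame the ORF runs
    from the first start codon (ATG/GTG/TTG) to the stop codon or the
    sequence end.  Spans are 1-based inclusive on the forward strand and
    include the stop codon when present.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    seq = seq.upper()
    if set(seq) - _DNA:
        raise ValueError("find_orfs requires a plain ACGT sequence")
    n = len(seq)
    hits: list[OrfHit] = []
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            seg_start = 0  # codon index where current stop-free segment begins
            i = 0
            while i <= len(codons):
                at_end = i == len(codons)
                is_stop = not at_end and str(Seq(codons[i]).translate(table=table)) == "*"
                if at_end or is_stop:
                    for j in range(seg_start, i):
                        if codons[j] in START_CODONS:
                            aa_len = i - j
                            if aa_len >= min_aa:
                                nt_start = frame + 3 * j + 1
                                nt_end = frame + 3 * i + (3 if is_stop else 0)
                                peptide = str(
                                    Seq("".join(codons[j:i])).translate(table=table)
                                )
                                if strand == "+":
                                    hits.append(
                                        OrfHit(nt_start, nt_end, "+", peptide, aa_len)
                                    )
                                else:
                                    hits.append(
                                        OrfHit(
                                            n - nt_end + 1,
                                            n - nt_start + 1,
                                            "-",
                                            peptide,
                                            aa_len,
                                        )
                                    )
                            break
                    seg_start = i + 1
                i += 1
    hits.sort(key=lambda h: (-h.length_aa, h.start, h.strand))
    return hits


def scan_laglidadg(peptide: str) -> MotifScan:
    """Count non-overlapping LAGLIDADG-style motif copies in a peptide.

    Matches the packaged nine-position pattern with at most one mismatching
    position; greedy non-overlapping scan from the N terminus; count capped
    at 2 (two copies on one chain = monomeric enzyme form).
    """
    if len(peptide) < 20:
        raise ValueError("peptide too short to scan (< 20 aa)")
    peptide = peptide.upper()
    k = len(LAGLIDADG_PATTERN)
    positions: list[tuple[int, int]] = []
    i = 0
    while i <= len(peptide) - k and len(positions) < 2:
        mismatches = sum(
            1 for j, allowed in enumerate(LAGLIDADG_PATTERN) if peptide[i + j] not in allowed
        )
        if mismatches <= LAGLIDADG_MAX_MISMATCH:
            positions.append((i + 1, i + k))
            i += k
        else:
            i += 1
    count = len(positions)
    form = {0: "none", 1: "homodimer", 2: "monomer"}[count]
    return MotifScan(count=count, positions=tuple(positions), form=form)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def nussinov_fold(seq: str, min_loop: int = 3) -> tuple[int, str]:
    """Maximum base-pair count and a dot-bracket structure (Nussinov DP).

    Pairs are AU/AT, GC and GU/GT wobble; hairpin loops must hold at least
    ``min_loop`` unpaired bases.  Traceback ties are broken toward pairing
    the 5'-most candidate partner, giving a deterministic structure.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    s = seq.upper()
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if _can_pair(s[k], s[j]):
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + dp[k + 1, j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        # pair j with the 5'-most k achieving the optimum
        for k in range(i, j - min_loop):
            if _can_pair(s[k], s[j]):
                left = dp[i, k - 1] if k > i else 0
                if left + dp[k + 1, j - 1] + 1 == dp[i, j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return int(dp[0, n - 1]), "".join(structure)


def _junction_bhb(
    strand5: str,
    strand3: str,
    boundary5: int,
    boundary3: int,
    min_helix: int,
    max_gap: int,
    min_sep: int = 3,
    offset3: int = 0,
) -> BHBMotif | None:
    """Scan two junction strands for a bulge-helix-bulge configuration.

    ``strand5`` covers the 5' exon/intron boundary (boundary after 1-based
    position ``boundary5``); ``strand3`` covers the intron/3' exon boundary.
    The central helix pairs an intron-proximal segment of ``strand5``
    (starting 1..max_gap nt after the boundary) antiparallel with a segment
    of ``strand3`` ending 1..max_gap nt before its boundary; the skipped
    nucleotides plus one exon base form the two bulges, each holding one
    exon-intron boundary (the hypothesised excision sites).  ``offset3``
    maps strand3 coordinates onto the same intron as strand5 so that the two
    helix halves can be required not to overlap for very short introns.
    """
    best: BHBMotif | None = None
    for gap5 in range(1, max_gap + 1):
        a = boundary5 + gap5 + 1  # helix half A start on strand5
        for gap3 in range(1, max_gap + 1):
            b_end = boundary3 - gap3  # helix half B end on strand3
            max_h = min(len(strand5) - a + 1, b_end)
            for h in range(max_h, min_helix - 1, -1):
                if h < min_helix:
                    break
                b = b_end - h + 1
                if b < 1:
                    continue
                # both helix halves live on the same intron molecule: require
                # them to be separated (matters only for very short introns)
                intron_a_end = gap5 + h  # intron coords of helix half A end
                intron_b_start = offset3 + b
                if intron_b_start <= intron_a_end + min_sep:
                    continue
                ok = all(
                    _can_pair(strand5[a - 1 + k], strand3[b_end - 1 - k])
                    for k in range(h)
                )
                if ok:
                    motif = BHBMotif(
                        helix_len=h,
                        bulge5_len=gap5 + 1,
                        bulge3_len=gap3 + 1,
                        excision_sites=(boundary5, boundary3),
                        score=float(h),
                    )
                    if best is None or motif.score > best.score:
                        best = motif
                    break  # longer h already tried; move to next gap combo
    return best


def detect_bhb(call: IntronCall, window: int = 12, params: ClassifyParams | None = None) -> BHBMotif | None:
    """Search an intron call's junctions for a bulge-helix-bulge motif.

    Builds the two junction strands — last ``window`` exon nt + first
    ``window`` intron nt, and last ``window`` intron nt + first ``window``
    exon nt — and scans them for a central helix (>= 4 bp by default) whose
    flanking bulges (>= 2 nt) each contain one exon-intron boundary.  Only
    the windows are examined, so the result is invariant under extension of
    the exon flanks.  Truncated calls are rejected (they lack a junction).
    """
    if call.truncated:
        raise ValueError("truncated call has no complete junction pair; route to PRU")
    if window < 10:
        raise ValueError("window must be >= 10")
    params = params or ClassifyParams()
    if not call.upstream_flank or not call.downstream_flank:
        return None
    exon5 = call.upstream_flank[-window:]
    exon3 = call.downstream_flank[:window]
    intron5 = call.sequence[:window]
    intron3 = call.sequence[-window:]
    strand5 = exon5 + intron5
    strand3 = intron3 + exon3
    # offset of strand3's first base in intron coordinates (1-based)
    offset3 = len(call.sequence) - len(intron3)
    return _junction_bhb(
        strand5,
        strand3,
        boundary5=len(exon5),
        boundary3=len(intron3),
        min_helix=params.min_helix,
        max_gap=params.max_bulge_gap,
        offset3=offset3,
    )


def classify_intron(call: IntronCall, params: ClassifyParams | None = None) -> IntronClassification:
    """Assign one of HE / HP / REMNANT / PRU to a call (see module docstring)."""
    params = params or ClassifyParams()
    gc = _gc_fraction(call.sequence)

    if call.truncated:
        return IntronClassification("PRU", None, None, None, None, gc)

    orfs = [
        o
        for o in find_orfs(call.sequence, min_aa=params.min_orf_aa, table=params.genetic_table)
    ] if len(call.sequence) >= 3 * params.min_orf_aa else []

    best_orf: OrfHit | None = None
    best_scan: MotifScan | None = None
    for orf in orfs:
        scan = scan_laglidadg(orf.peptide)
        if best_scan is None or (scan.count, orf.length_aa) > (
            best_scan.count,
            best_orf.length_aa,
        ):
            best_orf, best_scan = orf, scan
    if best_scan is not None and best_scan.count >= 1:
        return IntronClassification("HE", best_scan, best_orf, None, None, gc)

    hairpin = None
    bhb = None
    if len(call.sequence) <= params.fold_max_len:
        pairs, _structure = nussinov_fold(call.sequence)
        hairpin = (pairs, 2.0 * pairs / len(call.sequence))
    if len(call.sequence) < params.hp_max_len:
        bhb = detect_bhb(call, window=params.bhb_window, params=params)
        if (
            hairpin is not None
            and hairpin[1] >= params.hp_min_paired_fraction
            and bhb is not None
        ):
            return IntronClassification("HP", best_scan, best_orf, hairpin, bhb, gc)

    if not orfs:
        return IntronClassification("REMNANT", best_scan, best_orf, hairpin, bhb, gc)
    return IntronClassification("PRU", best_scan, best_orf, hairpin, bhb, gc)


def _gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (s.count("G") + s.count("C")) / acgt


def gc_summary(seqs: Sequence[str]) -> tuple[float, float]:
    """Population mean and standard deviation of per-sequence GC, in percent.

    Ambiguity codes are excluded from both numerator and denominator.
    """
    if not seqs:
        raise ValueError("empty sequence list")
    fracs = np.array([_gc_fraction(s) for s in seqs])
    return float(fracs.mean() * 100.0), float(fracs.std(ddof=0) * 100.0)
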