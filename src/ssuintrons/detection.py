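"""Structural intron detection: insertions relative to the intron-free reference.

Detection is purely positional — a call is a maximal run of query positions
with no reference coordinate, at least ``min_insert`` nt long.  The locus of a
call is the reference position directly before the insertion point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .reference import (
    CANONICAL_LOCI,
    AlignmentScoring,
    CoordinateMap,
    Locus,
    ReferenceModel,
    _left_align_insertions,
    align_to_reference,
)

__all__ = [
    "IntronCall",
    "detect_insertions",
    "snap_to_canonical",
    "excise_and_ligate",
    "calls_to_gff3",
    "calls_to_tsv",
]

FLANK_LEN = 15


@dataclass(frozen=True)
class IntronCall:
    """One detected insertion in a host gene.

    ``host_start``/``host_end`` are the 1-based inclusive span of the inserted
    sequence on the host; flanks are host exon sequence (up to 15 nt each
    side, excluded from the span).  ``truncated`` marks insertions cut off by
    a fragment end (missing one junction).
    """

    host_id: str
    locus: Locus
    host_start: int
    host_end: int
    sequence: str
    upstream_flank: str
    downstream_flank: str
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.host_end - self.host_start + 1

    def __post_init__(self) -> None:
        if self.host_end < self.host_start:
            raise ValueError("host_end < host_start")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with span")


def snap_to_canonical(
    raw_locus: int,
    canonical: frozenset[int] | set[int] = CANONICAL_LOCI,
    tolerance: int = 2,
) -> Locus:
    """Snap a raw locus to the canonical set within ``tolerance`` nt.

    Returns the canonical locus when exactly one canonical position lies
    within tolerance, else a non-canonical ("novel") locus at the raw
    position.  Two canonical loci within tolerance is rejected as ambiguous
    (cannot occur with the packaged set at tolerance <= 2; its closest pair
    is 7 nt apart).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    hits = [c for c in canonical if abs(raw_locus - c) <= tolerance]
    if len(hits) > 1:
        raise ValueError(
            f"ambiguous snap: {sorted(hits)} all within {tolerance} of {raw_locus}"
        )
    if hits:
        return Locus(position=hits[0], canonical=True)
    return Locus(position=raw_locus, canonical=False)


def _merge_islands(ref_pos, min_anchor: int = 10):
    """Flag short mapped segments between (or flanking) inserted runs.

    A few intron bases matching the reference by chance can split one
    insertion into two runs around a tiny mapped "island"; islands shorter
    than ``min_anchor`` are reabsorbed into the surrounding insertion.
    """
    from .reference import INSERTED as _I

    ref_pos = ref_pos.copy()
    n = len(ref_pos)
    changed = True
    while changed:
        changed = False
        # mapped segments as 0-based [s, e)
        segments = []
        i = 0
        while i < n:
            if ref_pos[i] == _I:
                i += 1
                continue
            s = i
            while i < n and ref_pos[i] != _I:
                i += 1
            segments.append((s, i))
        for s, e in segments:
            if e - s >= min_anchor:
                continue
            left_ins = s > 0 and ref_pos[s - 1] == _I
            right_ins = e < n and ref_pos[e] == _I
            if left_ins or right_ins:
                ref_pos[s:e] = _I
                changed = True
    return ref_pos


def _absorb_terminal_junk(
    ref_pos,
    query: str,
    ref_seq: str,
    min_strong_len: int = 20,
    min_strong_identity: float = 0.85,
):
    """Unmap unreliable mapped sequence at the query ends.

    A fragment ending inside an intron leaves a terminal stub that the free
    end gaps let the aligner stitch onto the reference as scattered match
    islands and mismatch-tolerated extensions.  Two cleanups, per end:

    1. absorb whole segments inward until the first *strong* anchor
       (>= ``min_strong_len`` mapped bases at >= ``min_strong_identity``);
    2. trim the surviving boundary back while the identity of the adjacent
       10-base window looks like random sequence (< 8/10 matches).

    Genuine exon ends are high-identity and survive both steps.
    """
    from .reference import INSERTED as _I

    ref_pos = ref_pos.copy()
    n = len(ref_pos)

    def segments():
        # contiguous in both query and reference: a jump in the reference
        # coordinate starts a new segment, so deletion-stitched match islands
        # cannot hide inside one long high-identity block
        out = []
        i = 0
        while i < n:
            if ref_pos[i] == _I:
                i += 1
                continue
            s = i
            i += 1
            while i < n and ref_pos[i] != _I and ref_pos[i] == ref_pos[i - 1] + 1:
                i += 1
            out.append((s, i))
        return out

    def identity(s: int, e: int) -> float:
        m = sum(query[k] == ref_seq[int(ref_pos[k]) - 1] for k in range(s, e))
        return m / (e - s)

    segs = segments()
    if not segs:
        return ref_pos
    for direction in (1, -1):
        ordered = list(reversed(segs)) if direction == 1 else list(segs)
        for s, e in ordered:
            if e - s >= min_strong_len and identity(s, e) >= min_strong_identity:
                break
            ref_pos[s:e] = _I
        segs = [seg for seg in segments() if True]
        if not segs:
            return ref_pos

    # boundary trim of runs touching the query ends
    w = 10
    if ref_pos[-1] == _I:  # 3'-terminal run: trim the preceding segment's tail
        b = n - 1
        while b >= 0 and ref_pos[b] == _I:
            b -= 1
        while b >= w - 1 and all(ref_pos[b - k] != _I for k in range(w)):
            matches = sum(
                query[b - k] == ref_seq[int(ref_pos[b - k]) - 1] for k in range(w)
            )
            if matches >= 8:
                break
            ref_pos[b] = _I
            b -= 1
    if ref_pos[0] == _I:  # 5'-terminal run: trim the following segment's head
        b = 0
        while b < n and ref_pos[b] == _I:
            b += 1
        while b <= n - w and all(ref_pos[b + k] != _I for k in range(w)):
            matches = sum(
                query[b + k] == ref_seq[int(ref_pos[b + k]) - 1] for k in range(w)
            )
            if matches >= 8:
                break
            ref_pos[b] = _I
            b += 1
    return ref_pos


def _rebalance_runs(ref_pos, query: str, ref_seq: str, max_jump: int = 12) -> None:
    """Re-anchor insertion-run boundaries against adjacent reference deletions.

    When diverged exon bases near a junction are eroded into the gap, the run
    grows while the matching reference positions go unmapped (a deletion
    right next to the insertion).  For each run whose flanking reference
    coordinates jump by ``jump + 1``, reattach ``jump`` boundary bases to the
    unmapped reference positions, splitting them between the two ends so as
    to maximise the number of restored matches; this recovers the exact
    exon/intron partition.  Modifies ``ref_pos`` in place.
    """
    from .reference import INSERTED as _I

    n = len(ref_pos)
    i = 0
    while i < n:
        if ref_pos[i] != _I:
            i += 1
            continue
        s = i
        while i < n and ref_pos[i] == _I:
            i += 1
        e = i  # run is 0-based [s, e)
        if s == 0 or e == n:
            continue  # truncated runs have no two-sided frame
        rbefore = int(ref_pos[s - 1])
        rafter = int(ref_pos[e])
        jump = rafter - rbefore - 1
        if jump <= 0 or jump > max_jump or e - s <= jump:
            continue
        best_j5, best_score = 0, -1
        for j5 in range(jump + 1):  # j5 bases reattach 5', jump - j5 reattach 3'
            j3 = jump - j5
            score = sum(
                query[s + k] == ref_seq[rbefore + k] for k in range(j5)
            ) + sum(
                query[e - j3 + k] == ref_seq[rafter - 1 - j3 + k] for k in range(j3)
            )
            if score > best_score:
                best_j5, best_score = j5, score
        for k in range(best_j5):
            ref_pos[s + k] = rbefore + 1 + k
        j3 = jump - best_j5
        for k in range(j3):
            ref_pos[e - j3 + k] = rafter - j3 + k


def detect_insertions(
    query: str,
    ref: ReferenceModel,
    min_insert: int = 12,
    host_id: str = "query",
    scoring: AlignmentScoring | None = None,
    snap_tolerance: int = 3,
    cmap: CoordinateMap | None = None,
    min_anchor: int = 6,
) -> list[IntronCall]:
    """Detect insertions >= ``min_insert`` nt in a 16S gene, sorted by locus.

    Inserted runs are cleaned up in three steps before calling: short mapped
    islands inside insertions are merged, run boundaries are re-anchored
    against adjacent reference deletions, and runs are left-aligned to their
    smallest reference coordinate.  The raw locus (reference coordinate
    directly before the run) is then snapped to the canonical locus set
    within ``snap_tolerance`` nt.  A second run snapping to an already-used
    locus in the same gene is kept as a novel locus with a warning.  Runs
    abutting the query ends are marked truncated.
    """
    query = query.upper()
    if cmap is None:
        cmap = align_to_reference(query, ref, scoring=scoring, query_id=host_id)
    ref_pos = _absorb_terminal_junk(cmap.ref_positions, query, ref.sequence)
    ref_pos = _merge_islands(ref_pos, min_anchor=min_anchor)
    _rebalance_runs(ref_pos, query, ref.sequence)
    ref_pos = _left_align_insertions(ref_pos, query)
    cmap = CoordinateMap(query_id=host_id, ref_positions=ref_pos, score=cmap.score)
    calls: list[IntronCall] = []
    seen: set[int] = set()
    for start, end in cmap.inserted_runs():
        if end - start + 1 < min_insert:
            continue
        truncated = start == 1 or end == cmap.query_length
        if start == 1:
            # 5'-truncated: place the locus just before the first mapped base
            nxt = cmap.ref_positions[end] if end < cmap.query_length else 1
            raw_locus = max(int(nxt) - 1, 1)
        else:
            raw_locus = int(cmap.ref_positions[start - 2])
        if truncated:
            # no second junction to anchor the boundary: snap to the nearest
            # canonical locus within a wider window instead of requiring a
            # unique hit
            near = min(CANONICAL_LOCI, key=lambda c: (abs(raw_locus - c), c))
            if abs(raw_locus - near) <= max(snap_tolerance, 6):
                locus = Locus(position=near, canonical=True)
            else:
                locus = Locus(position=raw_locus, canonical=False)
        else:
            locus = snap_to_canonical(raw_locus, tolerance=snap_tolerance)
        if locus.position in seen:
            warnings.warn(
                f"{host_id}: second insertion at locus {locus.position}; kept as novel",
                stacklevel=2,
            )
            locus = Locus(position=locus.position, canonical=False)
        seen.add(locus.position)
        calls.append(
            IntronCall(
                host_id=host_id,
                locus=locus,
                host_start=start,
                host_end=end,
                sequence=query[start - 1 : end],
                upstream_flank=query[max(start - 1 - FLANK_LEN, 0) : start - 1],
                downstream_flank=query[end : end + FLANK_LEN],
                truncated=truncated,
            )
        )
    calls.sort(key=lambda c: c.locus.position)
    return calls


def excise_and_ligate(query: str, calls: list[IntronCall]) -> str:
    """Remove all call spans from ``query`` and join the exons in order."""
    if not calls:
        return query
    ordered = sorted(calls, key=lambda c: c.host_start)
    prev_end = 0
    pieces = []
    for call in ordered:
        if call.host_start <= prev_end:
            raise ValueError(
                f"overlapping calls at host positions {call.host_start} <= {prev_end}"
            )
        pieces.append(query[prev_end : call.host_start - 1])
        prev_end = call.host_end
    pieces.append(query[prev_end:])
    return "".join(pieces)


def calls_to_gff3(calls: list[IntronCall]) -> str:
    """Render calls as GFF3 (type=intron, 1-based inclusive spans)."""
    lines = ["##gff-version 3"]
    for c in sorted(calls, key=lambda c: (c.host_id, c.host_start)):
        attrs = (
            f"locus={c.locus.position};length={c.length};"
            f"canonical={'true' if c.locus.canonical else 'false'};"
            f"truncated={'true' if c.truncated else 'false'}"
        )
        lines.append(
            "\t".join(
                [
                    c.host_id,
                    "ssuintrons",
                    "intron",
                    str(c.host_start),
                    str(c.host_end),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def calls_to_tsv(calls: list[IntronCall]) -> str:
    lines = ["host_id\tlocus\tcanonical\thost_start\thost_end\tlength\ttruncated"]
    for c in sorted(calls, key=lambda c: (c.host_id, c.host_start)):
        lines.append(
            f"{c.host_id}\t{c.locus.position}\t{int(c.locus.canonical)}\t"
            f"{c.host_start}\t{c.host_end}\t{c.length}\t{int(c.truncated)}"
        )
    return "\n".join(lines) + "\n"


def calls_to_fasta(calls: list[IntronCall]) -> str:
    """Intron sequences as FASTA with ``hostID|locusN`` headers."""
    out = []
    for c in sorted(calls, key=lambda c: (c.host_id, c.host_start)):
        out.append(f">{c.host_id}|locus{c.locus.position}")
        for i in range(0, len(c.sequence), 70):
            out.append(c.sequence[i : i + 70])
    return "\n".join(out) + "\n"
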