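"""Coordinate frame for 16S rRNA insertion-locus analysis.

All positions in this package are expressed in the coordinate system of a
packaged intron-free 16S rRNA gene ("reference numbering", 1-based, closed
intervals).  This module owns the packaged reference and its hypervariable
(V1-V9) interval table, semi-global query-to-reference alignment, the
query<->reference position map, V-region lookup, and tandem-locus geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "CANONICAL_LOCI",
    "ReferenceModel",
    "CoordinateMap",
    "Locus",
    "AlignmentScoring",
    "load_reference",
    "align_to_reference",
    "map_position",
    "v_region_of",
    "find_tandem_loci",
]

#: Canonical insertion loci (position directly before the insertion point).
CANONICAL_LOCI = frozenset(
    {374, 548, 722, 781, 803, 901, 908, 919, 978, 1093, 1205, 1213, 1391}
)

#: Sentinel stored in a CoordinateMap for query positions with no reference
#: coordinate (inserted relative to the reference).
INSERTED = 0

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


@dataclass(frozen=True)
class Locus:
    """An insertion locus: the reference position directly before the insertion."""

    position: int
    canonical: bool = False

    def __int__(self) -> int:
        return self.position


@dataclass(frozen=True)
class ReferenceModel:
    """Packaged intron-free reference gene plus its V-region intervals."""

    id: str
    sequence: str
    v_regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if set(self.sequence) - _DNA:
            raise ValueError("reference sequence contains non-ACGT characters")
        prev_end = 0
        for name, start, end in self.v_regions:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(f"V-region {name} outside reference bounds")
            if start <= prev_end:
                raise ValueError(f"V-region {name} overlaps or is unsorted")
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CoordinateMap:
    """Per-query-position reference coordinates from a semi-global alignment.

    ``ref_positions[i]`` is the 1-based reference coordinate of 1-based query
    position ``i + 1``, or ``INSERTED`` (0) when the position is inserted
    relative to the reference.  Mapped coordinates are strictly increasing.
    """

    query_id: str
    ref_positions: np.ndarray
    score: float

    def __post_init__(self) -> None:
        mapped = self.ref_positions[self.ref_positions != INSERTED]
        if len(mapped) > 1 and not np.all(np.diff(mapped) > 0):
            raise ValueError("mapped reference positions must be strictly increasing")

    @property
    def query_length(self) -> int:
        return len(self.ref_positions)

    def inserted_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of inserted query positions as 1-based (start, end)."""
        runs: list[tuple[int, int]] = []
        start = None
        for i, r in enumerate(self.ref_positions):
            if r == INSERTED:
                if start is None:
                    start = i + 1
            elif start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(self.ref_positions)))
        return runs

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("query_pos\tref_pos\n")
            for i, r in enumerate(self.ref_positions, 1):
                fh.write(f"{i}\t{'I' if r == INSERTED else int(r)}\n")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring for query-to-reference alignment.

    Defaults favour one long gap per insertion over many short gaps.  ``N``
    scores as a mismatch against everything (including ``N``) so that locus
    placement stays conservative.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -10.0
    # kept small so a long internal insertion is always cheaper than dumping
    # the downstream exon into a free terminal gap (a ~900-nt intron after
    # locus 1391 must not out-cost the final ~150 nt of aligned exon)
    gap_extend: float = -0.1


def _substitution_matrix(scoring: AlignmentScoring):
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                m[a, b] = scoring.match
            else:
                m[a, b] = scoring.mismatch
    return m


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(scoring)
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # Semi-global: terminal gaps are free on both sequences, so partial genes
    # and queries longer than the reference are not penalised at the ends.
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def load_reference() -> ReferenceModel:
    """Load the packaged reference gene and V-region table."""
    data = resources.files("ssuintrons.data")
    lines = (data / "reference_16s.fasta").read_text().splitlines()
    ref_id = lines[0][1:].split()[0]
    seq = "".join(lines[1:])
    v_regions = []
    for line in (data / "v_regions.tsv").read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, start, end, _source = line.split("\t")
        v_regions.append((name, int(start), int(end)))
    return ReferenceModel(id=ref_id, sequence=seq, v_regions=tuple(v_regions))


def load_curated_loci() -> list[dict]:
    """Packaged curated per-locus intron inventory.

    One row per canonical locus with homing-endonuclease CDS counts (split by
    motif copy number), hairpin and PRU counts, spanning primer names, and an
    ambiguity flag for rows whose hairpin/PRU split is uncertain in the
    source table.
    """
    text = (resources.files("ssuintrons.data") / "curated_loci.tsv").read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("locus\t"):
            continue
        locus, cds, m1, m2, hp, pru, primers, ambiguous = line.split("\t")
        rows.append(
            {
                "locus": int(locus),
                "cds": int(cds),
                "motifs1": int(m1),
                "motifs2": int(m2),
                "hp": int(hp),
                "pru": int(pru),
                "primers": [] if primers == "-" else primers.split(";"),
                "ambiguous": bool(int(ambiguous)),
            }
        )
    return rows


def _left_align_insertions(ref_pos: np.ndarray, query: str) -> np.ndarray:
    """Normalise each inserted run to its smallest reference coordinate.

    An insertion adjacent to a repeat is ambiguous; shifting is allowed while
    the base entering the run from the left equals the base leaving it on the
    right, which keeps the implied excised sequence identical.
    """
    ref_pos = ref_pos.copy()
    changed = True
    while changed:
        changed = False
        # runs as 0-based [s, e)
        i = 0
        n = len(ref_pos)
        while i < n:
            if ref_pos[i] != INSERTED:
                i += 1
                continue
            s = i
            while i < n and ref_pos[i] == INSERTED:
                i += 1
            e = i
            if e == n:
                continue  # terminal runs have no 3' anchor; rotation is spurious
            while s > 0 and ref_pos[s - 1] != INSERTED and query[s - 1] == query[e - 1]:
                ref_pos[e - 1] = ref_pos[s - 1]
                ref_pos[s - 1] = INSERTED
                s -= 1
                e -= 1
                changed = True
    return ref_pos


def align_to_reference(
    query: str,
    ref: ReferenceModel,
    scoring: AlignmentScoring | None = None,
    query_id: str = "query",
) -> CoordinateMap:
    """Semi-globally align ``query`` to the reference and build a position map.

    Terminal gaps are free (partial genes align without penalty); internal
    gaps use an affine model.  Query positions falling in a gap against the
    reference are flagged inserted-relative-to-reference; inserted runs are
    left-aligned to their smallest reference coordinate.

    Raises
    ------
    ValueError
        If the query is shorter than 200 nt or contains characters outside
        ``{A, C, G, T, N}``.
    """
    query = query.upper()
    if len(query) < 200:
        raise ValueError(f"query too short ({len(query)} nt < 200 nt)")
    bad = set(query) - _DNA_N
    if bad:
        raise ValueError(f"query contains non-nucleotide characters: {sorted(bad)}")
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    alignment = aligner.align(ref.sequence, query)[0]

    ref_pos = np.zeros(len(query), dtype=np.int32)
    for (t_start, t_end), (q_start, q_end) in zip(*alignment.aligned):
        ref_pos[q_start:q_end] = np.arange(t_start + 1, t_end + 1, dtype=np.int32)
    ref_pos = _left_align_insertions(ref_pos, query)
    return CoordinateMap(query_id=query_id, ref_positions=ref_pos, score=alignment.score)


def map_position(cmap: CoordinateMap, query_pos: int) -> int | None:
    """Reference coordinate of a 1-based query position, or None if inserted."""
    if not 1 <= query_pos <= cmap.query_length:
        raise ValueError(f"query position {query_pos} outside [1, {cmap.query_length}]")
    r = cmap.ref_positions[query_pos - 1]
    return None if r == INSERTED else int(r)


def v_region_of(ref: ReferenceModel, position: int) -> str | None:
    """Name of the V-region containing ``position``, or None."""
    if not 1 <= position <= len(ref):
        raise ValueError(f"position {position} outside [1, {len(ref)}]")
    for name, start, end in ref.v_regions:
        if start <= position <= end:
            return name
    return None


def find_tandem_loci(
    loci: Iterable[Locus | int], max_gap: int
) -> list[tuple[int, int, int]]:
    """Pairs of nearby loci ``(a, b, separation)`` with ``b - a <= max_gap``.

    Under the position-directly-before-insertion convention the separation
    ``b - a`` equals the number of exon nucleotides strictly between the two
    insertion points.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    positions = sorted({int(l) for l in loci})
    out = []
    for i, a in enumerate(positions):
        for b in positions[i + 1 :]:
            if b - a <= max_gap:
                out.append((a, b, b - a))
            else:
                break
    return out
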