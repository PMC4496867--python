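"""In-silico audit of degenerate "universal" primers against insertion loci.

A primer footprint spans locus ``L`` iff ``ref_start <= L < ref_end``: the
insertion point between ``L`` and ``L+1`` then lies strictly inside the
annealing region.  An insertion at the footprint's terminal 3' boundary does
not count as an interruption.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .detection import IntronCall
from .reference import Locus, ReferenceModel

__all__ = [
    "Primer",
    "PrimerFootprint",
    "PrimerAuditRecord",
    "AmpliconReport",
    "match_primer",
    "best_footprint",
    "audit_primer_set",
    "amplicon_intron_content",
    "read_primer_tsv",
    "load_primer_locus_map",
    "expand_degenerate",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    orientation: str  # F | R

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: invalid IUPAC characters {sorted(bad)}")
        if not 15 <= len(seq) <= 30:
            raise ValueError(f"primer {self.name}: length {len(seq)} outside 15-30")
        if self.orientation not in ("F", "R"):
            raise ValueError(f"primer {self.name}: orientation must be F or R")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class PrimerFootprint:
    """Ungapped placement of a primer on forward-strand reference coordinates."""

    name: str
    ref_start: int
    ref_end: int
    mismatches: int


@dataclass(frozen=True)
class PrimerAuditRecord:
    name: str
    loci_spanned: tuple[int, ...]
    interrupted: bool


@dataclass(frozen=True)
class AmpliconReport:
    amplifies: bool
    exon_start: int | None = None
    exon_end: int | None = None
    exon_length: int | None = None
    introns_contained: tuple[int, ...] = ()
    inflated_length: int | None = None


def reverse_complement_iupac(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def expand_degenerate(seq: str) -> list[str]:
    """All concrete ACGT sequences compatible with an IUPAC sequence."""
    return ["".join(p) for p in itertools.product(*(IUPAC[b] for b in seq.upper()))]


def match_primer(
    primer: Primer, ref: ReferenceModel, max_mismatch: int = 1
) -> list[PrimerFootprint]:
    """All ungapped placements of a primer with at most ``max_mismatch``.

    A primer code matches a reference base iff the base belongs to the code's
    set.  Reverse-orientation primers are matched as their reverse complement;
    footprints are always reported on forward-strand coordinates, sorted by
    (mismatches, ref_start).
    """
    probe = primer.sequence if primer.orientation == "F" else reverse_complement_iupac(
        primer.sequence
    )
    sets = [IUPAC[b] for b in probe]
    k = len(probe)
    refseq = ref.sequence
    hits = []
    for s in range(len(refseq) - k + 1):
        mm = 0
        for j in range(k):
            if refseq[s + j] not in sets[j]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(PrimerFootprint(primer.name, s + 1, s + k, mm))
    hits.sort(key=lambda f: (f.mismatches, f.ref_start))
    return hits


def best_footprint(footprints: Sequence[PrimerFootprint]) -> PrimerFootprint | None:
    """Fewest mismatches, then smallest start."""
    if not footprints:
        return None
    return min(footprints, key=lambda f: (f.mismatches, f.ref_start))


def footprint_spans(footprint: PrimerFootprint, locus: int) -> bool:
    return footprint.ref_start <= locus < footprint.ref_end


def audit_primer_set(
    footprints: Sequence[PrimerFootprint], loci: Iterable[Locus | int]
) -> list[PrimerAuditRecord]:
    """One record per footprint; interrupted iff it spans >= 1 locus."""
    positions = sorted({int(l) for l in loci})
    records = []
    for fp in footprints:
        spanned = tuple(L for L in positions if footprint_spans(fp, L))
        records.append(PrimerAuditRecord(fp.name, spanned, bool(spanned)))
    records.sort(key=lambda r: r.name)
    return records


def amplicon_intron_content(
    fwd: PrimerFootprint,
    rev: PrimerFootprint,
    calls: Sequence[IntronCall],
) -> AmpliconReport:
    """Predict the intron content of the amplicon framed by two footprints.

    A primer whose footprint spans a locus occupied by an intron in this gene
    cannot anneal contiguously, so the outcome is a no-amplification report
    rather than an error.
    """
    if fwd.ref_start >= rev.ref_start:
        raise ValueError("forward footprint must start before reverse footprint")
    occupied = [c.locus.position for c in calls]
    for fp in (fwd, rev):
        if any(footprint_spans(fp, L) for L in occupied):
            return AmpliconReport(amplifies=False)
    exon_start, exon_end = fwd.ref_start, rev.ref_end
    contained = tuple(
        sorted(
            c.locus.position
            for c in calls
            if exon_start <= c.locus.position < exon_end
        )
    )
    exon_len = exon_end - exon_start + 1
    intron_nt = sum(c.length for c in calls if c.locus.position in contained)
    return AmpliconReport(
        amplifies=True,
        exon_start=exon_start,
        exon_end=exon_end,
        exon_length=exon_len,
        introns_contained=contained,
        inflated_length=exon_len + intron_nt,
    )


def read_primer_tsv(path) -> list[Primer]:
    """Read a 3-column TSV: name, IUPAC sequence, orientation (F/R)."""
    primers = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            name, seq, orient = line.split("\t")[:3]
            primers.append(Primer(name, seq, orient))
    return primers


def load_primer_locus_map() -> dict[str, list[int]]:
    """Packaged curated mapping: primer name -> insertion loci it spans."""
    text = (resources.files("ssuintrons.data") / "curated_loci.tsv").read_text()
    mapping: dict[str, list[int]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("locus\t"):
            continue
        fields = line.split("\t")
        locus, primers = int(fields[0]), fields[6]
        if primers == "-":
            continue
        for name in primers.split(";"):
            mapping.setdefault(name, []).append(locus)
    return {k: sorted(v) for k, v in mapping.items()}


def audit_summary_json(records: Sequence[PrimerAuditRecord]) -> str:
    summary = {
        "n_primers": len(records),
        "interrupted_ge1": sum(1 for r in records if len(r.loci_spanned) >= 1),
        "interrupted_ge2": sum(1 for r in records if len(r.loci_spanned) >= 2),
    }
    return json.dumps(summary, indent=2, sort_keys=True)
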