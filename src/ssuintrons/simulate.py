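"""Synthetic 16S genes with planted introns and full ground truth.

Hosts are seeded substitution variants of the packaged reference (no exon
indels, so locus truth is exact).  Planted introns emulate the described
sequence properties: homing-endonuclease introns carry an ORF with one or two
LAGLIDADG motif copies, hairpin introns are < 50 nt with complementary arms,
and every non-truncated intron embeds bulge-helix-bulge-forming junction
cores (2-nt bulges + a 4-bp helix pairing the intron's two ends).  GC content
is steered toward a configurable target (default 0.57 vs ~0.67 host exons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import zlib

import numpy as np
from Bio.Data import CodonTable

from .classification import find_orfs
from .reference import CANONICAL_LOCI, ReferenceModel

__all__ = [
    "GeneratorConfig",
    "PlanEntry",
    "TruthRecord",
    "generate_host",
    "generate_intron",
    "generate_dataset",
]

KINDS = ("HE1", "HE2", "HP", "REMNANT", "TRUNCATED")
_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Length ranges (inclusive) per intron kind.
DEFAULT_LENGTH_RANGES = {
    "HE1": (700, 900),
    "HE2": (700, 900),
    "HP": (30, 48),
    "REMNANT": (100, 400),
    "TRUNCATED": (100, 400),
}


@dataclass(frozen=True)
class PlanEntry:
    locus: int
    kind: str
    geography: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown intron kind {self.kind!r}")


@dataclass(frozen=True)
class TruthRecord:
    host_id: str
    locus: int
    kind: str
    start: int  # 1-based inclusive span on the final host sequence
    end: int
    motifs: int
    geography: str | None
    truncated: bool = False


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_hosts: int = 1
    host_divergence: float = 0.05
    loci_plan: tuple[PlanEntry, ...] = ()
    intron_gc: float = 0.57
    length_ranges: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_RANGES))
    geography_divergence: float = 0.10
    within_divergence: float = 0.01

    def __post_init__(self) -> None:
        for entry in self.loci_plan:
            lo, hi = self.length_ranges[entry.kind]
            if entry.kind == "HP" and hi >= 50:
                raise ValueError("HP introns must be < 50 nt")
            if entry.kind in ("HE1", "HE2") and lo < 200:
                raise ValueError("HE introns must be >= 200 nt")


def _gc_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_gc_probs(gc)))


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def generate_host(
    ref: ReferenceModel,
    divergence: float,
    seed: int,
    protect: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Seeded i.i.d. substitution variant of the reference; no indels.

    Positions in ``protect`` (1-based) are never substituted — used for the
    exon stretches flanking planned insertion loci, which are highly
    conserved around real insertion sites.
    """
    if not 0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    seq = np.array(list(ref.sequence))
    hit = rng.random(len(seq)) < divergence
    for i in np.flatnonzero(hit):
        if i + 1 in protect:
            continue
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return "".join(seq)


def _encode_peptide(peptide: str, table_id: int, rng: np.random.Generator, gc: float) -> str:
    """Reverse-translate, choosing GC-steered synonymous codons."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    probs = _gc_probs(gc)
    base_p = {b: probs["ACGT".index(b)] for b in "ACGT"}
    out = []
    for aa in peptide:
        options = by_aa[aa]
        w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in options])
        w /= w.sum()
        out.append(options[rng.choice(len(options), p=w)])
    return "".join(out)


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    # avoid residues that could combine into spurious motif copies too easily
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _build_orf(
    rng: np.random.Generator, n_motifs: int, aa_len: int, gc: float, table_id: int = 11
) -> str:
    """ATG + GC-steered codons encoding a peptide with planted motif copies + stop."""
    motif = "LAGLIDADG"
    peptide = list("M" + _random_peptide(rng, aa_len - 1))
    if n_motifs == 1:
        slots = [aa_len // 2]
    else:
        slots = [aa_len // 4, aa_len // 4 + max(80, aa_len // 2)]
    for s in slots[:n_motifs]:
        peptide[s : s + len(motif)] = motif
    peptide = "".join(peptide)[:aa_len]
    nt = _encode_peptide(peptide, table_id, rng, gc)
    nt = "ATG" + nt[3:]  # force a start codon
    return nt + "TAA"


def _plant_bhb(rng: np.random.Generator, interior: str, gc: float) -> str:
    """Wrap an interior in BHB-forming ends.

    Layout: [2-nt bulge][4-nt helix A][interior][4-nt helix B][2-nt bulge],
    with helix B the reverse complement of helix A so the intron's two ends
    pair into the central helix; each 2-nt bulge plus one adjacent exon base
    forms an excision-site bulge.
    """
    helix_a = "".join(rng.choice(_BASES, size=4, p=_gc_probs(max(gc, 0.6))))
    bulge1 = _random_seq(rng, 2, gc)
    bulge2 = _random_seq(rng, 2, gc)
    return bulge1 + helix_a + interior + _revcomp(helix_a) + bulge2


def _has_orf(seq: str, min_aa: int = 50) -> bool:
    return len(seq) >= 3 * min_aa and bool(find_orfs(seq, min_aa=min_aa))


def generate_intron(
    kind: str,
    locus: int,
    config: GeneratorConfig,
    seed: int | np.random.Generator,
    exon5: str = "G",
    exon3: str = "G",
) -> tuple[str, TruthRecord]:
    """One planted intron of the given kind, with its truth record.

    ``exon5``/``exon3`` are the host exon flanks at the insertion point (the
    last base of ``exon5`` is the locus base); they anchor the planted
    junction bulges and are used to keep the insertion left-alignable to its
    true position (the intron never ends with the locus base).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown intron kind {kind!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = config.length_ranges[kind]
    if kind == "HP" and hi >= 50:
        raise ValueError("HP introns must be < 50 nt")
    length = int(rng.integers(lo, hi + 1))
    gc = config.intron_gc
    motifs = 0

    if kind in ("HE1", "HE2"):
        motifs = 1 if kind == "HE1" else 2
        aa_len = max(150, (length - 120) // 3 - 20)
        orf = _build_orf(rng, motifs, aa_len, gc)
        pad = length - 12 - len(orf)
        if pad < 6:
            length = 12 + len(orf) + 40
            pad = 40
        pre = pad // 2
        interior = _random_seq(rng, pre, gc) + orf + _random_seq(rng, pad - pre, gc)
    elif kind == "HP":
        interior_len = length - 12
        arm = (interior_len - 3) // 2
        loop = interior_len - 2 * arm
        arm_seq = _random_seq(rng, arm, max(gc, 0.6))
        interior = arm_seq + _random_seq(rng, loop, gc) + _revcomp(arm_seq)
    else:  # REMNANT / TRUNCATED
        for _ in range(200):
            interior = _random_seq(rng, length - 12, gc)
            if not _has_orf(interior):
                break
        else:
            raise RuntimeError("could not draw an ORF-free remnant interior")

    seq = _plant_bhb(rng, interior, gc)
    # keep the insertion left-alignable to its true locus
    locus_base = exon5[-1]
    if seq[-1] == locus_base:
        repl = [b for b in "ACGT" if b != locus_base]
        seq = seq[:-1] + repl[int(rng.integers(0, 3))]
    truth = TruthRecord(
        host_id="",
        locus=locus,
        kind=kind,
        start=0,
        end=0,
        motifs=motifs,
        geography=None,
        truncated=(kind == "TRUNCATED"),
    )
    return seq, truth


def _mutable_positions(seq: str, kind: str, motifs: int) -> np.ndarray:
    """Interior positions free to mutate without destroying planted evidence.

    Junction cores (first/last 6 nt) are always frozen; for HE introns the
    whole ORF region is frozen too (only the flanking spacers drift)."""
    n = len(seq)
    mask = np.ones(n, dtype=bool)
    mask[:6] = False
    mask[-6:] = False
    if kind in ("HE1", "HE2"):
        orfs = find_orfs(seq, min_aa=50)
        if orfs:
            best = orfs[0]
            mask[best.start - 1 : best.end] = False
    return np.flatnonzero(mask)


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray, rate: float) -> str:
    s = list(seq)
    for i in positions:
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != s[i]]
            s[i] = choices[rng.integers(0, 3)]
    return "".join(s)


def generate_dataset(
    config: GeneratorConfig, ref: ReferenceModel
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Hosts with planted introns per the loci plan, plus the truth table.

    Plan entries are dealt round-robin over ``n_hosts`` hosts, never placing
    two introns at one locus on the same host; truncated entries each get a
    dedicated fragment host (cut inside the intron, removing its 3'
    junction).  Introns planted at the same (locus, kind) share a common
    ancestor whose interior then receives geography-group substitutions and
    per-member noise — junction cores and HE ORFs stay intact, so per-locus
    trees can recover the planted geographic clades.
    """
    for e in config.loci_plan:
        if e.locus not in CANONICAL_LOCI and not 1 <= e.locus <= len(ref):
            raise ValueError(f"locus {e.locus} outside the reference frame")
    rng = np.random.default_rng(config.seed)
    # conserved exon cores around every planned locus (insertion-site flanks
    # are highly conserved in real genes; also keeps junctions alignable)
    protect = frozenset(
        p
        for e in config.loci_plan
        for p in range(max(e.locus - 9, 1), min(e.locus + 11, 1543))
    )
    regular = [e for e in config.loci_plan if e.kind != "TRUNCATED"]
    truncated = [e for e in config.loci_plan if e.kind == "TRUNCATED"]

    # host assignment, no duplicate locus per host
    host_entries: dict[int, list[PlanEntry]] = {i: [] for i in range(config.n_hosts)}
    for idx, entry in enumerate(regular):
        for offset in range(config.n_hosts):
            h = (idx + offset) % config.n_hosts
            if all(e.locus != entry.locus for e in host_entries[h]):
                host_entries[h].append(entry)
                break
        else:
            raise ValueError(f"cannot place a second intron at locus {entry.locus}: "
                             f"every host already carries one")

    # one ancestral intron per (locus, kind), shared by all members
    ancestors: dict[tuple[int, str], tuple[str, TruthRecord]] = {}

    hosts: dict[str, str] = {}
    truth: list[TruthRecord] = []

    def realize(entry: PlanEntry, host_seq: str, host_id: str) -> tuple[str, TruthRecord]:
        exon5 = host_seq[: entry.locus][-15:]
        exon3 = host_seq[entry.locus : entry.locus + 15]
        key = (entry.locus, entry.kind)
        if key not in ancestors:
            ancestors[key] = generate_intron(
                entry.kind, entry.locus, config, rng, exon5=exon5, exon3=exon3
            )
        base_seq, base_truth = ancestors[key]
        positions = _mutable_positions(base_seq, entry.kind, base_truth.motifs)
        seq = base_seq
        if entry.geography is not None:
            geo_rng = np.random.default_rng(
                (config.seed, zlib.crc32(entry.geography.encode()), entry.locus)
            )
            seq = _mutate(geo_rng, seq, positions, config.geography_divergence)
        for _ in range(50):
            cand = _mutate(rng, seq, positions, config.within_divergence)
            if entry.kind in ("REMNANT", "TRUNCATED") and _has_orf(cand):
                continue  # drift created a spurious ORF; redraw
            seq = cand
            break
        if seq[-1] == exon5[-1]:
            repl = [b for b in "ACGT" if b != exon5[-1]]
            seq = seq[:-1] + repl[int(rng.integers(0, 3))]
        rec = replace(base_truth, host_id=host_id, geography=entry.geography)
        return seq, rec

    for h in range(config.n_hosts):
        host_id = f"host{h:03d}"
        host_seq = generate_host(ref, config.host_divergence, int(rng.integers(0, 2**31)), protect=protect)
        entries = sorted(host_entries[h], key=lambda e: -e.locus)
        final = host_seq
        placed: list[tuple[PlanEntry, str, TruthRecord]] = []
        for entry in entries:  # insert right-to-left so loci stay valid
            seq, rec = realize(entry, host_seq, host_id)
            final = final[: entry.locus] + seq + final[entry.locus :]
            placed.append((entry, seq, rec))
        hosts[host_id] = final
        # spans on the final host coordinates
        placed.sort(key=lambda t: t[0].locus)
        offset = 0
        for entry, seq, rec in placed:
            start = entry.locus + offset + 1
            truth.append(replace(rec, start=start, end=start + len(seq) - 1))
            offset += len(seq)

    for t_idx, entry in enumerate(truncated):
        host_id = f"hostT{t_idx:02d}"
        host_seq = generate_host(ref, config.host_divergence, int(rng.integers(0, 2**31)), protect=protect)
        seq, rec = realize(entry, host_seq, host_id)
        cut = entry.locus + len(seq) // 2  # fragment ends inside the intron
        final = host_seq[: entry.locus] + seq
        final = final[:cut]
        hosts[host_id] = final
        truth.append(
            replace(rec, host_id=host_id, start=entry.locus + 1, end=len(final), truncated=True)
        )

    return hosts, truth


def write_fasta(hosts: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in hosts.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(truth: list[TruthRecord], config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed} n_hosts={config.n_hosts} "
                 f"host_divergence={config.host_divergence} intron_gc={config.intron_gc}\n")
        fh.write("host_id\tlocus\tkind\tstart\tend\tmotifs\tgeography\ttruncated\n")
        for t in truth:
            fh.write(
                f"{t.host_id}\t{t.locus}\t{t.kind}\t{t.start}\t{t.end}\t"
                f"{t.motifs}\t{t.geography or '-'}\t{int(t.truncated)}\n"
            )
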