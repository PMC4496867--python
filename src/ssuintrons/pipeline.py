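"""End-to-end orchestration: detect -> classify -> primer audit -> summary."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import classification, detection, primers, reference

__all__ = ["PipelineReport", "run_pipeline", "read_fasta"]


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


@dataclass
class PipelineReport:
    locus_counts: dict[int, dict[str, int]]  # locus -> {HE, HP, REMNANT, PRU}
    primer_audit: list[primers.PrimerAuditRecord]
    tandem_loci: list[tuple[int, int, int]]
    gc_mean: float | None
    gc_sd: float | None
    files: list[str] = field(default_factory=list)

    @property
    def total_calls(self) -> int:
        return sum(sum(v.values()) for v in self.locus_counts.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "locus_counts": {
                    str(k): v for k, v in sorted(self.locus_counts.items())
                },
                "total_calls": self.total_calls,
                "primer_audit": [
                    {
                        "name": r.name,
                        "loci_spanned": list(r.loci_spanned),
                        "interrupted": r.interrupted,
                    }
                    for r in self.primer_audit
                ],
                "tandem_loci": [list(t) for t in self.tandem_loci],
                "gc_mean_pct": self.gc_mean,
                "gc_sd_pct": self.gc_sd,
                "files": self.files,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline(
    genes: dict[str, str],
    primer_list: list[primers.Primer] | None = None,
    min_insert: int = 12,
    max_mismatch: int = 1,
    tandem_max_gap: int = 10,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run detection, classification and the primer audit over a gene set.

    Deterministic for fixed inputs; ``out_dir`` (optional) receives the GFF3
    call table, classification TSV, intron FASTA and a JSON report.
    """
    if not genes:
        raise ValueError("empty input: no gene sequences")
    ref = reference.load_reference()

    all_calls: list[detection.IntronCall] = []
    classifications: list[tuple[detection.IntronCall, classification.IntronClassification]] = []
    for host_id, seq in genes.items():
        calls = detection.detect_insertions(seq, ref, min_insert=min_insert, host_id=host_id)
        for call in calls:
            cls = classification.classify_intron(call)
            classifications.append((call, cls))
        all_calls.extend(calls)

    locus_counts: dict[int, dict[str, int]] = {}
    for call, cls in classifications:
        bucket = locus_counts.setdefault(
            call.locus.position, {"HE": 0, "HP": 0, "REMNANT": 0, "PRU": 0}
        )
        bucket[cls.category] += 1

    audit: list[primers.PrimerAuditRecord] = []
    if primer_list:
        observed_loci = sorted(locus_counts)
        best = []
        for p in primer_list:
            fp = primers.best_footprint(primers.match_primer(p, ref, max_mismatch=max_mismatch))
            if fp is not None:
                best.append(fp)
        audit = primers.audit_primer_set(best, observed_loci)

    tandem = reference.find_tandem_loci(sorted(locus_counts), max_gap=tandem_max_gap)

    gc_mean = gc_sd = None
    if all_calls:
        gc_mean, gc_sd = classification.gc_summary([c.sequence for c in all_calls])

    files: list[str] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "calls.gff3").write_text(detection.calls_to_gff3(all_calls))
        (out / "calls.tsv").write_text(detection.calls_to_tsv(all_calls))
        if all_calls:
            (out / "introns.fasta").write_text(detection.calls_to_fasta(all_calls))
        lines = [
            "host_id\tlocus\tlength\tcategory\tmotif_count\torf_span\t"
            "paired_fraction\tbhb_helix\tgc"
        ]
        for call, cls in classifications:
            orf_span = f"{cls.orf.start}-{cls.orf.end}" if cls.orf else "-"
            pf = f"{cls.hairpin[1]:.3f}" if cls.hairpin else "-"
            bh = str(cls.bhb.helix_len) if cls.bhb else "-"
            mc = str(cls.motif_scan.count) if cls.motif_scan else "0"
            lines.append(
                f"{call.host_id}\t{call.locus.position}\t{call.length}\t"
                f"{cls.category}\t{mc}\t{orf_span}\t{pf}\t{bh}\t{cls.gc:.4f}"
            )
        (out / "classification.tsv").write_text("\n".join(lines) + "\n")
        files = sorted(p.name for p in out.iterdir())

    report = PipelineReport(
        locus_counts=locus_counts,
        primer_audit=audit,
        tandem_loci=tandem,
        gc_mean=gc_mean,
        gc_sd=gc_sd,
        files=files,
    )
    if out_dir is not None:
        (Path(out_dir) / "report.json").write_text(report.to_json())
        report.files = sorted(p.name for p in Path(out_dir).iterdir())
    return report
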