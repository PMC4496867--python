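# ssuintrons

Detection, classification and analysis of introns in 16S (SSU) rRNA genes,
with a ground-truth synthetic data generator so the whole pipeline is
testable offline.

Intron insertions are called structurally — by semi-global alignment of a
gene against a packaged intron-free reference frame — and located by the
reference position directly before the insertion point. Calls are then
classified into four categories:

| category  | meaning |
|-----------|---------|
| `HE`      | encodes a homing endonuclease: an ORF (>= 50 aa) carrying one (homodimer form) or two (monomer form) LAGLIDADG-style motif copies |
| `HP`      | short (< 50 nt) hairpin-forming intron that maintains the bulge-helix-bulge (BHB) junction motif |
| `REMNANT` | intact junctions but no qualifying ORF |
| `PRU`     | partial (truncated by a fragment end) or otherwise uncharacterized |

Additional components:

- **reference frame** (`ssuintrons.reference`) — packaged 1,542-nt reference
  with V1–V9 hypervariable intervals, coordinate maps, V-region lookup, and
  tandem-locus geometry (e.g. loci 901/908 are separated by 7 exon nt,
  1205/1213 by 8).
- **primer audit** (`ssuintrons.primers`) — IUPAC-degenerate primer matching
  against the reference; a footprint `(s, e)` is *interrupted* by locus `L`
  iff `s <= L < e`. Includes amplicon intron-content prediction and a
  curated primer→locus interruption table.
- **per-locus phylogenetics** (`ssuintrons.phylo`) — p/Jukes-Cantor
  distances with pairwise deletion, Saitou–Nei neighbor-joining (exact on
  additive matrices), seeded column-resampling bootstrap supports,
  center-star MSA, and junction position-frequency matrices with per-column
  information content.
- **synthetic data** (`ssuintrons.simulate`) — seeded generator planting
  HE/HP/remnant/truncated introns (GC-steered, BHB junction cores,
  geography-correlated divergence) at the 13 canonical loci
  {374, 548, 722, 781, 803, 901, 908, 919, 978, 1093, 1205, 1213, 1391},
  with a full truth table.

## CLI

```bash
# generate a synthetic dataset with one intron at every canonical locus
ssuintrons simulate --seed 1 --n-hosts 3 --plan all13 --out-dir sim/

# call introns against the packaged reference
ssuintrons detect --input sim/hosts.fasta --min-insert 12 --out calls.gff3

# audit a primer list (3-column TSV: name, IUPAC sequence, F/R)
ssuintrons primers --primers primers.tsv --max-mismatch 1 \
    --out audit.tsv --json-out audit.json

# per-locus NJ tree with bootstrap supports
ssuintrons phylo --input sim/hosts.fasta --locus 1213 \
    --bootstrap 1000 --seed 7 --out tree.nwk

# everything at once, with a JSON report
ssuintrons run-all --input sim/hosts.fasta --primers primers.tsv --out-dir out/
```

Validation errors exit with status 2; logs go to stderr.

## Packaged fixtures (`src/ssuintrons/data/`)

- `reference_16s.fasta` — deterministic 1,542-nt intron-free reference
  frame (GC ≈ 0.67); see the FASTA header for provenance.
- `v_regions.tsv` — V1–V9 intervals with source annotation.
- `curated_loci.tsv` — curated per-locus intron inventory (CDS/HP/PRU
  counts, motif-copy splits, spanning primers); typographically uncertain
  rows are flagged `ambiguous`.
- `demo_primers.tsv` — small demo primer list drawn from the packaged
  reference for end-to-end runs.

## Limitations

- Hosts in the synthetic generator are substitution variants of the packaged
  reference, not real thermophile genomes; exon indel robustness is
  exercised separately through explicit coordinate-map tests.
- Folding is base-pair maximisation (Nussinov) with GU wobble, not
  free-energy minimisation; no pseudoknots, no temperature dependence.
- Trees are neighbor-joining only; the center-star MSA is intended for
  high-identity within-locus sets (cross-locus comparison is refused below
  20 % mean identity).
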