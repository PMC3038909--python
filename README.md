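# conslocus

Locus-scale comparative-genomics toolkit for detecting conserved
non-coding elements in multi-species alignments, characterising
CTCF-binding motifs, and calling segmental duplications from read depth.

## What it does

Regulatory sequence tends to survive as short, strongly conserved
islands in otherwise divergent non-coding DNA. `conslocus` finds those
islands in a gapped alignment of several species with an exact-match
**seed-and-extend** detector:

- **Seed**: a window of `L` consecutive alignment columns in which some
  fixed subset of at least `S` species carries an identical, ungapped,
  N-free `L`-mer.
- **Extend**: each seed is grown column-by-column in both directions
  while at least `E` species share an identical real base in the next
  column (the agreeing subset may change per column).
- Overlapping and book-ended extensions merge; the result is a set of
  disjoint, maximal multi-species conserved sequences (MCSs) reported as
  BED intervals in reference coordinates.

The default setting `L=7, S=5, E=4` ("7-5-4") targets seven-species
mammalian locus alignments. Downstream, the package

- removes MCSs overlapping coding/transcript annotations (whole-element
  removal) to enrich for conserved **non-coding** elements,
- intersects the result with an independent conserved-element track
  (e.g. a phastCons elements BED file) and reports shared elements,
  shared bp and region fractions,
- builds 20-bp **CTCF-binding motif** models (two conserved cores,
  bases 4–8 and 10–18) from orthologous site sets, computes sequence-logo
  information content, scans sequences by log-odds, assigns
  LowOc/MedOc/HighOc occupancy classes, and labels cross-dataset
  occupancy patterns (species-specific vs shared),
- calls **segmental duplications** from windowed read-depth profiles as
  runs of windows exceeding `mu + k*sigma` of a trimmed background, with
  copy-number estimates `2 * depth / background` (diploid baseline),
- and ships a **synthetic-data generator** that produces every input
  type with planted ground truth, so the whole pipeline is testable
  without downloads.

## Worked example

```python
from conslocus import *
from conslocus.synthetic_data import *
from conslocus.intervals import GenomicInterval

spec = SimAlignmentSpec(
    n_species=7, length=4000, background_mismatch=0.5, gap_rate=0.01,
    planted_blocks=[PlantedBlock(500, 530, 6, 0.0),
                    PlantedBlock(1500, 1560, 5, 0.0),
                    PlantedBlock(3000, 3025, 7, 0.0)],
    rng_seed=17, ref_chrom="chrS",
)
aln, truth = simulate_alignment(spec)
mcs, summary = run_exactplus(aln, SeedParams(7, 5, 4))
for m in mcs:
    print(m.ref_chrom, m.ref_start, m.ref_end, m.length_bp, m.min_support)
print(summary)

ann = AnnotationSet([GenomicInterval("chrS", 1490, 1570, "coding", "exon1")])
kept, removed = filter_noncoding(mcs, ann)
print("kept", len(kept), "removed", len(removed))
```

prints

```
chrS 499 539 40 4
chrS 1497 1564 67 4
chrS 2999 3027 28 5
McsSummary(count=3, total_bp=135, min_len=28, max_len=67, mean_len=45.0,
           fraction_of_region=0.0338)
kept 2 removed 1
```

All three planted conserved blocks are recovered (each element extends a
column or two past its block because a background column satisfies the
4-of-7 agreement rule by chance fairly often); the element under the
coding annotation is removed by the non-coding filter; 135 bp of the
4-kb locus (3.4%) is called conserved.

The same steps are available from the shell:

```sh
conslocus simulate alignment --spec spec.json --seed 17 --out aln.fa --truth-out truth.json
conslocus exactplus --aln aln.fa --ref ref --L 7 --S 5 --E 4 --out mcs.bed
conslocus filter --mcs mcs.bed --ann coding.bed --out noncoding.bed
conslocus intersect --a noncoding.bed --b other_track.bed --region chrS:0-4000
conslocus motif build --sites sites.txt --out model.meme
conslocus motif scan --seq target.fa --model model.meme --out hits.bed
conslocus sd-scan --depth depth.bedgraph --w 1000 --k 3 --m 3 --out sd.bed
```

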