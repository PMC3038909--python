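# Methods

## Conserved-element detection

The detector operates on a gapped multiple alignment with one designated
reference row. Columns are classified by *support*: the largest number
of species sharing the same base in `{A,C,G,T}` at that column. Gaps and
`N` are never identical to anything (conservative conservation calls),
so they reduce support and terminate both seeds and extension.

**Seeds.** A window of `L` consecutive columns seeds an element when at
least `S` species carry an identical, fully ungapped, N-free `L`-mer —
a *fixed* agreeing subset across the window. This is computed exactly by
encoding each species' window as a base-4 integer and counting code
multiplicities; it is equivalent to enumerating all species subsets but
linear in alignment size. An alternative `per-column` seed rule (every
window column has support ≥ S, subset free to vary) is available as a
configuration flag.

**Extension and merging.** Every seed column has support ≥ S ≥ E, so the
extension of a seed under the per-column rule ("≥ E species identical in
the next column") is exactly the maximal run of support-≥-E columns
containing it. Elements are therefore computed as maximal qualifying
runs that contain at least one full seed window; overlapping and
book-ended extensions collapse into the same run automatically, and the
output is disjoint, sorted and maximal by construction. `min_support` is
the minimum column support over the run; `seeded_by` counts contained
seed windows.

**Coordinates.** Everything is 0-based half-open internally and in BED
output. Reference-gap columns at the edges of a run are trimmed from the
reported reference interval; interior reference gaps do not split an
element. An element whose entire run falls in reference gaps has no
reportable coordinates and is dropped. The reference species is not
required to be in the agreeing subset (a `require_ref` flag enables the
stricter rule).

**Defaults.** `L=7, S=5, E=4`, chosen for seven-species mammalian locus
alignments where five-way exact heptamer identity in half-divergent
non-coding background is rare enough to be a meaningful conservation
signal.

**Behaviour near block edges.** With seven species at background
per-site substitution probability 0.5, a random column reaches support
≥ 4 with probability ≈ 0.66 (one reference plus Bin(6, 0.5) ≥ 3), so an
element's extension runs a geometric-distributed ~2 columns past the
true boundary of a perfectly conserved block on each side. This is an
intrinsic property of the per-column extension rule, not an
implementation artefact: recall of planted blocks is essentially 100%,
while the interval Jaccard of a 60-bp block against its detected element
averages ≈ 0.93. Detected element boundaries should be read as slightly
outward-biased.

## Annotation filtering and track intersection

Non-coding enrichment removes any element overlapping any annotation
interval by ≥ 1 bp — whole-element removal, matching the downstream use
of elements as atomic units (a `trim` mode would clip instead; it is not
the default because partial elements no longer satisfy the seed
predicate). Intersection of two tracks reports (a) the number of
A-elements touched by B — deliberately asymmetric, the natural direction
when A is the detector's output and B a published track — and (b) the
per-base intersection of the two merged unions, which is symmetric.
Region coverage uses union semantics after clipping. Overlap indexes use
interval trees; all results are independent of the index structure.

## Motif models and scanning

A motif model is a per-position frequency matrix over A,C,G,T built from
equal-length ungapped site sequences with pseudocount 0.01 per base
(`N` contributes to no base; gapped inputs are rejected so that callers
make degapping explicit — orthologous sites with lineage-specific
indels, such as a deleted core-spacer base, are excluded from model
building rather than modelled with gap characters). The consensus is the
per-column argmax with alphabetical tie-break. Canonical CTCF core
positions (bases 4–8 and 10–18, 1-based) are attached to models long
enough to carry them.

Logo information content is `IC_j = 2 + Σ_b f_jb log2 f_jb` bits with
`0·log 0 = 0` and no small-sample correction; symbol heights are
`f_jb · IC_j`. IC is clipped to [0, 2] only to guard floating-point
round-off at the closed forms.

Scanning scores every window (both strands by default; reverse-strand
hits keep forward coordinates) by log-odds against a uniform 0.25
background. The **relative score** normalises so the worst attainable
window is 0 and the consensus is 1 — the standard PSSM relative score.
Under the alternative score/maximum normalisation, a single mutated base
in a model built from identical sites costs ~30% of the score and even
slightly degenerate sites fall below any usable cutoff; the min-max form
makes the cost of k mutations proportional to k, which is what
occupancy-class thresholds need to be meaningful. Windows containing
non-ACGT characters are never reported.

Occupancy classes use relative-score cutoffs `tau_low=0.70`,
`tau_med=0.80`, `tau_high=0.90` (boundaries inclusive upward), with an
optional minimum ChIP-seq tag count gating the HighOc call (a
strong-motif site failing the tag cut falls to MedOc). The published
classification combines motif match and tag density qualitatively; these
numeric cutoffs are explicit, tunable stand-ins and should be
recalibrated against real ChIP-seq data before biological use.
Cross-dataset occupancy labels are a pure function of per-dataset ≥ 1 bp
peak overlap and a dataset→species map: `shared` when occupied datasets
span ≥ 2 species, `<species>-specific` for one, `unoccupied` for none.

## Read-depth duplication calling

The caller consumes a windowed depth profile directly (read recruitment
and mapping are upstream concerns). Background mean and SD are trimmed
moments: 5% of windows are discarded from each tail of the sorted counts
before taking the sample mean and SD — no consistency correction is
applied, so the SD is mildly conservative for Poisson data, and the
duplicated fraction of the genome must stay below the trim fraction for
the background to be clean. Windows with `count > mu + k*sigma` (k=3)
are flagged; flagged runs separated by at most `merge_gap=2` background
windows merge into one call, and calls require ≥ `m=3` flagged windows.
The gap tolerance exists because at per-window mean ~20 a truly
duplicated window dips below the threshold by Poisson chance ~9% of the
time, and a single-window dropout should not split a duplication;
raising `k` or `m` still never increases called bp. With a degenerate
background (`sigma=0`) any count strictly above the mean is flagged.
Copy number is `2 · mean_depth / background_mean` against a diploid
baseline. The window size default is 1 kb (configurable); published
depth-of-coverage duplication scans use larger windows on whole-genome
data, and the thresholds here are desk-scale stand-ins.

## Synthetic data

The alignment simulator draws a uniform-random reference row; every
other species copies it, substituting each site independently with the
background probability (uniformly to one of the other three bases) and
gapping sites at the gap rate as single-column gaps (a geometric indel
model was considered and rejected: the exact-match detector responds
only to per-column agreement counts, which single-column gaps already
stress). Inside a planted block, the first `conserved_species_count`
rows — the reference counts as one — substitute at the block's own rate
and receive no gaps. No phylogenetic branch structure is modelled, for
the same reason. The motif planter embeds consensus-derived instances
(per-position mutation, uniform to other bases) at non-overlapping
uniform positions in uniform background. The depth simulator draws
per-window counts Poisson with mean `mean_depth · cn/2`, where
`mean_depth` is defined as the expected per-window count at copy
number 2 and partially-overlapped windows take the coverage-weighted
copy number.

What the generators do *not* emulate: phylogenetic correlation between
species, alignment error, repeat content and mappability structure,
sequencing-error profiles, GC bias, and motif instances drawn from a
non-consensus-centred distribution. Tests passing on this synthetic data
show algorithmic correctness (the detectors find exactly what their
rules define, with calibrated false-positive behaviour), not robustness
to those real-data artefacts. All generators are pure functions of their
spec including the seed; identical specs give byte-identical output.

## Problem sizes

The validation suite runs the detector-vs-enumerator comparison on 200
random alignments of up to 300 columns × 8 species, planted-block
recovery over 50 replicates of a 60-bp block in a 7 × 1000 alignment,
interval algebra against per-base bitmap oracles over 1000 random
interval sets on a 600-bp region, and the duplication caller on 1000
1-kb windows with 200 null replicates; the end-to-end locus run uses a
7-species 40-kb alignment with ~80 planted blocks. These sizes give
stable statistics for every stochastic check while keeping the full
suite in seconds.

## Known limitations

- Element boundaries are outward-biased by chance extension (see above);
  boundary-sensitive analyses should re-trim against column support.
- Seed detection assumes a fixed agreeing subset per window, the
  stricter of the two defensible readings of the rule; the per-column
  variant is available but changes element counts.
- MAF input is read block-wise and the first block only — locus-scale
  single-block files, not whole-genome streams.
- Duplicated species rows (paralog mixtures) are not handled; each row
  must be one species.
- Occupancy thresholds and duplication-calling parameters are synthetic
  calibrations, not published constants.
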