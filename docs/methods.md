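# Methods

## Data model and conventions

All coordinates are 0-based half-open (BED convention). A paired-end
fragment `[start, end)` represents the DNA between two MNase cuts; its
two *cleavage ends* are the terminal bases `start` and `end − 1` — the
base `end` itself lies outside the fragment, so both cut sites land on
real bases and a length-1 fragment contributes a count of 2 at its single
base. Signal tracks are dense per-base vectors per chromosome and declare
their units (`raw`, `depth_scaled`, `genome_scaled`); operations that mix
units raise rather than guess. Bedgraph output merges runs of equal value
and omits zero runs; values are written with shortest-round-trip `repr`
so the read/write cycle is value-exact at every base.

## Normalization

Two schemes serve different questions:

* **Depth scaling** (`v / total_ends × total_mapped_bases`) removes
  sequencing-depth differences between samples and is used for track
  visualization, the composite maximum, and the kinetic window sums.
* **Genome scaling** (`v × G / fragments_mapped`, default
  `G = 12,495,000` bp for budding yeast, overridable) puts average
  cleavage profiles on a per-genome scale; each sample is scaled with its
  own fragment count before the free-MNase control is subtracted.

Control subtraction keeps negative differences. Averaging over sites
expects unbiased residuals; flooring at zero would bias every profile
upward exactly where the control is strong. "Total mapped bases" is the
sum of fragment lengths in the sample.

## Peak calling

The composite track takes the per-base maximum of the depth-normalized
time-point tracks (depth normalization first, because time points differ
in sequencing depth). The threshold is `fold × mean`, where the mean runs
over every base of every chromosome with zeros included, and
qualification is inclusive (`value ≥ T`). Qualifying positions whose
coordinates differ by ≤ `merge_distance` (default 30 bp) collapse into
one peak reported as `[first, last + 1)`; peak midpoint is
`⌊(start + end)/2⌋`. A window of width `w` around a midpoint `m` spans
`[m − ⌊w/2⌋, m + ⌈w/2⌉)`, clipped at chromosome edges (clipping counted
and warned). The all-zero track is a degenerate input: the threshold
would be 0 and inclusive comparison would select the whole genome, so the
caller short-circuits to zero peaks with a warning. Overlap operations
(free-MNase FDR, window-set intersection, slow-site uniqueness) use the
≥ 1 shared-bp criterion on half-open intervals, so abutting windows do
not overlap; they are implemented with sorted-array searchsorted/cummax
sweeps and tested against all-pairs brute force.

## Kinetic classification

Each peak's row of 50-bp window sums across the ordered time points is
Z-scored with the population (n) standard deviation — the convention of
the classic clustering tools this step follows; constant rows map to zero
and carry a degeneracy flag. k-means (k = 2, Euclidean, 10 restarts, best
inertia, fixed integer seed) partitions the rows; the cluster whose rows
reach their maximum earlier (mean over actual time values, ties resolved
to the earliest time point — conservatively favouring "fast") is labelled
fast. Constant rows are assigned slow: a flat course has no detectable
early maximum.

## Motif scoring and exact p-values

A count matrix becomes probabilities via
`(count + κ·bg) / (colsum + κ)` with pseudocount `κ = 0.1` distributed by
the background, and log-odds `log2(p/bg)` against a zero-order background
estimated from the genome composition (uniform available by flag).
Scores are discretized to an integer grid of ~1,000 bins spanning the
attainable range (per-row minima shifted to 0). The exact null
distribution of the integer score of a background-generated w-mer is
built by convolving the per-position score distributions; the p-value of
a match is the tail sum `P(score ≥ s)`, which is monotone nonincreasing
and never 0. Zero probabilities (possible only at `κ = 0`) score −∞ in
log-odds and are pinned to a finite floor far below any attainable score
for the integer grid only. The DP result equals brute-force enumeration
over all `4^w` words on the same grid (tested exhaustively for w ≤ 6).

Scanning takes the best match over both strands and all offsets of the
50-bp window centered on the peak midpoint; ties break to the leftmost
offset, then the + strand. Offsets containing N are skipped; windows with
no scoreable offset are dropped with a logged count. The match *center*
(anchor for 100-bp profile and shape windows) is `start + ⌊w/2⌋`. Sites
split at `p < 0.001` (strict) into high-scoring vs low-scoring. Random
control sites are rejection-sampled uniformly (length-weighted chromosome
choice) against ≥ 1-bp overlap with the excluded site sets, equal in
number to the low-scoring set.

## Cleavage profiles and asymmetry

Profiles average end counts over `[center − flank, center + flank)`
windows, reversing minus-strand windows so offsets increase in the
motif's 5′→3′ direction; sites whose window leaves the chromosome are
skipped and counted. Per-included-site means are used (identical to
pooled counts divided by site count when nothing is clipped). Confidence
bands are percentile bootstrap over sites (default 1,000 resamples,
seeded) — site signals are heavy-tailed, so a normal approximation is not
trusted. The asymmetry index is `(U − D)/(U + D)` with `U`/`D` the summed
signal at offsets `< −h` / `≥ h`, `h = ⌈w/2⌉`: the symmetric interior
margin (rather than the exact match footprint) makes strand reflection
negate the index bit-exactly for any motif width, and interior cleavage
is a separate phenomenon in any case. The sums use `math.fsum`, which is
summation-order independent, so the reflection identity holds exactly in
floating point.

## DNA shape

Shape is predicted by a sliding pentamer: the center base receives the
pentamer's MGW and ProT; the two dinucleotide steps flanking the center
receive its Roll/HelT step values. Because the table carries values only
for the two central steps of each pentamer, an interior step is covered
by at most two pentamers and receives their average (documented here
because conventions differ). A length-L window yields L−4 base-centered
values; margins, N-containing pentamers, and pentamers absent from a
partial table are NaN and excluded from per-offset means with per-offset
n tracked. The pentamer query table is consumed as data (TSV: `pentamer
MGW ProT Roll1 Roll2 HelT1 HelT2`); the packaged generator produces a
*synthetic* reverse-complement-symmetric table with values drawn once per
pentamer/reverse-complement pair in physically plausible ranges (MGW
3–6.2 Å, ProT −16…−2°, Roll −6…8°, HelT 30–38°). It has the structure and
symmetries of a measured table, not its values — shape-profile *contrasts*
computed with it are meaningful, absolute values are not. Profile
comparison reports, per feature, the Pearson correlation of the aligned
mean vectors and a two-sample KS test on the two mean vectors' value
distributions (mean-vector mode; pooled per-site distributions would be
the alternative reading and can be built from `predict_shape` directly).

## Sequence-vs-shape discrimination

Sequence windows are one-hot encoded (4 columns/position, ACGT); shape
features are concatenated per position and min-max scaled to [0, 1] per
feature over the training set, with stored extremes reused (unclipped) on
held-out data. The model is ridge regression on 0/1 labels — AUROC is
rank-based, so linear regression and logistic classification give the
same statistic. AUROC is computed from predictions pooled over a seeded
10-fold split (in-sample AUROC also reported); λ defaults to 1.0.

## Simulator: what it emulates and what it does not

The simulator plants `n_fast` exact-consensus and `n_slow` 1–2-mismatch
motif instances (random strands, ≥ 220 bp apart) in an i.i.d. genome at
yeast GC content (0.39). Cleavage intensity per site is cumulative in
digestion time: fast sites saturate as `1 − exp(−t/45 s)`; slow sites
follow the same saturation (τ = 600 s) after a 300-s onset delay —
delayed-onset, not amplitude-reduced, which is what makes
time-of-maximum informative. Site intensities vary lognormally (σ = 0.25,
mean 150 relative units); background cleavage accrues at 2×10⁻⁵ per bp
per second; each sample is sequenced to a fixed expected depth (60,000
fragments, Poisson) drawn multinomially from the pool. Fixed depth is the
realistic regime — libraries are sequenced to a set depth regardless of
digestion extent — and it produces the signature the kinetics step
exploits: a fast site's *share* of reads peaks early and declines as slow
sites and background accumulate. Cuts land 1–5 bp outside a motif edge
(|N(1.5, 1)| clipped), on either side (`symmetric`) or only 5′ of the
motif (`upstream_only`); the cut base is one fragment end and the
fragment extends away with length N(60, 15) clipped to [30, 150]. The
control is background-only at the same depth.

Default problem sizes (100-kb genome, 200 + 200 sites, 6 time points,
60k fragments/sample) were chosen so every planted peak is comfortably
above the 10× genome-mean threshold while the whole study runs in
seconds; these are the package's standard test conditions. The simulator
does not model MNase sequence preference, nucleosome occupancy,
mappability, or chromatin accessibility, so passing recovery tests show
the pipeline's inference is correct under its own model — not that real
data meet these error rates.

## Known limitations

* Genome-scale results (peak counts in the tens of thousands, replicate
  correlations of real libraries) require real sequencing data and are
  out of scope; the package reports these statistics for whatever data it
  is given.
* The KS comparison of shape profiles treats the two mean vectors as
  samples; with ~96 offsets its p-values are coarse.
* SAM/BAM parsing is not included: the pipeline ingests fragment BED
  files produced upstream.
* The shape table shipped for testing is synthetic (see above); supply a
  measured pentamer table via `read_shape_table` for real analyses.
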