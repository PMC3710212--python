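# Methods

## Coordinate model

All coordinates are 0-based half-open, matching BED; hg19-style inputs
pass through unshifted. A `SegmentTrack` keeps its raw (possibly
overlapping) segments; set operations that need disjoint intervals merge
on the fly, and book-ended intervals ([a,b) + [b,c)) coalesce when merged.
Peak midpoints use floor((start+end)/2), so they are deterministic
integers. Blacklist filtering removes any peak sharing ≥1 bp with a
blacklisted region *whole* — artefact filtering discards peaks, it never
trims them.

Overlap in base pairs is computed through the piecewise-linear cumulative
coverage of one (merged) track evaluated at the other's endpoints; this is
exact for integer coordinates below 2^53 and is the same primitive the
Monte-Carlo inner loop uses, so observed and null statistics are computed
identically.

## Monte-Carlo null models

**Segment–segment.** The query track is randomized per chromosome by
independently permuting the multiset of segment lengths and the multiset
of gap lengths (terminal gaps included) and re-concatenating. Every draw
therefore preserves both empirical length distributions exactly; with k
segments there are at most k!·(k+1)! arrangements, and for tiny genomes
the null can be enumerated exhaustively (the acceptance suite checks
total-variation distance < 0.05 against this enumeration). Chromosomes
are randomized independently. A consequence worth knowing: a zero-length
gap (a segment flush at the chromosome start, say) may land between two
segments, which then appear as one interval in merged views; coverage
statistics are unaffected.

**Point–segment.** Points are resampled from an *intensity track*: per-bin
weights (default bin 10 kb) built from the empirical distribution of
point-to-nearest-gene distances. Distances are histogrammed into
log2-spaced classes ({0}, [1,2), [2,4), …); each genomic bin is assigned
the class of its own midpoint distance and receives weight
(class point-fraction) / (bins in class), normalized to 1. Bins farther
from genes than any observed point get zero weight. This makes the null
points match the observed gene-proximity profile — the confounder the
control is meant to absorb — while remaining a proper density. Distance
is measured to gene bodies by default (`use_tss=True` switches to
transcription start sites). Excluded chromosomes (e.g. a chromosome with
no genes of interest) are dropped from points, segments and intensity,
and the weights renormalized.

**Case–control.** Segment positions of both tracks stay fixed; the binary
labels of the query are permuted, preserving label counts. The statistic
is T = overlap_bp(case)/covered_bp(case) −
overlap_bp(control)/covered_bp(control), i.e. a per-bp overlap-rate
difference; the test is two-sided on |T|. The track must be
non-overlapping within itself (pool per-group merged tracks before
labelling) so per-label coverage is a sum of segment lengths.

**P-values.** All empirical p-values use the add-one convention
p = (b+1)/(n+1): never zero, minimum 1/(n+1). Default tail is "greater";
group comparisons are two-sided. Every Monte-Carlo entry point accepts an
explicit seed or generator, and results record n and the seed.

The statistic is discrete, so exact uniformity of p-values under
independence requires it to take many values: calibration checks use
tracks dense enough (~20–30% coverage) that ties — particularly an atom
at zero overlap — are negligible. Sparse tracks give conservative
(super-uniform) p-values, which is the safe direction.

## Genomic categories

A midpoint inside any gene span is UTR if inside a UTR sub-interval, else
exonic if inside an exon, else intronic — across all genes jointly, so
genic assignments beat flanking ones when genes overlap. Outside genes,
strand-aware 5 kb flanks assign upstream/downstream; qualifying for both
(with respect to any genes) gives up-and-downstream; otherwise
intergenic. This yields seven mutually exclusive categories whose counts
sum to the number of peaks. Percentages are reported to one decimal with
half-up rounding, the convention of printed summary tables (29.25 → 29.3).

## Disease-associated regions

A region is the closed ±flank window around a qualifying SNP
([pos−flank, pos+flank+1) half-open, so the SNP base is included and a
100 kb flank spans 200,001 bp), merged across SNPs. Qualification is
association p ≤ 1e-7 (inclusive) for the selected traits; identical
(chromosome, position) loci are de-duplicated within a selection. Pooled
multi-disease analyses merge overlapping regions; per-disease analyses
use per-trait tracks through the same code path. The 100 kb default is a
linkage-disequilibrium proxy; `flank_sweep` rebuilds regions at a ladder
of flank sizes and re-tests, which concentrates genuinely SNP-proximal
binding into rising fold at small flanks.

## Cohort statistics

Pearson r carries a two-sided p from t = r·sqrt(n−2)/sqrt(1−r²) with n−2
df. The high/low group comparison uses an exact two-sided rank-sum test:
all C(n_a+n_b, n_a) label assignments are enumerated (mid-ranks for
ties), p = 2·min(tail probabilities) capped at 1; enumeration is refused
above n = 20. Groups split at 75 nmol/L serum 25(OH)D, the clinical
sufficiency cutoff, with the boundary value in the sufficient group.
Category correlations default to percentage columns (absolute counts
remain available), since with strongly varying totals the percentage
columns are the comparable quantity. A pooled binding site is "unique"
when peaks from exactly one sample intersect it, computed on the merged
union of all samples.

## Motifs

PWMs store per-column probabilities with an explicit background;
count→probability conversion adds a 0.25 pseudocount per base; the
background defaults to uniform, or to the scanned set's mononucleotide
frequencies in EM. Score p-values are exact under the background:
per-column log-odds are discretized to a common step (chosen so the DP
table has ≤1e5 states, bounding the p error by one step) and convolved
position by position; scanning uses the same integer scores, so hit
p-values are consistent with the table by construction. Both strands are
scanned by default; windows containing N are skipped.

De novo discovery is single-motif ZOOPS EM (zero or one site per
sequence): the E-step computes a posterior over {no site} ∪ {site at each
offset}, the M-step re-estimates the PWM (with pseudocounts) and the
per-sequence site prior γ; the log-likelihood is non-decreasing and the
best of several random restarts is kept. Restarts are seeded from random
subsequences, smoothed 0.7/0.1.

Iterative refinement alternates scanning (p ≤ 1e-4 per window) with EM
rediscovery on the positive set at the seed's width. It stops after the
requested rounds, when the positive set falls below 10 sequences
(re-estimating from a handful of chance hits only overfits them), or when
the rediscovered matrix's mean per-column information content drops below
0.3 bits — the operational definition of a degenerate motif; the last
non-degenerate matrix is returned with a flag. EM is free to rediscover
the motif phase-shifted or reverse-complemented, so comparisons to a
target matrix align over small shifts and both orientations, as motif
comparison tools do. The count curve reports, per p threshold, the number
of sequences with ≥1 hit, with a size-corrected p = p × (number of
scanned windows), capped at 1 — a Bonferroni-style stand-in for
multi-motif E-values, which are out of scope.

The bundled seed motif (`dr3_like_seed_pwm`) is a *synthetic* DR3-style
nuclear-receptor matrix — two RGKTCA half-sites with a 3-bp spacer — used
as a scanning/refinement seed; it is constructed, not a database matrix.

## Synthetic data

The generator encodes the structure the analysis is designed to detect.
Per sample, the binding-site count is max(0, round(a + b·x + ε)) with
ε ~ N(0, σ²) — truncated Gaussian noise on the count scale, the simplest
model consistent with a strong linear correlation. Each peak is placed by
a three-component mixture: uniform background, uniform within disease
regions, uniform within ±5 kb gene windows, with weights that may differ
between the ≥75 and <75 nmol/L groups (defaults 0.55/0.25/0.20 vs
0.65/0.15/0.20, giving the sufficient group the stronger disease-region
affinity). Peak lengths are log-normal (median ≈ 400 bp, log-sd 0.5,
clipped to [50, 5000] bp) — typical called-peak scales. The default
cohort is nine samples with 25(OH)D {80, 107, 76, 85, 75, 29, 32, 34, 22}
nmol/L (five sufficient, four not) on a 2 × 5 Mb genome with 200
non-overlapping multi-exon genes; the default count model (a = −1475,
b = 71, σ = 800) reproduces group-mean counts in the observed range. The
association catalog plants genome-wide-significant SNPs (p drawn in
[1e-15, 1e-8]) for chosen traits among sub-threshold decoys.

What the generator does **not** emulate: sequence composition and
mappability structure, read-level noise, correlated peak shapes,
linkage-disequilibrium block structure, or inter-sample technical
covariates. Passing tests therefore demonstrate that the statistical
machinery recovers planted structure of the stated kind — not that real
ChIP-seq artefacts are handled beyond blacklist removal.

## Problem sizes

Tests and the acceptance script run on deliberately small instances so
the full enumeration and replication counts stay cheap: calibration uses
200 replicates of 99 randomizations on 100 kb toy chromosomes; planted
disease-region recovery uses 100 seeded cohorts of ~150 peaks on 2 Mb
with 999 randomizations; clustering recovery uses 50 cohorts of 5+4
samples; EM recovery uses 20 runs of 200 sequences × 50 bp; the flank
sweep uses 10 runs with 999 randomizations. These sizes give the binomial
margins the thresholds assume while keeping each suite in seconds to a
couple of minutes.

## Known limitations

* The length/gap-permutation null conditions on the observed gap
  multiset. When the query's inter-peak spacing itself matches the
  reference's spacing (peaks at SNPs vs regions around the same SNPs),
  partial reconstructions inflate the null mean relative to a fully
  uniform null; fold values are accordingly conservative.
* No GC- or mappability-matched nulls, and no analytical p-values; large
  n is the only route to small p (minimum 1/(n+1)).
* The exact rank-sum test enumerates; above n = 20 use the normal
  approximation from scipy instead.
* Case–control analysis assumes within-track disjointness; overlapping
  labelled segments are not modelled.
* BED12/GTF parsing covers the minimal gene-model subset used here, not
  the full format zoo.
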