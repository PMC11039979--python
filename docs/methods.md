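# Methods

This note documents the models and procedures implemented in `methylhic`,
the parameters that matter, the design choices made where the design was
genuinely open, and what validation on synthetic data does and does not
establish.

## Data model and conventions

All coordinates are 0-based half-open.  The central input is the extended
pairs table: one row per ligated mate pair with `chrom1, pos1, chrom2,
pos2` and per-mate methylated/covered CpG counts `meth1, total1, meth2,
total2`.  Per-read methylation from Methyl-HiC has no standard on-disk
format, so the package defines a tab-separated dialect with a mandatory
header.  Intra-chromosomal records are stored with `pos1 <= pos2` (counts
swap along), and cis contacts closer than 1 kb are removed on read
(strict `<`; the cutoff is a parameter) because short-range ligation
products carry no long-range information.  Inter-chromosomal pairs are
parsed and retained but excluded from all distance-stratified analyses.
In memory, pairs live in a pandas DataFrame; a `PairRecord` NamedTuple is
provided for single-record use.

## Contact matrices

Pairs are binned into dense symmetric per-chromosome matrices (cell
`(pos1//b, pos2//b)` plus its mirror; self-bin pairs counted once).  Bins
whose raw marginal falls below 10% of the median marginal are masked
(NaN) before balancing — standard practice; the fraction is configurable.
Balancing is iterative correction (ICE): divide alternately by
marginal-proportional factors until the worst relative marginal deviation
is below `tol` (default 1e-5, up to 1000 iterations; ~250 are typical for
a 200-bin matrix).  ICE was chosen over KR for its simple fixed-point
contract; downstream analyses use only ratios, for which the two are
equivalent.  The expected profile is the mean over unmasked cells of each
diagonal; O/E divides by it, so every unmasked diagonal of an O/E matrix
averages to exactly 1.  For cross-sample comparisons of interaction
strength, raw matrices are scaled so the genome-wide sum equals 1e9.

## Compartments

The compartment signal is the leading eigenvector of the Pearson
correlation matrix of O/E columns, computed per chromosome at 250 kb (no
genome-wide stitching).  The eigenvector's sign is arbitrary, so the
track is oriented to correlate non-negatively with a sequence covariate —
CpG density per bin by default, GC fraction equivalently; an exact-zero
correlation is broken by making the mean eigenvector entry over the top
covariate decile positive.  Every unmasked bin is labelled by sign (A
positive, B negative); no minimum |entry| threshold is applied.
Switching categories come from the sign pair across conditions.  The
saddle aggregates O/E over 20 eigenvector-quantile pairs; strength is
(mean AA corner + mean BB corner) / (2 × mean AB corner) with corners the
outer 20% of quantiles.  Eigenvector–methylation correlation is Pearson r
of entries versus per-bin methylation change, computed within A and
within B bins separately.

## TADs

Insulation uses diamond windows from 200 kb to 500 kb in 50 kb steps at
50 kb resolution.  Per-window tracks are z-scored per chromosome (zero
variance ⇒ 0) and averaged into a combined separation score.  Candidate
boundaries are local minima with prominence ≥ 0.05 on the combined
z-scale.  Each candidate is tested by a one-sided Mann–Whitney rank sum
comparing the per-window diamond values at the two nearest insulation
*maxima* (intra-domain positions) against those at the candidate; kept at
p < 0.05.  The flank-at-maxima choice matters: with windows comparable to
the domain size, fixed offsets `e ± w` land across neighbouring
boundaries and erase the contrast.  Kept boundaries closer than 2 bins
are pruned to the deeper minimum so TADs (the tiling between consecutive
boundaries) are at least 2 bins.  TAD overlap between conditions uses the
reciprocal rule: matched iff the intersection exceeds 60% of both.  ATA
resamples each TAD square plus 50% flanks to a common size (bilinear),
averages, and scores center-half mean over the mean of the two distal
diagonal corner squares; windows touching masked bins are skipped and
isolated data-free cells (the empty O/E diagonal of simulated data) count
as the neutral value 1.  Boundary methylation classification averages the
per-bin methylation change over ±2 bins (100 kb, configurable — the
appropriate width is genuinely open) and crosses hyper/hypo with the
compartment of the containing 250-kb bin.

## Loops

The caller is a fully specified donut/lower-left local-background Poisson
test, deliberately substituted for scale-space black-box callers so every
step is testable.  For each band pixel (20 kb–2 Mb by default): local
expected = expected(d) × max(median O/E of the donut ring with Chebyshev
radii 2–5, center row/column excluded; median O/E of the lower-left
quadrant), converted to count scale through the balancing weights;
p = Poisson upper tail of the raw count; BH-FDR at 0.05 across the band.
Calls are significant pixels that are 8-neighbourhood enrichment maxima
with fold ≥ 3 over the local background, merged within a 1-bin radius.
The fold floor is set above domain-level block enrichment (a TAD-scale
elevation of ~2× would otherwise surface its corner pixels as loops — the
corner-dot artifact); it only removes calls, so null false-call control
is preserved.  Differential loops: a condition-A loop with no B call
within 1 bin and pixel O/E ratio ≥ 1.5 is lost; gained is symmetric;
everything else shared.  APA averages O/E windows (halfwidth 5) around
loop pixels and scores center over the 3×3 lower-left corner.
Pairwise-region aggregation does the same over all region×region pixels
in a distance band, against a circularly shifted control (1 Mb).
Anchor annotation classes loops E-P/P-P/E-E/other with promoter taking
precedence over enhancer on an anchor overlapping both; loop-size
comparisons use Welch's unequal-variance t-test on log10 distance,
implemented from its closed form (Satterthwaite df) and cross-checked
against an independent implementation in the tests.

## Methylome

Mate counts are attributed uniformly to the CpGs under each 100-bp mate
footprint (a mate covering k CpGs adds total/k and meth/k to each);
accumulation is fractional.  CpGs with accumulated coverage below 10 are
masked ("coverage above 10" is read inclusively, ≥ 10; parameter).
Binned levels are pooled `sum(meth)/sum(total)`, never means of ratios.

DMRs: per-CpG counts are smoothed with a 1 kb centered window; the
per-CpG two-proportion z is computed on the *windowed* count sums (raw
per-CpG tests at ~20× coverage fragment true regions), candidates are
maximal runs of consecutive CpGs with one smoothed-diff sign and
windowed-test p < 0.001, and a region is reported iff it has ≥ 5 CpGs,
pooled |Δβ| > 0.20 (from raw counts) and Stouffer-combined p < 0.01.
Because adjacent windowed z's share reads, the Stouffer denominator uses
√(n·m) with m the mean window/raw read ratio — without this overlap
correction the selected-run statistic is anti-conservative and the
empirical FDR on planted data runs near 25% instead of ≤ 5%.  The three
region gates are the standard published thresholds; the candidate
formation is this package's procedure and its two internal parameters
were fixed by calibration on planted data.  Swapping the two conditions
provably flips every region's direction and leaves intervals unchanged.

CGI forests are maximal runs of CpG islands with inter-island gaps below
50 kb (the source segmentations do not pin this number; it is a
documented parameter), spanning island bounds; prairies tile the rest, so
the two classes partition each chromosome.  Per-domain CpG density uses
1-kb non-overlapping windows.  The forest–prairie methylation gap pools
CpG counts over all domains of a class; an unweighted across-domain mean
lets tiny sliver domains at segmentation edges distort the gap by several
percent.  Profile aggregation averages a stepwise bedGraph signal into
column bins around reference points (strand-aware flipping); interval
enrichment compares observed query–target overlap counts with
chromosome- and length-preserving random placements (+1-corrected
empirical p).

## Concordance

Each qualifying cis pair contributes one point (x, y) =
(meth1/total1, meth2/total2); mates below the CpG floor exclude the whole
pair.  PCC is computed per stratum — log-spaced distance bins (default
1 kb–10 Mb, 10 bins) and per-mate CpG floors — with strata under 100
pairs, or with zero variance, reported explicitly as undefined rather
than dropped.  Points are unweighted: a pair with 2 CpGs per mate counts
as much as one with 20, matching the statistic's definition; the CpG
floor, not weighting, is the resolution control.  Loop-restricted
concordance keeps only pairs whose mates fall in the two (padded) anchors
of one loop.

## Synthetic data generator

The generator defines the study conditions.  Defaults: two 10-Mb
chromosomes at 50 kb model resolution; alternating A/B compartment blocks
of 1–2 Mb on a 250-kb grid; 20 TADs per chromosome (≥ 4 bins, random
sizes); 15 loops per chromosome with anchor distances 200 kb–1.8 Mb.  CGI
forests coincide with A blocks and carry 1-kb islands every ~10 kb; CpG
positions are a piecewise-Poisson process with prairie rate 0.002/bp,
forest background 0.004/bp and an island rate solved so the
forest/prairie density contrast hits the configured 10×.  Methylation:
islands 0.10, forest background 0.65, prairies 0.80 (mES-like ordering),
iid noise sd 0.03, clipped to [0.02, 0.98].

Contacts are sampled from an exact pixel distribution: weight
∝ d^(−1) × f_comp (1.6, same compartment) × f_tad (2.0, same TAD) ×
f_loop (5.0, loop pixels).  The structure factors are not reported
quantities anywhere; they were chosen once to make the planted structures
detectable at desk scale (2×10⁶ pairs) and are all configurable.
Expected counts for any pixel are available in closed form, which the
tests exploit (empirical vs expected within 3 SE per stratum).

Mate methylation uses a latent-Gaussian copula: per pair draw (z₁, z₂)
standard bivariate normal with correlation ρ (default 0.6); mate i's
success probability is Φ(√(1+σ²)·Φ⁻¹(mᵢ) + σzᵢ) with σ = 0.5 and mᵢ the
mean surface level under the footprint — the √(1+σ²) factor makes the
marginal mean exactly mᵢ; counts are Binomial(totalᵢ, pᵢ).  The copula
(rather than shared-Bernoulli mixing) makes the planted ρ directly
comparable to the measured PCC via a small Monte-Carlo oracle.  ρ may
optionally decay with distance (exp(−d/L)) and be overridden at loop
pixels; both are off by default.

The knockout perturbation raises forest methylation (+0.10), scales the
compartment and TAD contrast factors toward 1 (×0.5 on the excess),
removes loops beyond 500 kb (fraction 1.0 by default), and raises ρ by
0.2 — the directions expected of Tet loss.  It can also plant discrete
hyper-DMRs (+0.3 over ~2-kb forest windows with ≥ 8 CpGs) as ground truth
for DMR validation; DMRs are planted in forest background so the full
delta survives the [0,1] clip.  An independent track simulator draws
per-CpG coverage Poisson(20×) for methylome-only analyses.

Two analysis-specific configurations are used where the default genome is
physically unsuitable: concordance recovery uses a CpG-dense flat-surface
genome (uniform 0.12 CpG/bp, all levels 0.5) because a 100-bp mate covers
~1 CpG at genomic density while the statistic needs ≥ 10 CpGs per mate,
and a flat surface isolates the copula ρ from the surface autocorrelation
of nearby mates (which genuinely raises measured concordance — a real
phenomenon, but a confound for parameter recovery).

## What the synthetic validation shows — and does not

Passing tests establish that each implementation recovers exactly the
structure its generator plants, with calibrated error control under
Poisson/binomial sampling noise.  The generator omits, deliberately:
restriction-fragment geometry, PCR duplicates and bisulfite conversion
error, trans contacts, nested/hierarchical TADs, copy-number and
mappability artifacts, and realistic covariate structure between CpG
density and coverage.  Real-data performance therefore depends on
upstream filtering quality in ways these tests cannot certify; the
pipeline's parameters (coverage floors, masking fraction, fold floors)
are the intended adjustment points.

## Problem sizes and determinism

Validation runs use 2×10⁶ pairs per condition for contact-level
recovery, 2×10⁴–2×10⁵ pairs for concordance strata, 20× CpG coverage for
methylome analyses, and 20–50 replicates for null controls — sizes at
which every recovery criterion is comfortably powered on a single CPU in
seconds to tens of seconds per stage.  All randomness flows through
numpy `default_rng` seeds; identical seeds give byte-identical models,
simulations and results.
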