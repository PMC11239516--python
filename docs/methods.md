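# Methods

This note documents the models implemented in `replifork`, their
assumptions, the defaults that matter, and the limits of what the synthetic
generators can establish.

## Input model and conventions

The unit of data is a deduplicated molecule: one restriction-site position
observed once in one cell. Coordinates are 0-based, half-open everywhere
internally; 1-based inputs must be declared on load and are converted. Bins
are fixed-width, `bin index = floor(pos / bin_size)`, tiling each chromosome
from 0. Strand is carried through IO but ignored by every computation — no
downstream statistic uses it. Whether positions denote the restriction site
or a read midpoint is the caller's concern; the column is used as-is.

## Per-cell QC

Density: a cell passes when its mean count per 100-kb bin (all genome bins,
zeros included) lies inclusively within [0.37, 2.72] for single-pulse or
[0.08, 12.18] for double-pulse labeling.

Dispersion: with natural logs, a cell is kept iff

    log CV > −0.5 · log mean + 0.1.

The reference line `log CV = −0.5 · log mean` is exactly where a
Poisson-sampled (structureless) cell sits; labeled cells are over-dispersed
at 100-kb scale because their reads cluster in replication tracks, so the
criterion selects cells with real signal and removes background-only ones.
Cells with fewer than two nonzero bins have no defined CV and fail with a
warning. Order of operations: density/dispersion first, then foreground
selection; dispersion-failing cells are removed, not flagged.

Foreground selection fits a two-component exponential mixture by EM (median
split init, ≤ 200 iterations, relative tolerance 1e−8) on successive-read
gaps pooled over chromosomes. Each read is scored at its distance to the
nearest flanking read (chromosome ends use their single gap) and kept when
the posterior of the smaller-mean component exceeds 0.5. Non-convergence
keeps all reads and warns — a deliberate fail-open, since dropping a cell
silently would bias cohort composition.

## S-phase ordering

Profiles: each foreground read contributes a unit-mass Gaussian with
σ = 8,333.333 bp, evaluated on a 2,500-bp grid (σ/3.3; fine enough that the
kernel is resolved, coarse enough that a genome fits in memory). Similarity
between two cells is the Szymkiewicz–Simpson overlap coefficient per
chromosome, `Σ min(a,b) / min(Σa, Σb)` on the smoothed densities (the
smoothed-density reading of "overlap coefficient"; a thresholded-support
variant was the open alternative). Distance = `min(1/score − 1, 1000)`,
averaged over chromosomes; an all-zero profile on a chromosome contributes
the cap.

Embedding: the distance matrix is embedded to 1-D with UMAP
(`metric="precomputed"`, `n_neighbors = min(15, n−1)`, `min_dist = 0.1`),
repeated `n_runs` times (default 100) with seeds spawned from one master
seed. Each run's axis is z-scored. Runs whose mean |Spearman ρ| against the
other runs falls below 0.85 are discarded; fewer than 50 % concordant runs is
a global failure (`OrderingError`). Retained runs are sign-aligned to the
first retained run (the anchor is arbitrary; orientation is resolved later).
Per cell, sorted placements are split into clusters wherever a successive gap
is ≥ 0.1 (in z units, since the axis was just z-scored); the cell is kept
when the largest cluster holds ≥ 80 % of retained runs, and its consensus is
that cluster's mean. Kept cells' consensus values are ranked to S-phase
progression in [0, 1].

Orientation: with no external reference the direction of the axis is
arbitrary and reported as such. When a per-cell reference vector is supplied
(any stage surrogate, e.g. the cell's signal fraction in early-replicating
bins of a timing track), the axis is flipped so progression correlates
positively with it.

Numerical caveat observed while testing: 1-D UMAP occasionally folds a
perfect ladder, and on very small cohorts (≲ 15 cells) enough runs fold that
the 0.85-concordance filter rejects everything. The filter behaves as
intended — discordant runs are excluded, and a cohort too small to order
raises rather than returning a wrong order. Twin cells (zero mutual
distance) land at adjacent, not bit-identical, consensus ranks: the embedder
is stochastic.

## Hidden semi-Markov segmentation

Observations are the gaps between consecutive reads per chromosome; each
chromosome is a separate sequence. Two states, foreground and background,
must alternate (no self-transitions), with exponential emissions on gap
length and a per-state gamma sojourn on run length measured in gaps (bp-long
sojourns were the open alternative; gap count keeps the duration pmf small
and data-scaled). The k-th gap's state labels the read pair flanking it; a
track's reads are the union of reads flanking a maximal foreground gap run,
so an n-read track spans n−1 foreground gaps.

Durations are discretized, `p(d) ∝ Γcdf(d) − Γcdf(d−1)` for d = 1..Dmax
(default 300, capped at the sequence length) and renormalized. Every run —
including the final, possibly truncated one — is scored with this pmf; no
right-censoring. That convention makes the decoding objective factorize as
initial probability × per-run duration pmf × per-gap emission, identical to
what an exhaustive enumeration over labelings maximizes, which is how the
test suite proves the Viterbi implementation exact on all instances with
≤ 12 gaps.

EM: explicit-duration forward–backward gives per-gap state posteriors and
expected run-length distributions; the M-step re-estimates exponential means
as posterior-weighted averages and the gamma sojourn by method of moments on
the expected run-length histogram. Method-of-moments is not the exact
maximizer, so the likelihood trace can dip by ~1e−5 relative near
convergence; the tests allow 1e−4 relative slack. Initialization: foreground
emission at the 10th gap percentile, background at the 90th, sojourn shape 2
with mean run length 5, tolerance 1e−6, ≤ 200 iterations.

Degeneracy: when the fitted background gap scale is less than twice the
foreground scale there is no two-scale structure to decode (a single
exponential fits the data); the result is flagged `collapsed` and decoding
falls back to a quantile threshold at the geometric mean of the 10th and
90th gap percentiles. The factor 2 was chosen because genuine foreground/
background scales differ by orders of magnitude (kb vs tens to hundreds of
kb) while a single-exponential fit yields near-equal means.

Width correction: a track's raw width w (first to last read) underestimates
the labeled stretch; `corrected = w + w/(n−1)`, the uniform-maximum
estimator. Tracks with n < 2 have no defined width and are excluded from
width statistics. Width-based speed = corrected width / pulse length
(15 min default); note that the two divergent forks of one origin label one
contiguous stretch under a single pulse, so an origin-spanning track moves at
twice the per-fork speed — per-fork claims from widths require isolated
forks, which is exactly what the track simulator provides.

Downsampling analysis refits the HSMM from scratch at each retained-read
fraction (reusing the full-data model would leak information across
fractions). Fork counts default to min 2 reads per track, with the ≥ 3-read
subset reported alongside.

## Pair-correlation speed estimation

Distances: all unordered within-cell, within-chromosome read pairs ≤ 400 kb,
enumerated with a sorted sliding window (exact, not approximate). Display
binning is 5 kb; the mixture is fitted on raw distances — binning would only
discard information.

Mixture: four components on (0, 400 kb] — uniform (unrelated pairs),
exponential with mean constrained > 1,000 bp and weight > 0.01 (short-range
clustering), half-normal anchored at 0 (intra-pulse pairs), and a free
normal whose mean is the interpulse distance Δx̄ (pairs straddling the two
pulses of one fork). EM with soft labels: weighted means for the exponential
and normal, weighted variances for the half-normal and normal; constraints
projected each iteration; stop at relative tolerance 1e−8 or 100 iterations
(stopping at the cap is a valid stop, not a failure). Initialization:
exponential mean 5 kb, half-normal sd 10 kb, uniform weights, and the normal
mean seeded at the mode of the 5-kb-binned density beyond 20 kb — data-driven
seeding that avoids the normal component latching onto the short-distance
features. If the normal mean still collapses below 1 kb, up to three
restarts with a uniformly perturbed seed are attempted before flagging the
fit degenerate. The EM core is batched over rows of a distance matrix, which
is what makes B = 100 bootstrap refits cost ~seconds.

Speed: Δx̄/Δt in kb/min; Δt is the pulse center-to-center spacing (45, 75 or
105 min). Confidence intervals: percentile 2.5/97.5 over B = 100 (default)
bootstrap resamples refitted from the shared data-driven initialization; a
resample whose normal component collapsed is excluded, and more than 20 %
exclusions sets a `widened` flag.

Bias and its correction: under uniform per-bp sampling a fork moving at
speed s labels windows of length ∝ s and contributes ∝ s read pairs, so the
pooled fitted mean over-weights fast forks whenever speeds vary. The
simulation draws window scalings s from a truncated normal (at 0), places
Poisson(80) candidate reads uniformly on [−200, 200] kb and retains those in
(−45s, −30s) ∪ (30s, 45s) — window centers 75·s kb apart, i.e. the geometry
of a 15-min double pulse with Δt = 75 min. In the equal-intensity scenario
retained counts scale with s (bias present); in the unequal-intensity
scenario the uniform support is also scaled by s, so counts are
s-independent (no bias) — the surface is therefore built from the
equal-intensity mode. For each (μ, σ) on a grid (defaults μ = 0.4..2.0 step
0.2, σ = 0..0.6 step 0.1 kb/min, 2,000 forks per point), pooled within-fork
distances are fitted with the same mixture and the fitted normal mean/sd
converted to speed units; local quadratic regression with tricube weights
(span 0.75) predicts the generating μ and σ from a measured (mean, sd).
Queries outside the simulated hull are clipped to the boundary and flagged.
At σ = 0 the mapping is the identity to within Monte-Carlo noise; at broad σ
the corrected mean is below the fitted mean, as the weighting argument
requires.

## Synthetic data: what it does and does not establish

`simulate_pulse_tracks` reproduces the estimator-comparison design: reads
per pulse ~ Poisson(λ), placed uniformly in unit windows (first pulse 0–1,
second 2–3), one unit = pulse length × speed (15 kb at 1 kb/min), so ground
truth is 1 kb/min by construction and the double-pulse estimator (mean
pairwise first-to-second pulse distance over the 2-unit center spacing) is
unbiased at any λ, while the width estimator's expectation is
`n/(n+1) × truth` — the downsampling-robustness contrast the tests assert.
Tracks here are single (unidirectional) forks; whether the original design
used single or bidirectional forks is unstated, and single forks are the
reading under which "per-track speed" is well defined.

`simulate_paircorr_cell` is the retained-window design described above.

`simulate_whole_cell` places bidirectional origins on a genome (two
divergent forks per origin, truncated-normal speeds), labels pulse windows
per scheme, samples reads at a per-kb rate inside windows (default 0.5/kb ≈
7 reads per 15-kb track, matching the ~7 reads/track, ~5 % coverage regime
of real data) plus uniform background, and deduplicates positions. Staged
cohorts draw origins where a triangular-wave timing profile (period 4 Mb)
lies within a bandwidth (default 0.2) of the cell's stage, so same-stage
domains recur across the genome the way early/late replication domains do.
The desk-scale genome (tens of Mb, tens of origins) is a ~100× scale-down of
a real cell; fork counts and absolute read totals are therefore not
comparable to real data, only the per-track and per-distance statistics are.

Not emulated: restriction-site spacing (~250 bp granularity of real
positions), mappability, copy number, sequencing error, and origin-firing
correlations beyond the timing profile. A green end-to-end test therefore
establishes that the estimators recover their own generative truth under
idealized sampling — not that real-data values will match.

## Numerical and design choices

- All randomness flows from `numpy.random.SeedSequence`; simulators are
  bit-reproducible under a fixed seed, and the CLI funnels one master seed.
- Viterbi ties are broken toward background (conservative track calling).
- Distance-matrix entries are exact up to the 1000 cap; the cap binds at
  score ≤ 1/1001.
- Max-normalizing an all-zero heatmap row returns zeros, never NaN.
- The gene-overlap priority rule is deterministic: higher raw count wins,
  ties go to the earlier interval start.
- The S-phase gate for pseudo-bulk expression is the conjunction
  0.333 < score < 0.75.
- Region-weighted speed densities use a Gaussian-kernel weighted histogram,
  max-normalized; the significance test resamples 10,000 draws per density
  and applies Welch's t-test with Bonferroni scaling across region classes.

## Known limitations

- Single-pulse track widths conflate the two forks of one origin; the
  package does not attempt origin splitting or fork-direction inference.
- The ordering consensus needs enough cells (≳ 20 in practice) and enough
  embedding runs; small cohorts fail loudly rather than silently.
- The mixture's `normal_sd` is the closest available measure of within-cell
  speed variability; no separate variability index is defined.
- Bootstrap CIs reflect sampling noise given the model; they do not cover
  model misspecification (e.g. non-exponential gap tails).
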