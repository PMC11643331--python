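# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of the package, at the level of detail a maintainer or reviewer
needs to trust (or challenge) its outputs.

## Serially balanced sequences

A circular *type 1 index 1 serially balanced* sequence over an alphabet of
`n` trial types has length `n^2` and contains every ordered pair of types
-- self-pairs included -- exactly once among its circular adjacencies; this
balances first-order carryover across the session.  For even `n` the
package additionally requires the sequence to decompose into `n` aligned
blocks, each a permutation of the alphabet, which is what puts one probe
and one null trial in every block (five of each per 100-trial run at
`n = 20`).

Construction.  Self-pairs can only occur at block junctions (a type cannot
repeat inside a permutation block), so a blocked sequence is exactly a
closed chain of `n` arc-disjoint Hamiltonian paths on the loopless complete
digraph, consecutive paths linked end-to-start.  A natural candidate is a
row-complete (Williams) Latin square with its rows chained -- but that
cannot work: the last-minus-first element of any sequencing of Z_n equals
the sum of all nonzero residues, `n/2` for even `n`, so the row-chaining
permutation always splits into at least two cycles.  The package instead
searches: blocks are built one at a time as randomized Hamiltonian paths on
the remaining arcs (candidates ordered by fewest onward options, random
tie-break), with backtracking across blocks and seeded restarts.  This
finds blocked sequences essentially instantly for all even `n <= 20`
(about 1-2 s at `n = 20`).

Two genuine edge cases: `n = 4` has *no* blocked circular sequence at all
(verified by exhaustive enumeration of all start permutations and
arc-disjoint path chains), and odd `n` cannot have permutation blocks
(counts per block are not integral).  Both fall back to a randomized
Hierholzer Eulerian circuit on the complete digraph with self-loops, which
preserves the pair-coverage property without block structure.  The final
sequence gets a uniformly random seeded rotation (by whole blocks when the
block structure is present).

## Timing

ISIs are `min_isi + E`, with `E` exponential of mean `mean_isi - min_isi`
truncated at `3 x mean_isi`, iteratively rescaled so the run's ISI total is
exactly `n_trials x mean_isi`, then quantized to 0.1 s with the residual
repaired in 0.1 s steps (never violating the floor or the cap).  The total
constraint is what makes the default run duration exactly reproducible:
5 s lead-in + 3 context trials x (2.5 s stimulus + 2.5 s mean ISI) +
100 trials x 2.5 s + 250 s of ISI + 15 s tail = 535 s.

Design efficiency is Dale-style estimation efficiency
`1 / trace(C (X'X)^-1 C')`: per-condition boxcars convolved with a
canonical double-gamma response (gamma peaks at 6 s and 16 s, undershoot
ratio 6) at 0.1 s resolution, sampled at a 1 s TR, identity contrasts over
conditions by default, intercept excluded from the contrast.  Singular
designs score 0 with a warning.  `select_best_design` is a seeded argmax
over candidate timings with ties to the lowest index.  The efficiency
contrast set and the ISI truncation are choices of this package; only the
distribution shape, mean, minimum, and candidate count are externally
fixed.

## Synthetic ground truth

The generator produces the statistical structure the analyses assume:
per-subject, per-session condition x unit pattern tables whose noiseless
split-data RDM is a *known weighted mixture* of named model RDMs.

The subtle point is that split-data RDMs are correlation distances: after
per-unit z-scoring and the row-standardization implicit in Pearson
correlation, the neural RDM measures angles of the centered pattern
configuration, not raw Euclidean distances.  Generating patterns by metric
scaling of a mixture RDM (the textbook route) therefore distorts the
recovered geometry -- centering re-expresses everything as angles from the
centroid, and rank correlations between the generating RDM and the
recovered RDM top out around 0.83-0.95 even with zero noise.

The package's generator avoids this by working in correlation geometry
end to end:

1. Each model is a latent feature configuration `F` (category means plus
   exemplar noise, default 8 feature dimensions, exemplar scale 0.6) that
   is *balanced*: iterated column-centering, covariance whitening
   (eigenvalue floor 1e-3 x max for stability), and row-standardization to
   a fixed point.  The balanced configuration has near-zero column means,
   isotropic column covariance, and unit row norms.
2. The model RDM is `1 - F F'`, the correlation distance of the balanced
   configuration.
3. Subject patterns concatenate the models' configurations scaled by the
   square roots of their normalized mixture weights, mapped to unit space
   through a shared orthonormal map (scaled so each unit carries signal
   variance ~ 1/latent_dim), plus independent Gaussian noise per subject x
   session x unit; each unit's profile is then z-scored (population SD).

Because the blocks are row-standardized and the concatenated rows have
unit norm, the noiseless pattern-correlation matrix is exactly the
weighted sum of the models' correlation matrices, and the balancing makes
unit z-scoring a no-op in distribution.  Measured consequences (also
asserted in the tests): noiseless single-model recovery at Spearman
`rho >= 0.997` across seeds, and correct rank-ordering of four mixture
weights (1.0 / 0.7 / 0.4 / 0.2) by group-mean joint-regression
coefficients in 50/50 seeds at 20 subjects, 500 units, pattern noise
SD 1.0.

Inter-model correlation is steered by mixing a shared category-structured
component into each model's raw features, with the mixing weight found by
bisection against the measured mean pairwise Spearman correlation of the
resulting RDMs (tolerance ~0.02 at the bisection stage).  Even nominally
independent models retain a small positive RDM correlation (~0.05-0.09)
because they share the category partition; the default exemplar scale was
chosen so this floor stays below 0.1.

What the generator does *not* emulate: subject-specific functional
topographies (a single shared latent-to-unit map stands in for data that
have already been functionally aligned), hemodynamics and trial-level
variability (patterns are condition-level), realistic gaze saliency, and
real lexical semantics.  Passing tests therefore certify the estimators
and their statistical calibration, not robustness to those sources of
real-data structure.

Other generators: arrangements are 2D metric-scaling layouts of each
subset's sub-RDM, randomly rotated/reflected, scaled to the arena edge,
with isotropic placement jitter; gaze prototypes are low-pass random walks
per stimulus, with per-trial Gaussian jitter and censored blink spans whose
expected coverage equals `blink_prob` (1.0 censors whole trials);
annotations draw 2-5 verb and 3-6 nonverb tokens per stimulus from
category-clustered synthetic vocabularies with controllable cluster
separation.

## RDM construction choices

- Split-data RDMs symmetrize the two cross-session triangles by averaging;
  the diagonal stores `1 - c_ii` (split-half reliability complement) but
  is excluded from vectorization.  Zero-variance patterns are an error
  naming the stimulus.
- Arrangement distances are averaged raw (screen pixels) across trials and
  participants; an optional per-trial RMS normalization flag exists but
  defaults off.  A pair never measured in any trial is an error.
- Gaze preprocessing: invalid spans linearly interpolated from flanking
  valid samples; rolling median with the nearest odd sample count to 84 ms
  at the native rate (85 samples at 1000 Hz), window shrinking at the
  edges; decimation by per-bin means over `duration x out_rate` equal
  sample bins (60 bins at the defaults; bins differ by one sample when the
  ratio is not integral).  Fully censored trials are excluded.  Gaze trial
  distance is the sum over samples of the Euclidean distance between the
  two trajectories.
- Gaze reliability: participants are retained iff the mean pairwise
  Pearson correlation of their block RDM vectors reaches the threshold
  (default 0.1; -1 disables filtering); retained participants' RDMs are
  averaged over blocks, then participants; the report lists every
  participant's inter-block r.
- Semantic RDMs: unweighted token-vector means, cosine distance
  `1 - cos`; tokens missing from the embedding table are dropped with a
  warning and a stimulus losing all tokens is an error.
- Feature RDMs default to `1 - Pearson`; the metric is configurable
  (euclidean, cosine) because the appropriate metric for precomputed
  feature spaces is a user decision.

## Regression conventions

Model RDM vectors are rank-transformed (average ranks for ties) and
standardized; the response is rank-standardized too by default, so a
single-model fit equals Spearman rho squared exactly and joint `R^2` maps
live on the same scale as the correlation maps.  `rank_response=False`
switches to a mean/SD-standardized raw response.  Per-subject statistics
are computed first and averaged after: Fisher-z for correlations
(with +/-1 tolerated through the tanh limit for noiseless data),
arithmetic means for `R^2`.  Perfectly collinear predictor sets are an
error in direct joint fits; variance partitioning tolerates them through
the minimum-norm least-squares fit, where `R^2` (the only quantity it
uses) remains well-defined.  Negative unique `R^2` (suppression) is
reported as computed.

## Inference conventions

One-sided (greater) alternatives throughout; p-values use the add-one,
tie-inclusive convention `p = (1 + #{null >= observed}) / (1 + N)`, so p is
never 0 and exactly degenerate nulls (e.g., all subject correlations 0)
give the maximally conservative p = 1.  All tests take explicit seeds and
are bit-reproducible; each also has an exhaustive mode that enumerates the
full resampling space on tiny inputs, used by the test suite as an oracle.
Bootstrap CIs are percentile (2.5/97.5).  In the subjects-and-stimuli
bootstrap, cells pairing a stimulus with its own duplicate are excluded
from vectorization as zero-distance artifacts; draws on which the
statistic is undefined are discarded and logged, with more than 10%
discards an error.  Measured calibration (asserted in the tests): type-I
error of the sign-flip and condition-label tests within [0.03, 0.07] at
alpha = 0.05 over 1000 null replicates with 500 permutations each.

## Problem sizes used by the test suite

The suite exercises the full 90-stimulus, 20-type design; recovery studies
use 20 subjects x 2 sessions x 500 units over 50 seeds; calibration studies
use 1000 replicates at 500 permutations with 10-subject samples and
12-stimulus RDMs; exhaustive oracles use <= 3 subjects / <= 4 stimuli /
<= 4 models, where the full enumeration is small.  These sizes were chosen
so every stochastic claim is backed by enough replicates to be stable
across seeds while the whole suite stays fast enough to run routinely.

## Known limitations

- Searchlight neighborhoods are an explicit input (center -> member units);
  the package does not process cortical meshes or geodesic distances.
- The blocked-sequence search is heuristic; no existence proof is offered
  for all even alphabets (it has been verified for even n <= 20, and n = 4
  is provably impossible and handled by fallback).
- The recentered bootstrap inherits the usual caveat that subject
  resampling approximates the sampling distribution of the mean; it is not
  a second-order-accurate (BCa) interval.
- The ISC noise ceiling bounds models that are themselves estimated from
  comparably noisy data; noise-free model RDMs (as in the synthetic
  studies) can legitimately exceed the squared ceiling.
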