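# Methods

## Scope and data model

The package operates on three kinds of input: dyadic match records
(assay, cage, chronological order, two animal identifiers, win/loss/tie,
optional per-animal counts), BORIS-style ethogram event tables for the
tube test, and two-animal pose tracks (2 animals × 6 nodes × frames of
pixel coordinates with missing values) plus a reward-port landmark. All
tabular I/O is plain CSV (UTF-8, header row); pose recordings round-trip
through a small HDF5 layout (`tracks` 2×6×F×2, `node_names`, port/fps
attributes) or a long-format CSV.

## Rating systems

**Elo.** Ratings start at 1,000 and update per match as
`R' = R + K (S − E)` with `E_A = 1/(1 + 10^((R_B − R_A)/400))`,
`S ∈ {1, 0, 0.5}`, `K = 20`. The update is implemented as a single
transferred delta, so conservation (`ΣR` constant) holds exactly rather
than to roundoff. Ties participate via `S = 0.5`; animals listed for a
cage but never matched stay at baseline. `K` and the 400-point scale
control sensitivity; they are configurable but the defaults are the
values used throughout the analyses.

**David's score.** `DS = w + w2 − l − l2` on dyadic win proportions
`P_ij = α_ij/(α_ij + α_ji)`; dyads that never interacted contribute 0.
Ties are excluded from the win matrix: the tie-aware rating is Elo's
job, and a tie carries no directional information for a win-proportion
score. A group with zero decisive interactions raises an "unmeasurable"
error instead of returning zeros, since a David's score cannot be
computed for a cage that never fought.

**DCI.** `(H − L)/(H + L)` over per-dyad directional counts. Computed
directly from the win matrix; equals 1 iff every dyad is unidirectional
and is invariant to animal relabeling. Verified in tests against
brute-force counting.

**Rank simplification.** Scores map to dense ranks 1..n (1 = highest).
Exact score ties are broken by animal identifier — arbitrary but
deterministic, so rank vectors are always permutations and analyses are
reproducible. In practice continuous ratings almost never tie.

## Outcome rules

- **Urine marking:** tie if the spot counts differ by fewer than 5 spots
  *or* by less than 20% of the larger count; otherwise more spots wins.
  The comparison uses exact rational arithmetic (`Fraction`) so the 20%
  boundary cannot flip due to floating-point representation. Which
  denominator the percentage uses (larger count, mean, or sum) is an
  open choice; the larger count is used here.
- **Reward competition:** per-trial winner labels aggregate to a match
  outcome by majority of decisive trials (ties excluded from the
  denominator); an exact split is assigned deterministically to the
  lexicographically lower identifier, mirroring annotator practice of
  always assigning a winner.

## Dyad stability

Per-assay criteria, thresholds inclusive: agonistic — at least 3
interactions and ≥75% initiated by the same mouse (fewer than 3 →
unmeasurable); urine — all trials decisive with the same winner; tube —
≥75% same winner; reward — ≥60% of decisive trials same winner. A dyad
with no recorded interactions is unmeasurable in any assay. Stability
yields a dominant animal; only dyads stable in *both* assays of a pair
enter the maintained/reversed rank comparison, all others are counted
as excluded rather than folded into either bucket.

## Pose preprocessing and features

Missing node coordinates are linearly interpolated per node and axis
(edge gaps take the nearest present value), then each track is smoothed
with a Savitzky–Golay filter, window 25 frames, polynomial order 3. The
polynomial order is configurable; 3 is the common default in tracking
workflows and preserves cubic trajectories exactly (pinned by test).
Velocity is computed from the *smoothed* thorax positions as px/frame;
the first frame repeats the second frame's value to keep row alignment.

The seven features are built from sums and absolute differences across
the two animals (agent invariance) and from the port–thorax–nose angle
folded to [0°, 180°] (rotation invariance: clockwise and
counterclockwise headings coincide). Per-animal angles in [0, 180] make
the summed angle live in [0, 360] and the absolute difference in
[0, 180]. Degenerate angle frames (thorax coincident with nose or port
after smoothing — essentially impossible on real data) are imputed from
the nearest valid frame.

Frames are subsampled (every 3rd) *before* z-scoring, and z-scoring is
pooled across all recordings rather than per recording, because
clustering operates on the pooled frame set; per-recording normalization
would erase between-recording differences that are part of the signal.
A zero-variance feature maps to all-zeros rather than NaN.

## State discovery and statistics

K-means (k-means++ initialization, 10 restarts, fixed seed, best inertia
kept) clusters the z-scored features; k defaults to 8 but every analysis
here sets k to the known scripted state count. Cluster labels are
order-unstable across seeds by nature, so all cross-run comparisons use
the adjusted Rand index. UMAP (seeded, default parameters) is provided
strictly for visualization; labels never depend on it.

Percent enrichment of rank-difference stratum *i* in cluster *j* is
`n_ij/n_i· − n_·j/N`; rows sum to zero by construction and entries lie
in [−1, 1]. Frames from recordings without rank metadata are excluded,
not guessed. Per-recording cluster distributions (fractions summing
to 1) feed group comparisons, which are delegated to standard
statistical routines (scipy/statsmodels) as is the Fisher's exact test
on reversal proportions and the Holm–Bonferroni adjustment.

## Synthetic data

**Matches.** Each cage has distinct latent dominance values (default
1.5, 0.5, −0.5, −1.5); animal *i* beats *j* with Bradley–Terry
probability `1/(1 + exp(−β(d_i − d_j)))`, β = 2 by default (adjacent
ranks win ~88% of decisive contests — steep but stochastic), ties with
probability 0.1. Trials per dyad default to the assays' sampling depth:
10 agonistic observations, 2 urine trials, 10 tube matches, 6 reward
matches. Any assay can be inverted (win probability sign-flipped) to
emulate a strain in which that assay runs against the hierarchy.

**Poses.** A Markov dwell model switches among scripted states — both
at the port; one at the port with the other ~150 px away, facing away
and pacing; one at the port with the other pressed to the far wall;
roaming — in a 640×480 px arena with the port on the left wall, 30 fps.
Rigid 6-node skeletons (nose 25 px ahead of thorax, ears ±8 px lateral
of the forehead, tail 30 px behind) are rotated to each heading;
Gaussian pixel noise (sd 2) and missing-completely-at-random masking
(5%) are applied last. Mean dwell defaults to 300 frames (10 s; 450 for
roaming): bouts long enough that smoothing-induced transition blur
stays a small fraction of frames, consistent with animals that camp at
the port or wall for many seconds at a time. A configurable multiplier
(>1) inflates the near-avert dwell for rank-difference-3 dyads,
planting a known enrichment signal.

What the generator does *not* emulate: continuous locomotion between
state anchors (placements jump at state boundaries and the
Savitzky–Golay filter converts the jump into a ~25-frame ramp, a crude
stand-in for real transit), identity-swap tracking errors, occlusion-
structured missingness (a gap-structured option exists behind a flag),
and body-shape variation. Passing recovery tests therefore show that
the feature/clustering machinery works when states are geometrically
real; they do not certify performance on noisy real-world tracking.

## Problem sizes and numerical choices

The recovery experiments run at desk scale: hierarchy recovery uses 100
seeds × 1 cage × 50 trials/dyad; the inversion experiment 20 seeds × 8
cages; state-clustering recovery 10 seeds × 4 recordings × 1,800 frames;
enrichment recovery 9 recordings × 5,400 frames (~5 bouts per state per
recording are too few to beat dwell sampling noise, so the enrichment
experiment uses the longer recordings). Elo conservation is asserted to
1e-9; enrichment row sums to 1e-12; z-scored columns to |mean| < 1e-8.
Stability thresholds compare exact `Fraction`s, so "≥ 75%" at the
boundary is exact, not float-approximate.

## Known limitations

- Agonistic fights and chases are weighted equally as matches; the
  underlying observation protocol does not say otherwise.
- Hierarchy steepness/linearity beyond DCI (Landau's h, triangle
  transitivity) is out of scope.
- No temporal smoothing (HMM) of state sequences: k-means labels frames
  independently, so brief boundary misassignments are expected.
- The CLI ingests SLEAP-like HDF5 only in the package's documented
  layout; converting a native SLEAP analysis file is a one-line reshape
  but is not automated here.
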