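# Methods

## Geometry and coordinates

All piece and silhouette vertices live in the ring
{a + b·√2 : a, b rational}, which is closed under rotations by multiples of
45°.  Poses are computed exactly (`cts.exact.Rt2` holds the two rational
coefficients); only the final overlap/containment tests go through shapely
on float coordinates, with an area tolerance of 10⁻⁶ square units.  A
placement is legal when its polygon exceeds the uncovered region (target
minus placed pieces) by at most that tolerance, which simultaneously
screens piece overlap and silhouette containment while tolerating exact
edge contact.

Pieces rotate about their centroid and are anchored by the lower-left
corner of their post-rotation bounding box.  The anchor grid of a
silhouette is the set of lattice points with coordinates
i/2 + j·(√2/2) per axis inside the silhouette's bounding box, numbered
row-major from 1.  The √2 coefficient j is bounded (default |j| ≤ 1,
config-exposed): the unbounded set is dense in the plane, while one ±√2/2
offset per axis already reaches every anchor needed by 45°-rotated pieces
in the bundled puzzles (e.g. the House chimney anchor at x = 4 − √2/2).

The House and the Monk are defined programmatically, each as the exact
union of a hand-verified 7-placement solution (stored with the puzzle and
checked by the test suite).  The Monk also defines the modal
"unrecognized composition" placement: a big triangle with its hypotenuse
along the belly base.  Notably, this error does not make the state
unfeasible by itself — the second big triangle still fits diagonally
through the torso — it becomes unfeasible only after the torso
parallelogram lands, which reproduces the delayed way such errors surface.
The transcribed observed-frequency table for the Monk's initial phase ships
as a CSV fixture; a YAML mapping ties its printed grid values/rotations to
placements in this package's numbering (the printed table and the
accompanying text disagree about the modal location — the fixture preserves
the table as printed and documents the discrepancy rather than reconciling
it).

## Vision

The uncovered region is sampled at pixel centers (default 16 px/unit;
minimum 8) into a binary mask; the edge image is the morphological boundary
(dilation minus erosion).  Templates are built by the same rasterizer from
the same poses, so a hole exactly congruent to a piece at a
raster-aligned anchor produces an SSD of exactly 0 — the completeness
property the tests assert.  SSD maps are computed by FFT correlation on the
binary rasters and rounded to integers, making candidate ordering exact and
deterministic; ties break by (row, column) scan order.  Non-maximum
suppression uses a radius of half the template's larger dimension, and at
most five candidates per template are kept.  Similarity is normalized as
s = 1 − ssd/ssd_max with ssd_max = (template edge count) + (maximum window
edge count of the current image), an upper bound on any window's SSD.
Candidates snapping to the same placement are merged keeping the lower SSD.
Templates include interior-free outlines only (the boundary operator sees
the filled mask); resolution and mirroring are config-exposed.

## Cognition

Strength weights: vision variant k_d = 0.2, k_cv = 0.8 with the frequency
screen off (options pass with f = 0); frequency variant k_d = 0.8,
k_cv = 0.2; balanced variant f·(1 − λ(1 − s)) with λ = 0.5 — a
multiplicative penalty was chosen over an additive one so that an option
with no data support stays at zero strength no matter how good its visual
fit, which is what a data-anchored "penalty on the frequency of choice"
should mean.  All weights are config-exposed.

Activation is A = B + S + ε: B is the option strength (no base-level decay
— choices, not latencies, are modeled), S spreads W/|context| (W = 1) to
chunks present in the context buffer (association 1 for a self-match, 0
otherwise), and ε is logistic noise with scale 0.25 by default (retrieval
threshold τ = 0; noise 0 makes every decision a pure function of the
state).  The context buffer keeps the six strongest options, a capacity
chosen near the classic 7 ± 2 span of visual working memory; ties break by
higher frequency, then lower grid index, then lower rotation.  A
recently-retrieved list (span 4) blocks immediate re-retrieval.

An unfeasible region is detected indirectly: some unplaced piece kind has
zero legal placements, so its area must be split across regions that cannot
host it.  Detection short-circuits retrieval rather than competing through
activation — the noticed problem seizes attention until cleared.  When the
flag first rises, the most recent placement is tagged into a FIFO problem
queue; region backtracking removes queue-head placements until the flag
clears (the queue is dropped once feasibility returns).  If the queue
empties while the state is still unfeasible, or retrieval fails with
nothing usable, piece backtracking removes the stored action with the
lowest frequency re-evaluated at the *current* phase (an action with no
late-phase support goes first), ties to the most recent.

Phases bin the 1-based step index: phase 1 is steps 1–4 (opening patterns
stabilize by step 4), phase 2 runs to the ceiling of the mean trace length
(default bin edge 11), phase 3 is everything later.  Bin edges are
config-exposed; frequency tables normalize place-action counts to sum to 1
within each phase.

## Synthetic participants

The generator emulates the three-phase structure of human trials: a
best-fit start (the puzzle's opening pattern: head square + small triangle
for the Monk; chimney + roof for the House), an exploration phase, and a
best-fit completion.  With probability `p_perfect` a trace is a minimal
7-step solution (opening first, the remaining five placements shuffled
uniformly).  Otherwise the opening is placed, the modal composition error
follows with probability `p_composition_error` (default 0.7, reflecting how
dominant that error is in the observed initial-phase frequencies), and a
geometrically distributed number of exploration actions (rate 0.15, capped
at 20) mixes random legal placements with removals (probability 0.35; the
unnoticed error itself is protected until the final phase).  Exploration
placements exclude exact solution placements, so the perfect-strategy ratio
of a cohort is an unbiased binomial estimate of `p_perfect`.  Cleanup then
removes everything off-solution (the "noticing") and the completion places
the rest — every emitted trace replays legally and ends solved.  Default
`p_perfect` is 0.43 (House) and 0.27 (Monk), the perfect-strategy ratios of
the human training cohorts the generator stands in for; with the defaults a
200-trace Monk cohort has mean ≈ 11 steps and SD ≈ 5, right-skewed.

What the generator does *not* emulate: timing, mouse trajectories,
within-step "hovering" (imagining an action and abandoning it without
committing), individual skill differences, and any error type beyond the
modal composition error and random misplacement.  Tests passing against
synthetic cohorts therefore certify the machinery (legality, phase
structure, metric arithmetic, recovery of generator parameters), not
fidelity to any particular human population.

## Evaluation

Heatmap RMSE is computed per step over the five piece kinds with the
division by 5 inside the root, then averaged over the steps covered by both
heatmaps; columns are conditioned on traces still active at that step.
States plausibility compares state signatures — sorted lists of
(kind, grid_loc, rotation, mirror), so same-kind pieces are interchangeable
— over steps 3 to ceil(mean + 1·SD) of the data traces, with offset
schedule offset(s) = 1 + ⌊(s − 3)/4⌋ (growing with s to absorb longer
backtracking; both the schedule and whether duplicate model states are
deduplicated are flags, defaults: schedule as above, no deduplication).
Prediction accuracy replays each data trace step by step, asks the model
for its next action at every prefix, and scores a hit when the suggested
(action, kind, grid_loc, rotation) occurs within the next 2 steps; a flag
relaxes matching to piece kind only.  `overall_stats` counts removals as
steps by default (`count_removals` flag); without a puzzle to replay
against, a trace counts as perfect iff it is exactly 7 place actions,
which is exact for generated cohorts since they only emit solved traces.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds; batch runs
  use consecutive seeds.  Noise-off runs draw nothing, so they are pure
  functions of their inputs.
* SSD integer rounding absorbs FFT round-off (inputs are binary), making
  candidate ranking platform-stable.
* Degenerate inputs: an empty uncovered region rasterizes to an all-zero
  edge image; templates larger than the image match nothing; a blank edge
  image returns worst-case candidates (similarity 0) that die in
  filtering; a dead end (backtracking with nothing placed) aborts the run
  as unsolved rather than raising.
* The simulator binds each chosen option to a free piece instance of the
  matching kind, so at most 2 small triangles, 2 big triangles and 1 of
  each other kind are ever on the board.
* Problem sizes in the test-suite: soundness sweeps use 100 randomized
  partial states per puzzle with periodic full oracle-equivalence checks;
  generator-recovery checks use 200-trace cohorts against 3-binomial-SD
  bands; self-prediction uses noise-free model traces.
* Known limitations: the model must commit an action before it can
  backtrack it (no "immediate thinking"), which inflates step counts after
  mistakes; unfeasibility detection is exhaustive rather than perceptual,
  so it notices area splits a human might miss; frequency tables from
  small cohorts make the frequency-leaning variants brittle (options can
  lose all phase support and trigger long backtracking excursions).
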