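# cts — a cognitive tangram solver

`cts` simulates and anticipates how individual humans solve Tangram
puzzles, step by step.  It is aimed at researchers in computational
cognitive modeling and human-aware AI who need a process model of
sequential problem solving: not just *whether* a puzzle gets solved, but
*which* piece a person is likely to pick next, where they will put it, and
when they will backtrack.

## The model

A Tangram silhouette (area 8, with the small-triangle leg as the unit) must
be tiled by seven pieces — 2 small triangles, 1 medium triangle, 2 big
triangles, 1 square, 1 parallelogram — placed on an anchor grid at
45° rotation steps.  The solver couples a visual front end with an
activation-based memory model:

1. **Action-option extraction (vision).**  The uncovered region is
   rasterized, its boundary taken as a binary edge image, and one edge
   template per (piece kind, rotation, mirror) is slid across it.  Window
   positions are scored by the sum of squared differences (SSD); up to five
   local minima per template survive non-maximum suppression, are snapped
   to the nearest grid anchor, and screened for geometric legality and for
   support in training data at the current solution phase.  Each survivor
   is an *action-option* `(kind, location, rotation)` with similarity
   `s = 1 − ssd/ssd_max ∈ [0, 1]`.

2. **Strength (cognitive principles as one number).**  An option's strength
   combines its phase-conditioned relative frequency `f` in training traces
   with its visual similarity `s`:

   ```
   strength = k_d · f + k_cv · s          (vision / frequency variants)
   strength = f · (1 − λ · (1 − s))       (balanced variant)
   ```

   The *vision* variant (k_cv ≫ k_d, frequency screen off) leans on shape
   affordance ("best fit"); the *frequency* variant leans on the behavioral
   data; *balanced* discounts the data-derived frequency by the size of the
   template-matching error.

3. **Retrieval (choice).**  Strength is the option's base-level activation.
   The six strongest options form a context buffer and receive spreading
   activation `W/|context|`; retrieval returns the chunk maximizing
   `A = B + S + ε`, with `ε ~ logistic(0, noise_s)`, if `A` exceeds the
   retrieval threshold, and never re-retrieves a recently retrieved chunk.

4. **Backtracking.**  If some unplaced piece kind has no legal placement
   left, the partial solution is unfeasible: the most recently placed piece
   is tagged into a problem queue and removed queue-first (*region
   backtracking*).  A retrieval failure with no usable option instead
   removes the placed action with the lowest current-phase frequency
   (*piece backtracking*).

Two silhouettes ship with the package — the **House** (with chimney) and the
**Monk** — each with an exact, hand-verified 7-placement solution.  The Monk
additionally carries the modal "unrecognized composition" error: its belly
must be tiled by the two big triangles composed apex-to-apex, but a single
big triangle laid flat along the belly base looks like a best fit and later
wedges the second big triangle out.

Model runs and synthetic participants are compared with four metrics: step
count statistics with the perfect-strategy ratio (solved in exactly 7
steps), per-step piece-choice heatmap RMSE
`RMSE_s = sqrt(Σ_p (h(p,s,model) − h(p,s,data))² / 5)`, step-by-step state
plausibility (model states matching data states at step ± offset), and
2-step-window next-action prediction accuracy.

## Worked example

Generate a synthetic training cohort of 31 Monk solvers, run the balanced
solver 30 times with activation noise, and evaluate:

```bash
cts synth --puzzle monk --n 31 --seed 7 --out train_monk.csv
cts batch --puzzle monk --variant balanced --runs 30 --seed 1 \
    --training-traces train_monk.csv --out model_monk.csv
cts evaluate --puzzle monk --model-traces model_monk.csv \
    --data-traces train_monk.csv --variant balanced --seed 1
```

which prints

```
{"puzzle": "monk", "variant": "balanced", "runs": 30, "solved": 30,
 "mean_steps": 11.47, "sd_steps": 6.34, "perfect_ratio": 0.567}
{"mean_steps": 11.466666666666667, "sd_steps": 6.339440491646438,
 "perfect_ratio": 0.5666666666666667, "heatmap_rmse_mean": 0.19236038599510893,
 "plausibility": 0.27238805970149255, "prediction_accuracy": 0.32860520094562645}
```

Read: all 30 noisy runs solved the Monk, taking 11.5 steps on average
(SD 6.3) against the minimum of 7; 57 % of runs were "perfect" (no
backtracking).  Per step, the model's piece-choice distribution differs
from the cohort's by an RMSE of 0.19; 27 % of the model's intermediate
board states also occur in the cohort around the same step; and when used
as a predictor of each participant's next move, the exact
(piece, location, rotation) suggestion happens within the next two steps
33 % of the time.

The library mirrors the CLI: `cts.simulator.run_trial` /
`run_batch` / `predict_next`, `cts.traces.synth_participants`,
`cts.evaluation.evaluate`, with puzzles from `cts.puzzles.get_puzzle`.

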