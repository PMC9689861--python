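# Methods

## Model

A patient (bag) is an `n × d` matrix of patch feature vectors. The model has
three stages, differentiable end to end:

1. **Instance scorer.** Two affine maps shared across instances
   (equivalently, width-one 1-D convolutions): `d → h` with ReLU, then
   `h → 1` with no activation, giving one raw scalar score per instance.
   Default `h = 128` (the original slide-cohort width); desk-scale synthetic
   runs use `h = 32`.
2. **Percentile selection.** Scores are sorted ascending (stable sort,
   original index breaks ties). For each percentile `p` in the scheme the
   center rank is `c = round(p/100 · (n−1))` with half rounded away from
   zero — nearest rank, no interpolation, because the method selects actual
   instances and an interpolated value would belong to no instance. A window
   of `k` consecutive ranks is centered on `c` and *shifted inward* (never
   truncated) at the boundaries so the head input width `|P|·k` is constant;
   if `n < k` the window is every rank, padded by repeating the boundary
   ranks. Overlapping windows of nearby percentiles are allowed and not
   deduplicated: constant width takes priority. Seven built-in schemes grow
   from `[0, 100]` (2 points) to a 13-point list covering the whole
   distribution.
3. **Risk head.** MLP over the selected scores with ReLU hidden layers
   (default 128 → 64 → 1; a single-hidden-layer 128 → 1 variant is one
   configuration flag away) producing the bag-level risk `O_i`.

Because selection happens on the sorted scores, the model is invariant to
instance permutations within a bag. The backward pass is derived by hand in
NumPy: the percentile gather back-propagates by scatter-adding the head's
input gradients into the selected score positions (the exact adjoint of a
gather), and the scorer/head layers use standard dense backprop. All
aggregators implement one forward/backward interface, so the comparators
(mean pooling, max-pooling top-1/top-10, top-plus-bottom-10) differ from the
percentile model only in the aggregation step; the mean-feature comparator
bypasses the neural path entirely and fits an L1-penalized Cox model (via
lifelines) on bag-level mean feature vectors, with the penalty chosen by
internal cross-validation over a geometric grid when not given.

**Attention variant.** Within each percentile window the `k` selected
scores are combined into one value by softmax attention weights from a small
scalar → tanh → logit network, so the head sees exactly one input per
percentile location (equal prior weight per location regardless of `k`).
With `k = 1` it reduces exactly to the plain model. The published
description of this variant is underdetermined; this implementation attends
within windows and makes no claim of architectural equivalence to any other.

## Training objective

The Cox negative log partial likelihood uses the Breslow convention for
tied event times: the risk set of subject `i` is every subject with
observed time `≥ t_i`, including `i`. The printed form of this loss in some
sources carries a sign typo (`δ_i(−O_i − log Σ e^{O_j})`, which is not a
likelihood); the implementation uses the standard
`−Σ δ_i (O_i − log Σ_{t_j ≥ t_i} e^{O_j})`. The log-sum-exp is max-shifted
so scores up to `|O| ≈ 10³` do not overflow. During training the loss is
divided by the number of events so magnitudes are comparable across batch
sizes; the unnormalized value is exposed for exactness tests. All-censored
input contributes no terms and returns exactly zero with a warning.

Risk sets are formed within each training batch; the default batch is the
whole training cohort, which desk-scale cohorts allow, so no approximation
is introduced. Optimization is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with
optional decoupled-as-L2 weight decay. Early stopping is patience-based on
the validation Cox loss (default patience 10, max 200 epochs) and the
parameters of the best validation epoch are restored. A small grid over
learning rate {1e-3, 1e-4} × weight decay {0, 1e-4} is searched by
validation loss by default; desk-scale runs use the single point
(1e-3, 0) to keep a run in seconds. Parameters are initialized
fan-in-scaled uniform from a seeded generator; every run is deterministic
given its seed.

## Evaluation conventions

* **Concordance index (Harrell).** Comparable pairs are `(i, j)` with
  `t_i < t_j` and `δ_i = 1`; tied observed times are not comparable; tied
  predicted risks count ½. An input with no comparable pair raises instead
  of returning 0.5.
* **Risk stratification.** Threshold = median of *training* risks (midpoint
  of central order statistics for even counts); an evaluation risk `≥`
  threshold is high-risk. A split that empties one group raises.
* **Kaplan–Meier / log-rank.** Standard product-limit estimator (events
  before censorings at tied times) and the two-group log-rank chi-square
  with one degree of freedom; both are cross-checked against lifelines in
  the test suite.

## Synthetic cohort generator

The generator emulates post-extraction feature bags, not images. Per bag:
mixture proportions over `n_types = 4` latent tissue-like types are drawn
from Dirichlet(2, 2, 2, 2); instance types are multinomial in those
proportions; each instance carries a latent scalar `u = type mean + N(0, 1)`
with type means (−1.5, −0.5, 0.5, 1.5); features are the type's mean vector
(drawn once per cohort from N(0, 0.5)) plus isotropic N(0, 0.3²) noise,
with `u` added to feature column 0 so the scorer must learn a nontrivial
but low-dimensional mapping. The true log-hazard is
`r = Σ_q β_q · Q_u(q)`, where `Q_u` uses the *same* nearest-rank convention
as the model's selection (removing a confound in recovery tests). Event
times are Exponential(λ₀·e^r) with λ₀ = 0.05/month; censoring is an
independent Uniform(0, 60] months administrative limit, mirroring a typical
five-year follow-up window and yielding ≈ 65% observed events. Defaults:
300 bags × 200 instances × 16 features.

Three named conditions: **null** (β = 0, no signal; truth-based oracle
C-index is exactly 0.5), **mid-quantile** (β = 1 at the 25/50/75th
percentiles of `u`; oracle ≈ 0.76 — extremes-only readers are nearly blind
to it), and **strong-signal** (β = 1.2 at 10/25/50/75/90; oracle ≈ 0.86,
used for stratification tests).

What the generator does *not* emulate: spatial correlation between patches,
batch/stain effects, heavy-tailed feature noise, non-proportional hazards,
and informative censoring. Passing the synthetic recovery tests therefore
shows the pipeline can detect distribution-located signal under clean
proportional-hazards conditions — not that it reaches any particular
performance on real slide cohorts.

## Desk-scale experiment protocol

Trend and calibration checks use, per seed, 3-fold cross-validation within
one 300-bag cohort: each fold serves once as the monitored validation split
on which the C-index is reported (the slide-cohort protocol is 5-fold/80-20;
3 folds keep the full sweep in minutes on one CPU). Cohorts generated from
different seeds draw different latent type feature means and are therefore
*not* i.i.d. hold-outs for one another; evaluation always stays within a
cohort. Stratification checks train on 180 bags, early-stop on 60 and
evaluate the median split on the remaining 60.

## Numerical choices and degenerate inputs

* Percentile → rank rounding is half-away-from-zero; `round`, `floor` and
  interpolation variants disagree only at exact .5 boundaries, and the
  chosen convention is pinned by oracle tests for every `n ≤ 50` and
  `n = 12,000`.
* Bag resampling to a fixed size draws without replacement when shrinking
  and retains all originals, topping up with replacement, when growing —
  preserving maximal information in both directions. It is fixed once per
  bag per run (seeded), not redrawn per epoch; a flag-equivalent (re-calling
  with a new seed) exists because the original protocol is silent on this.
* Checkpoints are a `.npz` parameter archive plus a JSON sidecar echoing
  the architecture (scheme, widths, seed), so they are self-describing.
* Degenerate inputs raise early with specific messages: empty cohorts,
  non-finite features, events outside {0, 1}, non-positive times, duplicate
  bag ids, feature-dimension mismatches, no comparable pairs, zero-event
  log-rank tables, empty median-split groups.

## Known limitations

* The neighborhood effect (`k > 1`) has almost no headroom under this
  generator: the true hazard reads exact `k = 1` nearest-rank quantiles of
  `u`, and with feature noise sd 0.3 the learned scores are nearly
  noiseless reads of `u`, so the single-instance reader is already aligned
  with the truth. Desk-scale experiments accordingly check non-inferiority
  of `k = 3` rather than expecting a measurable improvement; a generator
  with heavier instance noise would be needed to reproduce a positive
  neighborhood benefit.
* The L1-penalized Cox comparator delegates to lifelines' elastic-net
  implementation (`l1_ratio = 1`), which uses a smooth approximation to the
  L1 penalty; coefficients near zero are small rather than exactly zero.
* No GPU paths, no distributed training, no confidence intervals on the
  C-index, and no alternative survival losses.
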