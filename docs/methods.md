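# Methods

## The composite score

Given one model's panel of `n` evaluation metrics `d_1, …, d_n` (each a
non-negative number on a shared scale, normally `[0, 1]`), the metrics are
drawn as rays on a 2-D polar plane, laid counter-clockwise in panel order
and equally spaced by the included angle

    θ = 2π / n.

Adjacent rays `d_i`, `d_(i+1)` span a triangle of area
`(1/2)·d_i·d_(i+1)·sin θ` (the SAS triangle-area identity: the height onto
side `d_i` is `d_(i+1)·sin θ`). The cumulative performance score is the area
of the closed polygon through the ray tips,

    Area_total = (1/2)·sin θ · Σ_{i=1}^{n} d_i · d_(i+1),   with d_(n+1) = d_1.

The wrap-around term closes the polygon; without it the figure is not a
polygon and the "total area" reading fails, so cyclic closure is part of the
definition here. The score rewards models that are strong on *adjacent pairs*
of metrics simultaneously — a single excellent metric surrounded by weak
ones contributes almost nothing, which is precisely the intended contrast
with looking at one metric at a time.

Properties that the test suite asserts, all consequences of the formula:

- **Oracle equivalence.** The triangle sum equals the surveyor's (shoelace)
  formula applied to the Cartesian vertices `(d_i cos iθ, d_i sin iθ)`.
  The tests keep a separate shoelace implementation as an independent check.
- **Quadratic scaling**: `score(c·d) = c²·score(d)` for `c > 0` (areas scale
  with the square of lengths). Rankings are therefore invariant to a common
  rescaling of all models.
- **Bound**: for values in `[0, u]`, `0 ≤ score ≤ (n/2)·sin(2π/n)·u²`, with
  equality at the all-`u` panel (the regular n-gon).
- **Monotonicity**: raising any single metric while the rest stay positive
  strictly raises the score; coordinate-wise dominance implies a higher score.
- **Order dependence**: the score is invariant to cyclic rotation and to
  reversal of the panel order but *not* to arbitrary permutations (swapping
  non-adjacent rays changes which products appear). All models in a table are
  therefore scored under one shared ordering — the table's column order — and
  that ordering is recorded in the result's `PolarGeometry` and echoed in
  reports.

## Weighting

A weight vector maps metric names to non-negative factors; the weighted
score replaces each raw value by `S_weighted = S_metric × W_metric` before
projection. Metrics absent from the mapping keep weight 1, so an empty
mapping is exactly the unweighted analysis. A weight of exactly 0 means the
user excludes that metric: it is removed from the panel, `n` shrinks and θ is
recomputed, rather than leaving a zero-length ray (which would silently
annihilate the two neighbouring triangles). Negative weights are rejected.
Weights above 1 are allowed and may push values past the declared upper
bound; that triggers a warning, not an error, and only affects the clamped
`normalized_score`.

## Normalization (convenience extra)

The primary output is the raw area. `normalized_score` divides it by the
maximum attainable area for the same geometry and declared upper bound `u`,
`(n/2)·sin(2π/n)·u²`, giving a `[0, 1]` number comparable across panels of
different sizes. It is an addition of this package, clearly labelled as such,
not part of the score's definition.

## Degenerate inputs and numerical choices

- `n ≥ 3` is enforced **after** zero-weight exclusion: `n = 2` gives
  `sin(π) = 0` (zero area for any input) and `n = 1` is not a polygon. Both
  raise `DegenerateGeometryError`.
- Missing/NaN metric values are an error, never an implicit 0.
- Negative values are rejected; metrics natively on `[−1, 1]` (Matthews
  correlation) must be rescaled, and `rescale_unit_interval` is provided.
  The panel accordingly only offers `mcc_rescaled = (MCC + 1)/2`.
- Values above the declared upper bound (default 1) warn and clamp the
  normalized score; the raw area is reported as computed.
- Equality tests run at 1e-9 absolute; the measured agreement with the
  shoelace oracle is at machine precision (~1e-15).
- Ranking ties share the minimum rank (competition ranking), are flagged in
  a `tied` column, and row order under ties falls back to lexicographic model
  name so reports are byte-deterministic.

## The metric panel

`metric_panel` computes, from true labels and hard predictions (plus
continuous scores where needed): accuracy, balanced accuracy, precision,
recall, specificity, F1, rescaled MCC, average precision (step-wise,
non-interpolated) and ROC AUC (trapezoid rule; tied scores contribute their
midpoint, so a constant score gives exactly 0.5). The default panel is
{accuracy, balanced_accuracy, precision, recall, f1, average_precision,
roc_auc}; composition is user-selected since no single canonical panel
exists. Ranking metrics are delegated to scikit-learn; threshold metrics are
computed from the confusion counts directly so that an undefined value (e.g.
precision when the model never predicts positive) raises
`UndefinedMetricError` with a remediation hint instead of a silent 0 — a
silent zero ray would distort the polygon badly.

## SD baseline and rank comparison

`compare_rankings` reports, per model, the composite score and the sample
standard deviation (n−1 denominator) of its raw metric scores, with ranks
under both criteria. The SD is always computed on the *unweighted* metrics,
even for a weighted score: it characterises the spread of the panel as
measured. The sample (rather than population) SD is a documented choice;
with the small panels involved (4–9 metrics) the distinction never reorders
models in any fixture used here. The two rankings can genuinely disagree — a
uniformly mediocre model has minimal SD but a small polygon — and the report
is required to be able to express that divergence. Given a second table with
the same models (e.g. held-out evaluation), the report adds cross-table
ranks, the count of identically ranked models, and the Spearman correlation
between the two score vectors.

## Synthetic data

The generators define the test conditions of the whole suite.

`simulate_classifier` draws labels `y ~ Bernoulli(balance)` and a latent
score `x | y ~ Normal(y·s, 1)` where `s` is the `separation` parameter (the
gap between class-conditional means, in SD units). The reported probability
is the exact posterior of the positive class under that generative model,

    p = expit( s·(x − s/2) + logit(balance) ),

thresholded at 0.5 (configurable) for the hard prediction. The calibrated
link was chosen over an arbitrary squashing of `x` because it yields two
clean analytic anchors that the tests check: the ROC AUC is
`Φ(s/√2)` for any `s` (so `s = 0 → 0.5`, `s = 3 → 0.983`, `s = 6 → ~1`), and
at `s = 0` the posterior collapses to the constant prior, i.e. the
majority-class predictor, whose accuracy is `max(balance, 1 − balance)`.
Defaults: `balance = 0.5`, `threshold = 0.5`; sample sizes in tests and the
acceptance script are 10,000, large enough that Monte-Carlo error on AUC and
accuracy is well under the 0.02 checking margin. One explicit integer seed
drives all randomness through `numpy.random.default_rng`; global RNG state is
never touched.

What this generator does *not* emulate: feature matrices (it simulates
classifier *outputs*, not classifiers), miscalibrated scores, label noise,
or dependence between models evaluated on the same test set. Passing tests
show the scoring pipeline behaves correctly on metric panels of the shapes
real pipelines produce; they say nothing about any particular biological
dataset.

`make_metric_table` produces tables that are i.i.d. `U[0,1]` (`random`),
strictly coordinate-wise dominance-ordered via per-column descending sort
(`dominated`, giving a known true ranking that is permutation-robust), or
identical rows (`constant`, exercising tie handling).

## IO and CLI

Tables are plain CSV/TSV (header = metric names, first column = model
names); **the column order in the file is the ray order** and is preserved
exactly. Numeric parsing uses Python's `float()` for full round-trip
precision, so write → read → write is byte-identical. Weights are JSON or
YAML mappings. In-memory construction from a pandas DataFrame is provided
(`MetricsTable.from_dataframe`) instead of inventing a file dialect for it.
All file writes (reports, tables, plots) go through a temp-file-and-rename
step so a failure never leaves a partial output.

The CLI is a thin layer: `mlcps panel` turns per-model prediction files into
a metrics table; `mlcps score` turns a metrics table into a ranked report,
optionally with a plot (`--plot kind:path`). Plot testing targets the data
arrays handed to matplotlib (vertex radii, bar heights), never rendered
pixels.

## Known limitations

- The score has no uncertainty quantification; no CI or bootstrap is defined
  for it here.
- Binary classification only; multi-class averaging is out of scope.
- The order-dependence means two users with different column orders get
  different absolute scores (though identical rankings whenever one model
  dominates another); the geometry echoed in every result is the guard rail.
- Metrics on incommensurate scales are the user's responsibility beyond the
  declared-upper-bound warning.
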