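# mlcps

A cumulative performance score for comparing classification models across a
whole panel of evaluation metrics at once.

Choosing "the best" classifier from a leaderboard of accuracy, precision,
recall, F1, AUC, … is tedious and biased toward whichever metric the reader
favours — and on imbalanced biomedical data a single metric is routinely
misleading. `mlcps` condenses a model's metric panel into one number with a
simple geometric construction: the `n` metric values `d_1, …, d_n` are drawn
as rays on a polar plane, equally spaced by `θ = 2π/n`, and the score is the
area of the closed polygon through the ray tips:

```
MLcps = (1/2) · sin θ · Σ_{i=1..n} d_i · d_{i+1},    d_{n+1} = d_1
```

(each term is the SAS area of the triangle spanned by two adjacent rays).
The area is large only when the model is strong across adjacent metrics
simultaneously, so it rewards all-round performance rather than one shining
number. Optional non-negative weights rescale individual metrics first; a
weight of 0 removes a metric entirely (the polygon loses a vertex and θ is
recomputed). See `docs/methods.md` for the full model, its invariances and
the design choices.

Intended users: anyone with a models × metrics table — the routine output of
an ML benchmarking pipeline — who wants a defensible single-number ranking,
plus the plots to justify it.

## Worked example

```python
from mlcps import MetricsTable, compare_rankings

table = MetricsTable(
    model_names=["knn", "svm", "random_forest", "dummy"],
    metric_names=["accuracy", "precision", "recall", "f1"],
    values=[
        [0.86, 0.84, 0.88, 0.86],
        [0.90, 0.92, 0.87, 0.89],
        [0.93, 0.91, 0.94, 0.92],
        [0.50, 0.50, 0.50, 0.50],
    ],
)
print(compare_rankings(table).to_string())
```

prints

```
        model    mlcps  mlcps_normalized       sd  rank_mlcps  rank_sd  tied            effective_metrics
random_forest 1.711050          0.855525 0.012910           1        2 False accuracy;precision;recall;f1
          svm 1.601850          0.800925 0.020817           2        4 False accuracy;precision;recall;f1
          knn 1.479000          0.739500 0.016330           3        3 False accuracy;precision;recall;f1
        dummy 0.500000          0.250000 0.000000           4        1 False accuracy;precision;recall;f1
```

`mlcps` is the polygon area (with 4 metrics on [0, 1] the maximum is 2.0,
reached by an all-ones row); `mlcps_normalized` divides by that maximum.
`rank_mlcps` is the composite ranking. Note the dummy model: its metrics
have the *smallest* spread (`rank_sd` 1, SD 0) yet it is the worst model —
ranking by consistency (SD) alone would pick it; the polygon area does not.

More narrative scripts live in `examples/` (weighted scoring and
zero-weight exclusion, building a metric panel from simulated classifier
predictions, SD-vs-score divergence, all three plot kinds).

## Command line

```bash
# per-model prediction files (y_true,y_pred[,y_score]) -> metrics table
mlcps panel --predictions knn.csv --predictions svm.csv --out metrics.csv

# metrics table -> ranked report + bar chart
mlcps score --metrics metrics.csv --weights weights.json \
            --out report.csv --plot bar:scores.svg
```

The column order of the metrics table is the ray order of the polygon and is
preserved exactly; all models in a table are scored under that one shared
geometry so their areas are comparable.

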