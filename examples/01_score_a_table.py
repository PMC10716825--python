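"""Score a small metrics table and rank the models.

Four classifiers evaluated with four metrics; each row becomes a closed
polygon on a polar plane and the polygon area is the composite score.
"""

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

report = compare_rankings(table)
print(report.to_string())
# The mlcps column is the polygon area (max 2.0 for four metrics on [0, 1]);
# rank_mlcps orders the models by it, rank_sd by the spread of their metrics.
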