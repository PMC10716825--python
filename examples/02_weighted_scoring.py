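"""Weight the metrics: emphasise recall, exclude precision entirely.

Weights multiply raw scores before projection; a weight of 0 removes the
metric, so the polygon loses a vertex and the ray angle is recomputed.
"""

from mlcps import MetricVector, WeightVector, compute_mlcps

metrics = MetricVector.from_dict(
    {"accuracy": 0.86, "precision": 0.84, "recall": 0.88, "f1": 0.86}
)

# expect a UserWarning: recall * 1.5 = 1.32 exceeds the declared upper bound
# of 1, so the normalized score is clamped (the raw area is unaffected).
plain = compute_mlcps(metrics, model_name="knn")
recall_heavy = compute_mlcps(
    metrics, WeightVector({"recall": 1.5}), model_name="knn"
)
no_precision = compute_mlcps(
    metrics, WeightVector({"precision": 0.0}), model_name="knn"
)

print(f"unweighted:          score={plain.score:.4f}  n={plain.geometry.n_metrics}")
print(f"recall weighted 1.5: score={recall_heavy.score:.4f}  n={recall_heavy.geometry.n_metrics}")
print(f"precision excluded:  score={no_precision.score:.4f}  n={no_precision.geometry.n_metrics} "
      f"(metrics: {', '.join(no_precision.effective_metrics)})")
# Upweighting recall grows the two triangles touching that ray; excluding a
# metric shrinks n from 4 to 3, so the remaining rays spread over 120 degrees.
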