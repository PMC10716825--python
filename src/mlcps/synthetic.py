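"""Synthetic fixtures with known structure.

Two generators make every stage testable without external data:

* :func:`simulate_classifier` draws labels and a one-dimensional Gaussian
  score whose class-conditional means are ``separation`` apart (unit
  variance).  The score is mapped to a probability through the calibrated
  logistic link implied by that Gaussian model, so the resulting classifier
  has an analytically known ROC AUC of ``Phi(separation / sqrt(2))`` and, at
  ``separation = 0``, degenerates to the majority-class predictor whose
  accuracy is ``max(balance, 1 - balance)``.

* :func:`make_metric_table` builds metric tables that are i.i.d. random,
  coordinate-wise dominance-ordered (so the true ranking is known and
  permutation-robust), or constant (so ties are exercised).

All randomness flows through one explicit seed; nothing touches global RNG
state, and identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .errors import InvalidMetricsError
from .io import MetricsTable
from .metrics import PredictionSet

__all__ = ["SimulatedClassifierSpec", "simulate_classifier", "make_metric_table"]


@dataclass(frozen=True)
class SimulatedClassifierSpec:
    """Parameters of one simulated binary classifier.

    separation is the difference of the class-conditional Gaussian score
    means (unit variance); 0 is an uninformative classifier, 3 a strong one
    (AUC ~ 0.983), 6 near-perfect.  class_balance is the positive fraction;
    threshold cuts the probability scale (default 0.5).
    """

    n_samples: int
    class_balance: float = 0.5
    separation: float = 0.0
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_samples, (int, np.integer)) and self.n_samples >= 1):
            raise InvalidMetricsError(f"n_samples must be a positive int, got {self.n_samples!r}")
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidMetricsError("class_balance must be in (0, 1)")
        if not (np.isfinite(self.separation) and self.separation >= 0):
            raise InvalidMetricsError("separation must be finite and >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise InvalidMetricsError("threshold must be in (0, 1)")


def simulate_classifier(spec: SimulatedClassifierSpec) -> PredictionSet:
    """Draw one simulated classifier's labels, probabilities and predictions.

    Labels are Bernoulli(class_balance).  The latent score is
    ``x | y ~ Normal(y * separation, 1)``; the reported probability is the
    posterior of the positive class under that model and the label prior,

        p = expit(separation * (x - separation/2) + logit(class_balance)),

    thresholded at ``spec.threshold`` for the hard prediction.  The expit
    argument is the exact log-likelihood-ratio plus prior log-odds, so the
    probabilities are calibrated and monotone in the latent score.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_samples) < spec.class_balance).astype(np.int8)
    x = rng.standard_normal(spec.n_samples) + spec.separation * y
    log_odds = spec.separation * (x - spec.separation / 2.0) + logit(spec.class_balance)
    prob = expit(log_odds)
    y_pred = (prob > spec.threshold).astype(np.int8)
    return PredictionSet(y_true=y, y_pred=y_pred, y_score=prob)


def make_metric_table(
    n_models: int,
    n_metrics: int,
    structure: str = "random",
    seed: int = 0,
) -> MetricsTable:
    """Generate a metrics table with known ground-truth structure.

    structure:
      ``random``    — i.i.d. Uniform[0, 1] cells.
      ``dominated`` — every metric of model_1 strictly exceeds model_2's,
                      and so on down the rows: the true ranking is the row
                      order, whatever the metric ordering.
      ``constant``  — all models identical (one uniform row repeated).
    """
    if not (isinstance(n_models, (int, np.integer)) and n_models >= 1):
        raise InvalidMetricsError("n_models must be >= 1")
    if not (isinstance(n_metrics, (int, np.integer)) and n_metrics >= 3):
        raise InvalidMetricsError("n_metrics must be >= 3")
    rng = np.random.default_rng(seed)
    if structure == "random":
        values = rng.random((n_models, n_metrics))
    elif structure == "dominated":
        # per-column descending sort => coordinate-wise strict dominance a.s.
        values = np.sort(rng.random((n_models, n_metrics)), axis=0)[::-1]
        while np.any(np.diff(values, axis=0) == 0):  # pragma: no cover
            values = np.sort(rng.random((n_models, n_metrics)), axis=0)[::-1]
    elif structure == "constant":
        values = np.tile(rng.random(n_metrics), (n_models, 1))
    else:
        raise InvalidMetricsError(
            f"structure must be random|dominated|constant, got {structure!r}"
        )
    models = [f"model_{i + 1}" for i in range(n_models)]
    metrics = [f"metric_{j + 1}" for j in range(n_metrics)]
    return MetricsTable(models, metrics, values)
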