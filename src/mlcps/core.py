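"""Cumulative performance score: polygon area on a polar metric layout.

A model's evaluation metrics are drawn as rays on a 2-D polar plane, one ray
per metric, equally spaced by the included angle ``theta = 2*pi/n``.  Adjacent
rays of lengths ``d_i`` and ``d_{i+1}`` span a triangle of area
``(1/2) * d_i * d_{i+1} * sin(theta)``; the cumulative performance score
(MLcps) is the area of the closed polygon, i.e. the cyclic sum

    Area_total = (1/2) * sin(theta) * sum_{i=1..n} d_i * d_{i+1},

with the wrap-around convention ``d_{n+1} = d_1``.  Larger areas mean a model
that scores well across the whole metric panel simultaneously.

Weights multiply raw metric scores before projection; a weight of exactly zero
removes the metric entirely, shrinking ``n`` (and hence ``theta``) before the
area is computed.

The score is order-dependent: it is invariant to cyclic rotation and reversal
of the metric ordering but not to arbitrary permutations, so a whole table of
models must share one fixed ordering for scores to be comparable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InvalidMetricsError

if TYPE_CHECKING:  # pragma: no cover
    from .io import MetricsTable

logger = logging.getLogger(__name__)

__all__ = [
    "MetricVector",
    "WeightVector",
    "PolarGeometry",
    "MLcpsResult",
    "compute_angle",
    "apply_weights",
    "compute_mlcps",
    "compute_mlcps_table",
    "max_polygon_area",
]

#: minimum number of effective metrics for a non-degenerate polygon
MIN_METRICS = 3


def _as_clean_names(names: Iterable[str]) -> tuple[str, ...]:
    names = tuple(str(n) for n in names)
    if len(names) == 0:
        raise InvalidMetricsError("at least one metric name is required")
    if any(n == "" for n in names):
        raise InvalidMetricsError("metric names must be non-empty strings")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if list(names).count(n) > 1})
        raise InvalidMetricsError(f"duplicate metric names: {dupes}")
    return names


@dataclass(frozen=True)
class MetricVector:
    """Named, ordered metric scores for one model.

    The order of ``names`` is the ray order on the polar plane and therefore
    part of the score's definition.  Values are the ray lengths ``d_i``:
    finite, non-negative reals on a common scale (metrics natively on
    ``[-1, 1]`` such as Matthews correlation must be rescaled first, see
    :func:`mlcps.metrics.rescale_unit_interval`).
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __init__(self, names: Iterable[str], values: Iterable[float]):
        object.__setattr__(self, "names", _as_clean_names(names))
        vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                          dtype=float)
        if vals.ndim != 1 or vals.shape[0] != len(self.names):
            raise InvalidMetricsError(
                f"expected {len(self.names)} values, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            bad = [self.names[i] for i in np.flatnonzero(~np.isfinite(vals))]
            raise InvalidMetricsError(
                f"non-finite metric values for {bad}; missing cells must be "
                "resolved explicitly, they are not treated as zero"
            )
        if np.any(vals < 0):
            bad = [self.names[i] for i in np.flatnonzero(vals < 0)]
            raise InvalidMetricsError(
                f"negative metric values for {bad}; ray lengths must be >= 0 "
                "(rescale signed metrics to [0, 1] first)"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "MetricVector":
        """Build from an ordered name -> value mapping (insertion order kept)."""
        return cls(list(mapping.keys()), list(mapping.values()))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class WeightVector:
    """Non-negative per-metric weights ``W_metric``.

    Metrics absent from the mapping implicitly keep weight 1; a weight of
    exactly 0 excludes the metric from the score.  Negative weights are
    rejected at construction.
    """

    weights: Mapping[str, float]

    def __init__(self, weights: Mapping[str, float]):
        clean: dict[str, float] = {}
        for name, w in dict(weights).items():
            try:
                w = float(w)
            except (TypeError, ValueError):
                raise InvalidMetricsError(f"weight for {name!r} is not numeric: {w!r}")
            if not math.isfinite(w) or w < 0:
                raise InvalidMetricsError(
                    f"weight for {name!r} must be finite and >= 0, got {w}"
                )
            clean[str(name)] = w
        object.__setattr__(self, "weights", clean)

    def __getitem__(self, name: str) -> float:
        return self.weights.get(name, 1.0)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class PolarGeometry:
    """The polar layout shared by every model in one comparison.

    ``angle_rad`` is the included angle between adjacent rays, always
    ``2*pi/n_metrics``; ``ordering`` is the metric ordering used to lay rays
    counter-clockwise starting at angle 0.
    """

    n_metrics: int
    angle_rad: float
    ordering: tuple[str, ...]

    @classmethod
    def for_metrics(cls, names: Sequence[str]) -> "PolarGeometry":
        n = len(names)
        return cls(n_metrics=n, angle_rad=compute_angle(n), ordering=tuple(names))


@dataclass(frozen=True)
class MLcpsResult:
    """Composite score for one model plus the geometry that produced it."""

    model_name: str
    score: float
    normalized_score: float
    geometry: PolarGeometry
    effective_metrics: tuple[str, ...]
    weighted: bool = False
    tied: bool = field(default=False, compare=False)

    def __repr__(self) -> str:  # compact, the dataclass default is noisy
        return (f"MLcpsResult({self.model_name!r}, score={self.score:.6g}, "
                f"n={self.geometry.n_metrics}, weighted={self.weighted})")


def compute_angle(n_metrics: int) -> float:
    """Included angle between adjacent rays: ``2*pi / n_metrics`` radians.

    Equivalently 360 degrees divided by the number of metrics, in radians.
    """
    if isinstance(n_metrics, bool) or not isinstance(n_metrics, (int, np.integer)):
        raise InvalidMetricsError(f"n_metrics must be an integer, got {n_metrics!r}")
    if n_metrics < 1:
        raise InvalidMetricsError(f"n_metrics must be >= 1, got {n_metrics}")
    return 2.0 * math.pi / int(n_metrics)


def apply_weights(metrics: MetricVector, weights: WeightVector) -> MetricVector:
    """Multiply each metric by its weight; drop metrics weighted exactly 0.

    Metrics not mentioned in ``weights`` keep weight 1 (an empty weight
    vector is the identity).  Weight keys naming metrics that do not exist
    are an error — a typo would otherwise silently leave the intended metric
    unweighted.  Zero-weight exclusion shrinks the vector, so the downstream
    geometry (``n``, ``theta``) shrinks with it.
    """
    unknown = sorted(set(weights.weights) - set(metrics.names))
    if unknown:
        raise InvalidMetricsError(
            f"weights refer to unknown metrics {unknown}; "
            f"available: {list(metrics.names)}"
        )
    kept_names = [n for n in metrics.names if weights[n] != 0.0]
    if len(kept_names) < len(metrics.names):
        dropped = [n for n in metrics.names if weights[n] == 0.0]
        logger.info("zero-weight exclusion removed metrics %s", dropped)
    vals = [metrics.to_dict()[n] * weights[n] for n in kept_names]
    if not kept_names:
        raise DegenerateGeometryError(
            "every metric was excluded by zero weights"
        )
    return MetricVector(kept_names, vals)


def max_polygon_area(n_metrics: int, upper_bound: float = 1.0) -> float:
    """Largest attainable area for ``n`` rays capped at ``upper_bound``.

    Attained by the regular polygon with every ray at the cap:
    ``(n/2) * sin(2*pi/n) * u**2``.
    """
    return 0.5 * n_metrics * math.sin(compute_angle(n_metrics)) * upper_bound ** 2


def _polygon_area(values: np.ndarray, angle: float) -> float:
    # cyclic sum: d_1 d_2 + d_2 d_3 + ... + d_n d_1
    return 0.5 * math.sin(angle) * float(np.dot(values, np.roll(values, -1)))


def compute_mlcps(
    metrics: MetricVector,
    weights: WeightVector | None = None,
    upper_bound: float = 1.0,
    model_name: str = "model",
) -> MLcpsResult:
    """Score one model: the closed-polygon area of its metric rays.

    Parameters
    ----------
    metrics
        Ordered metric scores (the ray lengths).  Order matters.
    weights
        Optional per-metric weights applied before projection; weight 0
        excludes a metric, shrinking the geometry.
    upper_bound
        Declared common scale ceiling ``u`` (default 1).  Values above it
        only warn — weights > 1 legitimately push scores past the cap — but
        ``normalized_score`` is then clamped to 1.
    model_name
        Carried into the result for reporting.

    Returns
    -------
    MLcpsResult
        ``score`` is the raw area; ``normalized_score`` divides by the
        maximum attainable area ``(n/2) sin(2*pi/n) u**2`` as a convenience
        for cross-geometry comparison.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 metrics remain after zero-weight exclusion
        (``n = 2`` spans zero area and ``n = 1`` is not a polygon).
    """
    weighted = weights is not None and len(weights) > 0
    effective = apply_weights(metrics, weights) if weights is not None else metrics

    n = len(effective)
    if n < MIN_METRICS:
        raise DegenerateGeometryError(
            f"{n} effective metric(s) after exclusion; need >= {MIN_METRICS} "
            "to form a polygon"
        )
    if not (math.isfinite(upper_bound) and upper_bound > 0):
        raise InvalidMetricsError(f"upper_bound must be finite and > 0, got {upper_bound}")

    angle = compute_angle(n)
    area = _polygon_area(effective.values, angle)
    max_area = max_polygon_area(n, upper_bound)
    normalized = area / max_area
    if np.any(effective.values > upper_bound):
        over = [effective.names[i]
                for i in np.flatnonzero(effective.values > upper_bound)]
        warnings.warn(
            f"metric values exceed the declared upper bound {upper_bound} "
            f"for {over}; normalized_score is clamped to 1",
            stacklevel=2,
        )
        logger.info("clamping normalized_score for %s (was %.6g)", model_name, normalized)
        normalized = min(normalized, 1.0)

    return MLcpsResult(
        model_name=model_name,
        score=area,
        normalized_score=normalized,
        geometry=PolarGeometry(n, angle, effective.names),
        effective_metrics=effective.names,
        weighted=weighted,
    )


def compute_mlcps_table(
    table: "MetricsTable",
    weights: WeightVector | None = None,
) -> list[MLcpsResult]:
    """Score every model in a table under one shared geometry.

    All rows use the table's column order as the ray order, so scores are
    mutually comparable.  A row violating the preconditions raises an error
    naming the offending model.
    """
    results: list[MLcpsResult] = []
    for model in table.model_names:
        try:
            results.append(
                compute_mlcps(
                    table.row(model),
                    weights=weights,
                    upper_bound=table.declared_upper_bound,
                    model_name=model,
                )
            )
        except DegenerateGeometryError:
            raise
        except InvalidMetricsError as exc:
            raise InvalidMetricsError(f"model {model!r}: {exc}") from exc
    return results
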