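import numpy as np
import pytest

from mlcps import MetricsTable


def shoelace_area(values) -> float:
    """Independent polygon-area oracle: surveyor's formula on the Cartesian
    vertices (d_i cos(i*theta), d_i sin(i*theta)) with theta = 2*pi/n.

    Deliberately shares no code with the scored path (pairwise-triangle sum).
    """
    d = np.asarray(values, dtype=float)
    n = d.size
    theta = 2.0 * np.pi / n
    angles = np.arange(n) * theta
    x = d * np.cos(angles)
    y = d * np.sin(angles)
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


@pytest.fixture
def oracle():
    return shoelace_area


@pytest.fixture
def small_table() -> MetricsTable:
    """Two models, four metrics, hand-pickable numbers."""
    return MetricsTable(
        ["knn", "svm"],
        ["accuracy", "precision", "recall", "f1"],
        [[0.8, 0.6, 0.9, 0.7],
         [0.7, 0.7, 0.7, 0.7]],
    )


@pytest.fixture
def divergence_table() -> MetricsTable:
    """A consistent-but-poor model vs a strong model: the poor one has the
    smaller metric SD yet must lose on the polygon score."""
    return MetricsTable(
        ["steady_poor", "strong"],
        ["m1", "m2", "m3", "m4"],
        [[0.5, 0.5, 0.5, 0.5],
         [0.95, 0.90, 0.92, 0.93]],
    )
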