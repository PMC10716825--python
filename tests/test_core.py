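"""Polygon-area score: closed forms, oracle equivalence, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlcps import (
    DegenerateGeometryError,
    InvalidMetricsError,
    MetricsTable,
    MetricVector,
    WeightVector,
    apply_weights,
    compute_angle,
    compute_mlcps,
    compute_mlcps_table,
    max_polygon_area,
)

TOL = 1e-9


def mv(**kwargs):
    return MetricVector.from_dict(kwargs)


class TestComputeAngle:
    @pytest.mark.parametrize("n,expected", [
        (4, math.pi / 2),
        (360, 2 * math.pi / 360),
        (3, 2 * math.pi / 3),
        (1, 2 * math.pi),
    ])
    def test_angle_is_full_circle_over_n(self, n, expected):
        assert compute_angle(n) == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize("bad", [0, -2, 2.5, "4", None, True])
    def test_rejects_degenerate_or_nonintegral_counts(self, bad):
        with pytest.raises(InvalidMetricsError):
            compute_angle(bad)


class TestMetricVector:
    def test_preserves_insertion_order(self):
        v = mv(z=0.1, a=0.2, m=0.3)
        assert v.names == ("z", "a", "m")

    @pytest.mark.parametrize("values", [[0.5, -0.1, 0.2], [0.5, np.nan, 0.2],
                                        [np.inf, 0.1, 0.2]])
    def test_rejects_negative_and_nonfinite_values(self, values):
        with pytest.raises(InvalidMetricsError):
            MetricVector(["a", "b", "c"], values)

    def test_rejects_duplicate_and_empty_names(self):
        with pytest.raises(InvalidMetricsError):
            MetricVector(["a", "a"], [0.1, 0.2])
        with pytest.raises(InvalidMetricsError):
            MetricVector(["a", ""], [0.1, 0.2])
        with pytest.raises(InvalidMetricsError):
            MetricVector([], [])


class TestApplyWeights:
    def test_multiplies_each_score_by_its_weight(self):
        out = apply_weights(mv(f1=0.9, acc=0.5), WeightVector({"f1": 2.0}))
        assert out.to_dict() == pytest.approx({"f1": 1.8, "acc": 0.5})

    def test_empty_weights_are_the_identity(self):
        v = mv(acc=0.8, f1=0.6, rec=0.7)
        out = apply_weights(v, WeightVector({}))
        assert out.to_dict() == v.to_dict()
        assert out.names == v.names

    def test_zero_weight_removes_the_metric(self):
        v = mv(acc=0.8, f1=0.6, rec=0.7, pre=0.5)
        out = apply_weights(v, WeightVector({"pre": 0.0}))
        assert out.names == ("acc", "f1", "rec")
        assert out.to_dict() == pytest.approx({"acc": 0.8, "f1": 0.6, "rec": 0.7})

    def test_negative_weight_rejected_at_construction(self):
        with pytest.raises(InvalidMetricsError, match=">= 0"):
            WeightVector({"f1": -1})

    def test_unknown_weight_key_is_an_error(self):
        with pytest.raises(InvalidMetricsError, match="unknown"):
            apply_weights(mv(a=1, b=1, c=1), WeightVector({"typo": 2}))


class TestComputeMlcps:
    @pytest.mark.parametrize("n,expected", [
        (3, 3 * math.sqrt(3) / 4),      # equilateral triangle in unit circle
        (4, 2.0),                        # unit square rotated 45 degrees
        (5, 2.3776412907378837),         # regular pentagon, oracle-recomputed
        (10, 2.938926261462366),
    ])
    def test_all_ones_vector_gives_regular_polygon_area(self, n, expected, oracle):
        v = MetricVector([f"m{i}" for i in range(n)], np.ones(n))
        res = compute_mlcps(v)
        assert res.score == pytest.approx(expected, abs=TOL)
        assert res.score == pytest.approx(oracle(np.ones(n)), abs=TOL)
        assert res.normalized_score == pytest.approx(1.0, abs=TOL)

    def test_mostly_zero_vector_has_zero_area(self):
        res = compute_mlcps(mv(m1=0, m2=0, m3=0, m4=0.9))
        assert res.score == 0.0

    def test_zero_weight_exclusion_recomputes_geometry(self, oracle):
        full = mv(a=0.8, b=0.6, c=0.9, d=0.7)
        excluded = compute_mlcps(full, weights=WeightVector({"d": 0.0}))
        reduced = compute_mlcps(mv(a=0.8, b=0.6, c=0.9))
        assert excluded.score == pytest.approx(reduced.score, abs=TOL)
        assert excluded.geometry.angle_rad == pytest.approx(2 * math.pi / 3, abs=TOL)
        assert excluded.effective_metrics == ("a", "b", "c")
        assert excluded.score == pytest.approx(oracle([0.8, 0.6, 0.9]), abs=TOL)

    def test_fewer_than_three_effective_metrics_errors(self):
        with pytest.raises(DegenerateGeometryError):
            compute_mlcps(mv(a=1, b=1))
        with pytest.raises(DegenerateGeometryError):
            compute_mlcps(mv(a=1, b=1, c=1), weights=WeightVector({"c": 0}))

    def test_values_above_upper_bound_warn_and_clamp_normalized(self):
        v = mv(a=0.9, b=0.8, c=0.7)
        with pytest.warns(UserWarning, match="upper bound"):
            res = compute_mlcps(v, weights=WeightVector({"a": 3.0}))
        assert res.normalized_score == 1.0
        assert res.score > 0

    def test_oracle_equivalence_on_random_vectors(self, oracle):
        rng = np.random.default_rng(20240601)
        for _ in range(1000):
            n = int(rng.integers(3, 13))
            d = rng.random(n)
            v = MetricVector([f"m{i}" for i in range(n)], d)
            assert compute_mlcps(v).score == pytest.approx(oracle(d), abs=TOL)

    @pytest.mark.filterwarnings("ignore:metric values exceed")
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=3, max_size=12),
        st.floats(1e-3, 1e3),
    )
    def test_quadratic_scaling_in_any_positive_factor(self, values, c):
        names = [f"m{i}" for i in range(len(values))]
        base = compute_mlcps(MetricVector(names, values)).score
        scaled = compute_mlcps(MetricVector(names, [c * v for v in values])).score
        assert scaled == pytest.approx(c * c * base, rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=3, max_size=12))
    def test_score_bounded_by_regular_polygon_area(self, values):
        n = len(values)
        score = compute_mlcps(MetricVector([f"m{i}" for i in range(n)], values)).score
        assert -1e-12 <= score <= max_polygon_area(n) + 1e-12

    @pytest.mark.filterwarnings("ignore:metric values exceed")
    def test_raising_one_metric_strictly_raises_the_score(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 10))
            d = rng.uniform(0.05, 1.0, n)  # all strictly positive
            i = int(rng.integers(n))
            names = [f"m{k}" for k in range(n)]
            lo = compute_mlcps(MetricVector(names, d)).score
            d2 = d.copy()
            d2[i] += 0.1
            hi = compute_mlcps(MetricVector(names, d2)).score
            assert hi > lo

    def test_invariant_to_cyclic_rotation_and_reversal(self):
        d = [0.9, 0.4, 0.7, 0.2, 0.6]
        names = ["a", "b", "c", "d", "e"]
        base = compute_mlcps(MetricVector(names, d)).score
        for k in range(1, 5):
            rot = compute_mlcps(MetricVector(names[k:] + names[:k], d[k:] + d[:k])).score
            assert rot == pytest.approx(base, abs=TOL)
        rev = compute_mlcps(MetricVector(names[::-1], d[::-1])).score
        assert rev == pytest.approx(base, abs=TOL)

    def test_order_sensitivity_is_real(self):
        # swapping two non-adjacent rays changes the neighbour products
        a = compute_mlcps(mv(m1=1.0, m2=0.1, m3=1.0, m4=0.1)).score
        b = compute_mlcps(mv(m1=1.0, m2=1.0, m3=0.1, m4=0.1)).score
        assert abs(a - b) > 1e-3

    def test_weight_one_identity(self):
        v = mv(a=0.8, b=0.5, c=0.9, d=0.4)
        unweighted = compute_mlcps(v)
        all_ones = compute_mlcps(v, weights=WeightVector({n: 1.0 for n in v.names}))
        assert all_ones.score == pytest.approx(unweighted.score, abs=TOL)


class TestComputeMlcpsTable:
    def test_identical_rows_get_identical_scores(self):
        t = MetricsTable(["a", "b"], ["m1", "m2", "m3"],
                         [[0.5, 0.6, 0.7], [0.5, 0.6, 0.7]])
        r = compute_mlcps_table(t)
        assert r[0].score == r[1].score
        assert r[0].geometry == r[1].geometry

    def test_strict_dominance_gives_strictly_higher_score(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            low = rng.uniform(0.05, 0.8, n)
            high = low + rng.uniform(0.01, 0.19, n)
            t = MetricsTable(["hi", "lo"], [f"m{i}" for i in range(n)],
                             np.vstack([high, low]))
            r = {res.model_name: res.score for res in compute_mlcps_table(t)}
            assert r["hi"] > r["lo"]

    def test_single_row_all_ones(self):
        t = MetricsTable(["only"], ["m1", "m2", "m3", "m4"], [[1, 1, 1, 1]])
        (res,) = compute_mlcps_table(t)
        assert res.score == pytest.approx(2.0, abs=TOL)

    def test_row_failure_names_the_model(self):
        t = MetricsTable(["good", "overweight"], ["m1", "m2", "m3"],
                         [[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
        with pytest.raises(InvalidMetricsError, match="unknown"):
            compute_mlcps_table(t, weights=WeightVector({"nope": 1}))
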