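"""Model ranking and robustness comparison.

Two orderings of the same model family are compared: by the cumulative
polygon score (higher = better, rank 1 = largest) and by the standard
deviation of the raw metric scores (smaller = more consistent, rank 1 =
smallest).  The two can disagree — a model with uniformly poor metrics has a
tiny SD yet a small polygon — which is exactly why the SD alone is an
unreliable model-selection criterion and why both are reported side by side.

Given a second table (e.g. the same models evaluated on held-out data), the
report adds cross-table ranks, the number of models whose score rank is
identical in both tables, and the Spearman correlation between the two score
orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetricVector, WeightVector, compute_mlcps_table
from .errors import InvalidMetricsError
from .io import MetricsTable, _atomic_write_text

__all__ = ["RankingReport", "metric_sd", "compare_rankings"]

REPORT_COLUMNS = [
    "model", "mlcps", "mlcps_normalized", "sd",
    "rank_mlcps", "rank_sd", "tied", "effective_metrics",
]


def metric_sd(metrics: MetricVector) -> float:
    """Sample standard deviation (n-1 denominator) of one model's raw metrics.

    Always computed on the unweighted scores: the SD baseline characterises
    the spread of the panel as measured, independent of any user weighting
    of the composite score.
    """
    if len(metrics) < 2:
        raise InvalidMetricsError("metric_sd needs at least 2 metric values")
    return float(np.std(metrics.values, ddof=1))


def _min_rank_desc(values: np.ndarray) -> np.ndarray:
    """Competition ranks, 1 = largest; ties share the minimum rank."""
    s = pd.Series(values)
    return s.rank(method="min", ascending=False).astype(int).to_numpy()


def _min_rank_asc(values: np.ndarray) -> np.ndarray:
    s = pd.Series(values)
    return s.rank(method="min", ascending=True).astype(int).to_numpy()


@dataclass(frozen=True)
class RankingReport:
    """Per-model scores, SDs and ranks, plus cross-table agreement.

    ``table`` columns: model, mlcps, mlcps_normalized, sd, rank_mlcps
    (1 = highest score), rank_sd (1 = smallest SD), tied (score shared with
    another model), effective_metrics; with a second input table also
    mlcps_b, rank_mlcps_b and rank_match.  Rows are ordered by descending
    score, ties broken lexicographically by model name for deterministic
    output.
    """

    table: pd.DataFrame
    n_rank_matches: int | None = None
    spearman_rho: float | None = None

    def to_csv(self, path) -> None:
        _atomic_write_text(path, self.table.to_csv(index=False))

    def to_string(self) -> str:
        lines = [self.table.to_string(index=False, float_format=lambda v: f"{v:.6f}")]
        if self.spearman_rho is not None:
            lines.append(
                f"cross-table agreement: {self.n_rank_matches}/{len(self.table)} "
                f"identical ranks, Spearman rho = {self.spearman_rho:.4f}"
            )
        return "\n".join(lines)


def _score_frame(table: MetricsTable, weights: WeightVector | None) -> pd.DataFrame:
    results = compute_mlcps_table(table, weights=weights)
    rows = []
    for model, res in zip(table.model_names, results):
        rows.append({
            "model": model,
            "mlcps": res.score,
            "mlcps_normalized": res.normalized_score,
            "sd": metric_sd(table.row(model)),
            "effective_metrics": ";".join(res.effective_metrics),
        })
    return pd.DataFrame(rows)


def compare_rankings(
    table_a: MetricsTable,
    table_b: MetricsTable | None = None,
    weights: WeightVector | None = None,
) -> RankingReport:
    """Rank models by composite score and by metric SD, optionally across
    a second table of the same models (train vs test consistency).

    The SD column always uses the raw unweighted metrics even when the
    composite score is weighted.
    """
    df = _score_frame(table_a, weights)
    df["rank_mlcps"] = _min_rank_desc(df["mlcps"].to_numpy())
    df["rank_sd"] = _min_rank_asc(df["sd"].to_numpy())
    counts = df["mlcps"].round(12).value_counts()
    df["tied"] = df["mlcps"].round(12).map(counts).gt(1)

    n_matches: int | None = None
    rho: float | None = None
    if table_b is not None:
        if set(table_b.model_names) != set(table_a.model_names):
            raise InvalidMetricsError(
                "the two tables must contain the same model names"
            )
        if table_b.metric_names != table_a.metric_names:
            raise InvalidMetricsError(
                "the two tables must share metric columns in the same order"
            )
        df_b = _score_frame(table_b, weights)
        df_b["rank_mlcps_b"] = _min_rank_desc(df_b["mlcps"].to_numpy())
        df_b = df_b.rename(columns={"mlcps": "mlcps_b"})
        df = df.merge(df_b[["model", "mlcps_b", "rank_mlcps_b"]], on="model")
        df["rank_match"] = df["rank_mlcps"] == df["rank_mlcps_b"]
        n_matches = int(df["rank_match"].sum())
        rho = float(stats.spearmanr(df["mlcps"], df["mlcps_b"]).statistic)

    df = df.sort_values(
        ["mlcps", "model"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ordered = [c for c in REPORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return RankingReport(df[ordered + extra], n_rank_matches=n_matches, spearman_rho=rho)
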