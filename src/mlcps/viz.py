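"""Radar, bar and SD-comparison plots.

Each plot kind has a ``*_plot_data`` function returning the exact arrays
handed to matplotlib — vertex angles/radii for the radar, bar heights and
bracketed rank labels for the bar chart, paired SD/score series for the
dual-axis comparison.  Tests target those arrays, never rendered pixels.
:func:`render` draws them and writes the file atomically (SVG, PNG, or SVG
embedded in a minimal HTML page).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # non-interactive backend; file output only
import matplotlib.pyplot as plt
import numpy as np

from .analysis import RankingReport
from .core import MLcpsResult, WeightVector, apply_weights
from .errors import InvalidMetricsError
from .io import MetricsTable

__all__ = [
    "PlotSpec",
    "radar_plot_data",
    "bar_plot_data",
    "sd_comparison_plot_data",
    "render",
]

PLOT_KINDS = ("radar", "bar", "sd_comparison")
PLOT_FORMATS = ("svg", "png", "html")

#: radar overlays beyond this many models become unreadable
DEFAULT_MAX_RADAR_MODELS = 8


@dataclass(frozen=True)
class PlotSpec:
    """What to draw and where to write it."""

    kind: str
    path: str | Path
    format: str | None = None  # inferred from path suffix when None
    title: str = ""
    include_values: bool = True
    max_radar_models: int = DEFAULT_MAX_RADAR_MODELS

    def resolved_format(self) -> str:
        fmt = self.format or Path(self.path).suffix.lstrip(".").lower()
        if fmt not in PLOT_FORMATS:
            raise InvalidMetricsError(
                f"unsupported plot format {fmt!r}; choose from {PLOT_FORMATS}"
            )
        return fmt

    def __post_init__(self):
        if self.kind not in PLOT_KINDS:
            raise InvalidMetricsError(
                f"unsupported plot kind {self.kind!r}; choose from {PLOT_KINDS}"
            )


def radar_plot_data(
    table: MetricsTable,
    weights: WeightVector | None = None,
    max_models: int = DEFAULT_MAX_RADAR_MODELS,
) -> dict:
    """Closed polygon vertices per model on a shared polar frame.

    Returns ``{"angles": ..., "labels": ..., "models": {name: radii}}`` where
    each radii array is closed (first vertex repeated) and equals the
    (weighted) metric values in table column order.
    """
    first = table.row(table.model_names[0])
    effective = apply_weights(first, weights) if weights is not None else first
    labels = list(effective.names)
    n = len(labels)
    angles = np.arange(n + 1) * (2 * np.pi / n)  # closed
    models: dict[str, np.ndarray] = {}
    for name in table.model_names[:max_models]:
        mv = table.row(name)
        if weights is not None:
            mv = apply_weights(mv, weights)
        radii = np.concatenate([mv.values, mv.values[:1]])
        models[name] = radii
    return {"angles": angles, "labels": labels, "models": models}


def bar_plot_data(results: Sequence[MLcpsResult] | RankingReport) -> dict:
    """Bars sorted by score descending with bracketed ranks.

    Returns ``{"models": [...], "heights": [...], "labels": ["name [rank]"]}``;
    heights equal the reported composite scores exactly.
    """
    if isinstance(results, RankingReport):
        df = results.table
        pairs = list(zip(df["model"], df["mlcps"], df["rank_mlcps"]))
    else:
        if not results:
            raise InvalidMetricsError("empty results")
        ordered = sorted(results, key=lambda r: (-r.score, r.model_name))
        scores = [r.score for r in ordered]
        ranks = [1 + sum(s > r.score for s in scores) for r in ordered]
        pairs = [(r.model_name, r.score, rank) for r, rank in zip(ordered, ranks)]
    if not pairs:
        raise InvalidMetricsError("empty results")
    models = [p[0] for p in pairs]
    heights = np.array([p[1] for p in pairs], dtype=float)
    labels = [f"{m} [{rank}]" for m, _, rank in pairs]
    return {"models": models, "heights": heights, "labels": labels}


def sd_comparison_plot_data(report: RankingReport) -> dict:
    """Bars = metric SD ascending left-to-right; points = composite score.

    The two series share the model axis but separate y-axes, making visible
    any disagreement between the SD ordering and the score ordering.
    """
    df = report.table.sort_values(["sd", "model"], kind="mergesort")
    return {
        "models": df["model"].tolist(),
        "sd": df["sd"].to_numpy(dtype=float),
        "mlcps": df["mlcps"].to_numpy(dtype=float),
    }


def _atomic_savefig(fig, spec: PlotSpec) -> None:
    path = Path(spec.path)
    fmt = spec.resolved_format()
    save_fmt = "svg" if fmt == "html" else fmt
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=f".{save_fmt}")
    os.close(fd)
    try:
        fig.savefig(tmp, format=save_fmt, bbox_inches="tight")
        if fmt == "html":
            svg = Path(tmp).read_text(encoding="utf-8")
            body = (f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
                    f"<title>{spec.title}</title></head><body>{svg}</body></html>")
            Path(tmp).write_text(body, encoding="utf-8")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    finally:
        plt.close(fig)


def render(results, spec: PlotSpec) -> Path:
    """Draw one plot and write it to ``spec.path``; returns the path.

    ``results`` is a MetricsTable (radar), a RankingReport or list of
    MLcpsResult (bar), or a RankingReport (sd_comparison).
    """
    if spec.kind == "radar":
        if not isinstance(results, MetricsTable):
            raise InvalidMetricsError("radar plots need a MetricsTable")
        data = radar_plot_data(results, max_models=spec.max_radar_models)
        fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(6, 6))
        for name, radii in data["models"].items():
            ax.plot(data["angles"], radii, label=name, linewidth=1.5)
            ax.fill(data["angles"], radii, alpha=0.08)
        ax.set_xticks(data["angles"][:-1])
        ax.set_xticklabels(data["labels"], fontsize=8)
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    elif spec.kind == "bar":
        data = bar_plot_data(results)
        fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(data["models"])), 4))
        bars = ax.bar(data["labels"], data["heights"], color="#4878d0")
        ax.set_ylabel("cumulative performance score (polygon area)")
        ax.tick_params(axis="x", rotation=45)
        if spec.include_values:
            for rect, h in zip(bars, data["heights"]):
                ax.text(rect.get_x() + rect.get_width() / 2, h / 2,
                        f"{h:.3f}", ha="center", va="center",
                        fontsize=8, color="white", rotation=90)
    elif spec.kind == "sd_comparison":
        if not isinstance(results, RankingReport):
            raise InvalidMetricsError("sd_comparison plots need a RankingReport")
        data = sd_comparison_plot_data(results)
        fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(data["models"])), 4))
        ax.bar(data["models"], data["sd"], color="#bdbdbd", label="metric SD")
        ax.set_ylabel("SD of metric scores")
        ax2 = ax.twinx()
        ax2.plot(data["models"], data["mlcps"], "o-", color="#d65f5f",
                 label="composite score")
        ax2.set_ylabel("cumulative performance score")
        ax.tick_params(axis="x", rotation=45)
        lines, labs = ax.get_legend_handles_labels()
        lines2, labs2 = ax2.get_legend_handles_labels()
        ax.legend(lines + lines2, labs + labs2, loc="upper left", fontsize=8)
    else:  # pragma: no cover - PlotSpec already validated
        raise InvalidMetricsError(f"unsupported plot kind {spec.kind!r}")

    if spec.title:
        fig.suptitle(spec.title)
    _atomic_savefig(fig, spec)
    return Path(spec.path)
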