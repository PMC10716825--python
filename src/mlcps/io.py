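"""Delimited-text input/output with strict validation.

File conventions
----------------
Metrics table (CSV or TSV): header row = metric names, first column = model
names, every other cell numeric (dot decimal, locale-independent).  The
column order in the file IS the ray order on the polar plane, identical for
every model, and is preserved exactly on read and write.

Predictions (CSV): header required, columns ``y_true,y_pred[,y_score]``.

Weights: a JSON or YAML mapping metric-name -> non-negative number.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml

from .core import MetricVector, WeightVector
from .errors import InvalidMetricsError, TableFormatError
from .metrics import PredictionSet

__all__ = [
    "MetricsTable",
    "read_metrics_table",
    "write_metrics_table",
    "read_weights",
    "read_predictions",
    "write_predictions",
]

Delimiter = Literal["auto", "comma", "tab"]
_DELIMS = {"comma": ",", "tab": "\t"}


def _atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so failures leave no partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass(frozen=True)
class MetricsTable:
    """Models x metrics matrix with a fixed, shared metric ordering.

    Rows are models, columns are metrics, cells are scores on a common scale
    with declared ceiling ``declared_upper_bound`` (default 1).  Rectangular,
    no missing cells, unique names, order significant.
    """

    model_names: tuple[str, ...]
    metric_names: tuple[str, ...]
    values: np.ndarray
    declared_upper_bound: float = 1.0
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __init__(
        self,
        model_names: Iterable[str],
        metric_names: Iterable[str],
        values,
        declared_upper_bound: float = 1.0,
    ):
        models = tuple(str(m) for m in model_names)
        metrics = tuple(str(m) for m in metric_names)
        if len(models) == 0:
            raise TableFormatError("no models: the table has no data rows")
        if len(set(models)) != len(models):
            raise TableFormatError("duplicate model names")
        if len(set(metrics)) != len(metrics):
            raise TableFormatError("duplicate metric names")
        if len(metrics) < 3:
            raise TableFormatError(
                f"{len(metrics)} metric column(s); at least 3 are required "
                "to form a polygon"
            )
        vals = np.asarray(values, dtype=float)
        if vals.shape != (len(models), len(metrics)):
            raise TableFormatError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(models)} models x {len(metrics)} metrics"
            )
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise TableFormatError(
                f"missing or non-finite cell at model {models[r]!r}, "
                f"metric {metrics[c]!r}"
            )
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "model_names", models)
        object.__setattr__(self, "metric_names", metrics)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "declared_upper_bound", float(declared_upper_bound))
        object.__setattr__(self, "_index", {m: i for i, m in enumerate(models)})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, declared_upper_bound: float = 1.0) -> "MetricsTable":
        """In-process constructor: index = model names, columns = metrics."""
        return cls(df.index, df.columns, df.to_numpy(), declared_upper_bound)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.values), index=list(self.model_names),
            columns=list(self.metric_names),
        ).rename_axis("model")

    def row(self, model: str) -> MetricVector:
        """One model's metrics as a MetricVector, in table column order."""
        try:
            i = self._index[model]
        except KeyError:
            raise InvalidMetricsError(f"unknown model {model!r}")
        return MetricVector(self.metric_names, self.values[i])

    @property
    def n_models(self) -> int:
        return len(self.model_names)


def _resolve_delimiter(path: Path, delimiter: Delimiter) -> str | None:
    if delimiter in _DELIMS:
        return _DELIMS[delimiter]
    if delimiter != "auto":
        raise InvalidMetricsError(f"unknown delimiter option {delimiter!r}")
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    return None  # let pandas sniff


def read_metrics_table(
    path: str | Path,
    delimiter: Delimiter = "auto",
    declared_upper_bound: float = 1.0,
) -> MetricsTable:
    """Read and validate a metrics table from CSV/TSV.

    First column = model names, header row = metric names.  Errors name the
    offending row/column: missing cells, duplicate names, non-numeric cells
    and tables with fewer than 3 metric columns are all rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _resolve_delimiter(path, delimiter)
    kwargs = dict(index_col=0, dtype=str, keep_default_na=False,
                  skip_blank_lines=True)
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", **kwargs)
    else:
        df = pd.read_csv(path, sep=sep, **kwargs)
    if df.shape[0] == 0:
        raise TableFormatError(f"{path}: no models (header-only file)")
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        raw = df[col].str.strip()
        empty = raw == ""
        if empty.any():
            row = df.index[empty.argmax()]
            raise TableFormatError(
                f"{path}: empty cell at model {row!r}, metric {col!r}"
            )
        # builtin float() round-trips full precision (pd.to_numeric does not)
        def _parse(s: str):
            try:
                return float(s)
            except ValueError:
                return None

        parsed = raw.map(_parse)
        bad = parsed.isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise TableFormatError(
                f"{path}: non-numeric cell {raw[bad].iloc[0]!r} at model "
                f"{row!r}, metric {col!r}"
            )
        numeric[col] = parsed.astype(float)
    try:
        return MetricsTable.from_dataframe(numeric, declared_upper_bound)
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def write_metrics_table(
    table: MetricsTable, path: str | Path, delimiter: Delimiter = "auto"
) -> None:
    """Write a table as delimited text; round-trips through read_metrics_table."""
    path = Path(path)
    sep = _resolve_delimiter(path, delimiter) or ","
    # repr-precision floats so read -> write is byte-stable
    text = table.to_dataframe().to_csv(sep=sep, float_format=None)
    _atomic_write_text(path, text)


def read_weights(path: str | Path) -> WeightVector:
    """Read a metric-name -> weight mapping from JSON or YAML."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise TableFormatError(f"{path}: cannot parse weights: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise TableFormatError(
            f"{path}: weights must be a mapping metric-name -> number"
        )
    return WeightVector(data)


def read_predictions(path: str | Path, positive_label=1) -> PredictionSet:
    """Read a prediction file: header y_true,y_pred[,y_score]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"y_true", "y_pred"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: prediction files need columns y_true,y_pred[,y_score]; "
            f"found {list(df.columns)}"
        )
    if df[["y_true", "y_pred"]].isna().any().any():
        raise TableFormatError(f"{path}: missing label cells")
    y_score = df["y_score"].to_numpy(float) if "y_score" in df.columns else None
    return PredictionSet(
        y_true=df["y_true"].to_numpy(),
        y_pred=df["y_pred"].to_numpy(),
        y_score=y_score,
        positive_label=positive_label,
    )


def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    data = {"y_true": preds.y_true, "y_pred": preds.y_pred}
    if preds.y_score is not None:
        data["y_score"] = preds.y_score
    _atomic_write_text(path, pd.DataFrame(data).to_csv(index=False))
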