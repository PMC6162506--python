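"""Labeled event tables: the universal input of training and prediction.

An event table is an ``n_events x n_channels`` real matrix — one row per
cell/particle event, one column per detector channel (forward scatter,
side scatter, fluorescence channels such as FITC or PE) — optionally
carrying integer class labels produced by manual gating.  CSV is the
primary interchange format; FCS 3.0/3.1 list-mode files are read through
:mod:`swarmgate.fcs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "EventTable",
    "ScalingParams",
    "read_events",
    "write_events",
    "fit_minmax",
    "apply_minmax",
    "stratified_split",
]


@dataclass
class EventTable:
    """Event matrix with channel names and optional class labels.

    Parameters
    ----------
    values
        ``(n_events, n_channels)`` float array; all entries finite.
    channel_names
        Unique, nonempty channel identifiers, one per column.
    labels
        Optional integer class labels in ``{0..K-1}``, one per event.
    label_names
        Optional human-readable names for the K classes.
    """

    values: np.ndarray
    channel_names: list[str]
    labels: Optional[np.ndarray] = None
    label_names: Optional[list[str]] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("event values must be finite")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.values.shape[1]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SchemaError("channel names must be unique")
        if any(not c for c in self.channel_names):
            raise SchemaError("channel names must be nonempty")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise SchemaError("labels length must equal n_events")
            if self.labels.size and self.labels.min() < 0:
                raise SchemaError("labels must be nonnegative integers")
            if self.label_names is not None and self.labels.size:
                if self.labels.max() >= len(self.label_names):
                    raise SchemaError("label exceeds label_names length")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            raise SchemaError("table has no labels")
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise SchemaError("operation requires a labeled table")
        return self.labels

    def subset(self, idx: np.ndarray) -> "EventTable":
        """Row subset preserving channels, labels and label names."""
        return EventTable(
            self.values[idx],
            list(self.channel_names),
            None if self.labels is None else self.labels[idx],
            self.label_names,
        )

    def select_channels(self, names: Sequence[str]) -> "EventTable":
        """Column subset by channel name (order as given)."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise SchemaError(f"unknown channels: {missing}")
        cols = [self.channel_names.index(n) for n in names]
        return EventTable(self.values[:, cols], list(names), self.labels, self.label_names)


@dataclass
class ScalingParams:
    """Per-channel minimum/maximum observed on a reference (training) table."""

    channel_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("per-channel max must be >= min")


def read_events(
    path: str | Path,
    format: str = "csv",
    label_column: Optional[str] = None,
) -> EventTable:
    """Read a labeled event table from delimited text or an FCS file.

    Rows containing non-finite values are dropped (their count is logged),
    since exported cytometry tables commonly carry saturated events.

    Parameters
    ----------
    path
        Input file.
    format
        ``"csv"`` (header row of channel names, ``.`` decimal) or
        ``"fcs"`` (FCS 3.0/3.1 list mode; channel names from $PnN/$PnS).
    label_column
        When given, that column is detached as integer class labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        values, names = _read_csv_matrix(path)
    elif format == "fcs":
        from .fcs import read_fcs

        values, names = read_fcs(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    labels = None
    if label_column is not None:
        if label_column not in names:
            raise SchemaError(f"label column {label_column!r} not found in {path}")
        col = names.index(label_column)
        labels = values[:, col]
        if not np.allclose(labels[np.isfinite(labels)] % 1, 0):
            raise ParseError(f"label column {label_column!r} holds non-integer values")
        values = np.delete(values, col, axis=1)
        names = [n for i, n in enumerate(names) if i != col]

    finite = np.all(np.isfinite(values), axis=1)
    if labels is not None:
        finite &= np.isfinite(labels)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("dropped %d rows with non-finite values from %s", n_dropped, path)
        values = values[finite]
        labels = labels[finite] if labels is not None else None
    return EventTable(values, names, None if labels is None else labels.astype(int))


def _read_csv_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot parse {path} as CSV: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no columns")
    names = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {r + 1}, "
            f"column {names[c]!r}"
        )
    return numeric.to_numpy(dtype=float), names


def write_events(table: EventTable, path: str | Path, label_column: str = "label") -> None:
    """Write a table as CSV; labels, when present, go to a final column."""
    df = pd.DataFrame(table.values, columns=table.channel_names)
    if table.labels is not None:
        df[label_column] = table.labels
    df.to_csv(path, index=False)


def fit_minmax(table: EventTable) -> ScalingParams:
    """Per-channel min/max of a reference table (raises on empty input)."""
    if table.n_events == 0:
        raise ValueError("cannot fit scaling on an empty table")
    return ScalingParams(
        list(table.channel_names),
        table.values.min(axis=0),
        table.values.max(axis=0),
    )


def apply_minmax(table: EventTable, params: ScalingParams) -> EventTable:
    """Map each value to ``(v - min) / (max - min)`` using reference params.

    Values outside the reference range extrapolate beyond [0, 1]; channels
    that were constant in the reference map to 0.
    """
    if list(table.channel_names) != list(params.channel_names):
        raise SchemaError(
            f"channel mismatch: table {table.channel_names} vs "
            f"params {params.channel_names}"
        )
    span = params.maxs - params.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.values - params.mins) / safe
    scaled[:, span == 0] = 0.0
    return EventTable(scaled, list(table.channel_names), table.labels, table.label_names)


def stratified_split(
    table: EventTable, train_fraction: float, seed: int
) -> tuple[EventTable, EventTable]:
    """Per-class deterministic train/test partition.

    Each class contributes ``floor(train_fraction * n_class)`` events
    (minimum 1) to the training table; the remainder go to test.  Events
    are shuffled per class by a generator seeded from ``seed``, so the
    split is reproducible.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = table.require_labels()
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has {idx.size} event(s); need >= 2")
        rng = np.random.default_rng([seed, int(cls)])
        idx = rng.permutation(idx)
        n_train = max(1, int(np.floor(train_fraction * idx.size)))
        n_train = min(n_train, idx.size - 1)  # keep at least one test event
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return (
        table.subset(np.sort(np.concatenate(train_idx))),
        table.subset(np.sort(np.concatenate(test_idx))),
    )
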