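"""Ordinal response data container and CSV reader."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["OrdinalData", "read_ordinal_csv"]

log = logging.getLogger("factortree")


@dataclass(frozen=True)
class OrdinalData:
    """An n x d matrix of ordinal item responses coded 0 .. K_j - 1.

    Missing values are rejected: the models provide no treatment for them.
    """

    y: np.ndarray
    labels: Optional[Sequence[str]] = None
    _K: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        y = np.asarray(self.y)
        if y.ndim != 2:
            raise ValueError("response matrix must be 2-dimensional (n rows, d items)")
        if not np.issubdtype(y.dtype, np.integer):
            yf = np.asarray(self.y, dtype=float)
            if np.isnan(yf).any():
                i, j = np.argwhere(np.isnan(yf))[0]
                raise ValueError(f"missing value at row {i + 1}, item {j + 1}")
            if not np.all(yf == np.round(yf)):
                i, j = np.argwhere(yf != np.round(yf))[0]
                raise ValueError(f"non-integer response at row {i + 1}, item {j + 1}")
            y = yf.astype(np.int64)
        else:
            y = y.astype(np.int64)
        if (y < 0).any():
            i, j = np.argwhere(y < 0)[0]
            raise ValueError(f"negative category code at row {i + 1}, item {j + 1}")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "_K", y.max(axis=0) + 1 if len(y) else np.zeros(y.shape[1], int))
        if self.labels is not None and len(self.labels) != y.shape[1]:
            raise ValueError("number of labels does not match number of items")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.y.shape[1]

    @property
    def K(self) -> np.ndarray:
        """Per-item number of categories (1 + the largest observed code)."""
        return self._K

    def counts(self, j: int) -> np.ndarray:
        """Category counts for item j."""
        return np.bincount(self.y[:, j], minlength=self.K[j])

    def compact(self) -> "OrdinalData":
        """Relabel each item's observed categories to a dense 0-based range.

        Items with unobserved (zero-count) categories are collapsed with a
        log message; needed because the vine pmf divides by marginal
        category probabilities.
        """
        y = self.y.copy()
        changed = False
        for j in range(self.d):
            cats = np.unique(y[:, j])
            if len(cats) < 2:
                raise ValueError(
                    f"item {j + 1} is degenerate: only one observed category"
                )
            if cats[0] != 0 or cats[-1] != len(cats) - 1:
                mapping = {c: i for i, c in enumerate(cats)}
                log.warning(
                    "item %d: collapsing to %d observed categories (relabel %s)",
                    j + 1, len(cats), mapping,
                )
                y[:, j] = np.searchsorted(cats, y[:, j])
                changed = True
        return OrdinalData(y, labels=self.labels) if changed else self

    def to_frame(self) -> pd.DataFrame:
        cols = self.labels if self.labels is not None else [f"item{j + 1}" for j in range(self.d)]
        return pd.DataFrame(self.y, columns=list(cols))


def read_ordinal_csv(path, header: str | bool = "auto") -> OrdinalData:
    """Read an ordinal response matrix from a comma-separated file.

    A header row is auto-detected; responses coded 1..K are shifted to
    0..K-1, and per-item categories are relabeled to a dense 0-based range
    (both logged).  Missing or non-integer cells raise with their position.
    """
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = (
        header if isinstance(header, bool)
        else not all(np.issubdtype(np.asarray([v]).dtype, np.number) for v in first.iloc[0])
    )
    df = pd.read_csv(path, header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header else None

    arr = df.to_numpy()
    bad = pd.isna(df)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"{path}: empty or missing cell at row {i + 1}, column {j + 1}")
    try:
        arrf = arr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from None
    if not np.all(arrf == np.round(arrf)):
        i, j = np.argwhere(arrf != np.round(arrf))[0]
        raise ValueError(f"{path}: non-integer cell at row {i + 1}, column {j + 1}")
    y = arrf.astype(np.int64)
    if y.min() >= 1:
        log.info("%s: responses coded from %d; shifting to 0-based", path, y.min())
        y = y - y.min()
    return OrdinalData(y, labels=labels).compact()
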