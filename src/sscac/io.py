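"""Reading and writing expression matrices and label files.

On disk a matrix is a TSV/CSV with a header row and an id column; in memory
the items to cluster (genes or samples) are always columns of an
``m features x n items`` array, matching the indexing used throughout the
algorithm.  Class labels are 1-based externally; any 0-based conversion
happens past this boundary, never here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """An ``m x n`` real matrix whose columns are the items to cluster."""

    values: np.ndarray          # shape (m, n), float
    item_ids: list[str]         # length n, unique
    feature_ids: list[str]      # length m

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValueError(f"need m >= 1 features and n >= 2 items, got {m}x{n}")
        if len(self.item_ids) != n or len(self.feature_ids) != m:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.item_ids)) != n:
            raise ValueError("item ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path,
                    orientation: str = "items_as_columns") -> ExpressionMatrix:
    """Read a delimited matrix with a header row and a leading id column.

    ``orientation`` says what the file's columns are; the returned matrix
    always has items as columns.  A non-numeric or missing cell raises a
    ``ValueError`` naming the offending row and column ids.
    """
    if orientation not in ("items_as_columns", "items_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path.name}: header ids are not unique")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path.name}: row ids are not unique")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}")
    values = numeric.to_numpy(dtype=float)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "items_as_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    em = ExpressionMatrix(values=values, item_ids=col_ids, feature_ids=row_ids)
    logger.info("read expression matrix %s: m=%d features, n=%d items",
                path.name, em.n_features, em.n_items)
    return em


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    """Write ``em`` with items as columns; round-trips decimal values exactly."""
    path = Path(path)
    df = pd.DataFrame(em.values, index=em.feature_ids, columns=em.item_ids)
    df.to_csv(path, sep=_sep_for(path))


def read_labels(path: str | Path, item_ids: list[str]) -> dict[str, int]:
    """Read a two-column id/class file into ``{item id: class}``.

    Classes are 1-based positive integers; unknown ids, non-integer or
    non-positive classes are rejected.  An empty file yields an empty map
    (the caller must then supply the number of clusters itself).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), header=None,
                         names=["item", "label"], comment="#")
    except pd.errors.EmptyDataError:
        return {}
    if len(df) == 0:
        return {}
    known = set(item_ids)
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        item = str(row["item"])
        if item not in known:
            raise ValueError(f"label file {path.name}: unknown item id {item!r}")
        raw = row["label"]
        try:
            lab = int(raw)
        except (TypeError, ValueError):
            raise ValueError(f"label file {path.name}: non-integer class {raw!r} "
                             f"for item {item!r}") from None
        if float(raw) != lab:
            raise ValueError(f"label file {path.name}: non-integer class {raw!r} "
                             f"for item {item!r}")
        if lab < 1:
            raise ValueError(f"label file {path.name}: classes are 1-based, "
                             f"got {lab} for item {item!r}")
        out[item] = lab
    return out


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        for item, lab in labels.items():
            fh.write(f"{item}{sep}{lab}\n")
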