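"""Binarized and continuous miRNA expression tables.

The on-disk dialect is a plain CSV whose first two columns are ``ID``
(unique sample identifier) and ``Annots`` (binary annotation: 1 =
positive/diseased, 0 = negative/healthy), followed by one column per
miRNA marker.  Binarized tables hold 0/1 entries (1 = High expression,
0 = Low); continuous tables hold non-negative real expression levels in
the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinarizedDataset",
    "ContinuousDataset",
    "DatasetFormatError",
    "ProfileConflict",
    "read_dataset",
    "write_dataset",
    "check_consistency",
    "binarize",
]


class DatasetFormatError(ValueError):
    """Raised when a file or table violates the expression-table dialect."""


def _check_layout(sample_ids, annotations, mirna_ids, matrix):
    if len(mirna_ids) == 0:
        raise DatasetFormatError("dataset has no miRNA columns")
    if len(sample_ids) == 0:
        raise DatasetFormatError("dataset has no samples")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if list(sample_ids).count(s) > 1})
        raise DatasetFormatError(f"duplicate sample ID(s): {dupes}")
    if len(set(mirna_ids)) != len(mirna_ids):
        dupes = sorted({m for m in mirna_ids if list(mirna_ids).count(m) > 1})
        raise DatasetFormatError(f"duplicate miRNA ID(s): {dupes}")
    if len(annotations) != len(sample_ids):
        raise DatasetFormatError("annotation length does not match sample count")
    if matrix.shape != (len(sample_ids), len(mirna_ids)):
        raise DatasetFormatError(
            f"matrix shape {matrix.shape} does not match "
            f"({len(sample_ids)} samples, {len(mirna_ids)} miRNAs)"
        )


@dataclass(frozen=True)
class BinarizedDataset:
    """A sample-by-marker table of binarized (High=1 / Low=0) miRNA levels.

    Parameters
    ----------
    sample_ids : sequence
        Unique sample identifiers (row order preserved from file).
    annotations : ndarray of {0, 1}
        Per-sample class label; 1 = positive (diseased), 0 = negative.
    mirna_ids : sequence of str
        Unique marker identifiers (column order preserved from file).
    matrix : 2-D ndarray of {0, 1}
        Binarized expression, one row per sample.
    """

    sample_ids: tuple
    annotations: np.ndarray
    mirna_ids: tuple
    matrix: np.ndarray

    def __init__(self, sample_ids, annotations, mirna_ids, matrix):
        annotations = np.asarray(annotations)
        matrix = np.asarray(matrix)
        if not np.isin(annotations, (0, 1)).all():
            bad = np.unique(annotations[~np.isin(annotations, (0, 1))])
            raise DatasetFormatError(f"annotations must be 0/1, found {bad.tolist()}")
        if matrix.size and not np.isin(matrix, (0, 1)).all():
            r, c = np.argwhere(~np.isin(matrix, (0, 1)))[0]
            raise DatasetFormatError(
                f"non-binary value {matrix[r, c]!r} at sample "
                f"{list(sample_ids)[r]!r}, column {list(mirna_ids)[c]!r}"
            )
        _check_layout(sample_ids, annotations, mirna_ids, matrix)
        object.__setattr__(self, "sample_ids", tuple(sample_ids))
        object.__setattr__(self, "annotations", annotations.astype(np.int8))
        object.__setattr__(self, "mirna_ids", tuple(str(m) for m in mirna_ids))
        object.__setattr__(self, "matrix", matrix.astype(np.int8))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_positive(self) -> int:
        return int(self.annotations.sum())

    @property
    def n_negative(self) -> int:
        return self.n_samples - self.n_positive

    def profile(self, i: int) -> dict:
        """Row *i* as a marker → 0/1 mapping."""
        return dict(zip(self.mirna_ids, (int(v) for v in self.matrix[i])))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.mirna_ids))
        df.insert(0, "Annots", self.annotations)
        df.insert(0, "ID", list(self.sample_ids))
        return df

    def __eq__(self, other):
        if not isinstance(other, (BinarizedDataset, ContinuousDataset)):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.mirna_ids == other.mirna_ids
            and np.array_equal(self.annotations, other.annotations)
            and np.array_equal(self.matrix, other.matrix)
        )

    def subset(self, rows: Sequence[int]) -> "BinarizedDataset":
        rows = list(rows)
        return BinarizedDataset(
            [self.sample_ids[i] for i in rows],
            self.annotations[rows],
            self.mirna_ids,
            self.matrix[rows],
        )


@dataclass(frozen=True, eq=False)
class ContinuousDataset:
    """Same layout as :class:`BinarizedDataset` with real-valued entries.

    ``threshold`` optionally records the binarization threshold (expression
    units) used to derive a binary table from this one.
    """

    sample_ids: tuple
    annotations: np.ndarray
    mirna_ids: tuple
    matrix: np.ndarray
    threshold: float | None = field(default=None)

    def __init__(self, sample_ids, annotations, mirna_ids, matrix, threshold=None):
        annotations = np.asarray(annotations)
        matrix = np.asarray(matrix, dtype=float)
        if not np.isin(annotations, (0, 1)).all():
            raise DatasetFormatError("annotations must be 0/1")
        if matrix.size and not np.isfinite(matrix).all():
            raise DatasetFormatError("continuous entries must be finite")
        if matrix.size and (matrix < 0).any():
            r, c = np.argwhere(matrix < 0)[0]
            raise DatasetFormatError(
                f"negative expression {matrix[r, c]} at sample "
                f"{list(sample_ids)[r]!r}, column {list(mirna_ids)[c]!r}"
            )
        _check_layout(sample_ids, annotations, mirna_ids, matrix)
        object.__setattr__(self, "sample_ids", tuple(sample_ids))
        object.__setattr__(self, "annotations", annotations.astype(np.int8))
        object.__setattr__(self, "mirna_ids", tuple(str(m) for m in mirna_ids))
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "threshold", threshold)

    n_samples = BinarizedDataset.n_samples
    n_mirnas = BinarizedDataset.n_mirnas
    n_positive = BinarizedDataset.n_positive
    n_negative = BinarizedDataset.n_negative
    to_frame = BinarizedDataset.to_frame
    __eq__ = BinarizedDataset.__eq__

    def profile(self, i: int) -> dict:
        """Row *i* as a marker → expression-level mapping."""
        return dict(zip(self.mirna_ids, (float(v) for v in self.matrix[i])))


def read_dataset(path, mode: str = "binary"):
    """Read an expression table.

    Parameters
    ----------
    path : path-like
        CSV file whose header starts with ``ID,Annots``.
    mode : {"binary", "continuous"}
        Entry domain expected in the marker columns.
    """
    if mode not in ("binary", "continuous"):
        raise ValueError(f"mode must be 'binary' or 'continuous', got {mode!r}")
    # check the raw header first: pandas silently renames duplicate columns
    import csv

    with open(path, newline="") as fh:
        try:
            cols = next(csv.reader(fh))
        except StopIteration:
            raise DatasetFormatError("empty file") from None
    if len(cols) < 2 or cols[0] != "ID" or cols[1] != "Annots":
        raise DatasetFormatError(
            f"header must start with ID,Annots; found {cols[:2]}"
        )
    if len(cols) < 3:
        raise DatasetFormatError("no miRNA columns in header")
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise DatasetFormatError(f"duplicate header field(s): {dupes}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise DatasetFormatError("dataset contains a header but no data rows")
    mirna_ids = cols[2:]
    # the dialect identifies samples by numbers; keep integer IDs as
    # integers so write/read round-trips, fall back to raw tokens otherwise
    raw_ids = list(df["ID"])
    try:
        sample_ids = tuple(int(s) for s in raw_ids)
    except ValueError:
        sample_ids = tuple(raw_ids)
    try:
        annots = df["Annots"].astype(int).to_numpy()
    except ValueError as exc:
        raise DatasetFormatError(f"non-integer annotation: {exc}") from None
    if (df.iloc[:, 2:] == "").any().any():
        raise DatasetFormatError("missing values are not supported")
    if mode == "binary":
        body = df.iloc[:, 2:]
        ok = body.isin(["0", "1"])
        if not ok.all().all():
            r = int(np.argwhere(~ok.to_numpy())[0][0])
            c = int(np.argwhere(~ok.to_numpy())[0][1])
            raise DatasetFormatError(
                f"non-binary value {body.iat[r, c]!r} at sample "
                f"{sample_ids[r]!r}, column {mirna_ids[c]!r}"
            )
        return BinarizedDataset(sample_ids, annots, mirna_ids, body.astype(np.int8).to_numpy())
    try:
        matrix = df.iloc[:, 2:].astype(float).to_numpy()
    except ValueError as exc:
        raise DatasetFormatError(f"non-numeric continuous entry: {exc}") from None
    return ContinuousDataset(sample_ids, annots, mirna_ids, matrix)


def write_dataset(ds, path) -> None:
    """Write a dataset to CSV; round-trips bit-exactly through read_dataset."""
    df = ds.to_frame()
    if isinstance(ds, ContinuousDataset):
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class ProfileConflict:
    """Two samples sharing one binarized profile but annotated differently."""

    positive_id: object
    negative_id: object
    profile: tuple


def check_consistency(ds: BinarizedDataset) -> list[ProfileConflict]:
    """List all label-discordant pairs of samples with identical profiles.

    An empty list means no pair of identical profiles carries conflicting
    annotations, i.e. a perfect classifier is not ruled out by the data
    itself.
    """
    groups: dict[tuple, list[int]] = {}
    for i in range(ds.n_samples):
        groups.setdefault(tuple(int(v) for v in ds.matrix[i]), []).append(i)
    conflicts = []
    for prof, rows in groups.items():
        pos = [i for i in rows if ds.annotations[i] == 1]
        neg = [i for i in rows if ds.annotations[i] == 0]
        for p in pos:
            for n in neg:
                conflicts.append(
                    ProfileConflict(ds.sample_ids[p], ds.sample_ids[n], prof)
                )
    return conflicts


def binarize(cds: ContinuousDataset, threshold: float) -> BinarizedDataset:
    """Discretize a continuous table: value >= threshold maps to High (1).

    The choice of discretization method (and threshold) is deliberately the
    caller's; this helper implements only the fixed-threshold rule.
    """
    return BinarizedDataset(
        cds.sample_ids,
        cds.annotations,
        cds.mirna_ids,
        (cds.matrix >= threshold).astype(np.int8),
    )
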