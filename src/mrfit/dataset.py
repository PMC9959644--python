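"""Drying dataset container and CSV input/output.

A drying experiment is recorded as an ordered sequence of samples
``k = 1..kmax``, each holding the slice shrinkage ``S(k)`` (projected-area
ratio, dimensionless in (0, 1]) and the moisture ratio ``MR(k)``
(dimensionless, ~1 fresh, -> 0 dry).  The estimators treat the records as an
unordered regression sample; the sampling period ``delta`` (minutes) is kept
as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DatasetFormatError

CSV_COLUMNS = ("k", "time_min", "shrinkage", "moisture_ratio")


@dataclass(frozen=True)
class DryingDataset:
    """Ordered drying observations ``{(k, S(k), MR(k))}``.

    Parameters
    ----------
    shrinkage
        ``S(k)`` for ``k = 1..kmax`` in index order.
    moisture_ratio
        ``MR(k)`` aligned with ``shrinkage``.  Additive noise may push values
        slightly outside ``[0, 1]``; only finiteness is enforced.
    time_min
        Optional wall-clock sampling times in minutes.
    delta
        Sampling period in minutes (metadata; never used by the estimators).
    """

    shrinkage: np.ndarray
    moisture_ratio: np.ndarray
    time_min: np.ndarray | None = None
    delta: float = 0.5

    def __post_init__(self) -> None:
        s = np.asarray(self.shrinkage, dtype=float)
        mr = np.asarray(self.moisture_ratio, dtype=float)
        if s.ndim != 1 or mr.ndim != 1 or s.shape != mr.shape:
            raise ValueError("shrinkage and moisture_ratio must be 1-D arrays of equal length")
        if s.size < 2:
            raise ValueError("a drying dataset needs at least two records")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(mr)):
            raise ValueError("shrinkage and moisture_ratio must be finite")
        object.__setattr__(self, "shrinkage", s)
        object.__setattr__(self, "moisture_ratio", mr)
        if self.time_min is not None:
            t = np.asarray(self.time_min, dtype=float)
            if t.shape != s.shape:
                raise ValueError("time_min must align with shrinkage")
            object.__setattr__(self, "time_min", t)

    @property
    def kmax(self) -> int:
        """Number of records."""
        return int(self.shrinkage.size)

    @property
    def k(self) -> np.ndarray:
        """1-based sample indices ``1..kmax``."""
        return np.arange(1, self.kmax + 1)

    def design_matrix(self, order: int) -> np.ndarray:
        """Stacked information vectors: row ``k`` is ``[1, S, S^2, ..., S^order]``."""
        if order < 0:
            raise ValueError("polynomial order must be non-negative")
        return np.vander(self.shrinkage, order + 1, increasing=True)

    def to_frame(self) -> pd.DataFrame:
        t = self.time_min if self.time_min is not None else np.full(self.kmax, np.nan)
        return pd.DataFrame(
            {
                "k": self.k,
                "time_min": t,
                "shrinkage": self.shrinkage,
                "moisture_ratio": self.moisture_ratio,
            }
        )


def read_dataset(path) -> DryingDataset:
    """Read a drying dataset CSV.

    The file must carry a header with at least ``k``, ``shrinkage`` and
    ``moisture_ratio`` columns (``time_min`` optional, possibly empty).  The
    ``k`` column must enumerate ``1..kmax`` with no gaps or duplicates, and
    shrinkage must lie in ``(0, 1]``.  Violations raise
    :class:`~mrfit.errors.DatasetFormatError` naming the offending row
    (1-based, counting the header as row 1).
    """
    try:
        frame = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise DatasetFormatError(f"cannot parse {path}: {exc}") from exc
    missing = {"k", "shrinkage", "moisture_ratio"} - set(frame.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("k", "shrinkage", "moisture_ratio"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & frame[col].notna().to_numpy())[0]
        if bad.size:
            raise DatasetFormatError(f"{path}: non-numeric {col!r} at row {bad[0] + 2}")
        if frame[col].isna().any():
            row = int(np.nonzero(frame[col].isna().to_numpy())[0][0]) + 2
            raise DatasetFormatError(f"{path}: empty {col!r} cell at row {row}")
        frame[col] = vals

    frame = frame.sort_values("k", kind="stable").reset_index(drop=True)
    k = frame["k"].to_numpy()
    if not np.array_equal(k, np.arange(1, len(k) + 1)):
        # locate first duplicate or gap for the error message
        seen: set[int] = set()
        for i, kv in enumerate(k):
            kv_int = int(kv)
            if kv != kv_int or kv_int < 1:
                raise DatasetFormatError(f"{path}: invalid index k={kv} at row {i + 2}")
            if kv_int in seen:
                raise DatasetFormatError(f"{path}: duplicate index k={kv_int} at row {i + 2}")
            seen.add(kv_int)
        raise DatasetFormatError(f"{path}: index k has gaps (got {sorted(seen)[:5]}...)")

    s = frame["shrinkage"].to_numpy(dtype=float)
    out_of_range = np.nonzero((s <= 0) | (s > 1))[0]
    if out_of_range.size:
        i = int(out_of_range[0])
        raise DatasetFormatError(
            f"{path}: shrinkage {s[i]} out of range (0, 1] at row {i + 2}"
        )

    time_min = None
    if "time_min" in frame.columns and frame["time_min"].notna().any():
        time_min = pd.to_numeric(frame["time_min"], errors="coerce").to_numpy(dtype=float)
    return DryingDataset(
        shrinkage=s,
        moisture_ratio=frame["moisture_ratio"].to_numpy(dtype=float),
        time_min=time_min,
    )


def write_dataset(dataset: DryingDataset, path, precision: int = 9) -> None:
    """Write a dataset CSV with the canonical header at a fixed precision."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format=f"%.{precision}g")
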