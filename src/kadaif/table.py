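"""Feature tables and their on-disk TSV/CSV representation.

A feature table is the universal input: a samples x features matrix of
non-negative abundances (counts or relative abundances) with string
sample and feature identifiers. Tables are stored as plain TSV/CSV with
sample IDs as the row index by default; an orientation flag transposes
tables stored features-as-rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table", "write_scores"]


@dataclass
class FeatureTable:
    """Samples x features non-negative abundance matrix with IDs."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain NaN or infinite entries")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_samples(self, indices) -> "FeatureTable":
        indices = np.asarray(indices)
        return FeatureTable(
            [self.sample_ids[i] for i in indices],
            list(self.feature_ids),
            self.values[indices],
        )

    def relative_abundance(self) -> "FeatureTable":
        """Row-normalize so each sample sums to 1 (all-zero rows stay zero)."""
        sums = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(sums > 0, self.values / sums, 0.0)
        return FeatureTable(list(self.sample_ids), list(self.feature_ids), vals)


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if os.fspath(path).endswith(".csv") else "\t"


def read_feature_table(path, orientation: str = "samples", sep: str | None = None) -> FeatureTable:
    """Read a TSV/CSV abundance table.

    Parameters
    ----------
    path : str or path-like
        File with one ID axis per dimension; first column is the row index.
    orientation : {"samples", "features"}
        Which axis the file's rows represent. ``"features"`` transposes.
    sep : str, optional
        Field separator; inferred from the extension when omitted
        (``.csv`` -> comma, otherwise tab).
    """
    if orientation not in ("samples", "features"):
        raise ValueError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if orientation == "features":
        df = df.T
    if df.shape[1] == 0:
        raise ValueError(f"{path}: table has no feature columns")
    # locate non-numeric / empty cells with file coordinates before casting
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: empty or non-numeric cell at data line {i + 2}, "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    arr = numeric.to_numpy(dtype=np.float64)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative value at data line {i + 2}, "
            f"row {df.index[i]!r}, column {df.columns[j]!r}: {arr[i, j]}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column ID {dup!r}")
    return FeatureTable(list(df.index.astype(str)), list(df.columns.astype(str)), arr)


def write_feature_table(table: FeatureTable, path, sep: str | None = None) -> None:
    sep = _sep_for(path, sep)
    with open(path, "w") as fh:
        fh.write("sample_id" + sep + sep.join(table.feature_ids) + "\n")
        for sid, row in zip(table.sample_ids, table.values):
            fh.write(sid + sep + sep.join(f"{v:.12g}" for v in row) + "\n")


def write_scores(report, path) -> None:
    """Write an anomaly-score report as TSV.

    Columns: sample_id, mean_depth, anomaly_score, flagged. Floats carry
    12 significant digits so that scores round-trip.
    """
    with open(path, "w") as fh:
        fh.write("sample_id\tmean_depth\tanomaly_score\tflagged\n")
        for sid, d, s, f in zip(report.sample_ids, report.mean_depth, report.score, report.flagged):
            fh.write(f"{sid}\t{d:.12g}\t{s:.12g}\t{'true' if f else 'false'}\n")
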