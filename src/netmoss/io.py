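"""Reading, writing and filtering of abundance tables and correlation matrices.

Abundance tables are labelled taxa x samples matrices of relative
abundances (each sample column sums to one).  Correlation matrices are
square labelled matrices in [-1, 1] with unit diagonal.  Both travel as
plain TSV/CSV text; the delimiter is inferred from the file extension
(``.csv`` -> comma, anything else -> tab) unless given explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "CorrelationNetwork",
    "read_abundance_table",
    "filter_low_abundance",
    "read_correlation_matrix",
    "write_correlation_matrix",
    "write_abundance_table",
]

_RELATIVE_TOL = 1e-6
_SYMMETRY_TOL = 1e-8
_RANGE_TOL = 1e-8


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(labels, kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {kind} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class AbundanceTable:
    """A labelled taxa x samples matrix of non-negative abundances.

    ``data`` is indexed by taxon (rows) and sample (columns).  When
    ``relative`` is true each column is a composition summing to one.
    """

    data: pd.DataFrame
    study_id: str = ""
    group: Literal["case", "control", ""] = ""
    relative: bool = True

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def renormalized(self) -> "AbundanceTable":
        """Return a copy with each sample column rescaled to sum to one."""
        sums = self.data.sum(axis=0)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise ValueError(f"sample {bad!r} has zero total abundance")
        return replace(self, data=self.data / sums)


@dataclass
class CorrelationNetwork:
    """A symmetric taxon-taxon correlation matrix with its sample size.

    ``n`` is the number of samples the correlations were estimated from;
    it drives the inverse-variance weights during integration.
    """

    corr: pd.DataFrame
    n: int
    study_id: str = ""
    group: Literal["case", "control", ""] = ""

    def __post_init__(self) -> None:
        if self.corr.shape[0] != self.corr.shape[1]:
            raise ValueError(f"correlation matrix is not square: {self.corr.shape}")
        _check_unique(self.corr.index, "taxon")
        if list(self.corr.index) != list(self.corr.columns):
            raise ValueError("row and column labels of a correlation matrix differ")
        values = self.corr.to_numpy(dtype=float)
        if np.abs(values).max(initial=0.0) > 1 + _RANGE_TOL:
            worst = values.flat[np.abs(values).argmax()]
            raise ValueError(f"correlation entry out of [-1, 1]: {worst}")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0):
            raise ValueError("correlation matrix is not symmetric")
        if self.n < 3:
            raise ValueError(f"sample size n={self.n} < 3 cannot support a correlation")

    @property
    def taxa(self) -> list[str]:
        return list(self.corr.index)

    @property
    def values(self) -> np.ndarray:
        return self.corr.to_numpy(dtype=float)


def read_abundance_table(
    path: str | Path,
    delimiter: str | None = None,
    orientation: Literal["taxa_rows", "samples_rows"] = "taxa_rows",
    study_id: str = "",
    group: Literal["case", "control", ""] = "",
    relative: bool = True,
) -> AbundanceTable:
    """Read a labelled abundance table from delimited text.

    The first column holds row labels and the first row column labels.
    With ``orientation="samples_rows"`` the file is transposed on load so
    the returned table is always taxa x samples.  When ``relative`` is
    true, sample columns are renormalized to sum to one if they deviate
    by more than 1e-6.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"abundance table not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    non_numeric = frame.select_dtypes(exclude="number").columns
    if len(non_numeric) > 0:
        raise ValueError(f"non-numeric cell(s) in column {non_numeric[0]!r} of {path}")
    if orientation == "samples_rows":
        frame = frame.T
    elif orientation != "taxa_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    table = AbundanceTable(frame.astype(float), study_id=study_id, group=group, relative=relative)
    if relative:
        sums = table.data.sum(axis=0)
        if np.abs(sums - 1.0).max() > _RELATIVE_TOL:
            table = table.renormalized()
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    table.data.to_csv(path, sep=sep, float_format="%.17g")


def filter_low_abundance(
    table: AbundanceTable,
    min_rel: float = 0.001,
    min_prev: float = 0.10,
) -> AbundanceTable:
    """Drop taxa that never reach ``min_rel`` abundance in enough samples.

    A taxon is kept when its relative abundance is at least ``min_rel``
    (inclusive) in at least ``ceil(min_prev * n_samples)`` samples.
    Columns are *not* renormalized afterwards, so the retained fractions
    stay on the original scale.  Filtering is idempotent.
    """
    if not 0 <= min_rel <= 1:
        raise ValueError(f"min_rel must be in [0, 1], got {min_rel}")
    if not 0 < min_prev <= 1:
        raise ValueError(f"min_prev must be in (0, 1], got {min_prev}")
    needed = int(np.ceil(min_prev * table.n_samples))
    hits = (table.data.to_numpy(dtype=float) >= min_rel).sum(axis=1)
    keep = hits >= needed
    if not keep.any():
        raise ValueError(
            f"no taxon reaches abundance {min_rel} in {needed} samples; "
            "lower --min-rel or --min-prev"
        )
    return replace(table, data=table.data.loc[keep])


def read_correlation_matrix(
    path: str | Path,
    n: int = 3,
    delimiter: str | None = None,
    study_id: str = "",
    group: Literal["case", "control", ""] = "",
) -> CorrelationNetwork:
    """Read a labelled square correlation matrix from delimited text.

    Asymmetries up to 1e-8 are silently repaired by averaging with the
    transpose; larger ones are repaired with a warning.  The diagonal is
    forced to exactly one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"correlation matrix not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"correlation matrix in {path} is not square: {frame.shape}")
    values = frame.to_numpy(dtype=float)
    if np.abs(values).max(initial=0.0) > 1 + _RANGE_TOL:
        flat = np.abs(values).argmax()
        raise ValueError(
            f"correlation entry out of [-1, 1] in {path}: "
            f"{values.flat[flat]} at {frame.index[flat // len(values)]!r}"
        )
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > _SYMMETRY_TOL:
        warnings.warn(
            f"matrix in {path} asymmetric by {asym:.3g}; symmetrizing", stacklevel=2
        )
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    frame = pd.DataFrame(values, index=frame.index, columns=frame.index)
    return CorrelationNetwork(frame, n=n, study_id=study_id, group=group)


def write_correlation_matrix(net: CorrelationNetwork, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    net.corr.to_csv(path, sep=sep, float_format="%.17g")
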