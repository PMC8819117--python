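"""Coverage-matrix containers, TSV I/O, and the 100 -> 10 bin reduction.

Clustering runs on the mean-reduced matrix: each of the ten bins is the
arithmetic mean of ten consecutive gene-body positions.  Values are not
re-normalized after reduction, so the relative amplitudes the clustering
relies on are preserved.  All-zero cells (no coverage signal) are carried
through as zeros and flagged; they are excluded from clustering input and
labeled skewed at annotation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_model import N_PERCENTILES

N_REDUCED = 10
_FLOAT_FMT = "%.6f"


@dataclass
class CoverageMatrix:
    cell_ids: list[str]
    values: np.ndarray  # n_cells x 100, in [0, 1]
    zero_flags: np.ndarray  # bool per cell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_PERCENTILES:
            raise ValueError(f"coverage matrix must be n x {N_PERCENTILES}, got {self.values.shape}")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in coverage matrix")
        if self.zero_flags is None:
            self.zero_flags = ~self.values.any(axis=1)
        self.zero_flags = np.asarray(self.zero_flags, dtype=bool)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("coverage values out of [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ReducedMatrix:
    cell_ids: list[str]
    values: np.ndarray  # n_cells x 10
    zero_flags: np.ndarray
    bin_edges: tuple[tuple[int, int], ...] = tuple(
        (10 * k, 10 * k + 10) for k in range(N_REDUCED)
    )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def clustering_input(self) -> tuple[np.ndarray, list[str]]:
        """Rows entering the trimmed fit: flagged all-zero cells removed."""
        keep = ~self.zero_flags
        return self.values[keep], [c for c, k in zip(self.cell_ids, keep) if k]


def reduce_bins(matrix: CoverageMatrix) -> ReducedMatrix:
    """Mean-reduce the 100 positions to 10 bins of 10 consecutive positions."""
    if matrix.values.shape[1] != N_PERCENTILES:
        raise ValueError(f"expected {N_PERCENTILES} columns, got {matrix.values.shape[1]}")
    reduced = matrix.values.reshape(matrix.n_cells, N_REDUCED, 10).mean(axis=2)
    return ReducedMatrix(
        cell_ids=list(matrix.cell_ids),
        values=reduced,
        zero_flags=matrix.zero_flags.copy(),
    )


def save_matrix(matrix: CoverageMatrix, path: str | Path) -> None:
    """Write the coverage matrix TSV: header cell_id, pos_0..pos_99; 6 decimals."""
    df = pd.DataFrame(
        matrix.values, columns=[f"pos_{k}" for k in range(N_PERCENTILES)]
    )
    df.insert(0, "cell_id", matrix.cell_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_matrix(path: str | Path) -> CoverageMatrix:
    """Read a coverage matrix TSV (CRLF tolerated); validates range and shape."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "cell_id":
        raise ValueError(f"{path}: first column must be 'cell_id', got {df.columns[0]!r}")
    if df.shape[1] != N_PERCENTILES + 1:
        raise ValueError(
            f"{path}: expected {N_PERCENTILES} position columns, got {df.shape[1] - 1}"
        )
    cell_ids = df["cell_id"].tolist()
    if df["cell_id"].duplicated().any():
        dupes = df["cell_id"][df["cell_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate cell_id {dupes}")
    body = df.iloc[:, 1:]
    converted = {}
    for col in body.columns:
        numeric = pd.to_numeric(body[col], errors="coerce")
        bad = numeric.isna() & body[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(np.where(numeric.isna())[0][0])
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row + 1}, column {col}"
            )
        converted[col] = numeric
    values = pd.DataFrame(converted).to_numpy(dtype=float)
    if values.min() < 0 or values.max() > 1:
        i, j = np.unravel_index(
            np.argmax((values < 0) | (values > 1)), values.shape
        )
        raise ValueError(
            f"{path}: value {values[i, j]} out of [0, 1] at row {i + 1} column pos_{j}"
        )
    return CoverageMatrix(
        cell_ids=cell_ids, values=values, zero_flags=~values.any(axis=1)
    )


def save_reduced(matrix: ReducedMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=[f"bin_{k}" for k in range(N_REDUCED)])
    df.insert(0, "cell_id", matrix.cell_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
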