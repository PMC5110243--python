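"""Expression-matrix containers and I/O.

Single-cell and bulk expression values live in a cells x genes matrix of
non-negative reals. Raw values are FPKM; every downstream analysis operates
on the log2(FPKM + 1) scale, and the container carries an explicit scale
flag so the transform cannot be applied twice or skipped silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Scale flags for :class:`ExpressionMatrix`.
RAW_FPKM = "raw_fpkm"
LOG2P1 = "log2p1"

VALID_SPECIES = {"human", "chimpanzee", "orangutan", "mouse"}
VALID_SOURCES = {"organoid", "fetal", "iPSC", "endothelial", "B-cell"}
VALID_TYPES = {"AP", "BP", "N", "unassigned"}
VALID_ZONES = {"VZ", "iSVZ", "oSVZ", "CP", "unassigned"}
VALID_PHASES = {"G1", "G2M", "intermediate", "unassigned"}


class ExpressionIOError(ValueError):
    """Malformed expression input (duplicate ids, ragged rows, negatives)."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression matrix with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame with cell ids as the index and gene ids as columns.
        All entries must be finite and >= 0.
    scale
        Either ``"raw_fpkm"`` or ``"log2p1"``.
    """

    values: pd.DataFrame
    scale: str = LOG2P1

    def __post_init__(self) -> None:
        if self.scale not in (RAW_FPKM, LOG2P1):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ExpressionIOError(f"duplicate cell id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ExpressionIOError(f"duplicate gene id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ExpressionIOError("non-finite expression values")
        if arr.size and (arr < 0).any():
            raise ExpressionIOError("negative expression values")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def require_log(self) -> None:
        """Raise unless the matrix is on the log2(FPKM+1) scale."""
        if self.scale != LOG2P1:
            raise ValueError(
                "matrix must be log2(FPKM+1)-transformed before analysis; "
                "call log_transform first"
            )


@dataclass
class CellMeta:
    """Per-cell annotation table (species, source, type, zone, phase)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("cell_id", "species", "source", "assigned_type", "zone", "cycle_phase")

    def __post_init__(self) -> None:
        if self.table.empty:
            self.table = pd.DataFrame(columns=list(self.COLUMNS))
            return
        for col in self.COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"CellMeta missing column {col!r}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in CellMeta")
        checks = {
            "species": VALID_SPECIES,
            "source": VALID_SOURCES,
            "assigned_type": VALID_TYPES,
            "zone": VALID_ZONES,
            "cycle_phase": VALID_PHASES,
        }
        for col, allowed in checks.items():
            bad = set(self.table[col]) - allowed
            if bad:
                raise ValueError(f"invalid {col} values {sorted(bad)!r}")

    @classmethod
    def from_columns(
        cls,
        cell_ids: Iterable[str],
        species: Iterable[str],
        source: str = "organoid",
    ) -> "CellMeta":
        ids = list(cell_ids)
        return cls(
            pd.DataFrame(
                {
                    "cell_id": ids,
                    "species": list(species),
                    "source": source,
                    "assigned_type": "unassigned",
                    "zone": "unassigned",
                    "cycle_phase": "unassigned",
                }
            )
        )

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CellMeta":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix_tsv(path: str | Path, scale: str = LOG2P1) -> ExpressionMatrix:
    """Read a dense TSV matrix (cells in rows, header row of gene ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    # pandas mangles duplicate headers; detect them from the raw header line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dup = next(g for g in header if header.count(g) > 1)
        raise ExpressionIOError(f"duplicate gene id {dup!r} in header of {path}")
    arr = df.to_numpy()
    if arr.dtype == object or (arr.size and not np.isfinite(arr.astype(float)).all()):
        raise ExpressionIOError(f"non-numeric or missing entries in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_matrix_tsv(
    m: ExpressionMatrix, path: str | Path, float_format: str | None = None
) -> None:
    """Write a dense TSV matrix; full double precision unless a format is given."""
    fmt = float_format if float_format is not None else "%.17g"
    m.values.to_csv(path, sep="\t", float_format=fmt)


def read_matrix_triplets(
    path: str | Path,
    cell_ids: list[str],
    gene_ids: list[str],
    scale: str = LOG2P1,
) -> ExpressionMatrix:
    """Read a sparse triplet file (cell_index, gene_index, value; 0-based).

    Entries absent from the file are zero, following the sparse convention.
    """
    trip = pd.read_csv(
        path, sep="\t", header=None, names=["row", "col", "value"], comment="%"
    )
    arr = np.zeros((len(cell_ids), len(gene_ids)))
    rows = trip["row"].to_numpy(dtype=int)
    cols = trip["col"].to_numpy(dtype=int)
    if rows.size and (rows.min() < 0 or rows.max() >= len(cell_ids)):
        raise ExpressionIOError("triplet row index out of range")
    if cols.size and (cols.min() < 0 or cols.max() >= len(gene_ids)):
        raise ExpressionIOError("triplet col index out of range")
    arr[rows, cols] = trip["value"].to_numpy(dtype=float)
    df = pd.DataFrame(arr, index=cell_ids, columns=gene_ids)
    return ExpressionMatrix(df, scale=scale)


def write_matrix_triplets(m: ExpressionMatrix, path: str | Path) -> None:
    """Write nonzero entries as 0-based (row, col, value) triplets."""
    arr = m.values.to_numpy()
    rows, cols = np.nonzero(arr)
    with open(path, "w") as fh:
        fh.write(f"% {m.n_cells} {m.n_genes} {len(rows)}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{arr[r, c]:.17g}\n")


# ---------------------------------------------------------------------------
# transforms and filters


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply v -> log2(v + 1) to a raw-FPKM matrix.

    Refuses a matrix already on the log scale, so the transform cannot be
    applied twice.
    """
    if m.scale == LOG2P1:
        raise ValueError("matrix already log2(FPKM+1)-transformed")
    return ExpressionMatrix(np.log2(m.values + 1.0), scale=LOG2P1)


def filter_genes(
    m: ExpressionMatrix, min_cells: int = 2, require_variance: bool = True
) -> ExpressionMatrix:
    """Keep genes expressed (value > 0) in strictly more than ``min_cells``
    cells and, by default, with non-zero variance across cells.

    Gene order is preserved; the operation is idempotent.
    """
    m.require_log()
    arr = m.values.to_numpy()
    expressed = (arr > 0).sum(axis=0) > min_cells
    keep = expressed
    if require_variance:
        keep = keep & (arr.var(axis=0) > 0)
    if not keep.any():
        warnings.warn("no genes survive filtering", stacklevel=2)
    return ExpressionMatrix(m.values.loc[:, keep], scale=m.scale)
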