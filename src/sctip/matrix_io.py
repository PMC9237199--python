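"""Count-matrix and annotation I/O plus the shared data model.

Matrices are genes x cells everywhere inside the package.  On disk two
layouts are supported: MatrixMarket coordinate format with companion
``genes.tsv`` / ``barcodes.tsv`` identifier lists, and a dense TSV whose
first column holds gene ids and whose header row holds cell ids.  An
explicit ``transpose`` flag accommodates files stored cells x genes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class MatrixFormatError(ValueError):
    """Raised for malformed matrix or annotation files."""


class AnnotationError(ValueError):
    """Raised when annotations are missing, duplicated, or incomplete."""


GENE_FLAG_COLUMNS = (
    "is_mitochondrial",
    "is_housekeeping",
    "is_tf",
    "is_ligand",
    "is_receptor",
)

_TRUE_STRINGS = {"true", "1", "yes", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f", ""}


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixFormatError(f"duplicate {axis} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer UMI count matrix, genes as rows, cells as columns."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if sparse.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise MatrixFormatError("count matrix must be two-dimensional")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise MatrixFormatError(
                f"shape {values.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if np.issubdtype(values.dtype, np.floating):
            frac = values - np.floor(values)
            if np.any(frac != 0):
                g, c = np.argwhere(frac != 0)[0]
                raise MatrixFormatError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"cell {self.cell_ids[c]!r}"
                )
        if np.any(values < 0):
            g, c = np.argwhere(values < 0)[0]
            raise MatrixFormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"cell {self.cell_ids[c]!r}"
            )
        self.values = values.astype(np.int64, copy=False)

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def genes_detected_per_cell(self) -> np.ndarray:
        return (self.values > 0).sum(axis=0)

    def cells_detected_per_gene(self) -> np.ndarray:
        return (self.values > 0).sum(axis=1)

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return CountMatrix(self.values[:, idx], list(self.gene_ids), list(cell_ids))

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(self.values[idx, :], list(gene_ids), list(self.cell_ids))


@dataclass
class CellAnnotation:
    """Per-cell metadata with an explicit total order on time points."""

    table: pd.DataFrame
    time_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        tbl = self.table
        for col in ("cell_id", "time_point"):
            if col not in tbl.columns:
                raise AnnotationError(f"missing required column {col!r}")
        if tbl["cell_id"].duplicated().any():
            dup = tbl.loc[tbl["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise AnnotationError(f"cell_id not unique: {dup!r}")
        self.time_levels = tuple(str(t) for t in self.time_levels)
        observed = set(tbl["time_point"].astype(str))
        missing = observed - set(self.time_levels)
        if missing:
            raise AnnotationError(
                f"time points {sorted(missing)} absent from declared levels"
            )
        tbl = tbl.copy()
        tbl["cell_id"] = tbl["cell_id"].astype(str)
        tbl["time_point"] = tbl["time_point"].astype(str)
        self.table = tbl.reset_index(drop=True)

    @classmethod
    def from_frame(
        cls, table: pd.DataFrame, time_order: Sequence[str] | None = None
    ) -> "CellAnnotation":
        if time_order is None:
            if "time_point" not in table.columns:
                raise AnnotationError("missing required column 'time_point'")
            time_order = list(dict.fromkeys(table["time_point"].astype(str)))
        return cls(table, tuple(time_order))

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise AnnotationError(f"missing annotation column {name!r}")
        return self.table.set_index("cell_id")[name]

    def cells_at(self, time_point: str) -> list[str]:
        t = self.table
        return list(t.loc[t["time_point"] == str(time_point), "cell_id"])

    def require_covers(self, cell_ids: Iterable[str]) -> None:
        """Refuse matrices containing unannotated cells."""
        known = set(self.table["cell_id"])
        missing = [c for c in cell_ids if c not in known]
        if missing:
            raise AnnotationError(
                f"{len(missing)} cells lack annotation (first: {missing[0]!r})"
            )


@dataclass
class GeneAnnotation:
    """Per-gene boolean flags (mitochondrial / housekeeping / TF / ligand / receptor)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tbl = self.table.copy()
        if "gene_id" not in tbl.columns:
            raise AnnotationError("missing required column 'gene_id'")
        if tbl["gene_id"].duplicated().any():
            dup = tbl.loc[tbl["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise AnnotationError(f"gene_id not unique: {dup!r}")
        tbl["gene_id"] = tbl["gene_id"].astype(str)
        for col in GENE_FLAG_COLUMNS:
            if col not in tbl.columns:
                tbl[col] = False
            else:
                tbl[col] = tbl[col].map(_parse_bool)
        self.table = tbl.reset_index(drop=True)

    def flagged(self, flag: str) -> list[str]:
        if flag not in GENE_FLAG_COLUMNS:
            raise AnnotationError(f"unknown gene flag {flag!r}")
        t = self.table
        return list(t.loc[t[flag], "gene_id"])

    def require_covers(self, gene_ids: Iterable[str]) -> None:
        known = set(self.table["gene_id"])
        missing = [g for g in gene_ids if g not in known]
        if missing:
            raise AnnotationError(
                f"{len(missing)} genes lack annotation (first: {missing[0]!r})"
            )


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float, np.floating)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise AnnotationError(f"cannot parse boolean flag value {x!r}")


# ---------------------------------------------------------------------------
# count matrix readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(
    path: str | os.PathLike,
    format: str = "mtx",
    transpose: bool = False,
) -> CountMatrix:
    """Load a count matrix.

    ``mtx`` expects a directory containing ``matrix.mtx``, ``genes.tsv`` and
    ``barcodes.tsv`` (one identifier per line).  ``dense_tsv`` expects a
    single TSV, first column = gene ids, header = cell ids.  ``transpose``
    flips the on-disk orientation to the internal genes x cells layout.
    """
    path = os.fspath(path)
    if format == "mtx":
        mtx_file = os.path.join(path, "matrix.mtx")
        genes_file = os.path.join(path, "genes.tsv")
        cells_file = os.path.join(path, "barcodes.tsv")
        for f in (mtx_file, genes_file, cells_file):
            if not os.path.exists(f):
                raise MatrixFormatError(f"missing file: {f}")
        try:
            mat = spio.mmread(mtx_file)
        except ValueError as exc:
            raise MatrixFormatError(f"malformed MTX header in {mtx_file}: {exc}") from exc
        values = np.asarray(sparse.coo_matrix(mat).todense())
        gene_ids = _read_id_list(genes_file)
        cell_ids = _read_id_list(cells_file)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise MatrixFormatError(f"unknown format {format!r}")
    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return CountMatrix(values, gene_ids, cell_ids)


def write_count_matrix(
    cm: CountMatrix, path: str | os.PathLike, format: str = "mtx"
) -> None:
    path = os.fspath(path)
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        coo = sparse.coo_matrix(cm.values)
        spio.mmwrite(os.path.join(path, "matrix.mtx"), coo, field="integer")
        _write_id_list(os.path.join(path, "genes.tsv"), cm.gene_ids)
        _write_id_list(os.path.join(path, "barcodes.tsv"), cm.cell_ids)
    elif format == "dense_tsv":
        df = pd.DataFrame(cm.values, index=cm.gene_ids, columns=cm.cell_ids)
        df.to_csv(path, sep="\t")
    else:
        raise MatrixFormatError(f"unknown format {format!r}")


def _read_id_list(path: str) -> list[str]:
    with open(path) as fh:
        # tolerate multi-column 10x-style files; first field is the id
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _write_id_list(path: str, ids: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# annotation readers / writers
# ---------------------------------------------------------------------------

def read_cell_annotation(
    path: str | os.PathLike, time_order: Sequence[str] | None = None
) -> CellAnnotation:
    """Read a cell annotation TSV; unknown columns are kept as strings.

    When ``time_order`` is omitted the levels are taken in order of first
    appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CellAnnotation.from_frame(df, time_order)


def write_cell_annotation(ann: CellAnnotation, path: str | os.PathLike) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | os.PathLike) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GeneAnnotation(df)


def write_gene_annotation(ann: GeneAnnotation, path: str | os.PathLike) -> None:
    ann.table.to_csv(path, sep="\t", index=False)
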