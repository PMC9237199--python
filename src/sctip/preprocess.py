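"""Cell/gene quality filters, TPM-like log normalization, RLE diagnostic.

Filter contract (order matters and is part of the contract):

1. cells with fewer than ``min_genes`` detected genes are removed;
2. cells whose log10 total UMI lies strictly outside mean +/- ``umi_sd``
   standard deviations (ddof=1, computed on the input matrix) are removed;
3. mitochondrial genes and genes detected in fewer than ``min_cells`` of
   the surviving cells are removed.

Both cell criteria are evaluated on the unfiltered matrix in a single
pass; gene prevalence is counted on the post-cell-filter matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix, GeneAnnotation


class EmptyResultError(ValueError):
    """Raised when a filter would remove every cell or gene."""


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Natural-log TPM-like expression, genes x cells.

    ``values = ln(1 + count / cell_total * size_factor)``, so for every cell
    ``sum(exp(values) - 1) == size_factor``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    size_factor: float = 10_000.0
    pseudocount_convention: str = "log1p"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("shape does not match identifier lists")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "NormalizedMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return NormalizedMatrix(
            self.values[idx, :], list(gene_ids), list(self.cell_ids),
            self.size_factor, self.pseudocount_convention,
        )

    def subset_cells(self, cell_ids: Sequence[str]) -> "NormalizedMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in cell_ids]
        return NormalizedMatrix(
            self.values[:, idx], list(self.gene_ids), list(cell_ids),
            self.size_factor, self.pseudocount_convention,
        )

    def gene_vector(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene_id), :]
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None


@dataclass
class FilterReport:
    """Removal bookkeeping; each item is counted once under its first
    failing criterion, in the order the criteria are applied."""

    axis: str
    n_in: int
    n_out: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    def removal_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.removed.items()}

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "removal_counts": self.removal_counts(),
            "removed": self.removed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def filter_cells(
    cm: CountMatrix, min_genes: int = 500, umi_sd: float = 2.0
) -> tuple[CountMatrix, FilterReport]:
    """Remove low-complexity cells and log10-UMI outliers (see module docs)."""
    detected = cm.genes_detected_per_cell()
    totals = cm.cell_totals()
    low_gene = detected < min_genes

    positive = totals > 0
    log_tot = np.full(cm.n_cells, np.nan)
    log_tot[positive] = np.log10(totals[positive])
    usable = log_tot[positive]
    outlier = np.zeros(cm.n_cells, dtype=bool)
    if usable.size >= 2:
        mean = usable.mean()
        sd = usable.std(ddof=1)
        if sd > 0:
            outlier[positive] = np.abs(log_tot[positive] - mean) > umi_sd * sd
    # zero-total cells are always low-complexity when min_genes >= 1
    outlier[~positive] = False

    removed: dict[str, list[str]] = {"low_gene_cell": [], "umi_outlier_cell": []}
    keep: list[str] = []
    for i, cid in enumerate(cm.cell_ids):
        if low_gene[i]:
            removed["low_gene_cell"].append(cid)
        elif outlier[i]:
            removed["umi_outlier_cell"].append(cid)
        else:
            keep.append(cid)
    if not keep:
        raise EmptyResultError("cell filtering removed every cell")
    out = cm.subset_cells(keep)
    return out, FilterReport("cell", cm.n_cells, out.n_cells, removed)


def filter_genes(
    cm: CountMatrix,
    annotation: GeneAnnotation | None = None,
    min_cells: int = 10,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, FilterReport]:
    """Remove low-prevalence genes and mitochondrial genes.

    Mitochondrial genes come from the annotation flag when available,
    otherwise from a case-insensitive id-prefix rule.
    """
    if annotation is not None:
        annotation.require_covers(cm.gene_ids)
        mito_set = set(annotation.flagged("is_mitochondrial"))
        mito = np.asarray([g in mito_set for g in cm.gene_ids])
    else:
        mito = np.asarray(
            [g.lower().startswith(mito_prefix.lower()) for g in cm.gene_ids]
        )
    prevalence = cm.cells_detected_per_gene()
    low = prevalence < min_cells

    removed: dict[str, list[str]] = {"low_cell_gene": [], "mito_gene": []}
    keep: list[str] = []
    for i, gid in enumerate(cm.gene_ids):
        if low[i]:
            removed["low_cell_gene"].append(gid)
        elif mito[i]:
            removed["mito_gene"].append(gid)
        else:
            keep.append(gid)
    if not keep:
        raise EmptyResultError("gene filtering removed every gene")
    out = cm.subset_genes(keep)
    return out, FilterReport("gene", cm.n_genes, out.n_genes, removed)


def normalize(cm: CountMatrix, size_factor: float = 10_000.0) -> NormalizedMatrix:
    """ln(1 + count / total * size_factor) per entry."""
    totals = cm.cell_totals().astype(float)
    if np.any(totals == 0):
        bad = cm.cell_ids[int(np.argmax(totals == 0))]
        raise NormalizationError(
            f"cell {bad!r} has zero total UMIs; run filter_cells first"
        )
    values = np.log1p(cm.values / totals[None, :] * size_factor)
    return NormalizedMatrix(values, list(cm.gene_ids), list(cm.cell_ids), size_factor)


def rle_diagnostic(
    nm: NormalizedMatrix,
    housekeeping: Iterable[str],
    sample_of_cell: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Relative log expression of housekeeping genes, summarized per sample.

    RLE = log2(expr / median across all cells of that gene's expr), with
    expression on the TPM-like (pre-log) scale.  Genes with zero median and
    zero-expression entries cannot be log-transformed and are excluded
    (with a warning for zero-median genes).  Returns one row per sample
    with the median and IQR of the pooled RLE values.
    """
    hk = [g for g in housekeeping if g in nm.gene_ids]
    if len(hk) < 2:
        raise ValueError("need at least 2 housekeeping genes present in the matrix")
    sample_of_cell = pd.Series(sample_of_cell)
    missing = [c for c in nm.cell_ids if c not in sample_of_cell.index]
    if missing:
        raise ValueError(f"cells without sample label (first: {missing[0]!r})")

    sub = nm.subset_genes(hk)
    expr = np.expm1(sub.values)  # back to TPM-like scale
    medians = np.median(expr, axis=1)
    zero_med = medians == 0
    if zero_med.any():
        dropped = [g for g, z in zip(hk, zero_med) if z]
        warnings.warn(
            f"excluding {len(dropped)} housekeeping genes with zero median "
            f"expression (first: {dropped[0]!r})"
        )
    expr = expr[~zero_med, :]
    medians = medians[~zero_med]
    if expr.shape[0] < 2:
        raise ValueError("fewer than 2 housekeeping genes with nonzero median")

    with np.errstate(divide="ignore"):
        rle = np.log2(expr / medians[:, None])
    finite = np.isfinite(rle)

    labels = sample_of_cell.loc[list(nm.cell_ids)].to_numpy()
    rows = []
    for sample in pd.unique(labels):
        cols = labels == sample
        vals = rle[:, cols][finite[:, cols]]
        if vals.size == 0:
            rows.append((sample, 0, np.nan, np.nan))
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((sample, int(vals.size), med, q3 - q1))
    return pd.DataFrame(rows, columns=["sample", "n_values", "median_rle", "iqr_rle"])
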