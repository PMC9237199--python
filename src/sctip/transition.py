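"""Per-time-point correlation structure and the transition index.

The transition index at time t is the mean absolute Pearson correlation
over all unordered distinct gene pairs divided by the mean (absolute, by
default) Pearson correlation over all unordered distinct cell pairs.  A
peak across the time course marks a critical transition between two
attractor states: cells decohere (cell-cell correlation drops) while
genes co-fluctuate (gene-gene correlation rises).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix


class CorrelationError(ValueError):
    pass


def _pearson_matrix(data: np.ndarray, ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Correlation between rows of ``data``; zero-variance rows are dropped
    and their ids returned."""
    sd = data.std(axis=1)
    keep = sd > 0
    excluded = [i for i, k in zip(ids, keep) if not k]
    usable = data[keep, :]
    if usable.shape[0] < 2:
        raise CorrelationError(
            f"fewer than 2 rows with nonzero variance ({len(excluded)} excluded)"
        )
    corr = np.corrcoef(usable)
    np.fill_diagonal(corr, 1.0)
    return corr, excluded


def cell_cell_correlation(nm: NormalizedMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of every cell pair across genes.

    Returns the symmetric coefficient matrix (unit diagonal) and the ids of
    cells excluded for zero variance.
    """
    if nm.n_cells < 2 or nm.n_genes < 2:
        raise CorrelationError("need at least 2 cells and 2 genes")
    corr, excluded = _pearson_matrix(nm.values.T, nm.cell_ids)
    kept = [c for c in nm.cell_ids if c not in set(excluded)]
    return pd.DataFrame(corr, index=kept, columns=kept), excluded


def gene_gene_correlation(nm: NormalizedMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of every gene pair across cells."""
    if nm.n_cells < 2 or nm.n_genes < 2:
        raise CorrelationError("need at least 2 cells and 2 genes")
    corr, excluded = _pearson_matrix(nm.values, nm.gene_ids)
    kept = [g for g in nm.gene_ids if g not in set(excluded)]
    return pd.DataFrame(corr, index=kept, columns=kept), excluded


def mean_offdiagonal(corr: np.ndarray, absolute: bool = True) -> float:
    """Mean over unordered distinct pairs; the diagonal never contributes."""
    corr = np.asarray(corr)
    k = corr.shape[0]
    if k < 2:
        raise CorrelationError("need at least 2 rows for a pair mean")
    mat = np.abs(corr) if absolute else corr
    return float((mat.sum() - np.trace(mat)) / (k * (k - 1)))


@dataclass
class TransitionSeries:
    """Per-time-point correlation summary and transition index."""

    frame: pd.DataFrame  # indexed by time point, in series order
    gene_ids: list[str]
    signed_cell_corr: bool = False

    @property
    def time_points(self) -> list[str]:
        return list(self.frame.index)

    def argmax_ic(self) -> list[str]:
        ic = self.frame["ic"].dropna()
        if ic.empty:
            return []
        return list(ic.index[ic == ic.max()])

    def to_csv(self, path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "time_point"})
        out.to_csv(path, index=False, float_format="%.12g")


def transition_index(
    nm_by_time: Mapping[str, NormalizedMatrix],
    gene_set: Sequence[str] | None = None,
    signed_cell_corr: bool = False,
) -> TransitionSeries:
    """Compute the correlation series and transition index over a time course.

    ``nm_by_time`` maps time-point labels (in temporal order) to matrices.
    All time points are evaluated on one common gene universe: the supplied
    ``gene_set`` or the ordered intersection of gene ids across time points.
    When ``signed_cell_corr`` the denominator uses raw rather than absolute
    cell-cell coefficients.  A non-positive denominator leaves the index
    undefined (NaN) and flagged, never silently dropped.
    """
    if len(nm_by_time) < 3:
        raise CorrelationError("need at least 3 time points")
    times = list(nm_by_time)
    if gene_set is None:
        common = list(nm_by_time[times[0]].gene_ids)
        for t in times[1:]:
            present = set(nm_by_time[t].gene_ids)
            common = [g for g in common if g in present]
    else:
        common = list(gene_set)
        for t in times:
            present = set(nm_by_time[t].gene_ids)
            missing = [g for g in common if g not in present]
            if missing:
                raise CorrelationError(
                    f"gene {missing[0]!r} absent at time point {t!r}"
                )
    if len(common) < 2:
        raise CorrelationError("fewer than 2 genes shared across time points")

    rows = []
    for t in times:
        sub = nm_by_time[t].subset_genes(common)
        cell_corr, excl_cells = cell_cell_correlation(sub)
        gene_corr, excl_genes = gene_gene_correlation(sub)
        denom = mean_offdiagonal(cell_corr.to_numpy(), absolute=not signed_cell_corr)
        numer = mean_offdiagonal(gene_corr.to_numpy(), absolute=True)
        ic = numer / denom if denom > 0 else np.nan
        rows.append(
            {
                "time_point": t,
                "n_cells": sub.n_cells - len(excl_cells),
                "n_genes": len(common),
                "excluded_zero_variance_cells": len(excl_cells),
                "excluded_zero_variance_genes": len(excl_genes),
                "mean_cell_cell": denom,
                "mean_abs_gene_gene": numer,
                "ic": ic,
                "ic_defined": bool(denom > 0),
            }
        )
    frame = pd.DataFrame(rows).set_index("time_point")
    return TransitionSeries(frame, common, signed_cell_corr)


def correlation_trend_summary(series: TransitionSeries) -> dict:
    """Extremum positions and sign pattern of successive differences."""
    f = series.frame

    def _extrema(col: str, minimum: bool) -> list[str]:
        vals = f[col].dropna()
        if vals.empty or vals.nunique() == 1:
            return []
        target = vals.min() if minimum else vals.max()
        return list(vals.index[vals == target])

    def _signs(col: str) -> list[int]:
        d = np.diff(f[col].to_numpy())
        return [int(np.sign(x)) for x in d]

    flat = bool(
        f["mean_cell_cell"].nunique() == 1 and f["mean_abs_gene_gene"].nunique() == 1
    )
    return {
        "argmin_cell_cell": _extrema("mean_cell_cell", minimum=True),
        "argmax_gene_gene": _extrema("mean_abs_gene_gene", minimum=False),
        "argmax_ic": _extrema("ic", minimum=False),
        "cell_cell_diff_signs": _signs("mean_cell_cell"),
        "gene_gene_diff_signs": _signs("mean_abs_gene_gene"),
        "ic_diff_signs": _signs("ic"),
        "flat": flat,
    }
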