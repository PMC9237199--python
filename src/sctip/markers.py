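"""Wilcoxon rank-sum marker detection with detection-fraction and
fold-change pre-filters and Benjamini-Hochberg multiplicity control.

Conventions (recorded in the output): log fold changes are natural-log
values on the mean de-logged expression scale,
``ln(mean(exp(x) - 1) + 1)`` per group; the detection-fraction filter is
an OR across the two groups; BH q-values are computed over the genes
actually tested within each contrast.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

EXACT_LIMIT = 12  # exact enumeration when n_a + n_b <= this and no ties


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples (n_a + n_b <= 12);
    otherwise the normal approximation with midrank tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene detection fraction and log-mean expression for a block."""
    pct = (values > 0).mean(axis=1)
    log_mean = np.log(np.expm1(values).mean(axis=1) + 1.0)
    return pct, log_mean


def _contrast(
    nm: NormalizedMatrix,
    in_cells: np.ndarray,
    out_cells: np.ndarray,
    min_pct: float,
    logfc_threshold: float,
    q_threshold: float,
    block_logfc: float | None,
) -> pd.DataFrame:
    vin = nm.values[:, in_cells]
    vout = nm.values[:, out_cells]
    pct_in, mean_in = _group_stats(vin)
    pct_out, mean_out = _group_stats(vout)
    log_fc = mean_in - mean_out

    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (
        np.abs(log_fc) >= logfc_threshold
    )
    p = np.full(nm.n_genes, np.nan)
    for gi in np.flatnonzero(tested):
        p[gi] = rank_sum_test(vin[gi, :], vout[gi, :])
    q = np.full(nm.n_genes, np.nan)
    if tested.any():
        q[tested] = bh_qvalues(p[tested])

    passed = tested & (q < q_threshold)
    if block_logfc is not None:
        passed &= np.abs(log_fc) >= block_logfc
    return pd.DataFrame(
        {
            "gene_id": nm.gene_ids,
            "p_value": p,
            "q_value": q,
            "log_fc": log_fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "direction": np.where(log_fc > 0, "up", np.where(log_fc < 0, "down", "none")),
            "tested": tested,
            "passed_filters": passed,
        }
    )


def find_markers(
    nm: NormalizedMatrix,
    groups: Mapping[str, str] | pd.Series,
    mode: str = "one_vs_rest",
    min_pct: float = 0.2,
    logfc_threshold: float = 0.2,
    q_threshold: float = 0.05,
    block_logfc: float | None = None,
) -> pd.DataFrame:
    """Marker table over all contrasts implied by ``mode``.

    ``one_vs_rest`` contrasts every group against the pooled remainder;
    ``pairwise`` contrasts every unordered group pair.  ``block_logfc``
    adds the stricter fold-change requirement used for block comparisons
    on top of the q-value filter.
    """
    groups = pd.Series(groups)
    missing = [c for c in nm.cell_ids if c not in groups.index]
    if missing:
        raise ValueError(f"cells without group label (first: {missing[0]!r})")
    labels = groups.loc[list(nm.cell_ids)].to_numpy()
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 3]
    if not small.empty:
        raise ValueError(f"group {small.index[0]!r} has fewer than 3 cells")

    frames = []
    if mode == "one_vs_rest":
        for g in uniq:
            mask = labels == g
            tbl = _contrast(
                nm, mask, ~mask, min_pct, logfc_threshold, q_threshold, block_logfc
            )
            tbl.insert(0, "contrast", f"{g}_vs_rest")
            tbl.insert(1, "group", g)
            frames.append(tbl)
    elif mode == "pairwise":
        for i, ga in enumerate(uniq):
            for gb in uniq[i + 1:]:
                tbl = _contrast(
                    nm, labels == ga, labels == gb,
                    min_pct, logfc_threshold, q_threshold, block_logfc,
                )
                tbl.insert(0, "contrast", f"{ga}_vs_{gb}")
                tbl.insert(1, "group", ga)
                frames.append(tbl)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["logfc_convention"] = "ln(mean(expm1(x)) + 1) difference"
    return out


def select_stage_tfs(
    nm_early: NormalizedMatrix,
    nm_late: NormalizedMatrix,
    tf_genes: Sequence[str],
    p_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Split TFs into early- and late-stage sets by rank-sum p and mean.

    A TF lands in the early set when p < threshold and its mean expression
    is higher at the early stage, and vice versa; the sets are disjoint and
    TFs with indistinguishable distributions fall in neither.
    """
    tf_genes = [g for g in tf_genes]
    if not tf_genes:
        raise ValueError("no TF genes supplied")
    for g in tf_genes:
        if g not in nm_early.gene_ids or g not in nm_late.gene_ids:
            raise ValueError(f"TF {g!r} absent from one of the matrices")
    early: set[str] = set()
    late: set[str] = set()
    for g in tf_genes:
        x = nm_early.gene_vector(g)
        y = nm_late.gene_vector(g)
        if np.unique(np.concatenate([x, y])).size == 1:
            continue  # constant everywhere; no test possible
        p = rank_sum_test(x, y)
        if p >= p_threshold:
            continue
        if x.mean() > y.mean():
            early.add(g)
        elif y.mean() > x.mean():
            late.add(g)
    return early, late
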