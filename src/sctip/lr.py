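"""Ligand-receptor interaction scoring with a cluster-label permutation null.

For a pair (L, R) and an ordered (sender, receiver) cluster pair the
observed statistic is the mean of the sender-cluster mean of L and the
receiver-cluster mean of R, on natural-log normalized expression.  The
null redistributes cluster labels over cells; the p-value is the fraction
of permuted statistics at least as large as the observed one.  Pairs whose
ligand (receptor) is detected in less than ``min_frac`` of the sender
(receiver) cluster are not tested and carry p = 1.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix


class LRInputError(ValueError):
    pass


def lr_significance(
    nm: NormalizedMatrix,
    clusters: Mapping[str, str] | pd.Series,
    pairs: Sequence[tuple[str, str]],
    n_perm: int = 1000,
    seed: int | None = 0,
    min_frac: float = 0.1,
    include_self: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for every (pair, sender, receiver) combination.

    Returns a long table with columns ligand, receptor, sender, receiver,
    interaction_mean, p_value, tested.  Deterministic given ``seed``.
    """
    if n_perm <= 0:
        raise LRInputError("n_perm must be a positive integer")
    if not pairs:
        raise LRInputError("no ligand-receptor pairs supplied")
    clusters = pd.Series(clusters)
    missing_cells = [c for c in nm.cell_ids if c not in clusters.index]
    if missing_cells:
        raise LRInputError(f"cells without cluster label (first: {missing_cells[0]!r})")
    genes = []
    for lig, rec in pairs:
        for g in (lig, rec):
            if g not in nm.gene_ids:
                raise LRInputError(f"pair gene {g!r} absent from matrix")
            genes.append(g)
    genes = list(dict.fromkeys(genes))

    labels = clusters.loc[list(nm.cell_ids)].to_numpy()
    cluster_names = list(pd.unique(labels))
    if len(cluster_names) < 2:
        raise LRInputError("need at least 2 clusters")
    n_clusters = len(cluster_names)
    n_cells = nm.n_cells

    # indicator matrix for group means: (clusters x cells) / cluster sizes
    indicator = np.zeros((n_clusters, n_cells))
    for ki, name in enumerate(cluster_names):
        mask = labels == name
        indicator[ki, mask] = 1.0 / mask.sum()

    expr = nm.subset_genes(genes).values  # genes x cells
    gene_row = {g: i for i, g in enumerate(genes)}
    obs_means = indicator @ expr.T  # clusters x genes
    detect_frac = indicator @ (expr > 0).T

    rng = np.random.default_rng(seed)
    # permuting labels == permuting columns of expr under fixed indicator
    perm_means = np.empty((n_perm, n_clusters, len(genes)))
    for p in range(n_perm):
        order = rng.permutation(n_cells)
        perm_means[p] = indicator @ expr[:, order].T

    sr_pairs = [
        (s, r)
        for s in range(n_clusters)
        for r in range(n_clusters)
        if include_self or s != r
    ]
    rows = []
    for lig, rec in pairs:
        li, ri = gene_row[lig], gene_row[rec]
        for s, r in sr_pairs:
            obs = 0.5 * (obs_means[s, li] + obs_means[r, ri])
            tested = (
                detect_frac[s, li] >= min_frac and detect_frac[r, ri] >= min_frac
            )
            if tested:
                null = 0.5 * (perm_means[:, s, li] + perm_means[:, r, ri])
                p_value = float(np.mean(null >= obs))
            else:
                p_value = 1.0
            rows.append(
                {
                    "ligand": lig,
                    "receptor": rec,
                    "sender": cluster_names[s],
                    "receiver": cluster_names[r],
                    "interaction_mean": obs,
                    "p_value": p_value,
                    "tested": tested,
                }
            )
    return pd.DataFrame(rows)


def rank_and_select(
    table: pd.DataFrame, alpha: float = 0.05, top_n: int = 20
) -> pd.DataFrame:
    """Rank LR pairs by mean expression over significant cell-cluster pairs.

    Per pair: count of significant (p < alpha) cell-cluster pairs and the
    mean of their interaction means.  Pairs with no significant cell-cluster
    pair are excluded; the remainder is ranked descending and the top
    ``top_n`` retained.
    """
    sig = table[table["p_value"] < alpha]
    counts = (
        table.groupby(["ligand", "receptor"], sort=False)
        .size()
        .rename("n_cluster_pairs")
    )
    agg = (
        sig.groupby(["ligand", "receptor"], sort=False)
        .agg(
            n_significant_cell_pairs=("p_value", "size"),
            pair_mean_expression=("interaction_mean", "mean"),
        )
        .join(counts)
        .reset_index()
    )
    agg = agg[agg["n_significant_cell_pairs"] > 0].copy()
    agg = agg.sort_values(
        ["pair_mean_expression", "ligand", "receptor"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg.head(top_n).reset_index(drop=True)


def classify_delta(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    threshold: float = 0.4,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Between-condition change per LR pair over the union of top lists.

    delta = pair_mean_expression(B) - pair_mean_expression(A); a pair absent
    from one condition's list contributes 0 on that side and is flagged.
    Classes: increased (delta > +threshold), decreased (delta < -threshold),
    unchanged otherwise.
    """
    if label_a == label_b:
        raise LRInputError(f"condition labels are identical: {label_a!r}")
    key = ["ligand", "receptor"]
    a = table_a.set_index(key)["pair_mean_expression"]
    b = table_b.set_index(key)["pair_mean_expression"]
    union = a.index.union(b.index)
    rows = []
    for pair in union:
        va = float(a.get(pair, 0.0))
        vb = float(b.get(pair, 0.0))
        delta = vb - va
        if delta > threshold:
            cls = "increased"
        elif delta < -threshold:
            cls = "decreased"
        else:
            cls = "unchanged"
        rows.append(
            {
                "ligand": pair[0],
                "receptor": pair[1],
                "mean_a": va,
                "mean_b": vb,
                "delta": delta,
                "delta_class": cls,
                "missing_in_a": pair not in a.index,
                "missing_in_b": pair not in b.index,
            }
        )
    return pd.DataFrame(rows)
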