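"""Per-cell products of opposing stage-specific TF expression.

For every cross pair (one early-stage TF, one late-stage TF) the score in
a cell is the product of the two natural-log normalized expression values.
At a stable attractor one program is off, so the product sits near zero;
at a transition both programs are partially active and the product rises.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix


def tf_pair_products(
    nm_by_time: Mapping[str, NormalizedMatrix],
    early_tfs: Iterable[str],
    late_tfs: Iterable[str],
) -> pd.DataFrame:
    """Long table: one row per (time_point, early TF, late TF, cell).

    ``tf_value`` is the expression product; ``both_expressed`` and
    ``one_expressed`` support the co-expression/exclusivity fractions
    ("expressed" means normalized value > 0).
    """
    early = list(dict.fromkeys(early_tfs))
    late = list(dict.fromkeys(late_tfs))
    if not early or not late:
        raise ValueError("both TF sets must be non-empty")
    for t, nm in nm_by_time.items():
        for g in early + late:
            if g not in nm.gene_ids:
                raise ValueError(f"TF {g!r} absent from matrix at time {t!r}")

    frames = []
    for t, nm in nm_by_time.items():
        e_vals = nm.subset_genes(early).values  # len(early) x cells
        l_vals = nm.subset_genes(late).values
        for i, ge in enumerate(early):
            for j, gl in enumerate(late):
                if ge == gl:
                    continue
                x, y = e_vals[i, :], l_vals[j, :]
                frames.append(
                    pd.DataFrame(
                        {
                            "time_point": t,
                            "early_tf": ge,
                            "late_tf": gl,
                            "cell_id": nm.cell_ids,
                            "tf_value": x * y,
                            "both_expressed": (x > 0) & (y > 0),
                            "one_expressed": (x > 0) ^ (y > 0),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def pair_summaries(scores: pd.DataFrame) -> pd.DataFrame:
    """Per (time point, pair): mean product and expression fractions."""
    grp = scores.groupby(["time_point", "early_tf", "late_tf"], sort=False)
    out = grp.agg(
        mean_tf_value=("tf_value", "mean"),
        coexpression_fraction=("both_expressed", "mean"),
        exclusive_fraction=("one_expressed", "mean"),
        n_cells=("cell_id", "size"),
    ).reset_index()
    return out


def bifurcation_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point distribution summary pooled over all pairs.

    The upstream figure's exact statistic is not pinned down, so several
    candidates are reported side by side (mean, median, upper decile,
    co-expression and exclusivity fractions).
    """
    grp = scores.groupby("time_point", sort=False)
    out = grp.agg(
        mean_tf_value=("tf_value", "mean"),
        median_tf_value=("tf_value", "median"),
        upper_decile_tf_value=("tf_value", lambda v: float(np.quantile(v, 0.9))),
        coexpression_fraction=("both_expressed", "mean"),
        exclusive_fraction=("one_expressed", "mean"),
        n_values=("tf_value", "size"),
    ).reset_index()
    return out
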