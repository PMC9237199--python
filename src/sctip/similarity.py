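"""Jaccard matching of cluster signature-gene sets across datasets."""

from __future__ import annotations

from typing import Mapping, Sequence, Set

import pandas as pd


class SignatureError(ValueError):
    pass


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|a n b| / |a u b|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise SignatureError("jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def signature_sets(
    marker_table: pd.DataFrame,
    cap: int | None = 100,
    only_positive: bool = True,
) -> dict[str, set[str]]:
    """Cluster -> signature genes from a marker table.

    Identity genes are the positive (up-regulated) markers with
    ``passed_filters``, at most ``cap`` per cluster ordered by ascending
    q-value (the source figure states no cap; 100 is a configurable
    default).  Clusters with no passing genes are omitted: signature sets
    are non-empty by contract.
    """
    out: dict[str, set[str]] = {}
    for group, tbl in marker_table.groupby("group", sort=False):
        passed = tbl[tbl["passed_filters"]]
        if only_positive:
            passed = passed[passed["direction"] == "up"]
        passed = passed.sort_values(["q_value", "gene_id"], kind="mergesort")
        if cap is not None:
            passed = passed.head(cap)
        if len(passed):
            out[str(group)] = set(passed["gene_id"])
    return out


def similarity_matrix(
    sets_a: Mapping[str, Set[str]], sets_b: Mapping[str, Set[str]]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Full cross matrix of Jaccard similarities plus per-row best matches.

    Ties in a row's maximum are reported as a list, never broken silently.
    Empty sets raise, naming the offending cluster.
    """
    if not sets_a or not sets_b:
        raise SignatureError("need at least one signature set on each side")
    for side in (sets_a, sets_b):
        for name, genes in side.items():
            if not genes:
                raise SignatureError(
                    f"cluster {name!r}: signature sets must be non-empty"
                )
    rows = list(sets_a)
    cols = list(sets_b)
    mat = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for ra in rows:
        for cb in cols:
            try:
                mat.loc[ra, cb] = jaccard(sets_a[ra], sets_b[cb])
            except SignatureError as exc:
                raise SignatureError(
                    f"clusters {ra!r} vs {cb!r}: {exc}"
                ) from exc
    best: dict[str, list[str]] = {}
    for ra in rows:
        row = mat.loc[ra]
        best[ra] = list(row.index[row == row.max()])
    return mat, best
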