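import numpy as np
import pandas as pd
import pytest

from conftest import make_normalized
from sctip.matrix_io import CountMatrix, GeneAnnotation
from sctip.preprocess import (
    EmptyResultError,
    NormalizationError,
    filter_cells,
    filter_genes,
    normalize,
    rle_diagnostic,
)
from sctip.simulate import SimulationConfig, simulate_time_course


def _fixture_six_cells() -> CountMatrix:
    """6 cells, hand-computable: totals (1e3 x5, 1e9), detected genes
    (600, 600, 600, 600, 499, 600).

    log10 totals are (3, 3, 3, 3, 3, 9): mean 4, sd (ddof=1) sqrt(6) ~ 2.449,
    so the +/- 2 sd window is (-0.899, 8.899).  Cell 5 fails the 500-gene
    floor; cell 6 (log10 total = 9) is the only UMI outlier.
    """
    n_genes = 1000
    values = np.zeros((n_genes, 6), dtype=np.int64)
    for col in (0, 1, 2, 3, 5):
        values[:400, col] = 1
        values[400:600, col] = 3  # 400 + 600 = 1000 total, 600 detected
    values[:498, 4] = 1
    values[498, 4] = 502  # 499 detected genes, total 1000
    values[:599, 5] = 1
    values[600:, 5] = 0
    values[599, 5] = 10**9 - 599  # one huge gene; detected stays at 600
    genes = [f"g{i:04d}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(6)]
    return CountMatrix(values, genes, cells)


class TestFilterCells:
    def test_hand_computed_fixture(self):
        cm = _fixture_six_cells()
        assert list(cm.genes_detected_per_cell()) == [600, 600, 600, 600, 499, 600]
        assert list(cm.cell_totals())[:5] == [1000] * 5
        out, report = filter_cells(cm, min_genes=500, umi_sd=2.0)
        assert out.cell_ids == ["c0", "c1", "c2", "c3"]
        assert report.removed["low_gene_cell"] == ["c4"]
        assert report.removed["umi_outlier_cell"] == ["c5"]
        assert report.n_in - sum(report.removal_counts().values()) == report.n_out

    def test_exactly_500_detected_genes_kept(self):
        values = np.zeros((600, 3), dtype=np.int64)
        values[:500, 0] = 1
        values[:500, 1] = 1
        values[:500, 2] = 1
        cm = CountMatrix(values, [f"g{i}" for i in range(600)], ["a", "b", "c"])
        out, _ = filter_cells(cm, min_genes=500)
        assert out.n_cells == 3

    def test_identical_cells_none_removed(self):
        values = np.ones((600, 5), dtype=np.int64)
        cm = CountMatrix(values, [f"g{i}" for i in range(600)], list("abcde"))
        out, report = filter_cells(cm, min_genes=500)
        assert out.n_cells == 5
        assert sum(report.removal_counts().values()) == 0

    def test_all_removed_raises(self):
        cm = CountMatrix(np.ones((3, 2), dtype=np.int64), ["a", "b", "c"], ["x", "y"])
        with pytest.raises(EmptyResultError):
            filter_cells(cm, min_genes=500)

    def test_criteria_evaluated_on_input_matrix(self):
        # the outlier bounds include the removed low-gene cell's total
        cm = _fixture_six_cells()
        out, report = filter_cells(cm, min_genes=500, umi_sd=2.0)
        # with c5's 1e9 excluded from the stats, c5 itself could not be an
        # outlier; its removal proves stats were computed pre-removal
        assert "c5" in report.removed["umi_outlier_cell"]


class TestFilterGenes:
    def test_prevalence_boundary_inclusive(self):
        values = np.zeros((2, 12), dtype=np.int64)
        values[0, :9] = 1   # detected in 9 cells -> removed
        values[1, :10] = 1  # detected in 10 cells -> kept
        cm = CountMatrix(values, ["g9", "g10"], [f"c{i}" for i in range(12)])
        out, report = filter_genes(cm, min_cells=10)
        assert out.gene_ids == ["g10"]
        assert report.removed["low_cell_gene"] == ["g9"]

    def test_all_flagged_mito_removed_regardless_of_prevalence(self):
        values = np.ones((3, 15), dtype=np.int64)
        cm = CountMatrix(values, ["mito1", "mito2", "keep"], [f"c{i}" for i in range(15)])
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["mito1", "mito2", "keep"],
                    "is_mitochondrial": [True, True, False],
                }
            )
        )
        out, report = filter_genes(cm, ann, min_cells=10)
        assert out.gene_ids == ["keep"]
        assert sorted(report.removed["mito_gene"]) == ["mito1", "mito2"]

    def test_prefix_fallback_without_annotation(self):
        values = np.ones((2, 15), dtype=np.int64)
        cm = CountMatrix(values, ["mt-Nd1", "Actb"], [f"c{i}" for i in range(15)])
        out, _ = filter_genes(cm, None, min_cells=10)
        assert out.gene_ids == ["Actb"]

    def test_matches_brute_force_two_pass_oracle(self, rng):
        values = rng.negative_binomial(1, 0.5, size=(80, 40))
        genes = [f"g{i}" for i in range(78)] + ["mt-a", "mt-b"]
        cm = CountMatrix(values, genes, [f"c{i}" for i in range(40)])
        out, _ = filter_genes(cm, None, min_cells=10)
        expected = [
            g
            for gi, g in enumerate(genes)
            if (values[gi] > 0).sum() >= 10 and not g.startswith("mt-")
        ]
        assert out.gene_ids == expected


class TestNormalize:
    def test_single_gene_closed_form(self):
        cm = CountMatrix(np.array([[10]]), ["g"], ["c"])
        nm = normalize(cm)
        assert nm.values[0, 0] == pytest.approx(np.log(10001.0), abs=1e-9)

    def test_zero_count_maps_to_zero(self):
        cm = CountMatrix(np.array([[0], [5]]), ["g1", "g2"], ["c"])
        nm = normalize(cm)
        assert nm.values[0, 0] == 0.0

    def test_per_cell_invariant(self, small_counts):
        nm = normalize(small_counts)
        sums = np.expm1(nm.values).sum(axis=0)
        np.testing.assert_allclose(sums, 10_000.0, atol=1e-6)

    def test_monotone_and_zero_preserving(self, small_counts):
        nm = normalize(small_counts)
        col = 0
        counts = small_counts.values[:, col]
        vals = nm.values[:, col]
        order = np.argsort(counts, kind="mergesort")
        assert np.all(np.diff(vals[order]) >= 0)
        np.testing.assert_array_equal(vals == 0, counts == 0)

    def test_zero_total_cell_rejected(self):
        cm = CountMatrix(np.array([[1, 0]]), ["g"], ["c1", "c2"])
        with pytest.raises(NormalizationError, match="filter_cells"):
            normalize(cm)


class TestFilterOrderContract:
    def test_cells_then_genes(self):
        # a gene present only in a to-be-removed cell drops below prevalence
        values = np.zeros((600, 12), dtype=np.int64)
        values[:550, :] = 1  # all cells pass min_genes=500
        marker = 599
        values[marker, :] = 0
        values[marker, 0] = 1  # detected in 1 cell
        values[:, 11] = 0
        values[:499, 11] = 1  # cell 11 fails the gene floor
        cm = CountMatrix(
            values, [f"g{i}" for i in range(600)], [f"c{i}" for i in range(12)]
        )
        out_cells, _ = filter_cells(cm, min_genes=500)
        assert out_cells.n_cells == 11
        out, report = filter_genes(out_cells, None, min_cells=10)
        assert f"g{marker}" in report.removed["low_cell_gene"]

    def test_synthetic_default_qc_non_destructive(self):
        removed = []
        for seed in range(5):
            cm, _, genes, _ = simulate_time_course(SimulationConfig(seed=seed))
            out, _ = filter_cells(cm, min_genes=cm.n_genes // 2)
            removed.append(1 - out.n_cells / cm.n_cells)
            out2, gene_report = filter_genes(out, genes)
            assert gene_report.removal_counts() == {
                "low_cell_gene": 0,
                "mito_gene": 37,
            }
        assert np.mean(removed) < 0.05


class TestRLE:
    def _nm(self):
        cm, cells, genes, _ = simulate_time_course(
            SimulationConfig(seed=1, cells_per_time=100)
        )
        return normalize(cm), cells, genes

    def test_value_zero_when_equal_to_median(self):
        # 3 hk genes, 3 identical cells: every RLE value is 0
        vals = np.log1p(np.array([[5.0, 5, 5], [7, 7, 7], [2, 2, 2]]))
        nm = make_normalized(vals)
        samples = pd.Series(["s1", "s1", "s2"], index=nm.cell_ids)
        out = rle_diagnostic(nm, nm.gene_ids, samples)
        assert np.allclose(out["median_rle"], 0.0)
        assert np.allclose(out["iqr_rle"], 0.0)

    def test_doubling_gives_plus_one(self):
        base = np.array([[5.0, 5, 5, 5, 10]])  # last cell doubled, median 5
        vals = np.log1p(np.vstack([base, base * 0 + np.expm1(1.0)]))
        nm = make_normalized(vals)
        samples = pd.Series(["a"] * 4 + ["b"], index=nm.cell_ids)
        out = rle_diagnostic(nm, nm.gene_ids, samples).set_index("sample")
        # sample b pools gene-1 RLE (+1) and constant gene-2 RLE (0)
        assert out.loc["b", "median_rle"] == pytest.approx(0.5)

    def test_null_simulation_median_near_zero(self):
        nm, cells, genes = self._nm()
        samples = cells.column("time_point")
        out = rle_diagnostic(nm, genes.flagged("is_housekeeping"), samples)
        assert np.all(np.abs(out["median_rle"]) <= 0.1)

    def test_requires_two_housekeeping_genes(self):
        nm = make_normalized(np.ones((3, 4)))
        with pytest.raises(ValueError, match="housekeeping"):
            rle_diagnostic(nm, ["g0"], pd.Series(["s"] * 4, index=nm.cell_ids))

    def test_zero_median_gene_warns(self):
        vals = np.log1p(
            np.array([[5.0, 5, 5, 5], [0, 0, 0, 3], [4, 4, 4, 4]])
        )
        nm = make_normalized(vals)
        samples = pd.Series(["s"] * 4, index=nm.cell_ids)
        with pytest.warns(UserWarning, match="zero median"):
            rle_diagnostic(nm, nm.gene_ids, samples)
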