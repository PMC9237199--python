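import numpy as np
import pandas as pd
import pytest

from conftest import make_normalized, pair_mean_oracle, pearson_oracle
from sctip.preprocess import filter_cells, filter_genes, normalize
from sctip.simulate import SimulationConfig, simulate_time_course
from sctip.transition import (
    CorrelationError,
    cell_cell_correlation,
    correlation_trend_summary,
    gene_gene_correlation,
    mean_offdiagonal,
    transition_index,
)


def _nm_by_time(seed: int, cells_per_time: int = 200):
    cm, cells, genes, truth = simulate_time_course(
        SimulationConfig(seed=seed, cells_per_time=cells_per_time)
    )
    cm, _ = filter_cells(cm, min_genes=cm.n_genes // 2)
    cm, _ = filter_genes(cm, genes)
    nm = normalize(cm)
    tp = cells.column("time_point")
    return {
        t: nm.subset_cells([c for c in nm.cell_ids if tp[c] == t])
        for t in cells.time_levels
    }, truth


class TestCellCellCorrelation:
    def test_collinear_cells_all_one(self, collinear_nm):
        corr, excluded = cell_cell_correlation(collinear_nm)
        assert excluded == []
        np.testing.assert_allclose(corr.to_numpy(), 1.0, atol=1e-12)

    def test_reversed_cell_is_minus_one(self):
        nm = make_normalized(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        corr, _ = cell_cell_correlation(nm)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        vals = rng.normal(size=(20, 30))  # 20 genes x 30 cells
        nm = make_normalized(vals)
        corr, _ = cell_cell_correlation(nm)
        for i in range(30):
            for j in range(i + 1, 30):
                assert corr.iloc[i, j] == pytest.approx(
                    pearson_oracle(vals[:, i], vals[:, j]), abs=1e-10
                )

    def test_zero_variance_cell_excluded_and_reported(self, rng):
        vals = rng.normal(size=(5, 4))
        vals[:, 2] = 7.0
        nm = make_normalized(vals)
        corr, excluded = cell_cell_correlation(nm)
        assert excluded == ["c2"]
        assert list(corr.index) == ["c0", "c1", "c3"]

    def test_too_few_cells(self):
        nm = make_normalized(np.ones((3, 1)))
        with pytest.raises(CorrelationError):
            cell_cell_correlation(nm)


class TestGeneGeneCorrelation:
    def test_proportional_genes(self, collinear_nm):
        corr, _ = gene_gene_correlation(collinear_nm)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_genes_mean_abs_small(self, rng):
        vals = rng.normal(size=(30, 1000))
        nm = make_normalized(vals)
        corr, _ = gene_gene_correlation(nm)
        assert mean_offdiagonal(corr.to_numpy(), absolute=True) <= 0.05

    def test_matches_double_loop_oracle(self, rng):
        vals = rng.normal(size=(15, 25))
        nm = make_normalized(vals)
        corr, _ = gene_gene_correlation(nm)
        for i in range(15):
            for j in range(i + 1, 15):
                assert corr.iloc[i, j] == pytest.approx(
                    pearson_oracle(vals[i], vals[j]), abs=1e-10
                )


class TestTransitionIndex:
    def test_collinear_fixture_exact(self, collinear_nm):
        nm_by_time = {"t0": collinear_nm, "t1": collinear_nm, "t2": collinear_nm}
        series = transition_index(nm_by_time)
        row = series.frame.loc["t0"]
        assert row["mean_abs_gene_gene"] == 1.0
        assert row["mean_cell_cell"] == 1.0
        assert row["ic"] == 1.0

    def test_matches_oracle_random_matrices(self, rng):
        nm_by_time = {
            f"t{k}": make_normalized(rng.normal(size=(15, 20))) for k in range(3)
        }
        series = transition_index(nm_by_time)
        for t, nm in nm_by_time.items():
            num = pair_mean_oracle(nm.values, absolute=True)
            den = pair_mean_oracle(nm.values.T, absolute=True)
            assert series.frame.loc[t, "mean_abs_gene_gene"] == pytest.approx(num, abs=1e-10)
            assert series.frame.loc[t, "mean_cell_cell"] == pytest.approx(den, abs=1e-10)
            assert series.frame.loc[t, "ic"] == pytest.approx(num / den, abs=1e-10)

    def test_signed_denominator_switch(self, rng):
        nm_by_time = {
            f"t{k}": make_normalized(rng.normal(size=(10, 12))) for k in range(3)
        }
        signed = transition_index(nm_by_time, signed_cell_corr=True)
        for t, nm in nm_by_time.items():
            den = pair_mean_oracle(nm.values.T, absolute=False)
            assert signed.frame.loc[t, "mean_cell_cell"] == pytest.approx(den, abs=1e-10)

    def test_needs_three_time_points(self, collinear_nm):
        with pytest.raises(CorrelationError, match="3 time points"):
            transition_index({"a": collinear_nm, "b": collinear_nm})

    def test_common_gene_universe(self, rng):
        full = make_normalized(rng.normal(size=(10, 8)))
        partial = full.subset_genes(full.gene_ids[:7])
        series = transition_index({"a": full, "b": partial, "c": full})
        assert series.gene_ids == full.gene_ids[:7]
        assert (series.frame["n_genes"] == 7).all()

    def test_missing_gene_in_supplied_set(self, rng):
        nm = make_normalized(rng.normal(size=(5, 6)))
        with pytest.raises(CorrelationError, match="absent"):
            transition_index({"a": nm, "b": nm, "c": nm}, gene_set=["nope"])

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=(12, 15))
        nm = make_normalized(vals)
        shuffled_cells = list(rng.permutation(nm.cell_ids))
        shuffled_genes = list(rng.permutation(nm.gene_ids))
        nm_shuf = nm.subset_cells(shuffled_cells).subset_genes(shuffled_genes)
        a = transition_index({"x": nm, "y": nm, "z": nm})
        b = transition_index(
            {"x": nm_shuf, "y": nm_shuf, "z": nm_shuf}, gene_set=shuffled_genes
        )
        for col in ("mean_cell_cell", "mean_abs_gene_gene", "ic"):
            assert a.frame[col].to_numpy() == pytest.approx(
                b.frame[col].to_numpy(), abs=1e-12
            )

    def test_gene_scale_invariance(self, rng):
        # rescaling one gene leaves the gene-gene Pearson matrix unchanged
        # (cell profiles, and hence cell-cell correlations, do change)
        vals = rng.normal(size=(12, 15))
        scaled = vals.copy()
        scaled[3, :] *= 17.0
        a, _ = gene_gene_correlation(make_normalized(vals))
        b, _ = gene_gene_correlation(make_normalized(scaled))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_undefined_ic_flagged_not_dropped(self, rng):
        # anti-correlated cell pairs: signed denominator is negative
        vals = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        nm = make_normalized(vals)
        series = transition_index(
            {"a": nm, "b": nm, "c": nm}, signed_cell_corr=True
        )
        assert not series.frame["ic_defined"].any()
        assert series.frame["ic"].isna().all()
        assert list(series.frame.index) == ["a", "b", "c"]

    def test_synthetic_recovery_single_seed(self):
        nm_by_time, truth = _nm_by_time(seed=0)
        series = transition_index(nm_by_time)
        assert series.argmax_ic() == [f"T{truth.transition_index}"]


class TestTrendSummary:
    def test_worked_example(self):
        cc = [0.8, 0.5, 0.3, 0.6, 0.9]
        gg = [0.1, 0.2, 0.4, 0.3, 0.2]
        frame = pd.DataFrame(
            {
                "mean_cell_cell": cc,
                "mean_abs_gene_gene": gg,
                "ic": np.array(gg) / np.array(cc),
            },
            index=[f"t{i}" for i in range(5)],
        )
        from sctip.transition import TransitionSeries

        trend = correlation_trend_summary(TransitionSeries(frame, ["g"]))
        assert trend["argmin_cell_cell"] == ["t2"]
        assert trend["argmax_ic"] == ["t2"]
        assert trend["cell_cell_diff_signs"] == [-1, -1, 1, 1]

    def test_constant_series_flat(self):
        frame = pd.DataFrame(
            {
                "mean_cell_cell": [0.5] * 4,
                "mean_abs_gene_gene": [0.2] * 4,
                "ic": [0.4] * 4,
            },
            index=list("abcd"),
        )
        from sctip.transition import TransitionSeries

        trend = correlation_trend_summary(TransitionSeries(frame, ["g"]))
        assert trend["flat"]
        assert trend["argmin_cell_cell"] == []
        assert trend["argmax_ic"] == []


class TestSubsamplingStability:
    def test_half_cell_ic_correlates_with_full(self):
        cors = []
        for seed in range(10):
            nm_by_time, _ = _nm_by_time(seed=seed, cells_per_time=100)
            full = transition_index(nm_by_time).frame["ic"].to_numpy()
            rng = np.random.default_rng(seed + 1000)
            halves = {}
            for t, nm in nm_by_time.items():
                ids = list(rng.permutation(nm.cell_ids)[: nm.n_cells // 2])
                halves[t] = nm.subset_cells(ids)
            half = transition_index(halves).frame["ic"].to_numpy()
            cors.append(np.corrcoef(full, half)[0, 1])
        assert np.mean(cors) > 0.9
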