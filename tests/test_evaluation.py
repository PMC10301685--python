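import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathdrp.dataset import ResponseTable
from pathdrp.evaluation import (
    downsampling_experiment,
    improvement_vs_naive,
    paired_wilcoxon,
    per_ccl_metrics,
    percent_improvement,
    response_specificity,
)
from pathdrp.pathways import PathwayCollection
from pathdrp.prediction import make_prediction_table


class TestPerCCLMetrics:
    def test_monotone_predictions_have_perfect_rank_metrics(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        preds = make_prediction_table(
            [("c1", f"d{i}") for i in range(4)], y, np.exp(y)
        )
        row = per_ccl_metrics(preds).table.loc["c1"]
        assert row["scc"] == pytest.approx(1.0)
        assert row["c_index"] == pytest.approx(1.0)

    def test_constant_predictions_undefined_scc(self):
        preds = make_prediction_table(
            [("c1", f"d{i}") for i in range(4)],
            np.arange(4.0),
            np.full(4, 2.0),
        )
        row = per_ccl_metrics(preds).table.loc["c1"]
        assert np.isnan(row["scc"]) and np.isnan(row["pcc"])
        assert row["rmse"] == pytest.approx(np.sqrt(np.mean((np.arange(4.0) - 2) ** 2)))

    def test_matches_reference_implementations(self, random_prediction_table):
        """SCC/PCC/RMSE/MSE/R2/c-index agree with scipy/sklearn/lifelines
        to 1e-12 on random tables."""
        from lifelines.utils import concordance_index
        from sklearn.metrics import mean_squared_error, r2_score

        for seed in range(50):
            preds = random_prediction_table(seed)
            result = per_ccl_metrics(preds).table
            for cell, grp in preds.groupby("cellline_id"):
                yt = grp["y_true"].to_numpy()
                yp = grp["y_pred"].to_numpy()
                row = result.loc[cell]
                assert row["scc"] == pytest.approx(
                    stats.spearmanr(yt, yp).statistic, abs=1e-12)
                assert row["pcc"] == pytest.approx(
                    stats.pearsonr(yt, yp).statistic, abs=1e-12)
                assert row["mse"] == pytest.approx(
                    mean_squared_error(yt, yp), abs=1e-12)
                assert row["r2"] == pytest.approx(r2_score(yt, yp), abs=1e-12)
                assert row["c_index"] == pytest.approx(
                    concordance_index(yt, yp), abs=1e-12)

    def test_aggregates_exclude_and_count_undefined(self):
        rows = (
            [("c1", f"d{i}", float(i), float(i)) for i in range(3)]
            + [("c2", f"d{i}", float(i), 5.0) for i in range(3)]
        )
        preds = pd.DataFrame(rows, columns=["cellline_id", "drug_id", "y_true", "y_pred"])
        m = per_ccl_metrics(preds)
        assert m.aggregates.loc["scc", "n_defined"] == 1
        assert m.aggregates.loc["scc", "n_undefined"] == 1
        assert m.aggregates.loc["rmse", "n_defined"] == 2


class TestImprovement:
    def table(self, sccs, rmses):
        return pd.DataFrame(
            {"scc": sccs, "rmse": rmses, "pcc": sccs, "mse": rmses,
             "r2": sccs, "c_index": sccs, "n_pairs": 5},
            index=[f"c{i}" for i in range(len(sccs))],
        )

    def wrap(self, df):
        from pathdrp.evaluation import PerCCLMetrics

        return PerCCLMetrics(df)

    def test_identical_models_zero_delta(self):
        m = self.wrap(self.table([0.5, 0.6], [1.0, 2.0]))
        delta = improvement_vs_naive(m, m)
        assert (delta == 0).all().all()

    def test_sign_convention(self):
        model = self.wrap(self.table([0.7], [1.0]))
        naive = self.wrap(self.table([0.5], [1.5]))
        delta = improvement_vs_naive(model, naive)
        assert delta["delta_scc"].iloc[0] == pytest.approx(0.2)
        assert delta["delta_rmse"].iloc[0] == pytest.approx(0.5)  # lower rmse = +

    def test_undefined_propagates(self):
        model = self.wrap(self.table([0.7], [1.0]))
        naive = self.wrap(self.table([np.nan], [1.5]))
        delta = improvement_vs_naive(model, naive)
        assert np.isnan(delta["delta_scc"].iloc[0])
        assert delta["delta_rmse"].notna().all()

    def test_disjoint_cells_rejected(self):
        a = self.wrap(self.table([0.7], [1.0]))
        b = self.wrap(self.table([0.5, 0.6], [1.0, 1.0]))
        with pytest.raises(ValueError):
            improvement_vs_naive(a, b)


def enumeration_oracle(d):
    """Two-sided signed-rank p by exhaustive sign-flip enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_equal_vectors_p_one(self):
        res = paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.all_zero

    def test_unit_shift_minimal_p(self):
        a = np.arange(10.0)
        res = paired_wilcoxon(a + 1, a)
        assert res.p_value == pytest.approx(2 * (1 / 2**10))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = paired_wilcoxon(a, b)
            assert res.p_value == pytest.approx(enumeration_oracle(a - b), abs=1e-12)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert paired_wilcoxon(a, b).p_value == paired_wilcoxon(b, a).p_value

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 20))
            d = rng.normal(size=n)
            res = paired_wilcoxon(d, np.zeros(n))
            ref = stats.wilcoxon(d, mode="exact", alternative="two-sided").pvalue
            assert res.p_value == pytest.approx(ref, abs=1e-10)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, size=60)
        res = paired_wilcoxon(d, np.zeros(60))
        ref = stats.wilcoxon(
            d, mode="approx", alternative="two-sided", correction=False
        ).pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-6)

    def test_nan_pairs_dropped(self):
        res = paired_wilcoxon([1.0, np.nan, 3.0], [0.5, 1.0, 2.0])
        assert res.n_used == 2


class TestPercentImprovement:
    def test_equal_is_zero(self):
        assert percent_improvement(0.5, [0.5, 0.5]) == 0.0

    def test_scc_formula(self):
        assert percent_improvement(0.55, [0.5]) == pytest.approx(10.0)

    def test_rmse_sign_convention(self):
        # lower real RMSE than random mean -> positive improvement
        assert percent_improvement(0.9, [1.0], metric="rmse") == pytest.approx(10.0)

    def test_zero_random_mean_flagged(self):
        assert np.isnan(percent_improvement(0.5, [0.0]))

    def test_antisymmetry_single_replicate(self):
        # swapping real and the (single) random value flips the sign; the
        # magnitudes differ only through the denominator convention
        f = percent_improvement(0.6, [0.5])
        g = percent_improvement(0.5, [0.6])
        assert f > 0 > g
        assert f * 0.5 == pytest.approx(-g * 0.6)

    def test_replicate_mean_matches_recompute(self):
        rng = np.random.default_rng(0)
        randoms = rng.uniform(0.3, 0.6, size=20)
        val = percent_improvement(0.55, randoms)
        assert val == pytest.approx(100 * (0.55 - randoms.mean()) / abs(randoms.mean()))


class TestDownsampling:
    def collection(self):
        genes = tuple(f"g{i}" for i in range(30))
        return PathwayCollection(
            "c",
            tuple((f"P{i}", frozenset(genes[3 * i : 3 * i + 3])) for i in range(10)),
            genes,
        )

    def test_row_count_and_level_sizes(self):
        calls = []

        def evaluate(coll, seed):
            calls.append(coll.m)
            return float(coll.m)

        table = downsampling_experiment(
            self.collection(), evaluate, [0, 5], n_repeats=3
        )
        assert len(table) == 2
        assert table["n_pathways"].tolist() == [10, 5]
        assert table["mean"].tolist() == [10.0, 5.0]

    def test_failures_recorded_not_fatal(self):
        def evaluate(coll, seed):
            if seed % 2:
                raise RuntimeError("boom")
            return 1.0

        table = downsampling_experiment(
            self.collection(), evaluate, [1], n_repeats=4
        )
        assert table["n_failed"].iloc[0] + table["n_ok"].iloc[0] == 4
        assert table["n_failed"].iloc[0] > 0


class TestSpecificity:
    def make_responses(self, drug_sd, cell_sd, seed=0, n_drugs=12, n_cells=15):
        rng = np.random.default_rng(seed)
        b = rng.normal(scale=drug_sd, size=n_drugs)
        g = rng.normal(scale=cell_sd, size=n_cells)
        rows = [
            (f"c{i}", f"d{j}", g[i] + b[j] + rng.normal(scale=0.5))
            for i in range(n_cells)
            for j in range(n_drugs)
        ]
        return ResponseTable(
            pd.DataFrame(rows, columns=["cellline_id", "drug_id", "value"])
        )

    def test_drug_dominant_asymmetry(self):
        res = response_specificity(self.make_responses(drug_sd=3.0, cell_sd=0.2))
        assert res["drugs"]["fraction_significant"] > res["celllines"]["fraction_significant"]
        assert res["drugs"]["fraction_significant"] > 0.5

    def test_single_shifted_drug_detected(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"c{i}", f"d{j}", float(rng.normal()) + (10.0 if j == 0 else 0.0))
            for i in range(10)
            for j in range(6)
        ]
        table = ResponseTable(
            pd.DataFrame(rows, columns=["cellline_id", "drug_id", "value"])
        )
        res = response_specificity(table)
        assert res["drugs"]["fdr"]["d0"] < 0.05

    def test_requires_two_of_each(self):
        rows = [("c1", "d1", 1.0), ("c2", "d1", 2.0)]
        table = ResponseTable(
            pd.DataFrame(rows, columns=["cellline_id", "drug_id", "value"])
        )
        with pytest.raises(ValueError):
            response_specificity(table)
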