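from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest

from eegsel.cffs import CliqueSet, train_candidates
from eegsel.features import FeatureTable
from eegsel.shapley import (
    ImportanceTable,
    ShapleyError,
    aggregate_importance,
    exact_shapley,
    importance_breakdowns,
    shapley_for_record,
    summary_plot_data,
)
from conftest import make_random_table


def shapley_oracle(predict, x, background):
    """Textbook Shapley: explicit sum over subsets, one v(S) at a time."""
    n = len(x)
    players = list(range(n))

    def v(S):
        rows = np.tile(background, (1, 1)).astype(float).copy()
        for j in S:
            rows[:, j] = x[j]
        return float(np.mean(predict(rows)))

    phi = np.zeros(n)
    for i in players:
        for k in range(n):
            for S in combinations([p for p in players if p != i], k):
                w = factorial(len(S)) * factorial(n - len(S) - 1) / factorial(n)
                phi[i] += w * (v(set(S) | {i}) - v(set(S)))
    return phi, v(set())


class TestExactShapley:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(0)
        w = np.array([1.5, -2.0, 0.5, 3.0])
        b = 0.7
        predict = lambda rows: rows @ w + b
        x = rng.standard_normal(4)
        bg = rng.standard_normal((20, 4))
        phi, base = exact_shapley(predict, x, bg)
        assert np.allclose(phi, w * (x - bg.mean(axis=0)), atol=1e-6)
        assert base == pytest.approx(float(bg.mean(axis=0) @ w + b), abs=1e-12)

    def test_efficiency_identity(self):
        rng = np.random.default_rng(1)
        predict = lambda rows: np.tanh(rows @ [1.0, -1.0, 2.0]) + rows[:, 0] ** 2
        x = rng.standard_normal(3)
        bg = rng.standard_normal((10, 3))
        phi, base = exact_shapley(predict, x, bg)
        assert phi.sum() + base == pytest.approx(float(predict(x[None, :])[0]), abs=1e-9)

    def test_constant_predictor_all_zero(self):
        phi, base = exact_shapley(lambda rows: np.full(len(rows), 0.3),
                                  np.zeros(5), np.ones((4, 5)))
        assert np.allclose(phi, 0.0)
        assert base == pytest.approx(0.3)

    def test_symmetry_of_duplicated_features(self):
        # predictor symmetric in features 0 and 1; x and background symmetric too
        predict = lambda rows: rows[:, 0] * rows[:, 1] + rows[:, 0] + rows[:, 1]
        x = np.array([2.0, 2.0, 5.0])
        rng = np.random.default_rng(2)
        z = rng.standard_normal((8, 1))
        bg = np.hstack([z, z, rng.standard_normal((8, 1))])
        phi, _ = exact_shapley(predict, x, bg)
        assert phi[0] == pytest.approx(phi[1], abs=1e-10)

    def test_dummy_feature_zero(self):
        predict = lambda rows: rows[:, 0] * 2.0  # feature 1 never used
        rng = np.random.default_rng(3)
        phi, _ = exact_shapley(predict, rng.standard_normal(2), rng.standard_normal((6, 2)))
        assert phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_subset_sum_oracle(self):
        rng = np.random.default_rng(4)
        predict = lambda rows: 1.0 / (1.0 + np.exp(-(rows @ [0.8, -1.2, 0.4] + 0.1)))
        x = rng.standard_normal(3)
        bg = rng.standard_normal((7, 3))
        phi, base = exact_shapley(predict, x, bg)
        phi_o, base_o = shapley_oracle(predict, x, bg)
        assert np.allclose(phi, phi_o, atol=1e-12)
        assert base == pytest.approx(base_o, abs=1e-12)

    def test_empty_background_rejected(self):
        with pytest.raises(ShapleyError):
            exact_shapley(lambda r: r[:, 0], np.zeros(2), np.zeros((0, 2)))


@pytest.fixture(scope="module")
def trained_record():
    table = make_random_table(n_subjects=18, n_features=5, n_informative=2, seed=0)
    cs = CliqueSet((("feat00", "feat01", "feat02"),), 3, 9)
    recs = train_candidates(table, cs, positive_class="B", algorithms=("LR",), seed=0)
    return table, recs[0]


class TestShapleyForRecord:
    def test_every_subject_explained_with_efficiency(self, trained_record):
        table, record = trained_record
        record = shapley_for_record(record, table)
        assert record.shapley.shape == (18, 3)
        cols = [table.data.columns.get_loc(f) for f in record.feature_set]
        X = table.data.to_numpy()[:, cols]
        for s in range(18):
            model = record.fold_models[record.fold_assignment[s]]
            pos = list(model.classes_).index(1)
            pred = model.predict_proba(X[s][None, :])[0, pos]
            assert record.shapley[s].sum() + record.base_values[s] == pytest.approx(
                pred, abs=1e-6
            )

    def test_matches_oracle_on_lr_record(self, trained_record):
        table, record = trained_record
        record = shapley_for_record(record, table)
        cols = [table.data.columns.get_loc(f) for f in record.feature_set]
        X = table.data.to_numpy()[:, cols]
        s = 0
        f = record.fold_assignment[s]
        model = record.fold_models[f]
        pos = list(model.classes_).index(1)
        bg = X[record.fold_assignment != f]
        phi_o, base_o = shapley_oracle(
            lambda rows: model.predict_proba(rows)[:, pos], X[s], bg
        )
        assert np.allclose(record.shapley[s], phi_o, atol=1e-10)
        assert record.base_values[s] == pytest.approx(base_o, abs=1e-10)


class TestAggregation:
    def _fake_record(self, features, phi, alg="LR"):
        from eegsel.cffs import ModelRecord

        n = phi.shape[0]
        return ModelRecord(
            algorithm=alg, feature_set=tuple(features),
            fold_assignment=np.zeros(n, int), pooled_accuracy=0.9,
            per_subject_prediction=np.zeros(n), shapley=phi,
            base_values=np.zeros(n),
        )

    def test_single_model_single_feature(self):
        r = self._fake_record(["PSD_CP5_44-46_mean"], np.array([[0.2], [-0.4]]))
        imp = aggregate_importance([r])
        assert imp.scores["PSD_CP5_44-46_mean"] == 1.0

    def test_scores_sum_to_one_and_weighting(self):
        rng = np.random.default_rng(0)
        r1 = self._fake_record(["a_Cz_mean", "b_Cz_mean"], rng.standard_normal((4, 2)))
        r2 = self._fake_record(["a_Cz_mean", "c_Cz_mean"], rng.standard_normal((4, 2)))
        imp = aggregate_importance([r1, r2])
        assert imp.scores.sum() == pytest.approx(1.0, abs=1e-12)
        # 'a' appears in both models: its raw score is the sum of both means
        raw_a = abs(r1.shapley[:, 0]).mean() + abs(r2.shapley[:, 0]).mean()
        raw_all = raw_a + abs(r1.shapley[:, 1]).mean() + abs(r2.shapley[:, 1]).mean()
        assert imp.scores["a_Cz_mean"] == pytest.approx(raw_a / raw_all)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        rs = [
            self._fake_record([f"m{i}_Cz_mean", "shared_Cz_mean"], rng.standard_normal((3, 2)))
            for i in range(4)
        ]
        a = aggregate_importance(rs).scores
        b = aggregate_importance(rs[::-1]).scores
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_summary_plot_data_consistent_with_importance(self, trained_record):
        table, record = trained_record
        record = shapley_for_record(record, table)
        pts = summary_plot_data([record], table)
        assert set(pts["feature"]) == set(record.feature_set)
        assert len(pts) == 3 * 18
        # per-feature mean |shapley| ranking equals the importance ranking
        imp = aggregate_importance([record])
        rank_pts = (
            pts.groupby("feature")["shapley"].apply(lambda s: s.abs().mean())
            .sort_values(ascending=False).index.tolist()
        )
        # single model: same ordering up to ties
        assert rank_pts[0] == imp.scores.index[0]


class TestBreakdowns:
    def test_partitions_sum_to_total(self):
        scores = pd.Series(
            {"PSD_CP5_44-46_mean": 0.5, "LZC_T7_upper_qrt": 0.3, "MS_0_coverage": 0.2}
        )
        bd = importance_breakdowns(ImportanceTable(scores))
        for key in ("by_type", "by_frequency", "by_channel"):
            assert bd[key].sum() == pytest.approx(1.0, abs=1e-9)
        assert bd["by_type"]["PSD"] == pytest.approx(0.5)
        assert bd["by_type"]["microstate"] == pytest.approx(0.2)
        assert bd["by_frequency"]["44-46"] == pytest.approx(0.5)
        assert bd["by_channel"]["CP5"] == pytest.approx(0.5)

    def test_all_mass_on_one_channel(self):
        scores = pd.Series({"PSD_CP5_44-46_mean": 0.6, "PSD_CP5_30-32_std": 0.4})
        bd = importance_breakdowns(ImportanceTable(scores))
        assert bd["by_channel"].to_dict() == pytest.approx({"CP5": 1.0})

    def test_unparseable_name_rejected(self):
        with pytest.raises(Exception):
            importance_breakdowns(ImportanceTable(pd.Series({"???": 1.0})))


def test_plots_render_to_files(tmp_path, trained_record):
    from eegsel.montage import standard_montage
    from eegsel.shapley import plot_frequency_importance, plot_scalp_importance, plot_summary

    table, record = trained_record
    record = shapley_for_record(record, table)
    # rename features onto the naming grammar for breakdown plots
    pts = summary_plot_data([record], table)
    plot_summary(pts, tmp_path / "summary.png")
    bd_chan = pd.Series({"CP5": 0.7, "Fp1": 0.3})
    plot_scalp_importance(bd_chan, standard_montage(), tmp_path / "scalp.png")
    plot_frequency_importance(pd.Series({"44-46": 0.8, "non-PSD": 0.2}), tmp_path / "freq.png")
    for f in ("summary.png", "scalp.png", "freq.png"):
        assert (tmp_path / f).stat().st_size > 0
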