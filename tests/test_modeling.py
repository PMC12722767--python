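import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score

from respmon.features import FeatureMatrix
from respmon.labels import LBL_UNDEFINED
from respmon.modeling import (
    calibration_report,
    decision_tree_baseline,
    greedy_forward_select,
    make_splits,
    mean_reciprocal_rank,
    rext_baseline_score,
    sf_ratio_score,
    shap_feature_importance,
    shap_variable_importance,
    train_task_model,
)


def _toy_featmat(n_stays=30, bins_per_stay=40, n_noise=3, seed=0):
    """Planted-signal problem: label depends on feature 'sig' only."""
    rng = np.random.default_rng(seed)
    frames = []
    manifest = [{"name": "sig", "category": "current", "variable": "sig", "horizon": None}]
    for j in range(n_noise):
        manifest.append(
            {"name": f"noise{j}", "category": "current", "variable": f"noise{j}", "horizon": None}
        )
    labels = []
    for i in range(n_stays):
        sig = rng.normal(size=bins_per_stay)
        cols = {"sig": sig}
        for j in range(n_noise):
            cols[f"noise{j}"] = rng.normal(size=bins_per_stay)
        df = pd.DataFrame(cols)
        df.insert(0, "stay_id", f"s{i}")
        df.insert(1, "bin", np.arange(bins_per_stay))
        frames.append(df)
        labels.append((sig > 0.3).astype(int))
    fm = FeatureMatrix(frame=pd.concat(frames, ignore_index=True), manifest=manifest)
    return fm, np.concatenate(labels)


@pytest.fixture(scope="module")
def toy():
    return _toy_featmat()


@pytest.fixture(scope="module")
def toy_splits(toy):
    fm, _ = toy
    ids = fm.frame["stay_id"].unique().tolist()
    return make_splits(ids, n_replicates=2, seed=0)


class TestMakeSplits:
    def test_partition_sizes(self):
        plan = make_splits([f"p{i}" for i in range(125)], n_replicates=5, seed=1)
        assert len(plan.test_ids) == 25
        for tr, va in plan.replicates:
            assert len(tr) == 80 and len(va) == 20

    def test_no_overlap(self):
        plan = make_splits([f"p{i}" for i in range(50)], seed=2)
        test = set(plan.test_ids)
        for tr, va in plan.replicates:
            assert not (set(tr) & set(va))
            assert not (test & set(tr)) and not (test & set(va))

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(40)]
        a = make_splits(ids, seed=3)
        b = make_splits(ids, seed=3)
        assert a.test_ids == b.test_ids and a.replicates == b.replicates

    def test_too_few_stays(self):
        with pytest.raises(ValueError):
            make_splits(["a", "b"], seed=0)


class TestTrainTaskModel:
    def test_separable_data_high_auprc(self, toy, toy_splits):
        fm, labels = toy
        tr, va = toy_splits.replicates[0]
        tm = train_task_model("toy", fm, labels, tr, va, seed=0, max_rounds=150)
        assert tm.val_auprc > 0.95

    def test_shuffled_labels_near_prevalence(self, toy, toy_splits):
        fm, labels = toy
        rng = np.random.default_rng(5)
        shuffled = rng.permutation(labels)
        tr, va = toy_splits.replicates[0]
        tm = train_task_model("null", fm, shuffled, tr, va, seed=0, max_rounds=60)
        prev = shuffled.mean()
        assert tm.val_auprc < prev + 0.15

    def test_seed_reproducibility(self, toy, toy_splits):
        fm, labels = toy
        tr, va = toy_splits.replicates[0]
        a = train_task_model("toy", fm, labels, tr, va, seed=7, max_rounds=80)
        b = train_task_model("toy", fm, labels, tr, va, seed=7, max_rounds=80)
        assert a.best_iteration == b.best_iteration
        assert a.val_auprc == pytest.approx(b.val_auprc)

    def test_single_class_rejected(self, toy, toy_splits):
        fm, labels = toy
        tr, va = toy_splits.replicates[0]
        with pytest.raises(ValueError):
            train_task_model("bad", fm, np.zeros_like(labels), tr, va)

    def test_undefined_rows_excluded(self, toy, toy_splits):
        fm, labels = toy
        tr, va = toy_splits.replicates[0]
        lab2 = labels.copy()
        lab2[::3] = LBL_UNDEFINED
        tm = train_task_model("toy", fm, lab2, tr, va, seed=0, max_rounds=80)
        assert tm.val_auprc > 0.9


class TestShapImportance:
    def test_planted_signal_ranks_first(self, toy, toy_splits):
        fm, labels = toy
        tr, va = toy_splits.replicates[0]
        tm = train_task_model("toy", fm, labels, tr, va, seed=0, max_rounds=100)
        va_mask = fm.frame["stay_id"].isin(set(va)).to_numpy()
        imp = shap_feature_importance(tm, fm.frame[va_mask], max_rows=80, seed=0)
        ranking = shap_variable_importance(imp, fm)
        assert ranking.index[0] == "sig"
        assert ranking.iloc[0] > 3 * ranking.iloc[1]

    def test_variable_importance_max_over_features(self, toy):
        fm, _ = toy
        s = pd.Series({"sig": 1.0, "noise0": 0.2, "noise1": 0.6, "noise2": 0.1})
        ranking = shap_variable_importance(s, fm)
        assert list(ranking.index[:2]) == ["sig", "noise1"]


class TestGreedySelection:
    def test_planted_signal_selected_first(self, toy, toy_splits):
        fm, labels = toy
        ranking, traces = greedy_forward_select(
            ["sig", "noise0", "noise1"], fm, labels, toy_splits,
            max_rounds=30, max_steps=2,
        )
        assert ranking.index[0] == "sig"
        assert ranking.loc["sig"] == pytest.approx(1.0)  # first in every trace
        for t in traces:
            assert t[0] == "sig"

    def test_trace_length_equals_candidates(self, toy, toy_splits):
        fm, labels = toy
        _, traces = greedy_forward_select(
            ["sig", "noise0"], fm, labels, toy_splits, max_rounds=20
        )
        for t in traces:
            assert sorted(t) == ["noise0", "sig"]

    def test_mrr_arithmetic(self):
        traces = [["a", "b"]] * 5
        mrr = mean_reciprocal_rank(traces)
        assert mrr["a"] == 1.0 and mrr["b"] == 0.5

    def test_empty_candidates(self, toy, toy_splits):
        fm, labels = toy
        with pytest.raises(ValueError):
            greedy_forward_select([], fm, labels, toy_splits)

    def test_first_step_equals_exhaustive_singleton_search(self, toy, toy_splits):
        fm, labels = toy
        cands = ["sig", "noise0", "noise1", "noise2"]
        tr, va = toy_splits.replicates[0]
        single_plan = type(toy_splits)(test_ids=toy_splits.test_ids, replicates=[(tr, va)])
        _, traces = greedy_forward_select(
            cands, fm, labels, single_plan, max_rounds=30, max_steps=1
        )
        # oracle: exhaustively train each singleton model
        scores = {}
        for v in cands:
            tm = train_task_model(
                "x", fm, labels, tr, va, seed=0, max_rounds=30, feature_names=[v]
            )
            scores[v] = tm.val_auprc
        assert traces[0][0] == max(scores, key=scores.get)


class TestCalibration:
    def test_perfect_scores_brier_zero(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = calibration_report(y.astype(float), y)
        assert rep.brier == 0.0

    def test_constant_score_closed_form(self):
        rng = np.random.default_rng(0)
        p = 0.3
        y = (rng.random(20000) < p).astype(float)
        rep = calibration_report(np.full(20000, y.mean()), y)
        assert rep.brier == pytest.approx(y.mean() * (1 - y.mean()), abs=1e-12)

    def test_bin_width_0_05(self):
        rng = np.random.default_rng(1)
        s = rng.random(1000)
        rep = calibration_report(s, (rng.random(1000) < s).astype(int))
        widths = np.diff(rep.bin_edges)
        assert np.allclose(widths[:-1], 0.05)

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(2)
        s = rng.random(500)
        y = (rng.random(500) < s).astype(int)
        rep = calibration_report(s, y)
        for i in range(len(rep.bin_centers)):
            lo, hi = rep.bin_edges[i], rep.bin_edges[i + 1]
            if i == len(rep.bin_centers) - 1:
                m = (s >= lo) & (s <= hi)
            else:
                m = (s >= lo) & (s < hi)
            if m.sum() == 0:
                assert np.isnan(rep.observed[i])
            else:
                assert rep.observed[i] == pytest.approx(y[m].mean())
                assert rep.counts[i] == m.sum()

    def test_calibrated_scores_near_diagonal(self):
        rng = np.random.default_rng(3)
        s = rng.random(50000)
        y = (rng.random(50000) < s).astype(int)
        rep = calibration_report(s, y)
        ok = rep.counts > 200
        # binomial CI: 4 standard errors
        se = np.sqrt(rep.bin_centers * (1 - rep.bin_centers) / np.maximum(rep.counts, 1))
        assert np.all(np.abs(rep.observed[ok] - rep.bin_centers[ok]) < 4 * se[ok] + 0.01)


class TestClinicalBaselines:
    def test_sf_ratio_ordering(self):
        risky = sf_ratio_score(np.array([92.0]), np.array([0.4]))
        safe = sf_ratio_score(np.array([98.0]), np.array([0.21]))
        assert risky > safe  # S/F 230 is riskier than S/F 467

    def test_rext_baseline_passthrough(self):
        v = np.array([0.0, 6.0, 12.0])
        assert np.array_equal(rext_baseline_score(v), v)

    def test_decision_tree_baseline_below_full_model(self):
        # nested-information simulation: the label depends on a latent that
        # the full model sees almost noiselessly through a history feature,
        # while the current-value baseline sees only a noisy copy
        rng = np.random.default_rng(11)
        frames, labels = [], []
        manifest = [
            {"name": "sig_current", "category": "current", "variable": "sig_current", "horizon": None},
            {"name": "sig_hist", "category": "multires", "variable": "sig_hist", "horizon": 10},
        ]
        for i in range(40):
            latent = rng.normal(size=50)
            df = pd.DataFrame(
                {
                    "sig_current": latent + rng.normal(scale=2.0, size=50),
                    "sig_hist": latent + rng.normal(scale=0.05, size=50),
                }
            )
            df.insert(0, "stay_id", f"s{i}")
            df.insert(1, "bin", np.arange(50))
            frames.append(df)
            labels.append((latent > 0.5).astype(int))
        fm = FeatureMatrix(frame=pd.concat(frames, ignore_index=True), manifest=manifest)
        labels = np.concatenate(labels)
        plan = make_splits(fm.frame["stay_id"].unique().tolist(), n_replicates=1, seed=0)
        tr, va = plan.replicates[0]
        full = train_task_model("RF", fm, labels, tr, va, seed=0, max_rounds=120)
        tree, cols = decision_tree_baseline(fm, labels, tr, variables=("sig_current",))
        va_mask = (labels != LBL_UNDEFINED) & fm.frame["stay_id"].isin(set(va)).to_numpy()
        X = fm.frame.loc[va_mask, cols].to_numpy(float)
        tree_auprc = average_precision_score(labels[va_mask], tree.predict_proba(X)[:, 1])
        assert full.val_auprc > tree_auprc


class TestGridSearch:
    def test_small_grid_picks_best_by_val_auprc(self, toy, toy_splits):
        from respmon.modeling import grid_search_task_model, DEFAULT_PARAMS

        fm, labels = toy
        tr, va = toy_splits.replicates[0]
        grid = [
            dict(DEFAULT_PARAMS, max_leaf_nodes=3),
            dict(DEFAULT_PARAMS, max_leaf_nodes=31),
        ]
        best = grid_search_task_model(
            "EF", fm, labels, tr, va, grid=grid, seed=0, max_rounds=60
        )
        singles = [
            train_task_model("EF", fm, labels, tr, va, g, seed=0, max_rounds=60)
            for g in grid
        ]
        assert best.val_auprc == pytest.approx(max(s.val_auprc for s in singles))
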