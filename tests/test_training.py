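"""Log loss, Bayesian optimization, threshold rule, TSPT ensemble, SMLA."""

import numpy as np
import pandas as pd
import pytest

import multlearn as ml
from multlearn.training import Real, SPACES, bayesian_optimize

from _reference import binary_log_loss, exhaustive_threshold


class TestLogLoss:
    def test_uninformative_prediction_is_ln2(self):
        assert ml.log_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2),
                                                                abs=1e-12)

    def test_perfect_prediction_near_zero(self):
        assert ml.log_loss([1.0, 0.0], [1.0, 0.0]) < 1e-12

    def test_matches_elementwise_reference(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 30))
            y = rng.integers(0, 2, size=n).astype(float)
            p = rng.random(n)
            assert ml.log_loss(y, p) == pytest.approx(binary_log_loss(y, p))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ml.ContractError):
            ml.log_loss([1, 0], [0.5])


class TestSelectThreshold:
    def test_perfect_separation(self):
        thr, j = ml.select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < thr < 0.8
        assert j == pytest.approx(1.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert ml.select_threshold(scores, labels) == pytest.approx(
                exhaustive_threshold(scores, labels))

    def test_all_scores_equal_degenerate(self):
        thr, j = ml.select_threshold([0.4, 0.4, 0.4], [1, 0, 1])
        assert thr == 0.4
        assert j == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ml.ContractError):
            ml.select_threshold([0.1, 0.9], [1, 1])


class TestBayesianOptimize:
    def test_recovers_known_quadratic_optimum(self):
        space = [Real("x", 0.0, 1.0)]
        for seed in range(5):
            res = bayesian_optimize(space, lambda p: (p["x"] - 0.3) ** 2,
                                    n_init=10, n_iter=20, seed=seed)
            assert abs(res.best_params["x"] - 0.3) < 0.05

    def test_best_loss_is_trace_minimum(self):
        res = bayesian_optimize([Real("x", 0.0, 1.0)],
                                lambda p: (p["x"] - 0.6) ** 2,
                                n_init=5, n_iter=5, seed=1)
        assert res.best_loss == min(l for _, l in res.trace)
        assert len(res.trace) == 10

    def test_best_never_worse_than_random_inits(self):
        res = bayesian_optimize([Real("x", 0.0, 1.0)],
                                lambda p: abs(p["x"] - 0.2),
                                n_init=6, n_iter=6, seed=3)
        assert res.best_loss <= min(l for _, l in res.trace[:6])

    def test_same_seed_identical_trace(self):
        space = [Real("x", 0.0, 1.0)]
        a = bayesian_optimize(space, lambda p: (p["x"] - 0.5) ** 2,
                              n_init=4, n_iter=4, seed=7)
        b = bayesian_optimize(space, lambda p: (p["x"] - 0.5) ** 2,
                              n_init=4, n_iter=4, seed=7)
        assert a.trace == b.trace

    def test_raising_objective_recorded_as_failure(self):
        calls = {"n": 0}

        def objective(p):
            calls["n"] += 1
            if p["x"] < 0.5:
                raise RuntimeError("boom")
            return p["x"]

        res = bayesian_optimize([Real("x", 0.0, 1.0)], objective,
                                n_init=6, n_iter=4, seed=0)
        assert calls["n"] == 10
        assert any(np.isinf(l) for _, l in res.trace)
        assert np.isfinite(res.best_loss)

    def test_sampled_points_respect_ranges(self):
        for space in SPACES.values():
            res = bayesian_optimize(space, lambda p: 1.0, n_init=5, n_iter=0,
                                    seed=0)
            for params, _ in res.trace:
                for dim in space:
                    v = params[dim.name]
                    if hasattr(dim, "choices"):
                        assert v in dim.choices
                    else:
                        assert dim.low <= v <= dim.high


def _planted_features(n=240, n_feat=10, effect=1.5, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, n_feat))
    X[:, :3] += effect * y[:, None]
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(n_feat)]), y


class TestTrainTSPT:
    def test_learns_planted_signal(self, tiny_settings):
        X, y = _planted_features()
        pred = ml.train_tspt(X, y, seed=0, settings=tiny_settings)
        scores = pred.predict_scores(X)
        assert ml.auc_score(y, scores) > 0.75

    def test_three_members_and_mean_score(self, tiny_settings):
        X, y = _planted_features(seed=1)
        pred = ml.train_tspt(X, y, seed=0, settings=tiny_settings)
        assert len(pred.boosters) == 3
        member = np.stack([m.predict_proba(X)[:, 1] for m in pred.boosters])
        np.testing.assert_allclose(pred.predict_scores(X), member.mean(axis=0))
        s = pred.predict_scores(X)
        assert ((s >= 0) & (s <= 1)).all()

    def test_identical_rows_identical_scores(self, tiny_settings):
        X, y = _planted_features(seed=2)
        pred = ml.train_tspt(X, y, seed=0, settings=tiny_settings)
        dup = pd.concat([X.iloc[[0]], X.iloc[[0]]], ignore_index=True)
        s = pred.predict_scores(dup)
        assert s[0] == s[1]

    def test_threshold_in_unit_interval(self, tiny_settings):
        X, y = _planted_features(seed=3)
        pred = ml.train_tspt(X, y, seed=0, settings=tiny_settings)
        assert 0.0 <= pred.threshold <= 1.0

    def test_single_class_rejected(self, tiny_settings):
        X, _ = _planted_features(seed=4)
        with pytest.raises(ml.ContractError):
            ml.train_tspt(X, np.ones(len(X)), seed=0, settings=tiny_settings)


class TestTrainSMLA:
    @pytest.mark.parametrize("model", ["gbt", "mlp", "svm"])
    def test_all_models_runnable(self, model, tiny_settings):
        X, y = _planted_features(n=160, seed=5)
        pred = ml.train_smla(X, y, model=model, alpha=0.05, seed=0,
                             settings=tiny_settings)
        scores = pred.predict_scores(X)
        assert len(scores) == len(y)
        assert ml.auc_score(y, scores) > 0.7
        assert 0.0 <= pred.threshold <= 1.0

    def test_no_markers_selected_raises(self, tiny_settings, rng):
        X = pd.DataFrame(rng.normal(size=(80, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = rng.integers(0, 2, size=80)
        with pytest.raises(ml.DataError, match="alpha"):
            ml.train_smla(X, y, model="gbt", alpha=1e-12, seed=0,
                          settings=tiny_settings)

    def test_passthrough_columns_kept(self, tiny_settings):
        X, y = _planted_features(n=160, seed=6)
        extra = pd.DataFrame({"treatment=A": np.ones(len(y))}, index=X.index)
        pred = ml.train_smla(X, y, model="gbt", seed=0,
                             settings=tiny_settings, passthrough=extra)
        assert "treatment=A" in pred.feature_columns


class TestTrainMult:
    def test_full_pipeline_learns_and_bundles(self, small_cohort, tiny_settings):
        cohort, truth = small_cohort
        pred = ml.train_mult(cohort, seed=0, settings=tiny_settings)
        assert pred.normalizer is not None
        assert pred.treatment_vocab == sorted(cohort.treatment.unique())
        scores = pred.score(cohort)
        assert ml.auc_score(cohort.ts, scores) > 0.8
        # feature layout starts with selected genes, ends with treatment block
        assert pred.feature_columns[-len(pred.treatment_vocab):] == [
            f"treatment={t}" for t in pred.treatment_vocab]

    def test_requires_ts(self, small_cohort, tiny_settings):
        cohort, _ = small_cohort
        from dataclasses import replace
        with pytest.raises(ml.ContractError):
            ml.train_mult(replace(cohort, ts=None), seed=0,
                          settings=tiny_settings)
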