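"""Metrics, recursive feature elimination, training, CV and the
model/results front end."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from thermoshift.core import ThermoshiftError
from thermoshift.model import (
    DeltaTmModel,
    MetricsReport,
    ModelBundle,
    cross_validate,
    make_estimator,
    metric_mae,
    metric_pcc,
    metric_r2,
    metric_rmse,
    predict,
    rfe_select,
    rfecv_select,
    train,
)
from thermoshift.simulate import make_selection_fixture


class TestMetrics:
    def test_worked_examples(self):
        assert metric_mae([0, 0], [3, -3]) == pytest.approx(3.0)
        assert metric_rmse([0, 0], [3, 4]) == pytest.approx(math.sqrt(12.5))
        assert metric_mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert metric_rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_r2_reference_points(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert metric_r2(y, y) == pytest.approx(1.0)
        assert metric_r2(y, np.full(4, y.mean())) == pytest.approx(0.0)
        assert metric_r2(y, -y) < 0  # worse than predicting the mean

    def test_pcc_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        assert metric_pcc(y, 2 * y + 5) == pytest.approx(1.0)
        assert metric_pcc(y, -y) == pytest.approx(-1.0)
        yhat = y + rng.normal(size=50)
        assert metric_pcc(y, yhat) == pytest.approx(metric_pcc(yhat, y))

    def test_undefined_metrics_reported_nan(self):
        assert math.isnan(metric_r2([2.0, 2.0], [1.0, 3.0]))
        assert math.isnan(metric_pcc([1.0, 2.0], [5.0, 5.0]))

    def test_errors(self):
        with pytest.raises(ValueError):
            metric_mae([], [])
        with pytest.raises(ValueError):
            metric_rmse([1.0], [1.0, 2.0])

    def test_rmse_scale_equivariance_and_jensen(self):
        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=30), rng.normal(size=30)
        assert metric_rmse(3 * y, 3 * yhat) == pytest.approx(3 * metric_rmse(y, yhat))
        assert metric_mae(y, yhat) <= metric_rmse(y, yhat)

    def test_r2_rmse_identity(self):
        rng = np.random.default_rng(2)
        y, yhat = rng.normal(size=40), rng.normal(size=40)
        m = len(y)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert metric_r2(y, yhat) == pytest.approx(
            1 - metric_rmse(y, yhat) ** 2 * m / ss_tot
        )


class TestRFE:
    def test_no_elimination_is_identity(self):
        X, y, _ = make_selection_fixture(0, n_rows=100)
        assert rfe_select(X, y, n_target=X.shape[1]) == list(X.columns)

    def test_deterministic_under_seed(self):
        X, y, _ = make_selection_fixture(3, n_rows=200)
        a = rfe_select(X, y, n_target=5, seed=11)
        b = rfe_select(X, y, n_target=5, seed=11)
        assert a == b

    def test_matches_sklearn_rfe_at_single_steps(self):
        # Dual route: same estimator family, same gain ranking, step=1.
        # All columns informative with distinct strengths, so no gain ties.
        from sklearn.feature_selection import RFE
        from thermoshift.model import _gain_importances

        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            rng.normal(size=(300, 6)), columns=[f"c{i}" for i in range(6)]
        )
        y = X @ np.array([4.0, 3.0, 2.0, 1.0, 0.5, 0.25]) + rng.normal(0, 0.1, 300)
        ours = rfe_select(X, y, n_target=3, seed=0)
        skl = RFE(
            make_estimator(seed=0),
            n_features_to_select=3,
            step=1,
            importance_getter=lambda est: _gain_importances(est, 6),
        ).fit(X, y)
        assert ours == list(X.columns[skl.support_])

    def test_invalid_target(self):
        X, y, _ = make_selection_fixture(0, n_rows=50)
        with pytest.raises(ValueError):
            rfe_select(X, y, n_target=0)
        with pytest.raises(ValueError):
            rfe_select(X, y, n_target=99)


class TestRFECV:
    def test_min_features_equal_to_all_columns_binds(self):
        X, y, _ = make_selection_fixture(0, n_rows=80)
        selected, chosen, _ = rfecv_select(X, y, min_features=X.shape[1])
        assert selected == list(X.columns) and chosen == X.shape[1]

    def test_deterministic(self):
        X, y, _ = make_selection_fixture(5, n_rows=150, n_noise=15)
        a = rfecv_select(X, y, min_features=5, seed=2)
        b = rfecv_select(X, y, min_features=5, seed=2)
        assert a == b


class TestTrainPredict:
    def _design(self, n=60, p=5, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        y = X["f0"] * 2 - X["f1"] + rng.normal(0, 0.1, n)
        return X, y

    def test_constant_labels_give_constant_predictions(self):
        X, _ = self._design()
        bundle = train(X, np.full(len(X), 1.5))
        assert predict(bundle, X) == pytest.approx(np.full(len(X), 1.5), abs=1e-6)

    def test_same_seed_identical_predictions(self):
        X, y = self._design()
        p1 = predict(train(X, y, seed=7), X)
        p2 = predict(train(X, y, seed=7), X)
        assert np.array_equal(p1, p2)

    def test_shuffled_columns_identical_predictions(self):
        X, y = self._design()
        bundle = train(X, y)
        shuffled = X[list(X.columns[::-1])]
        assert np.array_equal(predict(bundle, X), predict(bundle, shuffled))

    def test_missing_columns_enumerated(self):
        X, y = self._design()
        bundle = train(X, y)
        with pytest.raises(ThermoshiftError, match="f3.*f4"):
            predict(bundle, X[["f0", "f1", "f2"]])

    def test_ph_default_injected_for_ph_tm_bundle(self):
        X, y = self._design()
        X = X.rename(columns={"f4": "ph"})
        bundle = train(X, y, variant="ph_tm")
        with pytest.warns(UserWarning, match="7.0"):
            preds = predict(bundle, X.drop(columns=["ph"]))
        expected = predict(bundle, X.assign(ph=7.0))
        assert np.array_equal(preds, expected)

    def test_empty_or_nonfinite_rejected(self):
        X, y = self._design()
        with pytest.raises(ValueError):
            train(X.iloc[:0], y[:0])
        with pytest.raises(ValueError):
            train(X, np.full(len(X), np.nan))

    def test_bundle_roundtrip(self, tmp_path):
        X, y = self._design()
        bundle = train(X, y, variant="tm")
        bundle.save(tmp_path / "m.bundle")
        back = ModelBundle.load(tmp_path / "m.bundle")
        assert back.feature_names == bundle.feature_names
        assert back.config_hash == bundle.config_hash
        assert np.array_equal(predict(back, X), predict(bundle, X))

    def test_xgboost_backend_works(self):
        X, y = self._design()
        bundle = train(X, y, algorithm="xgboost")
        assert np.all(np.isfinite(predict(bundle, X)))


class TestCrossValidate:
    def test_leave_one_out_runs(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        y = rng.normal(size=10)
        report = cross_validate(X, y, folds=10)
        assert np.isfinite(report.pooled.mae)
        # single-row folds have undefined R2/PCC, flagged not coerced
        assert len(report.undefined_folds) == 10

    def test_protein_grouping_keeps_groups_whole(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        groups = [f"g{i % 8}" for i in range(40)]
        from sklearn.model_selection import GroupKFold

        splitter = GroupKFold(n_splits=4)
        for tr, te in splitter.split(X, groups=np.asarray(groups)):
            assert {groups[i] for i in tr}.isdisjoint({groups[i] for i in te})
        report = cross_validate(X, y, folds=4, grouping="protein", groups=groups)
        assert np.isfinite(report.pooled.mae)

    def test_grouping_requires_groups(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            cross_validate(X, [1, 2, 3, 4], folds=2, grouping="protein")


class TestModelResultsFrontEnd:
    def test_fit_summary_and_predict(self):
        X, y, _ = make_selection_fixture(8, n_rows=200, n_noise=10)
        model = DeltaTmModel(X, y, variant="common")
        res = model.fit(selection="rfe", n_features=5, seed=0)
        assert len(res.selected_features) == 5
        assert res.training_metrics.r2 > 0.8
        text = res.summary()
        assert "lightgbm" in text and "training" in text
        res.cross_validate(folds=5)
        assert "CV (pooled)" in res.summary()
        assert np.all(np.isfinite(res.predict(X)))

    def test_from_dataframe(self):
        X, y, _ = make_selection_fixture(9, n_rows=100, n_noise=5)
        df = X.assign(dtm=y)
        model = DeltaTmModel.from_dataframe(df)
        res = model.fit(seed=1)
        assert res.bundle.feature_names == list(X.columns)

    def test_feature_importances_ranked(self):
        X, y, informative = make_selection_fixture(10, n_rows=300)
        res = DeltaTmModel(X, y).fit(seed=0)
        top = set(res.feature_importances.head(5).index)
        assert len(top & set(informative)) >= 4
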