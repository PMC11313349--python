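"""Gradient-boosted dTm regression: metrics, feature selection,
training, cross-validation and a Model/Results front end.

The evaluation metrics are the four standard regression measures —
MAE, RMSE, the coefficient of determination R^2 and the Pearson
correlation coefficient — implemented directly from their defining
formulas.  Feature selection is recursive feature elimination driven
by gradient-boosting gain importances, optionally with cross-validated
choice of the retained count (RFECV).  Two regressor families are
supported with their library default hyperparameters: LightGBM (the
package default) and XGBoost.

For interactive use the module also exposes a statsmodels-style pair:
:class:`DeltaTmModel` is built from a feature table and labels and its
``fit()`` returns a :class:`DeltaTmResults` carrying the trained
bundle, training metrics, optional cross-validation report and a
``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold

from .core import ThermoshiftError
from .features.table import FeatureTable

logger = logging.getLogger(__name__)

ALGORITHMS = ("lightgbm", "xgboost")
DEFAULT_ALGORITHM = "lightgbm"


# ---------------------------------------------------------------------------
# Metrics


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty vectors")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return y, yhat


def metric_mae(y, yhat) -> float:
    """Mean absolute error (1/m) sum |y_i - yhat_i|."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def metric_rmse(y, yhat) -> float:
    """Root mean square error sqrt((1/m) sum (y_i - yhat_i)^2)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def metric_r2(y, yhat) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    Negative when predictions are worse than the observed mean;
    undefined (NaN) when the observed values are constant.
    """
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def metric_pcc(y, yhat) -> float:
    """Pearson correlation: cov(y, yhat) / (sd(y) sd(yhat)).

    Undefined (NaN) when either vector is constant.
    """
    y, yhat = _check_pair(y, yhat)
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    denom = np.sqrt(np.sum(yc**2) * np.sum(pc**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(yc * pc) / denom)


@dataclass
class MetricsReport:
    """The four evaluation metrics; NaN marks an undefined metric
    (constant truth or predictions) and is flagged, never coerced."""

    mae: float
    rmse: float
    r2: float
    pcc: float

    @staticmethod
    def compute(y, yhat) -> "MetricsReport":
        return MetricsReport(
            mae=metric_mae(y, yhat),
            rmse=metric_rmse(y, yhat),
            r2=metric_r2(y, yhat),
            pcc=metric_pcc(y, yhat),
        )

    @property
    def undefined(self) -> list[str]:
        return [k for k in ("mae", "rmse", "r2", "pcc") if np.isnan(getattr(self, k))]

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2, "pcc": self.pcc}


# ---------------------------------------------------------------------------
# Estimators


def make_estimator(
    algorithm: str = DEFAULT_ALGORITHM,
    params: Mapping | None = None,
    seed: int = 0,
):
    """A fresh regressor with library default hyperparameters.

    Only the seed, thread count and verbosity are pinned; everything
    else stays at the library defaults unless overridden via *params*.
    """
    params = dict(params or {})
    if algorithm == "lightgbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **params)
    if algorithm == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, importance_type="gain", **params
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _gain_importances(estimator, n_features: int) -> np.ndarray:
    """Per-feature gain importances from a fitted booster."""
    booster = getattr(estimator, "booster_", None)
    if booster is not None and hasattr(booster, "feature_importance"):
        return np.asarray(booster.feature_importance(importance_type="gain"), float)
    imp = getattr(estimator, "feature_importances_", None)
    if imp is None:
        raise ValueError("estimator exposes no feature importances")
    return np.asarray(imp, dtype=float)


def _as_frame(features: "FeatureTable | pd.DataFrame") -> pd.DataFrame:
    return features.df if isinstance(features, FeatureTable) else features


# ---------------------------------------------------------------------------
# Recursive feature elimination

#: Fraction of the remaining features eliminated per iteration.
RFE_STEP = 0.05


def rfe_path(
    features: "FeatureTable | pd.DataFrame",
    labels: Sequence[float],
    n_target: int,
    step: float = RFE_STEP,
    algorithm: str = DEFAULT_ALGORITHM,
    params: Mapping | None = None,
    seed: int = 0,
) -> list[str]:
    """Elimination order (first eliminated first) down to *n_target*.

    Each iteration fits the estimator on the surviving columns and
    drops the ``max(1, floor(step * remaining))`` lowest-gain features,
    never overshooting the target, so the final approach proceeds by
    single steps.  Ties break deterministically by column order.
    """
    X = _as_frame(features)
    y = np.asarray(labels, dtype=float)
    if n_target <= 0:
        raise ValueError(f"n_target must be positive, got {n_target}")
    if n_target > X.shape[1]:
        raise ValueError(f"n_target {n_target} exceeds {X.shape[1]} columns")
    remaining = list(X.columns)
    eliminated: list[str] = []
    while len(remaining) > n_target:
        est = make_estimator(algorithm, params, seed)
        est.fit(X[remaining], y)
        imp = _gain_importances(est, len(remaining))
        k = min(max(1, int(step * len(remaining))), len(remaining) - n_target)
        order = np.argsort(imp, kind="stable")[:k]
        for idx in sorted(order, reverse=True):
            eliminated.append(remaining.pop(int(idx)))
    return eliminated


def rfe_select(
    features: "FeatureTable | pd.DataFrame",
    labels: Sequence[float],
    n_target: int,
    step: float = RFE_STEP,
    algorithm: str = DEFAULT_ALGORITHM,
    params: Mapping | None = None,
    seed: int = 0,
) -> list[str]:
    """Names of the *n_target* surviving features, in original column
    order.  Deterministic under *seed*."""
    X = _as_frame(features)
    gone = set(
        rfe_path(features, labels, n_target, step, algorithm, params, seed)
    )
    return [c for c in X.columns if c not in gone]


def rfecv_select(
    features: "FeatureTable | pd.DataFrame",
    labels: Sequence[float],
    min_features: int = 50,
    folds: int = 5,
    step: float = RFE_STEP,
    algorithm: str = DEFAULT_ALGORITHM,
    params: Mapping | None = None,
    seed: int = 0,
) -> tuple[list[str], int, dict[int, float]]:
    """RFE with cross-validated choice of the retained feature count.

    The elimination path is computed once down to *min_features*; every
    count visited along the path (plus the full set) is scored by
    *folds*-fold CV MAE on the corresponding feature subset.  The
    count with the lowest CV MAE wins (ties -> fewer features).
    Returns (selected names, chosen count, {count: cv_mae}).
    """
    X = _as_frame(features)
    y = np.asarray(labels, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_cols = X.shape[1]
    min_features = min(min_features, n_cols)
    if min_features == n_cols:
        return list(X.columns), n_cols, {}
    path = rfe_path(features, labels, min_features, step, algorithm, params, seed)
    # feature subsets at each visited count: full set, then progressively fewer
    counts = sorted({n_cols - i for i in range(len(path) + 1)}, reverse=True)
    scores: dict[int, float] = {}
    for count in counts:
        gone = set(path[: n_cols - count])
        cols = [c for c in X.columns if c not in gone]
        preds = np.empty_like(y)
        for tr, te in KFold(folds, shuffle=True, random_state=seed).split(X):
            est = make_estimator(algorithm, params, seed)
            est.fit(X.iloc[tr][cols], y[tr])
            preds[te] = est.predict(X.iloc[te][cols])
        scores[count] = metric_mae(y, preds)
    chosen = min(sorted(scores), key=lambda c: (scores[c], c))
    gone = set(path[: n_cols - chosen])
    return [c for c in X.columns if c not in gone], chosen, scores


# ---------------------------------------------------------------------------
# Training / prediction


@dataclass
class ModelBundle:
    """Deployable artifact: trained regressor + the metadata needed to
    reproduce and validate its inputs."""

    estimator: object
    feature_names: list[str]
    algorithm: str = DEFAULT_ALGORITHM
    params: dict = field(default_factory=dict)
    variant: str = "common"
    context_length: int | str | None = None
    pooling: str | None = None
    combine: str | None = None
    seed: int = 0
    fixture_versions: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        manifest = json.dumps(
            {
                "feature_names": self.feature_names,
                "algorithm": self.algorithm,
                "params": {k: str(v) for k, v in self.params.items()},
                "variant": self.variant,
                "context_length": self.context_length,
                "pooling": self.pooling,
                "combine": self.combine,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(manifest.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with Path(path).open("wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        with Path(path).open("rb") as fh:
            bundle = pickle.load(fh)
        if not isinstance(bundle, ModelBundle):
            raise ThermoshiftError(f"{path} does not contain a model bundle")
        return bundle

    def predict(self, features: "FeatureTable | pd.DataFrame") -> np.ndarray:
        return predict(self, features)


def train(
    features: "FeatureTable | pd.DataFrame",
    labels: Sequence[float],
    algorithm: str = DEFAULT_ALGORITHM,
    params: Mapping | None = None,
    seed: int = 0,
    **metadata,
) -> ModelBundle:
    """Fit a regressor on the full table; returns the bundle."""
    X = _as_frame(features)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty feature table")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    est = make_estimator(algorithm, params, seed)
    est.fit(X, y)
    return ModelBundle(
        estimator=est,
        feature_names=list(X.columns),
        algorithm=algorithm,
        params=dict(params or {}),
        seed=seed,
        **metadata,
    )


DEFAULT_PH = 7.0


def predict(bundle: ModelBundle, features: "FeatureTable | pd.DataFrame") -> np.ndarray:
    """Predict dTm (degC) for each row of *features*.

    Columns are aligned by name.  A ph_tm bundle tolerates a missing
    pH column by injecting the neutral default 7.0 with a warning; any
    other missing column is an error listing all absentees.
    """
    X = _as_frame(features).copy()
    missing = [c for c in bundle.feature_names if c not in X.columns]
    if missing == ["ph"] and bundle.variant == "ph_tm":
        warnings.warn(
            f"pH column absent; defaulting to pH {DEFAULT_PH}", stacklevel=2
        )
        logger.warning("pH column absent; defaulting to pH %s", DEFAULT_PH)
        X["ph"] = DEFAULT_PH
        missing = []
    if missing:
        raise ThermoshiftError(f"feature table lacks required columns: {missing}")
    preds = np.asarray(
        bundle.estimator.predict(X[bundle.feature_names]), dtype=float
    )
    if not np.all(np.isfinite(preds)):
        raise ThermoshiftError("non-finite predictions")
    return preds


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    """Pooled out-of-fold metrics, per-fold metrics and their mean.

    Folds with constant truth get NaN R^2/PCC; they are listed in
    ``undefined_folds`` and excluded from the fold means.
    """

    pooled: MetricsReport
    per_fold: list[MetricsReport]
    fold_mean: MetricsReport
    undefined_folds: list[int]
    predictions: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "pooled": self.pooled.as_dict(),
            "fold_mean": self.fold_mean.as_dict(),
            "per_fold": [m.as_dict() for m in self.per_fold],
            "undefined_folds": self.undefined_folds,
        }


def cross_validate(
    features: "FeatureTable | pd.DataFrame",
    labels: Sequence[float],
    folds: int = 10,
    grouping: str = "record",
    seed: int = 0,
    algorithm: str = DEFAULT_ALGORITHM,
    params: Mapping | None = None,
    groups: Sequence | None = None,
    keep_predictions: bool = False,
) -> CVReport:
    """K-fold cross-validation with pooled out-of-fold metrics.

    ``grouping="record"`` shuffles rows independently;
    ``grouping="protein"`` keeps all rows of one protein in a single
    fold (requires *groups*, one group label per row).  All randomness
    derives from *seed*.
    """
    X = _as_frame(features)
    y = np.asarray(labels, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if grouping == "record":
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    elif grouping == "protein":
        if groups is None:
            raise ValueError("protein grouping requires per-row group labels")
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(X, groups=np.asarray(groups))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    oof = np.empty_like(y)
    per_fold: list[MetricsReport] = []
    undefined: list[int] = []
    for i, (tr, te) in enumerate(split):
        est = make_estimator(algorithm, params, seed)
        est.fit(X.iloc[tr], y[tr])
        oof[te] = est.predict(X.iloc[te])
        rep = MetricsReport.compute(y[te], oof[te])
        per_fold.append(rep)
        if rep.undefined:
            undefined.append(i)
    pooled = MetricsReport.compute(y, oof)

    def _nanmean(vals: list[float]) -> float:
        finite = [v for v in vals if not np.isnan(v)]
        return float(np.mean(finite)) if finite else float("nan")

    fold_mean = MetricsReport(
        mae=float(np.mean([m.mae for m in per_fold])),
        rmse=float(np.mean([m.rmse for m in per_fold])),
        r2=_nanmean([m.r2 for m in per_fold]),
        pcc=_nanmean([m.pcc for m in per_fold]),
    )
    return CVReport(
        pooled=pooled,
        per_fold=per_fold,
        fold_mean=fold_mean,
        undefined_folds=undefined,
        predictions=oof if keep_predictions else None,
    )


# ---------------------------------------------------------------------------
# Model / Results front end


class DeltaTmModel:
    """A dTm regression model specified by a feature table and labels.

    Follows the model/results convention: the model object holds the
    data and configuration; :meth:`fit` performs optional feature
    selection plus training and returns a :class:`DeltaTmResults`.
    """

    def __init__(
        self,
        features: "FeatureTable | pd.DataFrame",
        labels: Sequence[float],
        variant: str = "common",
        algorithm: str = DEFAULT_ALGORITHM,
        params: Mapping | None = None,
        groups: Sequence | None = None,
    ) -> None:
        self.features = features
        self.X = _as_frame(features)
        self.y = np.asarray(labels, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("features and labels disagree in length")
        self.variant = variant
        self.algorithm = algorithm
        self.params = dict(params or {})
        self.groups = None if groups is None else list(groups)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "dtm",
        feature_cols: Sequence[str] | None = None,
        **kwargs,
    ) -> "DeltaTmModel":
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in frame")
        cols = (
            [c for c in df.columns if c != label_col]
            if feature_cols is None
            else list(feature_cols)
        )
        return cls(df[cols], df[label_col].to_numpy(), **kwargs)

    def fit(
        self,
        selection: str | None = None,
        n_features: int | None = None,
        min_features: int = 50,
        folds: int = 5,
        seed: int = 0,
    ) -> "DeltaTmResults":
        """Select features (optionally) and train.

        ``selection=None`` uses every column; ``"rfe"`` keeps
        *n_features* by recursive elimination; ``"rfecv"`` chooses the
        count by cross-validation (>= *min_features*).
        """
        selection_scores: dict[int, float] = {}
        if selection is None:
            selected = list(self.X.columns)
        elif selection == "rfe":
            if n_features is None:
                raise ValueError("rfe selection requires n_features")
            selected = rfe_select(
                self.X, self.y, n_features, algorithm=self.algorithm,
                params=self.params, seed=seed,
            )
        elif selection == "rfecv":
            selected, _, selection_scores = rfecv_select(
                self.X, self.y, min_features=min_features, folds=folds,
                algorithm=self.algorithm, params=self.params, seed=seed,
            )
        else:
            raise ValueError(f"unknown selection {selection!r}")
        bundle = train(
            self.X[selected], self.y, algorithm=self.algorithm,
            params=self.params, seed=seed, variant=self.variant,
        )
        return DeltaTmResults(self, bundle, selection, selection_scores, seed)


class DeltaTmResults:
    """Fit results: trained bundle, selected features, diagnostics."""

    def __init__(
        self,
        model: DeltaTmModel,
        bundle: ModelBundle,
        selection: str | None,
        selection_scores: dict[int, float],
        seed: int,
    ) -> None:
        self.model = model
        self.bundle = bundle
        self.selection = selection
        self.selection_scores = selection_scores
        self.seed = seed
        self.fitted_values = predict(bundle, model.X[bundle.feature_names])
        self.training_metrics = MetricsReport.compute(model.y, self.fitted_values)
        self.cv_report: CVReport | None = None

    @property
    def selected_features(self) -> list[str]:
        return list(self.bundle.feature_names)

    @property
    def feature_importances(self) -> pd.Series:
        imp = _gain_importances(self.bundle.estimator, len(self.selected_features))
        return pd.Series(imp, index=self.selected_features).sort_values(
            ascending=False
        )

    def predict(self, features: "FeatureTable | pd.DataFrame") -> np.ndarray:
        return predict(self.bundle, features)

    def cross_validate(self, folds: int = 10, grouping: str = "record") -> CVReport:
        """Cross-validate the selected feature set (cached)."""
        self.cv_report = cross_validate(
            self.model.X[self.selected_features],
            self.model.y,
            folds=folds,
            grouping=grouping,
            seed=self.seed,
            algorithm=self.model.algorithm,
            params=self.model.params,
            groups=self.model.groups,
        )
        return self.cv_report

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "dTm regression results",
            "=" * 58,
            f"{'algorithm':<24}{self.bundle.algorithm}",
            f"{'dataset variant':<24}{self.bundle.variant}",
            f"{'n observations':<24}{len(self.model.y)}",
            f"{'n features (selected)':<24}{len(self.selected_features)}"
            f" / {self.model.X.shape[1]}",
            f"{'selection':<24}{self.selection or 'none'}",
            f"{'seed':<24}{self.seed}",
            f"{'config hash':<24}{self.bundle.config_hash}",
            "-" * 58,
            f"{'':<14}{'MAE':>9}{'RMSE':>9}{'R2':>9}{'PCC':>9}",
            "{:<14}{:>9.3f}{:>9.3f}{:>9.3f}{:>9.3f}".format(
                "training",
                self.training_metrics.mae,
                self.training_metrics.rmse,
                self.training_metrics.r2,
                self.training_metrics.pcc,
            ),
        ]
        if self.cv_report is not None:
            p = self.cv_report.pooled
            lines.append(
                "{:<14}{:>9.3f}{:>9.3f}{:>9.3f}{:>9.3f}".format(
                    "CV (pooled)", p.mae, p.rmse, p.r2, p.pcc
                )
            )
        lines.append("=" * 58)
        return "\n".join(lines)
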