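"""Self-supervised L1-penalized regression on basal transcriptomes.

Samples are labeled with continuous sensitivity scores; a LASSO model
learns to reproduce those labels from expression alone, detaching the
prediction from the reference dataset. Features are standardized on the
training split only; the penalty is chosen by k-fold cross-validation on
the training split (``min`` rule: penalty minimizing CV error; ``1se``:
largest penalty within one standard error of that minimum) and performance
is reported on an untouched held-out split. The robustness check of the
original workflow — dropping every signature gene from the feature matrix
before splitting and retraining — is supported through ``exclude``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .core_io import CrossomixError


@dataclass
class LassoModel:
    """Fitted L1 model with its standardization parameters."""

    features: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    excluded_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coefficients):
            raise CrossomixError("coefficients do not align with feature names")

    def nonzero_features(self) -> list[str]:
        return [f for f, c in zip(self.features, self.coefficients) if c != 0.0]

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "excluded_features": self.excluded_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LassoModel":
        return cls(
            features=list(d["features"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            lambda_=float(d["lambda"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            excluded_features=list(d.get("excluded_features", [])),
        )


@dataclass
class FitReport:
    """Held-out performance of a trained model."""

    pearson_r: float
    rmse: float
    n_train: int
    n_test: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
        }


def _standardize(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (x - means) / sds


def train_lasso(
    x: pd.DataFrame,
    y: pd.Series,
    test_fraction: float = 0.2,
    k_folds: int = 10,
    lambda_rule: str = "min",
    exclude: set[str] | None = None,
    seed: int = 0,
    n_lambdas: int = 50,
    tol: float = 1e-4,
) -> tuple[LassoModel, FitReport]:
    """Train/test split, CV penalty selection, final fit and held-out report.

    ``x`` is samples x genes; ``y`` the per-sample continuous labels.
    Columns named in ``exclude`` are dropped before splitting.
    """
    if lambda_rule not in ("min", "1se"):
        raise CrossomixError("lambda_rule must be 'min' or '1se'")
    if not 0 < test_fraction < 1:
        raise CrossomixError("test_fraction must be in (0, 1)")
    y = y.reindex(x.index)
    if y.isna().any() or not np.isfinite(y.to_numpy(dtype=float)).all():
        raise CrossomixError("labels must be finite and cover all samples")
    n = x.shape[0]
    if n < 30:
        raise CrossomixError("need >= 30 samples")
    excluded = sorted(set(exclude or ()) & set(x.columns))
    if excluded:
        x = x.drop(columns=excluded)
    if x.shape[1] == 0:
        raise CrossomixError("all features excluded")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    if n_test < 5:
        raise CrossomixError("test split smaller than 5 samples")
    test_idx, train_idx = order[:n_test], order[n_test:]

    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    x_train, x_test = xv[train_idx], xv[test_idx]
    y_train, y_test = yv[train_idx], yv[test_idx]

    means = x_train.mean(axis=0)
    sds = x_train.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    xs_train = _standardize(x_train, means, sds)

    cv = KFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % (2**32 - 1))
    cv_fit = LassoCV(
        alphas=n_lambdas, cv=cv, tol=tol, max_iter=10_000, random_state=0
    ).fit(xs_train, y_train)
    if lambda_rule == "min":
        lam = float(cv_fit.alpha_)
    else:
        mean_mse = cv_fit.mse_path_.mean(axis=1)
        se = cv_fit.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_fit.mse_path_.shape[1])
        i_min = int(np.argmin(mean_mse))
        threshold = mean_mse[i_min] + se[i_min]
        # alphas_ are descending; pick the largest penalty within 1 SE
        within = np.nonzero(mean_mse <= threshold)[0]
        lam = float(cv_fit.alphas_[within.min()])

    model_fit = Lasso(alpha=lam, tol=tol, max_iter=10_000).fit(xs_train, y_train)
    model = LassoModel(
        features=x.columns.tolist(),
        coefficients=model_fit.coef_.copy(),
        intercept=float(model_fit.intercept_),
        lambda_=lam,
        feature_means=means,
        feature_sds=sds,
        excluded_features=excluded,
    )
    y_hat = _standardize(x_test, means, sds) @ model.coefficients + model.intercept
    r = float(stats.pearsonr(y_test, y_hat)[0]) if np.std(y_hat) > 0 else 0.0
    rmse = float(np.sqrt(np.mean((y_test - y_hat) ** 2)))
    report = FitReport(
        pearson_r=r, rmse=rmse,
        n_train=len(train_idx), n_test=len(test_idx), seed=seed,
    )
    return model, report


def predict_lasso(model: LassoModel, x_new: pd.DataFrame) -> pd.Series:
    """Predict scores for new samples; columns are aligned by feature name,
    extra columns are ignored and missing ones are an error."""
    missing = [f for f in model.features if f not in x_new.columns]
    if missing:
        raise CrossomixError(f"missing feature columns: {missing[:5]}")
    xv = x_new[model.features].to_numpy(dtype=float)
    y = _standardize(xv, model.feature_means, model.feature_sds) @ model.coefficients
    return pd.Series(y + model.intercept, index=x_new.index, name="predicted")


def stratified_report(
    y_true: pd.Series,
    y_pred: pd.Series,
    strata: pd.Series,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-stratum Pearson r and RMSE on held-out samples; strata with
    fewer than ``min_n`` members are skipped with a warning."""
    import logging

    logger = logging.getLogger(__name__)
    common = y_true.index.intersection(y_pred.index).intersection(strata.index)
    rows = {}
    for stratum in sorted(strata.loc[common].unique()):
        members = common[strata.loc[common] == stratum]
        if len(members) < min_n:
            logger.warning("stratum %r has %d < %d samples; skipped",
                           stratum, len(members), min_n)
            continue
        t = y_true.loc[members].to_numpy(dtype=float)
        p = y_pred.loc[members].to_numpy(dtype=float)
        r = float(stats.pearsonr(t, p)[0]) if (t.std() > 0 and p.std() > 0) else float("nan")
        rows[stratum] = {
            "n": len(members),
            "pearson_r": r,
            "rmse": float(np.sqrt(np.mean((t - p) ** 2))),
        }
    if not rows:
        raise CrossomixError(f"no stratum with >= {min_n} samples")
    return pd.DataFrame(rows).T
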