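"""L1-regularized linear regression from stride features to a scalar target.

The monitoring models are LASSO regressions: a linear map from the stride
feature table to peak Achilles tendon load (BW) or walking speed (m/s), with
an L1 penalty that performs feature selection and tames the collinearity of
stride statistics.  Following the statsmodels idiom, :class:`StrideLassoModel`
is constructed from data and ``fit()`` returns a :class:`StrideLassoResults`
carrying the coefficients, the selected penalty, the standardization
parameters, inner-CV diagnostics and a ``summary()`` table.

Feature standardization (z-scores) is computed from the training rows only,
so evaluation protocols that hold out subjects or stride halves never leak
test statistics into the scaler.  The penalty weight is selected by inner
K-fold cross-validation minimizing MAPE — the same metric the models are
judged by — over a log-spaced grid anchored at the data-dependent critical
penalty (the smallest weight that zeroes every coefficient).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

# MAPE agreement thresholds set a priori from clinical experience
EXCELLENT_MAPE_PCT = 10.0
ACCEPTABLE_MAPE_PCT = 20.0


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, in percent: 100*mean(|yhat-y|/y)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty target vector")
    if np.any(y_true <= 0):
        raise ValueError("MAPE requires strictly positive reference values")
    return float(100.0 * np.mean(np.abs(y_pred - y_true) / y_true))


def grade_mape(mape_pct: float) -> str:
    """Clinical agreement grade: <10% excellent, <20% acceptable, else unacceptable."""
    if mape_pct < EXCELLENT_MAPE_PCT:
        return "excellent"
    if mape_pct < ACCEPTABLE_MAPE_PCT:
        return "acceptable"
    return "unacceptable"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the LASSO fit.

    penalty_grid : explicit penalty weights, or None to build a 30-point log
        grid spanning ``penalty_span`` times the data's critical penalty.
    inner_cv_folds : folds of the inner CV that selects the penalty by MAPE.
    """

    penalty_grid: tuple[float, ...] | None = None
    n_penalties: int = 30
    penalty_span: tuple[float, float] = (1e-4, 1e1)
    inner_cv_folds: int = 5
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.penalty_grid is not None:
            if len(self.penalty_grid) == 0 or any(a <= 0 for a in self.penalty_grid):
                raise ValueError("penalty_grid must be non-empty and strictly positive")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if self.n_penalties < 1 or self.penalty_span[0] <= 0 or self.penalty_span[1] <= 0:
            raise ValueError("invalid penalty grid specification")


class StrideLassoModel:
    """LASSO regression model over a stride feature table.

    Parameters
    ----------
    endog : array-like, the target vector (strictly positive).
    exog : DataFrame or array of feature columns.
    feature_names : required when ``exog`` is a bare array.
    """

    def __init__(self, endog, exog, feature_names=None):
        if isinstance(exog, pd.DataFrame):
            self.feature_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if feature_names is None:
                feature_names = [f"x{i}" for i in range(X.shape[1])]
            self.feature_names = list(feature_names)
        y = np.asarray(endog, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("exog must be 2-D with one row per target value")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("features and target must be finite")
        if np.ptp(y) == 0:
            raise ValueError("zero-variance target")
        if np.any(y <= 0):
            raise ValueError("target must be strictly positive (MAPE-based selection)")
        self.exog = X
        self.endog = y

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, target: str, feature_columns: list[str] | None = None
    ) -> "StrideLassoModel":
        """Build from a joined feature/target table.

        When ``feature_columns`` is omitted, every column that is not a key,
        label or target column is used (see :mod:`bootgait.features`).
        """
        from .features import KEY_COLUMNS, TARGET_COLUMNS

        if target not in table.columns:
            raise KeyError(f"target column {target!r} not in table")
        if feature_columns is None:
            skip = set(KEY_COLUMNS) | set(TARGET_COLUMNS) | {target}
            feature_columns = [c for c in table.columns if c not in skip]
        missing = [c for c in feature_columns if c not in table.columns]
        if missing:
            raise KeyError(f"feature columns missing from table: {missing}")
        return cls(table[target], table[feature_columns])

    # -- fitting ------------------------------------------------------------

    def _standardize(self, config: ModelConfig):
        means = self.exog.mean(axis=0)
        sds = self.exog.std(axis=0)
        active = sds > 0  # zero-variance features carry no information
        if not config.standardize:
            means = np.zeros_like(means)
            sds = np.ones_like(sds)
            sds[~active] = 1.0
        safe_sds = np.where(active, sds, 1.0)
        Xs = (self.exog - means) / safe_sds
        Xs[:, ~active] = 0.0
        return Xs, means, safe_sds, active

    def _penalty_grid(self, Xs, y, config: ModelConfig) -> np.ndarray:
        if config.penalty_grid is not None:
            return np.sort(np.asarray(config.penalty_grid, dtype=float))[::-1]
        yc = y - y.mean()
        alpha_max = np.max(np.abs(Xs.T @ yc)) / len(y)
        if alpha_max <= 0:
            alpha_max = 1.0
        lo, hi = config.penalty_span
        return alpha_max * np.logspace(np.log10(hi), np.log10(lo), config.n_penalties)

    def fit(self, config: ModelConfig = ModelConfig()) -> "StrideLassoResults":
        """Standardize, select the penalty by inner-CV MAPE, refit, wrap results."""
        y = self.endog
        if len(y) < config.inner_cv_folds:
            raise ValueError(
                f"{len(y)} rows is fewer than inner_cv_folds={config.inner_cv_folds}"
            )
        Xs, means, sds, active = self._standardize(config)
        Xa = Xs[:, active]
        alphas = self._penalty_grid(Xs, y, config)

        cv_mape = np.zeros((config.inner_cv_folds, len(alphas)))
        splitter = KFold(n_splits=config.inner_cv_folds, shuffle=True, random_state=config.seed)
        with warnings.catch_warnings():
            # near-zero penalties on collinear stride features stop early;
            # a loose duality gap there does not affect penalty selection
            warnings.simplefilter("ignore", ConvergenceWarning)
            for k, (tr, va) in enumerate(splitter.split(Xa)):
                y_tr = y[tr]
                yc = y_tr - y_tr.mean()
                _, coefs, _ = lasso_path(Xa[tr], yc, alphas=alphas, max_iter=2000, tol=1e-3)
                preds = y_tr.mean() + Xa[va] @ coefs  # (n_va, n_alphas)
                err = np.abs(preds - y[va][:, None]) / y[va][:, None]
                cv_mape[k] = 100.0 * err.mean(axis=0)
        mean_mape = cv_mape.mean(axis=0)
        # ties break toward the larger penalty (sparser model); alphas descend
        best = int(np.argmin(mean_mape))
        alpha = float(alphas[best])

        est = Lasso(alpha=alpha, fit_intercept=True, max_iter=50_000, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xa, y)
        coef = np.zeros(len(self.feature_names))
        coef[active] = est.coef_

        diagnostics = pd.DataFrame(
            {
                "penalty": alphas,
                "cv_mape_mean": mean_mape,
                "cv_mape_sd": cv_mape.std(axis=0, ddof=1) if config.inner_cv_folds > 1 else 0.0,
            }
        )
        return StrideLassoResults(
            model=self,
            coefficients=pd.Series(coef, index=self.feature_names),
            intercept=float(est.intercept_),
            scaler_means=pd.Series(means, index=self.feature_names),
            scaler_sds=pd.Series(sds, index=self.feature_names),
            active_features=pd.Series(active, index=self.feature_names),
            selected_penalty=alpha,
            cv_diagnostics=diagnostics,
            config=config,
        )


@dataclass
class StrideLassoResults:
    """Fitted LASSO monitoring model: estimates, diagnostics and prediction."""

    coefficients: pd.Series
    intercept: float
    scaler_means: pd.Series
    scaler_sds: pd.Series
    active_features: pd.Series
    selected_penalty: float
    cv_diagnostics: pd.DataFrame
    config: ModelConfig | None = None
    model: StrideLassoModel | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def nnz(self) -> int:
        """Number of features retained (nonzero coefficients)."""
        return int(np.count_nonzero(self.coefficients.to_numpy()))

    @property
    def cv_mape(self) -> float:
        """Inner-CV MAPE (%) at the selected penalty."""
        d = self.cv_diagnostics
        return float(d.loc[d["penalty"] == self.selected_penalty, "cv_mape_mean"].iloc[0])

    def predict(self, exog) -> np.ndarray:
        """Predict targets for new feature rows; columns align by name."""
        if isinstance(exog, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in exog.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            X = exog[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_names):
                raise ValueError("feature count mismatch; pass a DataFrame to align by name")
        Xs = (X - self.scaler_means.to_numpy()) / self.scaler_sds.to_numpy()
        Xs[:, ~self.active_features.to_numpy()] = 0.0
        return self.intercept + Xs @ self.coefficients.to_numpy()

    def score_mape(self, exog, y_true) -> float:
        return mape(y_true, self.predict(exog))

    # -- reporting ----------------------------------------------------------

    def summary(self, top: int | None = None) -> str:
        """Plain-text summary table in the statsmodels style."""
        coefs = self.coefficients[self.coefficients != 0].sort_values(key=np.abs)[::-1]
        if top is not None:
            coefs = coefs.iloc[:top]
        lines = [
            "              Stride LASSO Regression Results",
            "=" * 62,
            f"No. observations: {len(self.model.endog) if self.model else 'n/a':>10}"
            f"    Selected penalty: {self.selected_penalty:.6g}",
            f"Features:         {len(self.feature_names):>10}    Nonzero coefs:    {self.nnz}",
            f"Inner-CV MAPE:    {self.cv_mape:>9.3f}%    Grade:            {grade_mape(self.cv_mape)}",
            "-" * 62,
            f"{'feature':<38}{'coef (std. units)':>22}",
            "-" * 62,
            f"{'(intercept)':<38}{self.intercept:>22.6g}",
        ]
        for name, value in coefs.items():
            lines.append(f"{name:<38}{value:>22.6g}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_coefficients(self, ax=None, top: int = 15):
        """Bar plot of the largest-magnitude retained coefficients."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.35 * top + 1))
        coefs = self.coefficients[self.coefficients != 0]
        coefs = coefs.reindex(coefs.abs().sort_values(ascending=True).index).iloc[-top:]
        ax.barh(coefs.index, coefs.to_numpy())
        ax.set_xlabel("coefficient (standardized units)")
        ax.axvline(0, color="k", lw=0.8)
        return ax

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "scaler_means": self.scaler_means.tolist(),
            "scaler_sds": self.scaler_sds.tolist(),
            "active_features": self.active_features.astype(bool).tolist(),
            "selected_penalty": self.selected_penalty,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StrideLassoResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        names = d["feature_names"]
        return cls(
            coefficients=pd.Series(d["coefficients"], index=names),
            intercept=float(d["intercept"]),
            scaler_means=pd.Series(d["scaler_means"], index=names),
            scaler_sds=pd.Series(d["scaler_sds"], index=names),
            active_features=pd.Series(d["active_features"], index=names, dtype=bool),
            selected_penalty=float(d["selected_penalty"]),
            cv_diagnostics=pd.DataFrame(
                {"penalty": [d["selected_penalty"]], "cv_mape_mean": [np.nan], "cv_mape_sd": [np.nan]}
            ),
        )


def fit_l1(
    table: pd.DataFrame, target_column: str, config: ModelConfig = ModelConfig()
) -> StrideLassoResults:
    """Convenience wrapper: build a :class:`StrideLassoModel` from a table and fit."""
    return StrideLassoModel.from_dataframe(table, target_column).fit(config)
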