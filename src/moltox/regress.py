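"""Regression models for aqueous solubility (LogS) and caco-2
permeability (LogP, log10 apparent permeability — not octanol/water).

Three schemes are supported, each with its own variable-selection rule
applied to a descriptor table:

* MLR — ordinary least squares Y = a1*X1 + ... + an*Xn + C; the final
  descriptors are those with the smallest coefficient p-values in the
  full fit (top 15 for LogS, top 11 for LogP by default);
* RFR — random-forest regression with mtry tuned by OOB error (start 14,
  step 0.5, improvement 1e-5, 100 trees), refit on the most important
  descriptors (top 40 for LogS, top 10 for LogP);
* PLSR — partial least squares, tolerant of collinear descriptors, with
  the component count chosen by 10-fold cross-validated RMSE (capped at
  10) and the top five descriptors retained by absolute standardized
  coefficient.

Model/results follow the statsmodels idiom: :class:`DescriptorRegression`
is the specification, ``fit()`` returns a :class:`RegressionResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .featurize import FeatureTable
from .select_opt import rank_importance, subset_topk, tune_mtry

logger = logging.getLogger(__name__)

Algorithm = Literal["mlr", "rfr", "plsr"]

# default selection sizes per target, as used for the published models
MLR_TOP_K = {"LogS": 15, "LogP": 11}
RFR_TOP_K = {"LogS": 40, "LogP": 10}
PLSR_N_VARS = 5

RFR_TUNE = dict(start=14, step_factor=0.5, improve=1e-5, ntree=100)


@dataclass(frozen=True)
class RegressionEval:
    """Blind-set evaluation: Pearson r and squared-correlation R².

    ``r_squared`` is the squared Pearson correlation between observed and
    predicted values; ``cod`` is the coefficient-of-determination variant
    (1 - SSE/SST), exposed but not the default headline number.
    """

    pearson_r: float
    r_squared: float
    cod: float
    pairs: tuple[tuple[float, float], ...]


def evaluate_regression(pairs: Sequence[tuple[float, float]]) -> RegressionEval:
    """Correlation metrics over (observed, predicted) pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 (observed, predicted) pairs")
    obs = np.array([p[0] for p in pairs], dtype=float)
    pred = np.array([p[1] for p in pairs], dtype=float)
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("zero variance in observed or predicted values")
    r = float(pearsonr(obs, pred).statistic)
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    return RegressionEval(r, r * r, 1.0 - sse / sst, tuple((float(o), float(p)) for o, p in pairs))


# --------------------------------------------------------------------------
# variable selection and fitting primitives
# --------------------------------------------------------------------------

def select_mlr_descriptors(table: FeatureTable, k: int) -> list[str]:
    """Rank descriptors by coefficient p-value in the full linear fit.

    When the full fit is rank-deficient (n <= p + 1) the ranking falls
    back to univariate regression p-values, with a log notice.
    """
    if table.labels is None:
        raise ValueError("table has no regression target")
    if k > len(table.feature_names):
        raise ValueError("k exceeds available descriptors")
    X = table.X.to_numpy(dtype=float)
    y = table.labels.to_numpy(dtype=float)
    n, p = X.shape
    if n > p + 1 and np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) == p + 1:
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        pvals = pd.Series(fit.pvalues[1:], index=table.feature_names)
    else:
        logger.info("full linear fit rank-deficient; ranking by univariate p-values")
        pvals = pd.Series(
            {
                name: sm.OLS(y, sm.add_constant(table.X[name].to_numpy())).fit().pvalues[1]
                for name in table.feature_names
            }
        )
    order = sorted(pvals.items(), key=lambda kv: (kv[1], kv[0]))
    return [name for name, _ in order[:k]]


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR: columns past the numerical rank are the dependents
        _, r, piv = linalg.qr(design, pivoting=True)
        culprits = [
            names[j - 1] for j in piv[rank:] if j > 0
        ]
        raise ValueError(f"exactly collinear descriptors: {sorted(culprits)}")


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class RegressionResults:
    """A fitted LogS/LogP regression with its selected descriptors."""

    def __init__(
        self,
        algorithm: Algorithm,
        target: str,
        features: list[str],
        predict_fn,
        params: pd.Series | None = None,
        intercept: float | None = None,
        estimator=None,
        extra: dict | None = None,
    ):
        self.algorithm = algorithm
        self.target = target
        self.features = features
        self._predict_fn = predict_fn
        self.params = params
        self.intercept = intercept
        self.estimator = estimator
        self.extra = extra or {}

    def predict(self, table: FeatureTable) -> pd.Series:
        """Predicted target values (log10 scale), one per table row."""
        missing = [f for f in self.features if f not in table.X.columns]
        if missing:
            raise KeyError(f"query table lacks descriptors: {missing[:5]}")
        if table.n_rows == 0:
            return pd.Series([], dtype=float)
        X = table.X[self.features].to_numpy(dtype=float)
        return pd.Series(self._predict_fn(X), index=table.X.index, name=self.target)

    def evaluate(self, table: FeatureTable) -> RegressionEval:
        if table.labels is None:
            raise ValueError("evaluation table has no observed values")
        pred = self.predict(table)
        return evaluate_regression(list(zip(table.labels.to_numpy(dtype=float), pred)))

    def summary(self) -> str:
        lines = [
            f"{self.algorithm.upper()} regression for {self.target}",
            "=" * 40,
            f"descriptors ({len(self.features)}): {', '.join(self.features[:8])}"
            + (" ..." if len(self.features) > 8 else ""),
        ]
        if self.params is not None:
            lines.append(f"intercept C = {self.intercept:+.6g}")
            for name, a in self.params.items():
                lines.append(f"  a[{name}] = {a:+.6g}")
        for k, v in self.extra.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


class DescriptorRegression:
    """Specification of a LogS/LogP regression on a descriptor table.

    Parameters
    ----------
    table : FeatureTable with a real-valued target in ``labels``.
    algorithm : {"mlr", "rfr", "plsr"}
    target : {"LogS", "LogP"} or any label; sets selection-size defaults.
    """

    def __init__(self, table: FeatureTable, algorithm: Algorithm = "mlr",
                 target: str = "LogS", **options):
        if table.labels is None:
            raise ValueError("table has no regression target")
        if algorithm not in ("mlr", "rfr", "plsr"):
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.table = table
        self.algorithm = algorithm
        self.target = target
        self.options = options

    def fit(self, seed: int = 0) -> RegressionResults:
        if self.algorithm == "mlr":
            k = self.options.get("k", MLR_TOP_K.get(self.target, 15))
            sel = select_mlr_descriptors(self.table, min(k, len(self.table.feature_names)))
            return fit_mlr(self.table, sel, target=self.target)
        if self.algorithm == "rfr":
            return fit_rfr(
                self.table,
                seed=seed,
                top_k=self.options.get("top_k", RFR_TOP_K.get(self.target, 40)),
                ntree=self.options.get("ntree", RFR_TUNE["ntree"]),
                target=self.target,
            )
        return fit_plsr(
            self.table,
            n_vars=self.options.get("n_vars", PLSR_N_VARS),
            seed=seed,
            target=self.target,
        )


def fit_mlr(
    table: FeatureTable, descriptors: Sequence[str], target: str = "LogS"
) -> RegressionResults:
    """Least-squares fit Y = sum(a_i X_i) + C on the chosen descriptors."""
    descriptors = list(descriptors)
    if table.labels is None:
        raise ValueError("table has no regression target")
    if table.n_rows <= len(descriptors) + 1:
        raise ValueError("need n > number of descriptors + 1")
    X = table.X[descriptors].to_numpy(dtype=float)
    y = table.labels.to_numpy(dtype=float)
    _check_collinearity(X, descriptors)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    intercept = float(fit.params[0])
    coefs = pd.Series(fit.params[1:], index=descriptors)

    def _predict(Xq: np.ndarray) -> np.ndarray:
        return Xq @ coefs.to_numpy() + intercept

    return RegressionResults(
        "mlr", target, descriptors, _predict, params=coefs, intercept=intercept,
        extra={"train_r_squared": float(fit.rsquared)},
    )


def fit_rfr(
    table: FeatureTable,
    target: str = "LogS",
    mtry: int | None = None,
    ntree: int = 100,
    seed: int = 0,
    top_k: int | None = None,
    tune: bool = True,
) -> RegressionResults:
    """Random-forest regression with importance-based descriptor selection.

    The forest is grown at an OOB-tuned mtry (hill-climb from 14 with
    step 0.5 and improvement 1e-5 by default), descriptors are ranked by
    permutation importance, and the final forest is refit on the top_k.
    """
    if table.labels is None:
        raise ValueError("table has no regression target")
    p = len(table.feature_names)
    if top_k is None:
        top_k = RFR_TOP_K.get(target, 40)
    top_k = min(top_k, p)
    if table.labels.nunique() == 1:
        # constant target: tuning/importance is vacuous; any forest
        # predicts the constant
        sel = list(table.feature_names[:top_k])
        rf = RandomForestRegressor(n_estimators=ntree, random_state=seed, n_jobs=1)
        rf.fit(table.X[sel].to_numpy(dtype=float), table.labels.to_numpy(dtype=float))
        return RegressionResults("rfr", target, sel, rf.predict, estimator=rf,
                                 extra={"mtry": None, "ntree": ntree})
    if tune:
        start = min(RFR_TUNE["start"] if mtry is None else mtry, p)
        mtry_full = tune_mtry(
            table, start=start, step_factor=RFR_TUNE["step_factor"],
            improve=RFR_TUNE["improve"], ntree=ntree, seed=seed,
        )
    else:
        mtry_full = mtry if mtry is not None else max(1, p // 3)
        if mtry_full > top_k:
            raise ValueError(f"mtry={mtry_full} exceeds top_k={top_k} after selection")
    ranking = rank_importance(table, ntree=ntree, seed=seed, mtry=mtry_full)
    sel = subset_topk(ranking, k=top_k)
    sub = table.subset_columns(sel)
    mtry_final = min(mtry_full, top_k)
    rf = RandomForestRegressor(
        n_estimators=ntree, max_features=mtry_final, oob_score=True,
        random_state=seed, n_jobs=1,
    )
    rf.fit(sub.X.to_numpy(dtype=float), sub.labels.to_numpy(dtype=float))

    return RegressionResults(
        "rfr", target, sel, rf.predict, estimator=rf,
        extra={"mtry": mtry_final, "ntree": ntree,
               "oob_r_squared": float(rf.oob_score_)},
    )


def _pls_n_components(X: np.ndarray, y: np.ndarray, cap: int, seed: int) -> int:
    """Pick the PLS component count by 10-fold CV RMSE (capped)."""
    n, p = X.shape
    cap = max(1, min(cap, p, n - 2))
    folds = min(10, n)
    best_c, best_rmse = 1, math.inf
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for c in range(1, cap + 1):
        sse = 0.0
        for tr, te in cv.split(X):
            pls = PLSRegression(n_components=c)
            pls.fit(X[tr], y[tr])
            sse += float(np.sum((pls.predict(X[te]).ravel() - y[te]) ** 2))
        rmse = math.sqrt(sse / n)
        if rmse < best_rmse - 1e-12:
            best_rmse, best_c = rmse, c
    return best_c


def fit_plsr(
    table: FeatureTable,
    target: str = "LogS",
    n_vars: int | None = PLSR_N_VARS,
    n_components: int | None = None,
    max_components: int = 10,
    seed: int = 0,
) -> RegressionResults:
    """Partial least squares with descriptor selection.

    A PLS model on all descriptors ranks them by absolute standardized
    regression coefficient; the top ``n_vars`` (default 5) are retained
    and the model refit. ``n_vars=None`` skips selection. PLS handles
    collinear descriptor blocks without error.
    """
    if table.labels is None:
        raise ValueError("table has no regression target")
    y = table.labels.to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("zero-variance target")
    X = table.X.to_numpy(dtype=float)
    if n_vars is not None:
        if n_vars > X.shape[1]:
            raise ValueError("n_vars exceeds available descriptors")
        c0 = n_components or _pls_n_components(X, y, max_components, seed)
        pls0 = PLSRegression(n_components=c0)
        pls0.fit(X, y)
        weight = np.abs(pls0.coef_.ravel()) * table.X.std(axis=0, ddof=1).to_numpy()
        order = sorted(
            zip(table.feature_names, weight), key=lambda kv: (-kv[1], kv[0])
        )
        sel = [name for name, _ in order[:n_vars]]
        sub = table.subset_columns(sel)
        Xs = sub.X.to_numpy(dtype=float)
    else:
        sel = list(table.feature_names)
        Xs = X
    c = n_components or _pls_n_components(Xs, y, max_components, seed)
    c = min(c, Xs.shape[1])
    pls = PLSRegression(n_components=c)
    pls.fit(Xs, y)

    def _predict(Xq: np.ndarray) -> np.ndarray:
        return pls.predict(Xq).ravel()

    return RegressionResults(
        "plsr", target, sel, _predict, estimator=pls,
        extra={"n_components": c},
    )


def predict_regression(results: RegressionResults, table: FeatureTable) -> pd.Series:
    """Predicted log-scale values for every row of ``table``."""
    return results.predict(table)
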