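"""Model selection and feature-subset optimization.

This module covers the screening stages that precede the final models:

* cross-validated ROC comparison of candidate learners (RF, SVM, KNN,
  CART) on identical fold partitions;
* PCA projection for dimension compression;
* feature importance as out-of-bag (OOB) mean decrease in accuracy — for
  each tree, the drop in OOB accuracy after permuting one feature's
  values, averaged over trees;
* hill-climb tuning of mtry (candidate features per split) driven by the
  OOB error estimate;
* an OOB-error grid over (feature subset, mtry, ntree) combinations;
* the Wilcoxon rank-sum screen for class-discriminating features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .classify import (
    CALL_THRESHOLD,
    PerformanceReport,
    confusion,
    performance,
    roc_auc,
)
from .featurize import POSITIVE_LABEL, FeatureTable

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 20  # exact rank-sum p below this combined sample size


# --------------------------------------------------------------------------
# algorithm comparison
# --------------------------------------------------------------------------

def _make_estimator(name: str, seed: int):
    if name == "RF":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if name == "SVM":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if name == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if name == "CART":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"algorithm {name!r} unavailable (choose RF, SVM, KNN, CART)")


def crossval_compare(
    table: FeatureTable,
    algorithms: Sequence[str] = ("RF", "SVM", "KNN", "CART"),
    folds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean ROC AUC per algorithm over identical stratified CV folds."""
    if table.labels is None or table.labels.nunique() != 2:
        raise ValueError("cross-validation comparison needs binary labels")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = table.X.to_numpy(dtype=np.float64)
    y = table.labels.to_numpy()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out: dict[str, float] = {}
    for name in algorithms:
        est = _make_estimator(name, seed)
        scores = cross_val_score(est, X, y, scoring="roc_auc", cv=cv, n_jobs=1)
        out[name] = float(np.mean(scores))
    return out


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaResult:
    """Loadings (features × components), row scores, variance fractions."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_project(table: FeatureTable, n_components: int) -> PcaResult:
    """PCA on the feature matrix.

    Descriptor columns are z-scored (heterogeneous physical scales);
    fingerprint bit columns are centered only. Components are orthonormal
    and explained-variance fractions non-increasing.
    """
    X = table.X.to_numpy(dtype=np.float64).copy()
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("zero-variance table: PCA undefined")
    is_desc = np.array([table.kinds[c] == "descriptor" for c in table.X.columns])
    scale = np.where(is_desc & (sd > 0), sd, 1.0)
    X = (X - X.mean(axis=0)) / scale
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        loadings=pd.DataFrame(pca.components_.T, index=table.X.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=table.X.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# --------------------------------------------------------------------------
# OOB machinery
# --------------------------------------------------------------------------

def _oob_error(
    X: np.ndarray, y: np.ndarray, mtry: int, ntree: int, seed: int, task: str
) -> float:
    """OOB misclassification rate (classification) or OOB MSE (regression)."""
    if task == "classification":
        rf = RandomForestClassifier(
            n_estimators=ntree, max_features=mtry, oob_score=True,
            random_state=seed, n_jobs=1,
        )
        rf.fit(X, y)
        return 1.0 - float(rf.oob_score_)
    rf = RandomForestRegressor(
        n_estimators=ntree, max_features=mtry, oob_score=True,
        random_state=seed, n_jobs=1,
    )
    rf.fit(X, y)
    pred = rf.oob_prediction_
    return float(np.mean((pred - y) ** 2))


def _task_of(table: FeatureTable) -> str:
    if table.labels is None:
        raise ValueError("table has no labels/target")
    n_distinct = table.labels.nunique()
    if n_distinct < 2:
        raise ValueError("single-class labels (or constant target)")
    return "classification" if n_distinct == 2 else "regression"


def tune_mtry(
    table: FeatureTable,
    start: int | None = None,
    step_factor: float = 2.0,
    improve: float = 0.05,
    ntree: int = 500,
    seed: int = 0,
) -> int:
    """Hill-climb mtry by OOB error, returning the best value visited.

    From ``start`` (default sqrt(p) for classification, p/3 for
    regression), mtry is repeatedly multiplied and divided by
    ``step_factor`` in each direction while the relative OOB improvement
    exceeds ``improve``. A ``step_factor`` below 1 is interpreted
    reciprocally, so the published regression setting (start 14, step 0.5,
    improvement 1e-5) walks the same lattice as step 2.
    """
    task = _task_of(table)
    p = len(table.feature_names)
    if start is None:
        start = max(1, int(math.isqrt(p)) if task == "classification" else p // 3)
    if start < 1 or start > p:
        raise ValueError(f"start mtry {start} outside [1, {p}]")
    if step_factor <= 0:
        raise ValueError("step_factor must be positive")
    if step_factor < 1:
        step_factor = 1.0 / step_factor
    if improve < 0:
        raise ValueError("improve must be >= 0")
    X = table.X.to_numpy(dtype=np.float64)
    y = table.labels.to_numpy()
    visited: dict[int, float] = {}

    def err(m: int) -> float:
        if m not in visited:
            visited[m] = _oob_error(X, y, m, ntree, seed, task)
        return visited[m]

    base = err(start)
    if step_factor > 1:
        for direction in (1.0 / step_factor, step_factor):
            prev, m = base, start
            while True:
                nxt = int(round(m * direction))
                nxt = min(max(nxt, 1), p)
                if nxt == m:
                    break
                e = err(nxt)
                gain = (prev - e) / prev if prev > 0 else 0.0
                if gain <= improve:
                    break
                prev, m = e, nxt
    best = min(visited.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


# --------------------------------------------------------------------------
# importance ranking (OOB mean decrease in accuracy)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceRanking:
    """Features sorted by importance, non-increasing; ties lexicographic."""

    entries: tuple[tuple[str, float], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.entries)


def _oob_mean_decrease(rf, X: np.ndarray, y: np.ndarray, seed: int, task: str) -> np.ndarray:
    """Per-feature OOB permutation importance, one permutation per tree."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    Xf = np.asarray(X, dtype=np.float32)
    totals = np.zeros(p)
    n_trees = 0
    for tree in rf.estimators_:
        # recover this tree's OOB rows from its bootstrap RNG
        tree_rng = np.random.RandomState(tree.random_state)
        sampled = tree_rng.randint(0, n, n)
        oob = np.setdiff1d(np.arange(n), sampled, assume_unique=False)
        if oob.size < 2:
            continue
        Xo = Xf[oob].copy()
        yo = y[oob]

        if task == "classification":
            classes = tree.classes_

            def score_of(mat: np.ndarray) -> float:
                raw = tree.tree_.predict(mat).reshape(mat.shape[0], -1)
                return float(np.mean(classes[np.argmax(raw, axis=1)] == yo))
        else:

            def score_of(mat: np.ndarray) -> float:
                raw = tree.tree_.predict(mat).reshape(mat.shape[0], -1)
                return -float(np.mean((raw[:, 0] - yo) ** 2))

        base = score_of(Xo)
        perm = rng.permutation(oob.size)
        for j in range(p):
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[perm]
            totals[j] += base - score_of(Xo)
            Xo[:, j] = saved
        n_trees += 1
    if n_trees == 0:
        raise RuntimeError("no tree had enough OOB samples")
    return totals / n_trees


def rank_importance(
    table: FeatureTable,
    ntree: int = 500,
    seed: int = 0,
    mtry: int | None = None,
) -> ImportanceRanking:
    """Rank features by OOB mean decrease in accuracy at the tuned mtry.

    mtry is optimized first by :func:`tune_mtry` unless given explicitly.
    For regression targets the score is the mean increase in OOB MSE.
    """
    task = _task_of(table)
    if task == "classification" and table.labels.nunique() < 2:
        raise ValueError("single-class labels")
    if mtry is None:
        mtry = tune_mtry(table, ntree=min(ntree, 200), seed=seed)
    X = table.X.to_numpy(dtype=np.float64)
    y = table.labels.to_numpy()
    cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
    rf = cls(n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    scores = _oob_mean_decrease(rf, X, y, seed, task)
    order = sorted(
        zip(table.feature_names, scores), key=lambda kv: (-kv[1], kv[0])
    )
    return ImportanceRanking(tuple((n, float(s)) for n, s in order))


def subset_topk(
    ranking: ImportanceRanking,
    k: int | None = None,
    fraction: float | None = None,
) -> list[str]:
    """First k (or round(fraction * length)) feature names in rank order."""
    if (k is None) == (fraction is None):
        raise ValueError("give exactly one of k or fraction")
    if fraction is not None:
        k = int(round(fraction * len(ranking)))
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds {len(ranking)} ranked features")
    return ranking.names[:k]


# --------------------------------------------------------------------------
# OOB grid search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridPoint:
    subset_name: str
    subset_size: int
    mtry: int
    ntree: int
    oob_error: float
    metrics: PerformanceReport

    def __post_init__(self):
        if not 0 <= self.oob_error <= 1:
            raise ValueError("oob_error outside [0, 1]")
        if self.mtry > self.subset_size:
            raise ValueError("mtry exceeds subset size")


@dataclass(frozen=True)
class GridResult:
    points: tuple[GridPoint, ...]
    best: GridPoint

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            m = p.metrics.as_dict()
            rows.append(
                {
                    "subset": p.subset_name,
                    "subset_size": p.subset_size,
                    "mtry": p.mtry,
                    "ntree": p.ntree,
                    "oob_error": p.oob_error,
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "precision": m["precision"],
                    "accuracy": m["accuracy"],
                    "mcc": m["mcc"],
                }
            )
        return pd.DataFrame(rows)


def oob_grid(
    table: FeatureTable,
    subsets: Mapping[str, Sequence[str]],
    mtry_values: Mapping[str, Sequence[int]] | Sequence[int],
    ntree_values: Sequence[int] = (200, 400, 600, 800, 1000),
    seed: int = 0,
) -> GridResult:
    """OOB error and metrics over (subset, mtry, ntree) combinations.

    ``subsets`` maps subset names to feature-name lists (usually built via
    :func:`subset_topk`); ``mtry_values`` is either one list shared by all
    subsets or a per-subset mapping. The best point minimizes OOB error,
    ties resolved toward smaller subset, then smaller mtry, then smaller
    ntree — independent of enumeration order.
    """
    if table.labels is None or table.labels.nunique() != 2:
        raise ValueError("OOB grid needs binary labels")
    if not subsets:
        raise ValueError("empty grid")
    y = table.labels.to_numpy()
    points: list[GridPoint] = []
    for sname in sorted(subsets):
        feats = list(subsets[sname])
        mtries = mtry_values[sname] if isinstance(mtry_values, Mapping) else mtry_values
        X = table.X[feats].to_numpy(dtype=np.float64)
        for mtry in mtries:
            if mtry > len(feats):
                raise ValueError(f"mtry={mtry} exceeds subset {sname} size {len(feats)}")
            for ntree in ntree_values:
                rf = RandomForestClassifier(
                    n_estimators=ntree, max_features=mtry, oob_score=True,
                    random_state=seed, n_jobs=1,
                )
                rf.fit(X, y)
                pos_col = list(rf.classes_).index(POSITIVE_LABEL)
                proba = rf.oob_decision_function_[:, pos_col]
                ok = ~np.isnan(proba)
                calls = (proba[ok] > CALL_THRESHOLD).astype(int)
                auc = (
                    roc_auc(y[ok], proba[ok])
                    if len(np.unique(y[ok])) == 2
                    else None
                )
                rep = performance(confusion(y[ok], calls), roc_auc=auc)
                points.append(
                    GridPoint(sname, len(feats), mtry, ntree,
                              1.0 - float(rf.oob_score_), rep)
                )
    if not points:
        raise ValueError("empty grid")
    best = min(points, key=lambda p: (p.oob_error, p.subset_size, p.mtry, p.ntree))
    return GridResult(tuple(points), best)


def build_hybrid(desc_features: Sequence[str], fp_features: Sequence[str]) -> list[str]:
    """Concatenate descriptor and fingerprint selections, order preserved."""
    if not desc_features or not fp_features:
        raise ValueError("both feature lists must be non-empty")
    for lst, what in ((desc_features, "descriptor"), (fp_features, "fingerprint")):
        if len(set(lst)) != len(lst):
            dup = next(n for n in lst if list(lst).count(n) > 1)
            raise ValueError(f"duplicate {what} feature name: {dup!r}")
    combined = list(desc_features) + list(fp_features)
    if len(set(combined)) != len(combined):
        raise ValueError("descriptor and fingerprint names collide; namespace them")
    return combined


# --------------------------------------------------------------------------
# Wilcoxon rank-sum screen
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenHit:
    feature: str
    p_value: float
    direction: str  # "higher-in-toxin" | "higher-in-nontoxin"


def ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small untied samples, else the
    tie-corrected normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= EXACT_RANKSUM_MAX_N and no_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def wilcoxon_screen(table: FeatureTable, alpha: float = 0.05) -> list[ScreenHit]:
    """Features whose class distributions differ at p <= alpha (inclusive).

    Two-sided rank-sum test per feature, raw (uncorrected) p-values;
    direction from the class-median difference (tie broken by means).
    Hits are sorted by ascending p, then name.
    """
    if table.labels is None or table.labels.nunique() != 2:
        raise ValueError("screen needs binary labels")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y = table.labels.to_numpy()
    pos = y == POSITIVE_LABEL
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("each class needs >= 2 observations")
    hits: list[ScreenHit] = []
    for name in table.feature_names:
        v = table.X[name].to_numpy(dtype=float)
        a, b = v[pos], v[~pos]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue  # constant feature: no evidence either way
        p = ranksum_pvalue(a, b)
        if p <= alpha:
            diff = np.median(a) - np.median(b)
            if diff == 0:
                diff = a.mean() - b.mean()
            hits.append(
                ScreenHit(name, p, "higher-in-toxin" if diff > 0 else "higher-in-nontoxin")
            )
    hits.sort(key=lambda h: (h.p_value, h.feature))
    return hits
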