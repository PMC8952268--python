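"""Step 2: quantitative prediction of process performance from bioindicators.

SMOTE class balancing, a three-algorithm regression benchmark (linear, radial
SVM, random forest) under 5-fold cross-validation, random-forest regression
with out-of-bag explained variance, non-HRT bioindicator discovery by
node-purity importance, the time-independent set algebra, and the
100-replicate subsampled RRMSE evaluation protocol.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVR

from .selection import BioindicatorSet
from .tables import TableError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

@dataclass
class SmoteSpec:
    """Synthetic minority oversampling toward a balanced target size."""

    k_neighbors: int = 5
    target_total: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise TableError("k_neighbors must be >= 1")
        if self.target_total < 2:
            raise TableError("target_total must be >= 2")


def smote_oversample(
    features: pd.DataFrame,
    labels,
    spec: SmoteSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Balance two classes to ~spec.target_total samples by SMOTE interpolation.

    New points are convex combinations ``x + u * (neighbor - x)`` with
    ``u ~ Uniform(0, 1)`` between a class member and one of its
    ``k_neighbors`` nearest same-class neighbors, so every synthetic sample
    lies on a segment inside its class.  Originals are preserved verbatim;
    both classes are grown to ``target_total / 2`` when below it.
    """
    y = np.asarray(list(labels))
    classes = np.unique(y)
    if len(classes) != 2:
        raise TableError("SMOTE here supports exactly two classes")
    rng = np.random.default_rng(spec.seed)
    per_class = spec.target_total // 2
    out_X = [features]
    out_y = [y]
    for cls in classes:
        mask = y == cls
        n = int(mask.sum())
        need = per_class - n
        if need <= 0:
            continue
        if n <= spec.k_neighbors:
            raise TableError(
                f"class {cls!r} has {n} samples; needs > k_neighbors={spec.k_neighbors} "
                "(use a smaller k)"
            )
        X = features.loc[mask].to_numpy(dtype=float)
        nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(X)
        _, idx = nn.kneighbors(X)  # column 0 is the point itself
        seeds = rng.integers(0, n, size=need)
        picks = rng.integers(1, spec.k_neighbors + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        base = X[seeds]
        neigh = X[idx[seeds, picks]]
        synth = base + u[:, None] * (neigh - base)
        out_X.append(pd.DataFrame(synth, columns=features.columns,
                                  index=[f"smote_{cls}_{i}" for i in range(need)]))
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return pd.concat(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(measured, predicted) -> float:
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.size == 0:
        raise TableError("measured/predicted must be equal-length and non-empty")
    return float(np.sqrt(np.mean((m - p) ** 2)))


def rrmse(measured, predicted) -> float:
    """Relative RMSE in percent: 100 * RMSE / mean(measured)."""
    m = np.asarray(measured, dtype=float)
    mean = m.mean() if m.size else 0.0
    if mean <= 0:
        raise TableError("mean of measured values must be positive for RRMSE")
    return 100.0 * rmse(measured, predicted) / mean


# ---------------------------------------------------------------------------
# Random-forest regression
# ---------------------------------------------------------------------------

@dataclass
class RFRegressorSpec:
    """Regression forest: 2000 trees, mtry = max(1, p // 3) unless set."""

    n_trees: int = 2000
    m_try: int | None = None  # None -> max(1, p // 3)
    seed: int = 0


@dataclass
class PredictionReport:
    parameter: str
    train_reactor: str
    test_reactor: str
    measured: np.ndarray
    predicted: np.ndarray
    rmse: float
    rrmse: float
    explained_variance_train: float  # percent, out-of-bag
    slope: float
    intercept: float
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"measured": self.measured, "predicted": self.predicted})


def _fit_regressor(X: np.ndarray, y: np.ndarray, spec: RFRegressorSpec) -> RandomForestRegressor:
    p = X.shape[1]
    mtry = spec.m_try if spec.m_try is not None else max(1, p // 3)
    model = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=min(mtry, p),
        oob_score=True,
        random_state=spec.seed % (2**31),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def oob_explained_variance(model: RandomForestRegressor, y: np.ndarray) -> float:
    """Percent variance explained from out-of-bag residuals, 100*(1 - MSE_oob/Var)."""
    var = float(np.var(y))
    if var == 0:
        return float("-inf")
    oob = model.oob_prediction_
    mse = float(np.mean((y - oob) ** 2))
    return 100.0 * (1.0 - mse / var)


def rf_regress(
    features_train: pd.DataFrame,
    target_train,
    features_test: pd.DataFrame,
    target_test,
    spec: RFRegressorSpec,
    parameter: str = "",
    train_reactor: str = "",
    test_reactor: str = "",
) -> PredictionReport:
    """Fit a regression forest on one reactor, evaluate on the other."""
    y_tr = np.asarray(list(target_train), dtype=float)
    y_te = np.asarray(list(target_test), dtype=float)
    if np.isnan(y_tr).any() or np.isnan(y_te).any():
        raise TableError(f"missing target values for {parameter!r}")
    model = _fit_regressor(features_train.to_numpy(dtype=float), y_tr, spec)
    expl = oob_explained_variance(model, y_tr)
    pred = model.predict(features_test.to_numpy(dtype=float))
    err = rmse(y_te, pred)
    rel = rrmse(y_te, pred) if y_te.mean() > 0 else float("nan")
    if np.std(pred) > 0 and np.std(y_te) > 0:
        fit = stats.linregress(y_te, pred)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    else:
        slope, intercept, r2 = float("nan"), float("nan"), 0.0
    return PredictionReport(
        parameter=parameter, train_reactor=train_reactor, test_reactor=test_reactor,
        measured=y_te, predicted=pred, rmse=err, rrmse=rel,
        explained_variance_train=expl, slope=slope, intercept=intercept, r_squared=r2,
    )


# ---------------------------------------------------------------------------
# Benchmarking
# ---------------------------------------------------------------------------

def benchmark_regressors(
    features: pd.DataFrame,
    target,
    spec: RFRegressorSpec,
    smote_labels=None,
    smote_spec: SmoteSpec | None = None,
    n_folds: int = 5,
) -> pd.DataFrame:
    """5-fold CV RMSE of linear / radial-SVM / random-forest regressors.

    When ``smote_labels`` is given the benchmark also runs on the
    SMOTE-balanced dataset (targets interpolated alongside features).
    Returns a long-format frame (algorithm, dataset, fold, rmse).
    """
    y = np.asarray(list(target), dtype=float)
    if len(y) < 2 * n_folds:
        raise TableError(f"need at least {2 * n_folds} samples for {n_folds}-fold CV")
    if np.var(y) == 0:
        raise TableError("constant target cannot be benchmarked")

    datasets = {"original": (features, y)}
    if smote_labels is not None:
        sm_spec = smote_spec or SmoteSpec(seed=spec.seed)
        aug = features.copy()
        aug["__target__"] = y
        bal_X, _ = smote_oversample(aug, smote_labels, sm_spec)
        datasets["balanced"] = (bal_X.drop(columns="__target__"),
                                bal_X["__target__"].to_numpy())

    rows = []
    for ds_name, (X_df, y_ds) in datasets.items():
        X = X_df.to_numpy(dtype=float)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=spec.seed % (2**31))
        for fold, (tr, te) in enumerate(kf.split(X)):
            for algo, make in (
                ("linear", lambda: LinearRegression()),
                ("svm_radial", lambda: SVR(kernel="rbf")),
                ("rf", lambda: RandomForestRegressor(
                    n_estimators=spec.n_trees,
                    max_features=max(1, X.shape[1] // 3),
                    random_state=(spec.seed + fold) % (2**31), n_jobs=1)),
            ):
                model = make()
                model.fit(X[tr], y_ds[tr])
                rows.append({
                    "algorithm": algo, "dataset": ds_name, "fold": fold,
                    "rmse": rmse(y_ds[te], model.predict(X[te])),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Non-HRT bioindicators and the time-independent set
# ---------------------------------------------------------------------------

def select_nonhrt_bioindicators(
    features: pd.DataFrame,
    target,
    spec: RFRegressorSpec,
    k: int = 15,
    parameter: str = "",
    train_reactor: str = "",
) -> BioindicatorSet:
    """Top-*k* ASVs by regression-forest node-purity importance for one parameter.

    Importance is the residual-sum-of-squares (node impurity) decrease of the
    regression forest over all ASVs; ties break by id as in classification.
    """
    y = np.asarray(list(target), dtype=float)
    if np.isnan(y).any():
        raise TableError(f"missing values in parameter {parameter!r}")
    if np.var(y) == 0:
        raise TableError(f"parameter {parameter!r} is constant")
    model = _fit_regressor(features.to_numpy(dtype=float), y, spec)
    imp = pd.Series(model.feature_importances_, index=features.columns)
    order = sorted(imp.index, key=lambda a: (-imp[a], a))[:k]
    return BioindicatorSet(
        asv_ids=order,
        train_reactor=train_reactor,
        target=parameter,
        importances={a: float(imp[a]) for a in order},
    )


def time_independent_set(
    hrt_set: BioindicatorSet,
    nonhrt_sets: list[BioindicatorSet],
) -> BioindicatorSet:
    """HRT bioindicators absent from every non-HRT set ("irrespective of time")."""
    covered = set()
    for s in nonhrt_sets:
        covered.update(s.asv_ids)
    kept = [a for a in hrt_set.asv_ids if a not in covered]
    if not kept:
        logger.warning("non-HRT bioindicators cover the whole HRT set")
    return BioindicatorSet(
        asv_ids=kept,
        train_reactor=hrt_set.train_reactor,
        target="HRT-irrespective-of-time",
        importances={a: hrt_set.importances.get(a, 0.0) for a in kept},
    )


# ---------------------------------------------------------------------------
# Replicate RRMSE protocol
# ---------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    parameter: str
    set_name: str
    mean_rrmse: float
    rrmse_values: np.ndarray
    subsample_size: int


def replicate_rrmse(
    features_train: pd.DataFrame,
    target_train,
    features_test: pd.DataFrame,
    target_test,
    indicator_set: BioindicatorSet,
    spec: RFRegressorSpec,
    n_replicates: int = 100,
    subsample_size: int = 4,
    parameter: str = "",
) -> ReplicateResult:
    """Mean RRMSE over random sub-selections of the bioindicator set.

    Each replicate draws ``subsample_size`` ASVs uniformly without
    replacement, fits a fresh forest on the training reactor and scores
    RRMSE on the test reactor.
    """
    ids = indicator_set.asv_ids
    if subsample_size > len(ids):
        raise TableError(
            f"subsample_size {subsample_size} exceeds set size {len(ids)}"
        )
    rng = np.random.default_rng(spec.seed)
    values = np.empty(n_replicates)
    y_tr = np.asarray(list(target_train), dtype=float)
    y_te = np.asarray(list(target_test), dtype=float)
    for r in range(n_replicates):
        chosen = list(rng.choice(ids, size=subsample_size, replace=False))
        rep_spec = RFRegressorSpec(spec.n_trees, spec.m_try, spec.seed + 1 + r)
        model = _fit_regressor(
            features_train[chosen].to_numpy(dtype=float), y_tr, rep_spec
        )
        pred = model.predict(features_test[chosen].to_numpy(dtype=float))
        values[r] = rrmse(y_te, pred)
    return ReplicateResult(
        parameter=parameter,
        set_name=f"{indicator_set.target}/{indicator_set.train_reactor}",
        mean_rrmse=float(values.mean()),
        rrmse_values=values,
        subsample_size=subsample_size,
    )
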