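"""Per-omics subtype classifiers that transfer across cohorts and platforms.

Transfer rests on rank-preserving discretization: training features are
median-centered, standardized, and cut into B equal-frequency bins; an
external cohort (possibly from a different platform) is mapped through the
*training* scaler and placed into the *training* bins, so any per-feature
monotone platform distortion that the standardization removes leaves the
ordinal representation unchanged.  Features are then pruned by random-forest
recursive feature elimination under repeated cross-validation, and a
gradient-boosted tree classifier is tuned by sequential model-based (GP
expected-improvement) search over its hyperparameters.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
)
from scipy import stats
from xgboost import XGBClassifier

from .views import OmicsView

log = logging.getLogger(__name__)

__all__ = [
    "ScalerModel", "BinningModel", "FeatureSelection", "SubtypeClassifier",
    "fit_scaler", "standardize_external", "fit_bins", "apply_bins",
    "rf_rfe_select", "tune_train_classifier", "predict_subtypes",
    "intersect_features", "save_classifier", "load_classifier",
]


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass
class ScalerModel:
    """Per-feature training median plus mean/sd of the median-centered values."""

    feature_ids: list[str]
    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # sd == 0 flags

    def transform(self, values: np.ndarray) -> np.ndarray:
        """(x - median - mean) / sd; constant features pass through centered."""
        centered = values - self.median[:, None] - self.mean[:, None]
        sd = np.where(self.constant, 1.0, self.sd)
        return centered / sd[:, None]


def fit_scaler(view: OmicsView) -> ScalerModel:
    """Learn the median-scaling + standardization moments on training data."""
    if view.missing_mask.any():
        raise ValueError("fit_scaler requires a fully observed (imputed) view")
    v = view.values
    median = np.median(v, axis=1)
    centered = v - median[:, None]
    mean = centered.mean(axis=1)
    sd = centered.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("fit_scaler(%s): %d constant feature(s) flagged",
                    view.name, int(constant.sum()))
    return ScalerModel(list(view.feature_ids), median, mean, sd, constant)


def standardize_external(values: np.ndarray, scaler: ScalerModel, feature_ids=None) -> np.ndarray:
    """Map external data through the training median/mean/sd (never its own)."""
    if feature_ids is not None:
        pos = {f: i for i, f in enumerate(scaler.feature_ids)}
        unknown = [f for f in feature_ids if f not in pos]
        if unknown:
            raise KeyError(f"features not in the scaler: {unknown[:10]}")
        idx = np.array([pos[f] for f in feature_ids])
        sub = ScalerModel(
            list(feature_ids), scaler.median[idx], scaler.mean[idx],
            scaler.sd[idx], scaler.constant[idx],
        )
        return sub.transform(np.asarray(values, dtype=float))
    return scaler.transform(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# equal-frequency binning
# ---------------------------------------------------------------------------


@dataclass
class BinningModel:
    """Per-feature interior quantile edges mapping reals to ordinal bins 1..B."""

    n_bins: int
    feature_ids: list[str]
    edges: list[np.ndarray]  # per feature, ascending, duplicates merged

    def effective_bins(self, feature: str) -> int:
        return len(self.edges[self.feature_ids.index(feature)]) + 1


def fit_bins(scaled: np.ndarray, n_bins: int, feature_ids=None) -> BinningModel:
    """Equal-frequency edges at the i/B quantiles (linear interpolation).

    Tied values can produce duplicate edges; these are merged so every value
    still maps to exactly one bin (fewer effective bins, logged).
    """
    scaled = np.asarray(scaled, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if n_bins > scaled.shape[1]:
        raise ValueError(
            f"n_bins={n_bins} exceeds the {scaled.shape[1]} training samples"
        )
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(scaled.shape[0])]
    qs = np.arange(1, n_bins) / n_bins
    edges = []
    merged = 0
    for row in scaled:
        e = np.quantile(row, qs, method="linear")
        uniq = np.unique(e)
        # an edge at or below the training minimum would leave bin 1 empty
        # (constant features otherwise land in bin 2); merge it away
        uniq = uniq[uniq > row.min()]
        merged += len(e) - len(uniq)
        edges.append(uniq)
    if merged:
        log.info("fit_bins: merged %d duplicate edge(s) due to ties", merged)
    return BinningModel(n_bins=n_bins, feature_ids=list(feature_ids), edges=edges)


def apply_bins(model: BinningModel, scaled: np.ndarray, feature_ids=None) -> np.ndarray:
    """Assign each value to its training bin: below the first edge -> 1, at or
    above the last -> B, interior by half-open intervals [e_{i-1}, e_i)."""
    scaled = np.asarray(scaled, dtype=float)
    if not np.all(np.isfinite(scaled)):
        raise ValueError("apply_bins requires finite values")
    if feature_ids is None:
        feature_ids = model.feature_ids
        if scaled.shape[0] != len(feature_ids):
            raise ValueError("matrix row count does not match the binning model")
    pos = {f: i for i, f in enumerate(model.feature_ids)}
    missing = [f for f in feature_ids if f not in pos]
    if missing:
        raise KeyError(f"features not in the binning model: {missing[:10]}")
    out = np.empty(scaled.shape, dtype=int)
    for i, f in enumerate(feature_ids):
        out[i] = np.searchsorted(model.edges[pos[f]], scaled[i], side="right") + 1
    return out


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


@dataclass
class FeatureSelection:
    ranked_features: list[str]          # by decreasing RF importance
    cv_curve: pd.DataFrame              # n_features, mean_accuracy, sd_accuracy
    chosen_n: int

    @property
    def selected(self) -> list[str]:
        return self.ranked_features[: self.chosen_n]


def _count_grid(p: int) -> list[int]:
    grid = []
    n = 1
    while n < p:
        grid.append(n)
        n *= 2
    grid.append(p)
    return grid


def rf_rfe_select(
    binned: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
    grid: list[int] | None = None,
) -> FeatureSelection:
    """Random-forest feature ranking + repeated-CV pruning of feature counts.

    ``binned`` is samples x features.  Candidate counts form a doubling grid;
    the chosen count is the smallest whose mean accuracy is within one
    standard deviation of the best mean — a mechanical elbow rule.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class size {counts.min()}"
        )
    x = binned.to_numpy(dtype=float)
    ranker = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    ranker.fit(x, y)
    order = np.argsort(-ranker.feature_importances_, kind="stable")
    ranked = [binned.columns[i] for i in order]

    grid = grid or _count_grid(x.shape[1])
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rows = []
    for n in grid:
        est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        scores = cross_val_score(est, x[:, order[:n]], y, cv=cv, scoring="accuracy")
        rows.append({"n_features": n, "mean_accuracy": scores.mean(),
                     "sd_accuracy": scores.std()})
    curve = pd.DataFrame(rows)
    best = curve["mean_accuracy"].idxmax()
    cutoff = curve.loc[best, "mean_accuracy"] - curve.loc[best, "sd_accuracy"]
    chosen_n = int(curve.loc[curve["mean_accuracy"] >= cutoff, "n_features"].min())
    log.info("rf_rfe_select: chose %d/%d features (best mean acc %.3f)",
             chosen_n, x.shape[1], curve.loc[best, "mean_accuracy"])
    return FeatureSelection(ranked_features=ranked, cv_curve=curve, chosen_n=chosen_n)


# ---------------------------------------------------------------------------
# boosted-tree training with sequential model-based hyperparameter search
# ---------------------------------------------------------------------------

# (name, low, high, log-scale, integer)
_SPACE = [
    ("learning_rate", 0.01, 0.3, True, False),
    ("max_depth", 2, 8, False, True),
    ("n_estimators", 50, 400, True, True),
    ("subsample", 0.5, 1.0, False, False),
    ("colsample_bytree", 0.5, 1.0, False, False),
    ("min_child_weight", 1.0, 10.0, False, False),
]


def _decode(u: np.ndarray) -> dict:
    params = {}
    for ui, (name, lo, hi, logscale, integer) in zip(u, _SPACE):
        if logscale:
            val = np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo)))
        else:
            val = lo + ui * (hi - lo)
        params[name] = int(round(val)) if integer else float(val)
    return params


def _xgb(params: dict, seed: int, n_classes: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        objective="multi:softprob" if n_classes > 2 else "binary:logistic",
        random_state=seed, n_jobs=1, tree_method="hist", verbosity=0,
    )


@dataclass
class SubtypeClassifier:
    """Everything needed to call subtypes on new, identically-preprocessed data."""

    selected_features: list[str]
    model: XGBClassifier
    hyperparameters: dict
    cv_accuracy: float
    cv_auc: float
    scaler: ScalerModel
    binning: BinningModel
    classes: np.ndarray = field(default_factory=lambda: np.array([]))
    search_history: pd.DataFrame | None = None


def tune_train_classifier(
    binned: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    budget: int = 50,
    seed: int = 0,
    scaler: ScalerModel | None = None,
    binning: BinningModel | None = None,
    n_initial: int = 10,
) -> SubtypeClassifier:
    """Tune an XGBoost classifier by GP expected-improvement search.

    The objective is mean stratified ``folds``-fold CV accuracy; after the
    search the best configuration is refit on all data.  AUC (one-vs-rest
    macro for k > 2) is recorded from out-of-fold predicted probabilities.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    y = np.searchsorted(classes, y_raw)
    x = binned.to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)

    def evaluate(u: np.ndarray) -> float:
        est = _xgb(_decode(u), seed, len(classes))
        return float(cross_val_score(est, x, y, cv=cv, scoring="accuracy").mean())

    us, scores = [], []
    for _ in range(min(n_initial, budget)):
        u = rng.uniform(size=len(_SPACE))
        us.append(u)
        scores.append(evaluate(u))
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5), alpha=1e-4, normalize_y=True, random_state=seed
    )
    while len(us) < budget:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP length-scale bound chatter
            gp.fit(np.vstack(us), -np.asarray(scores))  # GP minimizes
        cand = rng.uniform(size=(256, len(_SPACE)))
        mu, sd = gp.predict(cand, return_std=True)
        best = -max(scores)
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        us.append(u)
        scores.append(evaluate(u))

    best_i = int(np.argmax(scores))
    params = _decode(us[best_i])
    final = _xgb(params, seed, len(classes))
    proba = cross_val_predict(final, x, y, cv=cv, method="predict_proba")
    if len(classes) == 2:
        auc = float(roc_auc_score(y, proba[:, 1]))
    else:
        auc = float(roc_auc_score(y, proba, multi_class="ovr", average="macro"))
    acc = float(accuracy_score(y, np.argmax(proba, axis=1)))
    final.fit(x, y)
    history = pd.DataFrame(
        [dict(_decode(u), cv_accuracy=s) for u, s in zip(us, scores)]
    )
    log.info("tune_train_classifier: best CV accuracy %.4f, AUC %.4f "
             "(budget %d)", scores[best_i], auc, budget)
    return SubtypeClassifier(
        selected_features=list(binned.columns),
        model=final,
        hyperparameters=params,
        cv_accuracy=acc,
        cv_auc=auc,
        scaler=scaler,
        binning=binning,
        classes=classes,
        search_history=history,
    )


def predict_subtypes(clf: SubtypeClassifier, external: OmicsView) -> pd.DataFrame:
    """Scale, standardize, bin and classify an external cohort.

    Returns a DataFrame (sample_id, subtype, plus one score column per class).
    """
    if clf.scaler is None or clf.binning is None:
        raise ValueError("classifier was trained without scaler/binning artifacts")
    missing = [f for f in clf.selected_features if f not in set(external.feature_ids)]
    if missing:
        raise KeyError(
            f"external view lacks selected feature(s): {missing[:10]}"
        )
    if external.n_samples == 0:
        return pd.DataFrame(columns=["sample_id", "subtype"])
    sub = external.subset(features=clf.selected_features)
    if sub.missing_mask.any():
        raise ValueError("external view must be fully observed (impute first)")
    z = standardize_external(sub.values, clf.scaler, feature_ids=clf.selected_features)
    b = apply_bins(clf.binning, z, feature_ids=clf.selected_features)
    proba = clf.model.predict_proba(b.T)
    labels = clf.classes[np.argmax(proba, axis=1)]
    out = pd.DataFrame({"sample_id": sub.sample_ids, "subtype": labels})
    for j, c in enumerate(clf.classes):
        out[f"score_{c}"] = proba[:, j]
    return out


def intersect_features(training: OmicsView, external: OmicsView) -> list[str]:
    """Common feature ids, in training order; empty intersection is an error."""
    ext = set(external.feature_ids)
    common = [f for f in training.feature_ids if f in ext]
    if not common:
        raise ValueError(
            f"views {training.name!r} and {external.name!r} share no features"
        )
    return common


def save_classifier(clf: SubtypeClassifier, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"schema": 1, "classifier": clf}, fh)


def load_classifier(path) -> SubtypeClassifier:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("schema") != 1:
        raise ValueError("unsupported classifier archive schema")
    return payload["classifier"]
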