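"""Univariate Youden-threshold models and multivariate classifiers assessed by
repeated stratified cross-validation.

Univariate models pick, on each training portion, the cut-point maximizing the
Youden index J = sensitivity + specificity - 1 (searching midpoints of
consecutive sorted unique values in both orientations) and are scored on the
held-out fold. Multivariate models (six families: linear discriminant,
linear/quadratic/cubic SVM, classification tree, KNN, plus random forest and
logistic regression for the literature presets) are fitted per trial, their
decision threshold chosen on training scores by the same Youden criterion,
and scored on the held-out fold; every non-empty subset of the selected
feature pool can be swept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selection import SplitScheme, mann_whitney_p

__all__ = [
    "ThresholdModel",
    "ClassifierSpec",
    "CVReport",
    "youden_threshold",
    "evaluate_univariate_cv",
    "evaluate_multivariate_cv",
    "smote_oversample",
    "train_final_model",
    "FinalModel",
    "univariate_association_report",
    "PROPOSED_FAMILIES",
    "hectors_classifier_spec",
    "jin_classifier_spec",
]

#: The six classifier families compared for the proposed model.
PROPOSED_FAMILIES = (
    "linear_discriminant",
    "svm_linear",
    "svm_quadratic",
    "svm_cubic",
    "tree",
    "knn",
)


# ---------------------------------------------------------------------------
# univariate threshold models
# ---------------------------------------------------------------------------

@dataclass
class ThresholdModel:
    """Single-feature cut-point classifier.

    ``direction`` is 'above' when values above the threshold are called
    positive and 'below' otherwise; it is fixed at training time.
    """

    feature: str
    threshold: float
    direction: str  # 'above' | 'below'
    youden: float = 0.0

    def predict(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v > self.threshold) if self.direction == "above" else (v < self.threshold)


def _sens_spec(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    y = np.asarray(labels, dtype=bool)
    sens = float(pred[y].mean()) if y.any() else np.nan
    spec = float((~pred[~y]).mean()) if (~y).any() else np.nan
    return sens, spec


def youden_threshold(
    values: np.ndarray, labels: np.ndarray, feature: str = ""
) -> ThresholdModel:
    """Exhaustive Youden-index cut-point search.

    Candidates are midpoints of consecutive sorted unique values plus
    sentinels beyond the data range, in both orientations. Ties are broken
    toward higher sensitivity, then lower threshold, then the 'above'
    orientation.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes required to fit a threshold")
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for direction in ("above", "below"):
        pos = v[y][:, None]
        neg = v[~y][:, None]
        if direction == "above":
            sens = (pos > cands).sum(axis=0) / n_pos
            spec = (neg <= cands).sum(axis=0) / n_neg
        else:
            sens = (pos < cands).sum(axis=0) / n_pos
            spec = (neg >= cands).sum(axis=0) / n_neg
        j = sens + spec - 1.0
        for t, jj, ss in zip(cands, j, sens):
            key = (jj, ss, -t, direction == "above")
            if best is None or key > best[0]:
                best = (key, ThresholdModel(feature, float(t), direction, float(jj)))
    return best[1]


@dataclass
class CVReport:
    """Per-trial sensitivity/specificity with mean +/- SD summaries.

    Trials whose held-out fold lacks one class contribute NaN to the affected
    metric and are excluded from the means (``n_undefined`` counts them).
    """

    model: str
    features: tuple[str, ...]
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)

    @property
    def mean_sens(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def sd_sens(self) -> float:
        return float(np.nanstd(self.sensitivity))

    @property
    def mean_spec(self) -> float:
        return float(np.nanmean(self.specificity))

    @property
    def sd_spec(self) -> float:
        return float(np.nanstd(self.specificity))

    @property
    def mean_youden(self) -> float:
        return self.mean_sens + self.mean_spec - 1.0

    @property
    def n_trials(self) -> int:
        return len(self.sensitivity)

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.sensitivity).sum() + np.isnan(self.specificity).sum())

    def summary(self) -> dict:
        return {
            "model": self.model,
            "features": list(self.features),
            "mean_sensitivity": self.mean_sens,
            "sd_sensitivity": self.sd_sens,
            "mean_specificity": self.mean_spec,
            "sd_specificity": self.sd_spec,
            "mean_youden": self.mean_youden,
            "n_trials": self.n_trials,
            "n_undefined": self.n_undefined,
        }


def evaluate_univariate_cv(
    values: np.ndarray, labels: np.ndarray, splits: SplitScheme, feature: str = ""
) -> CVReport:
    """Fit a Youden threshold on each training portion and score the held-out
    fold; report per-trial sensitivity/specificity over all trials."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    sens = np.empty(splits.n_trials)
    spec = np.empty(splits.n_trials)
    for t, (_, _, tr, va) in enumerate(splits.trials()):
        model = youden_threshold(v[tr], y[tr], feature)
        s, p = _sens_spec(model.predict(v[va]), y[va])
        sens[t], spec[t] = s, p
    return CVReport(model=f"youden[{feature}]", features=(feature,), sensitivity=sens, specificity=spec)


# ---------------------------------------------------------------------------
# multivariate classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its training-time policies.

    ``oversampling='smote'`` balances classes inside each training portion;
    ``decision_threshold_policy='youden_on_train'`` re-optimizes the score
    cut-point on training scores, 'default' keeps the family's native 0.5 /
    0 decision rule. ``zscore_inputs`` standardizes columns with
    training-portion statistics.
    """

    family: str
    hyperparameters: tuple = ()
    oversampling: str = "none"
    decision_threshold_policy: str = "youden_on_train"
    zscore_inputs: bool = False

    def build(self, seed: int = 0):
        hp = dict(self.hyperparameters)
        builders = {
            "linear_discriminant": lambda: LinearDiscriminantAnalysis(**hp),
            "svm_linear": lambda: SVC(kernel="linear", C=hp.get("C", 1.0)),
            "svm_quadratic": lambda: SVC(
                kernel="poly", degree=2, coef0=1.0, C=hp.get("C", 1.0)
            ),
            "svm_cubic": lambda: SVC(
                kernel="poly", degree=3, coef0=1.0, C=hp.get("C", 1.0)
            ),
            "tree": lambda: DecisionTreeClassifier(random_state=seed, **hp),
            "knn": lambda: KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5)),
            "random_forest": lambda: RandomForestClassifier(
                random_state=seed,
                **{
                    "max_depth": 16,
                    "max_features": None,
                    "min_samples_leaf": 2,
                    "min_samples_split": 2,
                    "max_leaf_nodes": 16,
                    **hp,
                },
            ),
            "logistic": lambda: LogisticRegression(max_iter=1000, **hp),
        }
        if self.family not in builders:
            raise ValueError(f"unknown classifier family {self.family!r}")
        return builders[self.family]()


def hectors_classifier_spec() -> ClassifierSpec:
    """Random forest (depth 16, no feature subsampling, min leaf 2, min split
    2, max 16 leaves) with SMOTE oversampling and native decision rule."""
    return ClassifierSpec(
        family="random_forest", oversampling="smote", decision_threshold_policy="default"
    )


def jin_classifier_spec() -> ClassifierSpec:
    """Logistic regression on z-normalized inputs with native decision rule."""
    return ClassifierSpec(
        family="logistic", decision_threshold_policy="default", zscore_inputs=True
    )


def smote_oversample(
    features: np.ndarray, labels: np.ndarray, rng: np.random.Generator, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: new minority samples are interpolated
    at a uniform random position on segments joining each (randomly chosen)
    minority sample to one of its ``k`` minority nearest neighbours, until the
    classes are balanced."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    x_min = x[y == minority]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return x.copy(), y.copy()
    if len(x_min) < 2:
        raise ValueError("minority class must have at least 2 samples for SMOTE")
    k_eff = min(k, len(x_min) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x_min)
    _, idx = nn.kneighbors(x_min)
    base = rng.integers(0, len(x_min), size=n_needed)
    pick = rng.integers(1, k_eff + 1, size=n_needed)
    gaps = rng.uniform(0.0, 1.0, size=n_needed)[:, None]
    neighbors = x_min[idx[base, pick]]
    synthetic = x_min[base] + gaps * (neighbors - x_min[base])
    return (
        np.vstack([x, synthetic]),
        np.concatenate([y, np.full(n_needed, minority, dtype=int)]),
    )


def _scores(clf, x: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(x), dtype=float)
    return np.asarray(clf.predict_proba(x)[:, 1], dtype=float)


def _fit_and_score_trial(
    spec: ClassifierSpec,
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    x_va: np.ndarray,
    rng: np.random.Generator,
    seed: int,
) -> np.ndarray:
    """Fit one training portion and return boolean validation predictions."""
    if spec.zscore_inputs:
        mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        x_tr = (x_tr - mu) / sd
        x_va = (x_va - mu) / sd
    if spec.oversampling == "smote":
        x_tr, y_tr = smote_oversample(x_tr, y_tr, rng)
    clf = spec.build(seed=seed)
    clf.fit(x_tr, y_tr)
    if spec.decision_threshold_policy == "youden_on_train":
        s_tr = _scores(clf, x_tr)
        thr = youden_threshold(s_tr, y_tr, feature="score")
        return thr.predict(_scores(clf, x_va))
    return np.asarray(clf.predict(x_va), dtype=bool)


def evaluate_multivariate_cv(
    features: pd.DataFrame,
    labels: np.ndarray,
    splits: SplitScheme,
    specs: list[ClassifierSpec],
    pool: list[str],
    seed: int = 0,
    combinations: str = "all",
) -> list[CVReport]:
    """Sweep classifier specs over feature combinations from the pool.

    ``combinations='all'`` evaluates every non-empty subset of ``pool``;
    ``'full'`` only the complete pool. Reports are returned ranked by
    descending mean Youden index.
    """
    from itertools import combinations as combos

    if not pool:
        raise ValueError("feature pool is empty")
    y = np.asarray(labels, dtype=int)
    if combinations == "all":
        subsets = [
            c for r in range(1, len(pool) + 1) for c in combos(pool, r)
        ]
    elif combinations == "full":
        subsets = [tuple(pool)]
    else:
        raise ValueError("combinations must be 'all' or 'full'")

    import zlib

    reports: list[CVReport] = []
    for spec in specs:
        for subset in subsets:
            x = features.loc[:, list(subset)].to_numpy(dtype=float)
            tag = zlib.crc32(repr((spec.family, subset)).encode())
            rng = np.random.default_rng(np.random.SeedSequence((seed, tag)))
            sens = np.empty(splits.n_trials)
            spec_arr = np.empty(splits.n_trials)
            for t, (_, _, tr, va) in enumerate(splits.trials()):
                pred = _fit_and_score_trial(
                    spec, x[tr], y[tr], x[va], rng, seed=int(seed % (2**31))
                )
                s, p = _sens_spec(pred, y[va])
                sens[t], spec_arr[t] = s, p
            reports.append(
                CVReport(
                    model=spec.family,
                    features=subset,
                    sensitivity=sens,
                    specificity=spec_arr,
                )
            )
    reports.sort(key=lambda r: (-r.mean_youden, r.model, r.features))
    return reports


# ---------------------------------------------------------------------------
# final shareable model
# ---------------------------------------------------------------------------

@dataclass
class FinalModel:
    """Whole-cohort model serialized to a portable JSON artifact.

    Supported families: univariate 'threshold', 'linear_discriminant' and
    'logistic' (the shareable proposed model is a linear discriminant); each
    stores explicit per-feature weights, intercept and score threshold so
    reloading reproduces predictions bitwise.
    """

    family: str
    features: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    threshold: float
    direction: str = "above"
    zscore_mu: np.ndarray | None = None
    zscore_sd: np.ndarray | None = None

    def scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.zscore_mu is not None:
            x = (x - self.zscore_mu) / self.zscore_sd
        return x @ self.weights + self.intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        s = self.scores(x)
        return (s > self.threshold) if self.direction == "above" else (s < self.threshold)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "family": self.family,
            "features": list(self.features),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "direction": self.direction,
            "zscore_mu": None if self.zscore_mu is None else self.zscore_mu.tolist(),
            "zscore_sd": None if self.zscore_sd is None else self.zscore_sd.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FinalModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            family=obj["family"],
            features=tuple(obj["features"]),
            weights=np.asarray(obj["weights"], dtype=float),
            intercept=float(obj["intercept"]),
            threshold=float(obj["threshold"]),
            direction=obj["direction"],
            zscore_mu=None if obj["zscore_mu"] is None else np.asarray(obj["zscore_mu"]),
            zscore_sd=None if obj["zscore_sd"] is None else np.asarray(obj["zscore_sd"]),
        )


def train_final_model(
    features: pd.DataFrame,
    labels: np.ndarray,
    spec: ClassifierSpec,
    pool: list[str],
) -> FinalModel:
    """Fit ``spec`` on the entire cohort and package it as a portable
    artifact. Only families with an explicit linear score are serializable
    ('threshold' single-feature models, 'linear_discriminant', 'logistic');
    other families raise ``ValueError``."""
    missing = [f for f in pool if f not in features.columns]
    if missing:
        raise ValueError(f"unresolved feature names: {missing}")
    x = features.loc[:, pool].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)

    if spec.family == "threshold":
        if len(pool) != 1:
            raise ValueError("threshold models take exactly one feature")
        thr = youden_threshold(x[:, 0], y, feature=pool[0])
        return FinalModel(
            family="threshold",
            features=tuple(pool),
            weights=np.array([1.0]),
            intercept=0.0,
            threshold=thr.threshold,
            direction=thr.direction,
        )

    mu = sd = None
    xin = x
    if spec.zscore_inputs:
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        xin = (x - mu) / sd
    if spec.family not in ("linear_discriminant", "logistic"):
        raise ValueError(
            f"family {spec.family!r} has no portable JSON serialization; "
            "use linear_discriminant, logistic or threshold"
        )
    clf = spec.build()
    clf.fit(xin, y)
    weights = np.asarray(clf.coef_, dtype=float).ravel()
    intercept = float(np.ravel(clf.intercept_)[0])
    scores = xin @ weights + intercept
    if spec.decision_threshold_policy == "youden_on_train":
        thr = youden_threshold(scores, y, feature="score")
        threshold, direction = thr.threshold, thr.direction
    else:
        threshold, direction = 0.0, "above"
    return FinalModel(
        family=spec.family,
        features=tuple(pool),
        weights=weights,
        intercept=intercept,
        threshold=threshold,
        direction=direction,
        zscore_mu=mu,
        zscore_sd=sd,
    )


def univariate_association_report(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_names: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Whole-cohort Mann-Whitney p per feature, with significance flags.

    Missing features are listed as unavailable rather than dropped.
    """
    y = np.asarray(labels, dtype=bool)
    rows = []
    for name in feature_names:
        if name not in features.columns:
            rows.append({"feature": name, "p_value": np.nan, "significant": False, "available": False})
            continue
        v = features[name].to_numpy(dtype=float)
        if np.isnan(v).any():
            rows.append({"feature": name, "p_value": np.nan, "significant": False, "available": False})
            continue
        p = mann_whitney_p(v[y], v[~y])
        rows.append({"feature": name, "p_value": p, "significant": bool(p <= alpha), "available": True})
    return pd.DataFrame(rows, columns=["feature", "p_value", "significant", "available"])
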