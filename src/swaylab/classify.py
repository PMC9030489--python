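"""Stable/unstable posture classification.

Feature sets are computed per sensor per body axis on the *raw*
acceleration (no filtering, matching how the statistical features were
defined for the ML stage):

* FS1 — seven time-domain moments: mean, range, variance, standard
  deviation, RMS, skewness, kurtosis;
* FS2 — magnitudes of the first five nonzero-frequency FFT
  coefficients (DC excluded, since it duplicates the mean);
* FS3 — FS1 and FS2 together (twelve features per sensor-axis).

Trials are labelled stable/unstable from the subjective rating (PPS:
stable iff < 5.0) or from the COP mean AP velocity (stable iff below
the median; the median itself is unstable). Features are z-scored over
the full dataset by default (the pipeline order the tables were built
with; a leakage-safe per-fold variant is one flag away), then evaluated
with seeded stratified 5-fold cross-validation over a fixed roster of
eleven classifiers, reporting percent accuracy (TP+TN)/(P+N)*100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .design import SENSOR_CONFIGS
from .measures import trial_copv_ap
from .simulate import StudyDataset

AXES = ("AP", "ML", "IS")
FS1_FEATURES = ("mean", "range", "variance", "std", "rms", "skewness", "kurtosis")
FS2_FEATURES = ("fft1", "fft2", "fft3", "fft4", "fft5")
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "FS1": FS1_FEATURES,
    "FS2": FS2_FEATURES,
    "FS3": FS1_FEATURES + FS2_FEATURES,
}

CLASSIFIER_ROSTER = (
    "KNN-CityBlock",
    "KNN-Euclidean",
    "GaussianNB",
    "KernelNB",
    "LogisticRegression",
    "DiscriminantAnalysis",
    "SVM-Linear",
    "SVM-Cubic",
    "DecisionTree",
    "BaggedTrees",
    "OptimizedEnsemble",
)


def accuracy_eq1(tp: int, tn: int, p: int, n: int) -> float:
    """Percent accuracy (TP + TN) / (P + N) * 100."""
    if p + n == 0:
        raise ValueError("empty sample")
    return (tp + tn) / (p + n) * 100.0


def _axis_features(x: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised per-axis features for a (trials, samples) block."""
    m = x.mean(axis=1)
    xc = x - m[:, None]
    var = (xc**2).mean(axis=1)
    sd = np.sqrt(var)
    m3 = (xc**3).mean(axis=1)
    m4 = (xc**4).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(sd > 0, m3 / sd**3, 0.0)  # degenerate -> 0
        kurt = np.where(var > 0, m4 / var**2 - 3.0, 0.0)
    fft_mag = np.abs(np.fft.rfft(x, axis=1)[:, 1:6])
    out = {
        "mean": m,
        "range": x.max(axis=1) - x.min(axis=1),
        "variance": var,
        "std": sd,
        "rms": np.sqrt((x**2).mean(axis=1)),
        "skewness": skew,
        "kurtosis": kurt,
    }
    for i in range(5):
        out[f"fft{i + 1}"] = fft_mag[:, i]
    return out


def resolve_sensors(sc: str | list[str]) -> list[str]:
    if isinstance(sc, str):
        if sc not in SENSOR_CONFIGS:
            raise ValueError(f"unknown sensor configuration {sc!r}")
        return list(SENSOR_CONFIGS[sc])
    return list(sc)


def extract_features(
    dataset: StudyDataset,
    sensors: str | list[str],
    feature_set: str = "FS3",
) -> pd.DataFrame:
    """Feature matrix for all trials: columns ``sensor|axis|feature``.

    Row order follows ``dataset.trials``. Widths per sensor are 21
    (FS1), 15 (FS2) and 36 (FS3).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    feats = FEATURE_SETS[feature_set]
    sensor_list = resolve_sensors(sensors)
    cols: dict[str, np.ndarray] = {}
    for sensor in sensor_list:
        block = np.stack([t.acc[sensor] for t in dataset.trials])  # (T, n, 3)
        for ax_idx, axis in enumerate(AXES):
            per_axis = _axis_features(block[:, :, ax_idx])
            for feat in feats:
                cols[f"{sensor}|{axis}|{feat}"] = per_axis[feat]
    return pd.DataFrame(cols)


def zscore(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Columnwise (x - mean) / SD with population SD; zero-variance
    columns become all-zeros and are returned as flagged names."""
    mean = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0)
    flagged = list(features.columns[sd == 0])
    sd_safe = sd.replace(0.0, 1.0)
    out = (features - mean) / sd_safe
    out[flagged] = 0.0
    return out, flagged


def label_trials(
    dataset: StudyDataset,
    criterion: str = "pps",
    cop_cutoff: float = 10.0,
) -> pd.Series:
    """Binary stable(0)/unstable(1) labels per trial.

    PPS criterion: unstable iff rating >= 5.0. COPV_AP criterion:
    unstable iff the trial's COP mean AP velocity >= the median over
    all trials (the boundary value is unstable), which balances the
    classes to within one trial.
    """
    if criterion == "pps":
        vals = np.array([t.pps for t in dataset.trials])
        labels = (vals >= 5.0).astype(int)
    elif criterion == "copv_ap":
        vals = np.array(
            [trial_copv_ap(t, cutoff=cop_cutoff) for t in dataset.trials]
        )
        labels = (vals >= np.median(vals)).astype(int)
    else:
        raise ValueError(f"unknown labeling criterion {criterion!r}")
    return pd.Series(labels, name="label")


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with a per-feature Gaussian kernel density estimate.

    Class-conditional densities are products of univariate KDEs with
    Silverman's rule-of-thumb bandwidth — the open equivalent of a
    kernel naive Bayes classifier.
    """

    def __init__(self, min_bandwidth: float = 1e-3):
        self.min_bandwidth = min_bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._train = {}
        self._bandwidth = {}
        self._log_prior = {}
        for c in self.classes_:
            xc = X[y == c]
            m = len(xc)
            sd = xc.std(axis=0, ddof=1) if m > 1 else np.zeros(X.shape[1])
            h = 1.06 * sd * m ** (-1 / 5)
            self._train[c] = xc
            self._bandwidth[c] = np.maximum(h, self.min_bandwidth)
            self._log_prior[c] = np.log(m / len(X))
        return self

    def _class_log_likelihood(self, X, c):
        xc, h = self._train[c], self._bandwidth[c]
        m = len(xc)
        total = np.zeros(len(X))
        # chunk features to bound the (q, m, chunk) broadcast memory
        for start in range(0, X.shape[1], 32):
            sl = slice(start, start + 32)
            z = (X[:, None, sl] - xc[None, :, sl]) / h[sl]
            logk = -0.5 * z**2 - np.log(h[sl] * np.sqrt(2 * np.pi))
            total += logsumexp(logk, axis=1).sum(axis=1) - logk.shape[2] * np.log(m)
        return total

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.column_stack(
            [
                self._log_prior[c] + self._class_log_likelihood(X, c)
                for c in self.classes_
            ]
        )
        return self.classes_[np.argmax(scores, axis=1)]


#: fixed hyperparameter grid explored by the optimised ensemble:
#: (method, n_estimators, tree depth)
OE_GRID = (
    ("bagging", 30, None),
    ("bagging", 60, None),
    ("adaboost", 30, 1),
    ("adaboost", 30, 3),
)


class OptimizedEnsemble(BaseEstimator, ClassifierMixin):
    """Tree ensemble with a small fixed grid search.

    Chooses among bagging and AdaBoost configurations (:data:`OE_GRID`)
    by inner stratified 5-fold cross-validation, then refits the winner
    on the full training data.
    """

    def __init__(self, random_state: int | None = None, inner_k: int = 5):
        self.random_state = random_state
        self.inner_k = inner_k

    def _candidate(self, method: str, n_est: int, depth: int | None):
        base = DecisionTreeClassifier(
            max_depth=depth, random_state=self.random_state
        )
        if method == "bagging":
            return BaggingClassifier(
                estimator=base, n_estimators=n_est, random_state=self.random_state
            )
        return AdaBoostClassifier(
            estimator=base, n_estimators=n_est, random_state=self.random_state
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        inner = StratifiedKFold(
            n_splits=self.inner_k, shuffle=True, random_state=self.random_state
        )
        best_score, best_cfg = -np.inf, OE_GRID[0]
        for cfg in OE_GRID:
            scores = []
            for tr, va in inner.split(X, y):
                est = self._candidate(*cfg)
                est.fit(X[tr], y[tr])
                scores.append(np.mean(est.predict(X[va]) == y[va]))
            score = float(np.mean(scores))
            if score > best_score:
                best_score, best_cfg = score, cfg
        self.best_config_ = best_cfg
        self.best_inner_score_ = best_score
        self.estimator_ = self._candidate(*best_cfg).fit(X, y)
        return self

    def predict(self, X):
        return self.estimator_.predict(np.asarray(X, dtype=float))


def make_classifier(name: str, seed: int | None = None):
    """Instantiate one roster classifier by name."""
    roster = {
        "KNN-CityBlock": lambda: KNeighborsClassifier(
            n_neighbors=10, metric="manhattan"
        ),
        "KNN-Euclidean": lambda: KNeighborsClassifier(n_neighbors=10),
        "GaussianNB": lambda: GaussianNB(),
        "KernelNB": lambda: KernelNaiveBayes(),
        "LogisticRegression": lambda: LogisticRegression(max_iter=2000),
        "DiscriminantAnalysis": lambda: LinearDiscriminantAnalysis(),
        "SVM-Linear": lambda: SVC(kernel="linear"),
        "SVM-Cubic": lambda: SVC(kernel="poly", degree=3),
        "DecisionTree": lambda: DecisionTreeClassifier(random_state=seed),
        "BaggedTrees": lambda: BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=100,
            random_state=seed,
        ),
        "OptimizedEnsemble": lambda: OptimizedEnsemble(random_state=seed),
    }
    if name not in roster:
        raise ValueError(f"unknown classifier {name!r}")
    return roster[name]()


def cross_validate(
    features: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
    classifier: str,
    k: int = 5,
    seed: int = 0,
    fold_safe_zscore: bool = False,
    groups: np.ndarray | None = None,
) -> dict[str, object]:
    """Seeded stratified k-fold accuracy for one roster classifier.

    Returns fold accuracies and their mean, in percent. With
    ``fold_safe_zscore`` the standardisation is refit on each training
    fold (leakage-safe variant); ``groups`` switches to grouped
    stratified folds (e.g. subject ids).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if len(y) < k:
        raise ValueError("fewer rows than folds")
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    fold_acc = []
    for tr, va in splits:
        Xtr, Xva = X[tr], X[va]
        if fold_safe_zscore:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xva = (Xva - mu) / sd
        est = make_classifier(classifier, seed=seed)
        est.fit(Xtr, y[tr])
        pred = est.predict(Xva)
        correct = int((pred == y[va]).sum())
        fold_acc.append(accuracy_eq1(correct, 0, len(va), 0))
    return {
        "fold_accuracies": fold_acc,
        "mean_accuracy": float(np.mean(fold_acc)),
    }


@dataclass
class ClassificationReport:
    """Accuracy grid over (sensor configuration x feature set x classifier)."""

    criterion: str
    accuracy: pd.DataFrame  # rows classifiers, columns (SC, FS), percent
    fold_detail: dict[tuple[str, str, str], list[float]] = field(default_factory=dict)

    def with_summary_rows(self) -> pd.DataFrame:
        out = self.accuracy.copy()
        out.loc["Maximum"] = self.accuracy.max(axis=0)
        out.loc["Average"] = self.accuracy.mean(axis=0)
        return out

    def summary(self) -> str:
        table = self.with_summary_rows().round(1)
        return (
            f"Classification accuracies (%) — labeling by {self.criterion}\n"
            + table.to_string()
        )


class ClassificationGrid:
    """Model object for the full SC x FS x classifier evaluation grid."""

    def __init__(
        self,
        dataset: StudyDataset,
        sensor_configs: tuple[str, ...] = ("SC1", "SC2", "SC3"),
        feature_sets: tuple[str, ...] = ("FS1", "FS2", "FS3"),
        classifiers: tuple[str, ...] = CLASSIFIER_ROSTER,
        criterion: str = "pps",
        k: int = 5,
        fold_safe_zscore: bool = False,
        group_by_subject: bool = False,
    ) -> None:
        self.dataset = dataset
        self.sensor_configs = tuple(sensor_configs)
        self.feature_sets = tuple(feature_sets)
        self.classifiers = tuple(classifiers) or CLASSIFIER_ROSTER
        self.criterion = criterion
        self.k = k
        self.fold_safe_zscore = fold_safe_zscore
        self.group_by_subject = group_by_subject

    def fit(self, seed: int = 0) -> ClassificationReport:
        labels = label_trials(self.dataset, self.criterion)
        groups = (
            np.array([t.subject_id for t in self.dataset.trials])
            if self.group_by_subject
            else None
        )
        cols: dict[tuple[str, str], list[float]] = {}
        detail: dict[tuple[str, str, str], list[float]] = {}
        for sc in self.sensor_configs:
            for fs in self.feature_sets:
                feats = extract_features(self.dataset, sc, fs)
                if not self.fold_safe_zscore:
                    feats, _ = zscore(feats)
                accs = []
                for clf in self.classifiers:
                    res = cross_validate(
                        feats,
                        labels,
                        clf,
                        k=self.k,
                        seed=seed,
                        fold_safe_zscore=self.fold_safe_zscore,
                        groups=groups,
                    )
                    accs.append(res["mean_accuracy"])
                    detail[(sc, fs, clf)] = res["fold_accuracies"]
                cols[(sc, fs)] = accs
        accuracy = pd.DataFrame(
            cols,
            index=list(self.classifiers),
            columns=pd.MultiIndex.from_tuples(cols.keys(), names=["SC", "FS"]),
        )
        return ClassificationReport(
            criterion=self.criterion, accuracy=accuracy, fold_detail=detail
        )


def run_grid(
    dataset: StudyDataset,
    sensor_configs: tuple[str, ...] = ("SC1", "SC2", "SC3"),
    feature_sets: tuple[str, ...] = ("FS1", "FS2", "FS3"),
    classifiers: tuple[str, ...] = CLASSIFIER_ROSTER,
    criterion: str = "pps",
    k: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Functional wrapper around :class:`ClassificationGrid`."""
    grid = ClassificationGrid(
        dataset,
        sensor_configs=sensor_configs,
        feature_sets=feature_sets,
        classifiers=classifiers,
        criterion=criterion,
        k=k,
    )
    return grid.fit(seed=seed)
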