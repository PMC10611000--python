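"""Per-emotion binary classifier ensemble with random hyperparameter search
and stratified five-fold cross-validation.

For each of the seven emotions, two classifier families — support vector
machines and random forests, chosen for their efficiency on small tabular
data — are tuned by seeded random search and scored by five-fold
cross-validated accuracy, precision, F-measure, and G-mean. Precision, F,
and G-mean are emphasized because they are insensitive to the residual
class imbalance left after undersampling. The family with the higher mean
F-measure (ties broken by G-mean, then SVM) becomes that emotion's head in
the final ensemble; prediction applies the seven heads independently, so a
face can be assigned several emotions or none.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset_builder import BinaryTask, FeelPixSample, binarize, undersample
from .emotions import EMOTIONS

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "f_score", "g_mean")

FAMILIES = ("svm", "rf")


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Binary classification metrics from confusion counts.

    accuracy = (tp+tn)/total; precision = tp/(tp+fp); F = harmonic mean of
    precision and recall; G-mean = sqrt(recall x specificity), the standard
    imbalance-insensitive geometric mean of sensitivity and specificity.
    Zero denominators yield 0 (logged at debug level).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
    if precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        f_score = 0.0
        logger.debug("degenerate F-measure: precision and recall both zero")
    g_mean = math.sqrt(recall * specificity)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "f_score": f_score,
        "g_mean": g_mean,
    }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) from binary truth/prediction vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return tp, fp, tn, fn


@dataclass(frozen=True)
class HyperparameterSpace:
    """Sampling distributions for one classifier family's random search.

    svm: cost C log-uniform on [1e-2, 1e3], kernel uniform over
    {linear, rbf}, kernel width gamma log-uniform on [1e-4, 10].
    rf: tree count uniform-integer on [50, 500], max depth uniform over
    {None, 2..20}, minimum split size uniform-integer on [2, 10].
    """

    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family '{self.family}'")

    def draw(self, rng: np.random.Generator) -> dict:
        if self.family == "svm":
            # draw every field each time so the random stream is stable
            log_c = rng.uniform(-2.0, 3.0)
            kernel = ["linear", "rbf"][rng.integers(0, 2)]
            log_gamma = rng.uniform(-4.0, 1.0)
            return {"C": 10.0 ** log_c, "kernel": kernel, "gamma": 10.0 ** log_gamma}
        n_estimators = int(rng.integers(50, 501))
        depth_choice = int(rng.integers(0, 20))  # 0 -> unlimited depth
        max_depth = None if depth_choice == 0 else depth_choice + 1
        min_samples_split = int(rng.integers(2, 11))
        return {
            "n_estimators": n_estimators,
            "max_depth": max_depth,
            "min_samples_split": min_samples_split,
        }


def make_estimator(family: str, params: Mapping, seed: int = 0):
    """Instantiate a fresh sklearn estimator for a drawn configuration."""
    if family == "svm":
        return SVC(C=params["C"], kernel=params["kernel"], gamma=params["gamma"],
                   random_state=seed)
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            min_samples_split=params["min_samples_split"],
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown family '{family}'")


@dataclass
class CVReport:
    """Cross-validated metrics for one (emotion, family, configuration)."""

    emotion: str
    family: str
    chosen_params: dict
    per_fold: dict[str, list[float]]
    mean: dict[str, float]
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            values = self.per_fold[name]
            if len(values) != self.n_folds:
                raise ValueError(f"per-fold '{name}' must have {self.n_folds} entries")
            if any(not (0.0 <= v <= 1.0) for v in values + [self.mean[name]]):
                raise ValueError(f"metric '{name}' out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "emotion": self.emotion,
            "family": self.family,
            "chosen_params": self.chosen_params,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def cross_validate(
    task: BinaryTask,
    family: str,
    params: Mapping,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of one configuration.

    Metrics are computed per held-out fold from its confusion counts and
    aggregated as the arithmetic mean over folds.
    """
    n_pos, n_neg = task.n_pos, task.n_neg
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"class smaller than k: pos={n_pos}, neg={n_neg}, k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    for fold, (train_idx, test_idx) in enumerate(skf.split(task.X, task.y)):
        est = make_estimator(family, params, seed=seed + fold)
        est.fit(task.X[train_idx], task.y[train_idx])
        y_pred = est.predict(task.X[test_idx])
        fold_metrics = metrics_from_confusion(*confusion_counts(task.y[test_idx], y_pred))
        for name in METRIC_NAMES:
            per_fold[name].append(fold_metrics[name])
    mean = {name: float(np.mean(per_fold[name])) for name in METRIC_NAMES}
    return CVReport(
        emotion=task.emotion, family=family, chosen_params=dict(params),
        per_fold=per_fold, mean=mean, n_folds=k, seed=seed,
    )


def random_search(
    task: BinaryTask,
    space: HyperparameterSpace,
    n_iter: int = 50,
    seed: int = 0,
    k: int = 5,
) -> dict:
    """Seeded random hyperparameter search scored by mean CV F-measure.

    Draws ``n_iter`` configurations, scores each with stratified k-fold CV,
    and returns the argmax; ties go to the earlier draw.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if task.n_pos == 0 or task.n_neg == 0:
        raise ValueError(f"single-class task for '{task.emotion}'")
    rng = np.random.default_rng(seed)
    best_params, best_score = None, -1.0
    for i in range(n_iter):
        params = space.draw(rng)
        report = cross_validate(task, space.family, params, k=k, seed=seed)
        if report.mean["f_score"] > best_score:
            best_params, best_score = params, report.mean["f_score"]
    return best_params


@dataclass
class EmotionHead:
    """One emotion's trained binary classifier plus its CV report."""

    emotion: str
    family: str
    params: dict
    model: object
    report: CVReport


@dataclass
class EmotionEnsemble:
    """Seven independent per-emotion binary heads."""

    heads: dict[str, EmotionHead]
    n_features: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.heads) != set(EMOTIONS):
            raise ValueError("ensemble must have exactly seven emotion heads")

    @property
    def reports(self) -> dict[str, CVReport]:
        return {e: h.report for e, h in self.heads.items()}

    def report_dict(self) -> dict:
        return {e: h.report.to_dict() for e, h in self.heads.items()}


def fit_best_per_emotion(
    dataset: Sequence[FeelPixSample],
    seed: int = 0,
    n_iter: int = 50,
    k: int = 5,
) -> EmotionEnsemble:
    """Train the full seven-head ensemble from a labelled dataset.

    For each emotion: binarize, undersample, run a random search per family,
    cross-validate both winners, and keep the family with the higher mean
    F-measure (ties broken by G-mean, then SVM). Each head is finally
    refit on its whole balanced task.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    heads: dict[str, EmotionHead] = {}
    for e_idx, emotion in enumerate(EMOTIONS):
        task = binarize(dataset, emotion)
        if task.n_pos == 0:
            raise ValueError(f"emotion '{emotion}' is never selected in the dataset")
        if task.n_neg == 0:
            raise ValueError(f"emotion '{emotion}' is selected in every sample")
        # deterministic per-emotion sub-seed, kept below 2**31
        sub_seed = (seed * 7 + e_idx) % (2**31 - 1)
        balanced = undersample(task, seed=sub_seed)
        candidates = []
        for family in FAMILIES:
            space = HyperparameterSpace(family=family)
            params = random_search(balanced, space, n_iter=n_iter, seed=sub_seed, k=k)
            report = cross_validate(balanced, family, params, k=k, seed=sub_seed)
            candidates.append((family, params, report))
        candidates.sort(key=lambda c: (
            -c[2].mean["f_score"], -c[2].mean["g_mean"], FAMILIES.index(c[0]),
        ))
        family, params, report = candidates[0]
        model = make_estimator(family, params, seed=sub_seed)
        model.fit(balanced.X, balanced.y)
        heads[emotion] = EmotionHead(
            emotion=emotion, family=family, params=params, model=model, report=report,
        )
        logger.info("emotion '%s': chose %s (mean F=%.3f, G=%.3f)",
                    emotion, family, report.mean["f_score"], report.mean["g_mean"])
    n_features = dataset[0].features.shape[0]
    return EmotionEnsemble(heads=heads, n_features=n_features, seed=seed)


def predict(ensemble: EmotionEnsemble, features: np.ndarray) -> np.ndarray:
    """Apply the seven binary heads to one feature vector.

    Returns a 7-bit vector in the fixed emotion order. Unlike human
    annotations, an all-zero prediction is allowed (and logged): the
    at-least-one-emotion rule constrains participants, not classifiers.
    """
    features = np.asarray(features, dtype=float)
    if features.shape != (ensemble.n_features,):
        raise ValueError(
            f"feature vector must have length {ensemble.n_features}, got {features.shape}"
        )
    bits = np.array([
        int(ensemble.heads[e].model.predict(features[None, :])[0]) for e in EMOTIONS
    ])
    if bits.sum() == 0:
        logger.debug("prediction assigned no emotion to the sample")
    return bits


def predict_many(ensemble: EmotionEnsemble, features: np.ndarray) -> np.ndarray:
    """Vectorized prediction: (n, 7) bit matrix for an (n, d) feature matrix."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != ensemble.n_features:
        raise ValueError(f"feature matrix must be (n, {ensemble.n_features})")
    cols = [ensemble.heads[e].model.predict(features).astype(int) for e in EMOTIONS]
    return np.column_stack(cols)
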