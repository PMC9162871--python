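"""Weak-classifier training, model selection and SVM stacking.

Each data source (three MRI sequences, two simulated single-stain images)
yields a feature table; per source, four classifier families are fitted and
the best (highest test AUC, with a preference for the more overfit model on
near-ties) becomes that modality's weak classifier. The two modality winners
feed a 2-dimensional RBF-SVM meta-classifier ("stacking"). Feature
selection, threshold choice and meta-training use the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import AlignmentError, MetricError, ParameterError

__all__ = [
    "ALGORITHMS",
    "WeakResult",
    "StackedModel",
    "EvalReport",
    "split_cohort",
    "select_features",
    "train_weak",
    "roc_and_auc",
    "youden_threshold",
    "operating_metrics",
    "auc_ci",
    "select_best_weak",
    "stack_and_evaluate",
]

ALGORITHMS = ("adaboost", "svm", "random_forest", "decision_tree")

MRI_SOURCES = ("DWI", "T1FSE", "T2FSE")
STAIN_SOURCES = ("hematoxylin", "eosin")


@dataclass
class WeakResult:
    """A fitted per-source classifier with its scores and test metrics."""

    source: str
    algorithm: str
    features: list[str]
    patient_ids: list[str]
    split: np.ndarray  # "train"/"test" per patient
    labels: np.ndarray
    scores: np.ndarray  # continuous class-1 tendency in [0, 1]
    threshold: float  # Youden threshold frozen on the train arm
    auc_train: float = float("nan")
    auc_test: float = float("nan")
    metrics_train: dict = field(default_factory=dict)
    metrics_test: dict = field(default_factory=dict)
    estimator: object = field(default=None, repr=False)

    def arm(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.split == which
        return self.scores[sel], self.labels[sel]


@dataclass
class EvalReport:
    """ROC/AUC + operating-point metrics with bootstrap CIs, per arm."""

    auc_train: float
    auc_train_ci: tuple[float, float]
    auc_test: float
    auc_test_ci: tuple[float, float]
    metrics_train: dict
    metrics_test: dict
    roc_train: tuple[np.ndarray, np.ndarray]
    roc_test: tuple[np.ndarray, np.ndarray]

    def as_dict(self) -> dict:
        return {
            "train": {
                "auc": self.auc_train,
                "auc_ci": list(self.auc_train_ci),
                **self.metrics_train,
            },
            "test": {
                "auc": self.auc_test,
                "auc_ci": list(self.auc_test_ci),
                **self.metrics_test,
            },
        }


@dataclass
class StackedModel:
    """The fused model: two weak classifiers plus an SVM over their scores."""

    weak_mri: WeakResult
    weak_stain: WeakResult
    meta: object
    threshold: float
    patient_ids: list[str]
    split: np.ndarray
    labels: np.ndarray
    scores: np.ndarray


def split_cohort(
    patient_ids,
    labels,
    test_fraction: float,
    stratify: bool = True,
    seed: int = 0,
) -> dict[str, str]:
    """Assign each patient to the train or test arm.

    Stratified mode preserves class prevalence per arm to within one
    patient. Deterministic for a fixed seed.
    """
    patient_ids = list(patient_ids)
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ParameterError("test_fraction must lie in (0, 1)")
    if len(np.unique(labels)) < 2 or min(np.bincount(labels)) < 2:
        raise ParameterError("need at least 2 patients per class to split")
    train_ids, test_ids = train_test_split(
        patient_ids,
        test_size=test_fraction,
        random_state=seed,
        stratify=labels if stratify else None,
        shuffle=True,
    )
    out = {pid: "train" for pid in train_ids}
    out.update({pid: "test" for pid in test_ids})
    return out


def select_features(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    alpha: float = 0.05,
    top_k: int = 8,
) -> list[str]:
    """Features strongly associated with the label on the *training* arm.

    Default rule: two-sided Mann–Whitney test per feature at ``alpha``; if
    nothing passes, fall back to the ``top_k`` features by absolute
    point-biserial correlation. Marginal screening only — a duplicated
    informative feature is selected twice.
    """
    train = table[table["split"] == "train"]
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in ("patient_id", "split", "label", "source")
        ]
    if not feature_columns:
        raise ParameterError("no candidate features to select from")
    y = train["label"].to_numpy()
    selected, ranks = [], []
    for col in feature_columns:
        x = train[col].to_numpy(dtype=float)
        x_pos, x_neg = x[y == 1], x[y == 0]
        if np.ptp(x) == 0:
            continue
        p = stats.mannwhitneyu(x_pos, x_neg, alternative="two-sided").pvalue
        r = abs(np.corrcoef(x, y)[0, 1])
        ranks.append((col, 0.0 if np.isnan(r) else r))
        if p < alpha:
            selected.append(col)
    if selected:
        return selected
    ranks.sort(key=lambda t: -t[1])
    fallback = [c for c, _ in ranks[:top_k]]
    if not fallback:
        raise ParameterError("feature selection found nothing usable")
    return fallback


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "adaboost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if algorithm == "svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", probability=True, random_state=seed)
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(max_depth=3, random_state=seed)
    raise ParameterError(f"unknown algorithm {algorithm!r}; roster is {ALGORITHMS}")


def _fit(estimator, x, y):
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates SVC(probability=True); Platt-scaled
        # probabilities are exactly the continuous scores wanted here.
        warnings.simplefilter("ignore", FutureWarning)
        estimator.fit(x, y)
    return estimator


def train_weak(
    table: pd.DataFrame,
    source: str,
    algorithm: str,
    seed: int = 0,
    alpha: float = 0.05,
    top_k: int = 8,
) -> WeakResult:
    """Fit one classifier family on one source's feature table.

    The table holds one row per patient (columns: ``patient_id``, ``label``,
    ``split``, features). Selection and fitting see the training arm only;
    scores are class-1 probabilities for every patient.
    """
    sub = table[table["source"] == source] if "source" in table.columns else table
    sub = sub.sort_values("patient_id").reset_index(drop=True)
    # The long table holds the union of all sources' feature columns;
    # keep only the columns this source actually populates.
    sub = sub.dropna(axis=1, how="any")
    train_mask = (sub["split"] == "train").to_numpy()
    y = sub["label"].to_numpy(dtype=int)
    if len(np.unique(y[train_mask])) < 2:
        raise ParameterError(f"{source}: training split holds a single class")
    features = select_features(sub, alpha=alpha, top_k=top_k)
    x = sub[features].to_numpy(dtype=float)
    est = _make_estimator(algorithm, seed)
    _fit(est, x[train_mask], y[train_mask])
    scores = est.predict_proba(x)[:, 1]
    split = np.where(train_mask, "train", "test")
    result = WeakResult(
        source=source,
        algorithm=algorithm,
        features=features,
        patient_ids=sub["patient_id"].tolist(),
        split=split,
        labels=y,
        scores=scores,
        threshold=float("nan"),
        estimator=est,
    )
    result.threshold = youden_threshold(*result.arm("train"))
    for which in ("train", "test"):
        s, lab = result.arm(which)
        _, auc = roc_and_auc(s, lab)
        sens, spec, acc, _ = operating_metrics(s, lab, result.threshold)
        metrics = {"sensitivity": sens, "specificity": spec, "accuracy": acc}
        if which == "train":
            result.auc_train, result.metrics_train = auc, metrics
        else:
            result.auc_test, result.metrics_test = auc, metrics
    return result


def roc_and_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """ROC curve over all distinct thresholds and its area.

    The AUC equals the Mann–Whitney statistic
    ``P(score_pos > score_neg) + 0.5 P(tie)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise MetricError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return (fpr, tpr, thresholds), float(roc_auc_score(labels, scores))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on these data.

    Ties go to the highest qualifying threshold (the more specific
    operating point).
    """
    (fpr, tpr, thresholds), _ = roc_and_auc(scores, labels)
    j = tpr - fpr
    return float(thresholds[int(np.argmax(j))])


def operating_metrics(
    scores, labels, threshold: float
) -> tuple[float, float, float, float]:
    """Sensitivity, specificity, accuracy at ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise MetricError("operating metrics need both classes present")
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[neg]).mean())
    accuracy = float((pred == labels.astype(bool)).mean())
    return sensitivity, specificity, accuracy, float(threshold)


def auc_ci(
    scores, labels, reps: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class.

    Positive and negative patients are resampled separately so every
    replicate contains both classes. Bounds are clipped to [0, 1].
    """
    if reps < 200:
        raise ParameterError("use at least 200 bootstrap replicates")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise MetricError("bootstrap CI needs both classes present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    for i in range(reps):
        p = rng.choice(pos, size=len(pos), replace=True)
        n = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([p, n])
        aucs[i] = roc_auc_score(labels[idx], scores[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def select_best_weak(
    results: list[WeakResult], tie_tolerance: float = 0.02
) -> WeakResult:
    """Pick the weak classifier by test AUC, preferring overfit near-ties.

    The highest test AUC wins outright; among candidates within
    ``tie_tolerance`` of the top, the one with the largest train-minus-test
    AUC gap is chosen (the rationale: an overfit model has learned more
    structure that a downstream meta-classifier can exploit).
    """
    if not results:
        raise ParameterError("no candidate weak classifiers")
    best_auc = max(r.auc_test for r in results)
    contenders = [r for r in results if best_auc - r.auc_test <= tie_tolerance]
    if len(contenders) == 1:
        return contenders[0]
    return max(contenders, key=lambda r: (r.auc_train - r.auc_test, r.auc_test))


def stack_and_evaluate(
    weak_mri: WeakResult,
    weak_stain: WeakResult,
    seed: int = 0,
    bootstrap_reps: int = 2000,
) -> tuple[StackedModel, EvalReport]:
    """Fuse the two modality winners with an RBF-SVM meta-classifier.

    The meta-model is fitted on the training arm's 2-dimensional weak-score
    pairs (continuous probabilities, not hard labels) and evaluated on both
    arms with ROC/AUC, bootstrap CIs and Youden operating metrics.
    """
    if weak_mri.patient_ids != weak_stain.patient_ids:
        raise AlignmentError("weak classifiers score different patient sets")
    if not np.array_equal(weak_mri.split, weak_stain.split) or not np.array_equal(
        weak_mri.labels, weak_stain.labels
    ):
        raise AlignmentError("weak classifiers disagree on splits or labels")
    x = np.column_stack([weak_mri.scores, weak_stain.scores])
    y = weak_mri.labels
    train = weak_mri.split == "train"
    meta = make_pipeline(
        StandardScaler(), SVC(kernel="rbf", probability=True, random_state=seed)
    )
    _fit(meta, x[train], y[train])
    scores = meta.predict_proba(x)[:, 1]
    threshold = youden_threshold(scores[train], y[train])
    report = {}
    for which, sel in (("train", train), ("test", ~train)):
        s, lab = scores[sel], y[sel]
        roc, auc = roc_and_auc(s, lab)
        ci = auc_ci(s, lab, reps=bootstrap_reps, seed=seed)
        sens, spec, acc, _ = operating_metrics(s, lab, threshold)
        report[which] = (auc, ci, {"sensitivity": sens, "specificity": spec, "accuracy": acc}, roc)
    stacked = StackedModel(
        weak_mri=weak_mri,
        weak_stain=weak_stain,
        meta=meta,
        threshold=threshold,
        patient_ids=weak_mri.patient_ids,
        split=weak_mri.split,
        labels=y,
        scores=scores,
    )
    eval_report = EvalReport(
        auc_train=report["train"][0],
        auc_train_ci=report["train"][1],
        auc_test=report["test"][0],
        auc_test_ci=report["test"][1],
        metrics_train=report["train"][2],
        metrics_test=report["test"][2],
        roc_train=report["train"][3][:2],
        roc_test=report["test"][3][:2],
    )
    return stacked, eval_report
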