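"""Subject-stratified cross-validation, confusion metrics, ROC/AUC.

Mapping acquisitions are pseudo-replicates: all ~500 spectra of a subject
share that subject's biology and substrate spot, so folds are built over
*subjects*, stratified by class, and every spectrum travels with its
subject.  Splitting at spectrum level would leak subject identity into
training and inflate every metric; a leakage assertion guards each run.

Per fold the training rows are column mean-centered (the centering vector
is then applied to the held-out rows), PLS-DA is fitted — with the number
of latent variables either fixed or chosen by an inner subject-level
cross-validation — and held-out spectra are scored.  Evaluation is
subject-level by default: a subject's score is the mean of its spectrum
scores, thresholded at 0.5, with sensitivity defined on the case (cancer)
group.  Fold ROCs are averaged vertically (fixed-FPR grid) and the mean
AUC is the arithmetic mean of fold AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SpectralDataset
from .plsda import PLSDA, encode_labels

__all__ = [
    "FoldPlan",
    "FoldMetrics",
    "CvReport",
    "ModelConfig",
    "make_folds",
    "cross_validate",
    "roc_auc",
    "average_roc",
]

FPR_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of subjects to folds 1..K (all spectra travel together)."""

    K: int
    assignments: Mapping[str, int]
    seed: int

    def fold_subjects(self, k: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == k]


@dataclass(frozen=True)
class ModelConfig:
    """Classifier settings for cross-validation.

    ``n_components``: fixed LV count, or ``"auto"`` to select by an inner
    subject-stratified cross-validation over ``1..a_max`` maximizing
    held-out accuracy (ties -> smallest).
    """

    n_components: int | str = "auto"
    a_max: int = 10
    inner_k: int = 5


@dataclass
class FoldMetrics:
    fold: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    n_components: int


@dataclass
class CvReport:
    """Per-fold and aggregate cross-validation metrics."""

    folds: list[FoldMetrics]
    evaluation_level: str
    mean_accuracy: float = field(init=False)
    mean_sensitivity: float = field(init=False)
    mean_specificity: float = field(init=False)
    mean_auc: float = field(init=False)
    avg_roc_fpr: np.ndarray = field(init=False)
    avg_roc_tpr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean([f.accuracy for f in self.folds]))
        self.mean_sensitivity = float(np.mean([f.sensitivity for f in self.folds]))
        self.mean_specificity = float(np.mean([f.specificity for f in self.folds]))
        (self.avg_roc_fpr, self.avg_roc_tpr), self.mean_auc = average_roc(
            [(f.roc_fpr, f.roc_tpr, f.auc) for f in self.folds]
        )

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fold": f.fold,
                    "tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn,
                    "accuracy": f.accuracy,
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                    "auc": f.auc,
                    "n_components": f.n_components,
                }
                for f in self.folds
            ]
        )

    def summary(self) -> str:
        lines = [
            f"{len(self.folds)}-fold cross-validation ({self.evaluation_level} level)",
            "=" * 52,
            f"mean accuracy     {self.mean_accuracy:.3f}",
            f"mean sensitivity  {self.mean_sensitivity:.3f}",
            f"mean specificity  {self.mean_specificity:.3f}",
            f"mean AUC          {self.mean_auc:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# folds


def make_folds(subject_ids: Sequence[str], class_labels: Sequence[str], K: int = 10,
               seed: int = 0) -> FoldPlan:
    """Stratified subject-level fold plan.

    Within each class, subjects are shuffled (seeded) and dealt round-robin
    to folds, so per-fold class counts differ by at most one subject from
    exact proportionality.
    """
    subject_class: dict[str, str] = {}
    for s, c in zip(subject_ids, class_labels):
        if subject_class.setdefault(s, c) != c:
            raise ValueError(f"subject {s!r} has conflicting class labels")
    subjects = list(subject_class)
    if len(subjects) < K:
        raise ValueError(
            f"{len(subjects)} subjects cannot fill K={K} folds; use a smaller K"
        )
    by_class: dict[str, list[str]] = {}
    for s in subjects:
        by_class.setdefault(subject_class[s], []).append(s)
    if any(len(v) < 2 for v in by_class.values()):
        raise ValueError("need >= 2 subjects in every class")

    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    offset = 0
    for cls in sorted(by_class):
        group = sorted(by_class[cls])
        rng.shuffle(group)
        for i, s in enumerate(group):
            # rotating the starting fold across classes balances fold sizes
            assignments[s] = 1 + (i + offset) % K
        offset += len(group)
    return FoldPlan(K=K, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# ROC


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    Thresholds run over the distinct score values; tied scores step the
    curve diagonally (simultaneous TP/FP increments), which makes the
    trapezoidal area equal the tie-corrected Mann-Whitney statistic
    U / (n1 * n0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # collapse ties: one step per distinct score
    distinct = np.r_[True, np.diff(s) != 0]
    tp = np.cumsum(l == 1)[np.r_[np.nonzero(distinct)[0][1:] - 1, s.size - 1]]
    fp = np.cumsum(l == 0)[np.r_[np.nonzero(distinct)[0][1:] - 1, s.size - 1]]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def average_roc(per_fold: Sequence[tuple[np.ndarray, np.ndarray, float]]
                ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Vertical (fixed-FPR) fold averaging plus arithmetic mean AUC.

    Each fold's TPR is interpolated on a 0..1 FPR grid with 0.01 spacing
    (vertical segments collapse to their upper envelope) and averaged
    point-wise.
    """
    if not per_fold:
        raise ValueError("no fold ROCs to average")
    curves = []
    for fpr, tpr, _ in per_fold:
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        # upper envelope at duplicate FPR values so interpolation follows
        # the attained ROC
        env_f, env_t = [], []
        for f, t in zip(fpr, tpr):
            if env_f and f == env_f[-1]:
                env_t[-1] = max(env_t[-1], t)
            else:
                env_f.append(f)
                env_t.append(t)
        curves.append(np.interp(FPR_GRID, env_f, env_t))
    mean_tpr = np.mean(curves, axis=0)
    mean_auc = float(np.mean([auc for _, _, auc in per_fold]))
    return (FPR_GRID.copy(), mean_tpr), mean_auc


# ---------------------------------------------------------------------------
# cross-validation


def _confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return tp, fp, tn, fn


def _select_n_components(X: np.ndarray, y: np.ndarray, subject_ids: np.ndarray,
                         class_labels: np.ndarray, config: ModelConfig, seed: int) -> int:
    """Inner subject-stratified CV over the LV count, maximizing accuracy."""
    subjects = list(dict.fromkeys(subject_ids.tolist()))
    inner_k = min(config.inner_k, len(subjects))
    try:
        plan = make_folds(subject_ids, class_labels, K=inner_k, seed=seed)
    except ValueError:
        return min(2, config.a_max)
    a_cap = config.a_max
    correct = np.zeros(a_cap)
    total = np.zeros(a_cap)
    for k in range(1, inner_k + 1):
        test_subj = set(plan.fold_subjects(k))
        te = np.isin(subject_ids, list(test_subj))
        tr = ~te
        if np.unique(y[tr]).size < 2 or not te.any():
            continue
        a_max = min(a_cap, int(np.sum(tr)) - 1, X.shape[1])
        try:
            res = PLSDA(X[tr], y[tr]).fit(a_max)
        except ValueError:
            continue
        # evaluate every truncation of one max-rank fit
        Xc = X[te] - res.x_mean
        T = np.empty((Xc.shape[0], a_max))
        Xd = Xc.copy()
        for a in range(a_max):
            T[:, a] = Xd @ res.weights[:, a]
            Xd -= np.outer(T[:, a], res.x_loadings[:, a])
        for a in range(a_max):
            yhat = T[:, : a + 1] @ res.y_loadings[: a + 1] + res.y_mean
            correct[a] += np.sum((yhat >= 0.5) == (y[te] == 1))
            total[a] += te.sum()
    if total.max() == 0:
        return min(2, a_cap)
    acc = np.where(total > 0, correct / np.maximum(total, 1), -1.0)
    return int(np.argmax(acc)) + 1  # argmax takes the smallest on ties


def cross_validate(dataset: SpectralDataset, case_labels: Sequence[str],
                   fold_plan: FoldPlan, model_config: ModelConfig | None = None,
                   evaluation_level: str = "subject") -> CvReport:
    """Run subject-stratified K-fold cross-validation of PLS-DA.

    *dataset* must already be despiked/baseline-corrected/smoothed/cropped/
    normalized; column centering happens here, per fold, on training rows
    only.  ``evaluation_level`` is "subject" (mean spectrum score per
    subject, the default) or "spectrum".
    """
    model_config = model_config or ModelConfig()
    if evaluation_level not in ("subject", "spectrum"):
        raise ValueError("evaluation_level must be 'subject' or 'spectrum'")
    y_all = encode_labels(dataset.class_labels, case_labels)
    folds: list[FoldMetrics] = []
    for k in range(1, fold_plan.K + 1):
        test_subjects = set(fold_plan.fold_subjects(k))
        te = np.isin(dataset.subject_ids, list(test_subjects))
        tr = ~te
        if not te.any():
            continue
        # leakage guard: no subject on both sides of the split
        assert not (set(dataset.subject_ids[tr]) & set(dataset.subject_ids[te])), \
            f"subject leakage between training and test in fold {k}"
        if np.unique(y_all[tr]).size < 2:
            raise ValueError(f"fold {k}: training rows contain a single class")
        if np.unique(y_all[te]).size < 2:
            raise ValueError(
                f"fold {k}: held-out rows contain a single class; "
                "ROC per fold needs both"
            )
        train = dataset.select(tr)
        if model_config.n_components == "auto":
            A = _select_n_components(train.X, y_all[tr], train.subject_ids,
                                     train.class_labels, model_config,
                                     seed=fold_plan.seed + k)
        else:
            A = int(model_config.n_components)
        A = max(1, min(A, train.X.shape[0] - 1, train.X.shape[1]))
        # PLSDA.fit removes and stores the training column means, so the
        # held-out rows are centered with training means only
        res = PLSDA(train.X, y_all[tr]).fit(A)
        scores = res.predict(dataset.X[te])
        truth = y_all[te].astype(int)

        if evaluation_level == "subject":
            subj = dataset.subject_ids[te]
            uniq = list(dict.fromkeys(subj.tolist()))
            scores = np.array([scores[subj == s].mean() for s in uniq])
            truth = np.array([int(y_all[te][subj == s][0]) for s in uniq])

        pred = (scores >= 0.5).astype(int)
        tp, fp, tn, fn = _confusion(pred, truth)
        total = tp + fp + tn + fn
        fpr, tpr, auc = roc_auc(scores, truth)
        folds.append(
            FoldMetrics(
                fold=k, tp=tp, fp=fp, tn=tn, fn=fn,
                accuracy=(tp + tn) / total,
                sensitivity=tp / (tp + fn),
                specificity=tn / (tn + fp),
                roc_fpr=fpr, roc_tpr=tpr, auc=auc,
                n_components=A,
            )
        )
    if not folds:
        raise ValueError("no usable folds")
    return CvReport(folds=folds, evaluation_level=evaluation_level)
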