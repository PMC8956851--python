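"""Subject-independent splitting and the multiclass metric suite.

The evaluation protocol partitions VOLUNTEERS, not samples: a model
trained on one group of subjects is scored on a disjoint group, so the
reported numbers measure generalization to unseen users.  Metrics are the
usual one-vs-rest quantities per class — TP rate (= recall), FP rate,
precision, F-score, ROC AUC — with macro (unweighted), micro and
support-weighted averages all reported since conventions differ between
studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from sdfl.dataset import LabeledFeatureSet, ValidationError

__all__ = [
    "EvaluationReport",
    "subject_independent_split",
    "evaluate",
    "accuracy_score",
    "confusion_matrix",
]


def subject_independent_split(
    data: LabeledFeatureSet,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[LabeledFeatureSet, LabeledFeatureSet]:
    """Partition subjects (not samples) into train and test groups.

    ``round(train_fraction * S)`` subjects, chosen by a seeded shuffle,
    form the training set; the rest form the test set.  The two outputs
    never share a subject ID.

    Raises
    ------
    ValidationError
        If fewer than two subjects exist, the fraction leaves either side
        empty, or the training side loses a class entirely.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    subjects = data.subject_ids
    if subjects.size < 2:
        raise ValidationError("need at least 2 distinct subjects to split")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(subjects)
    n_train = int(round(train_fraction * subjects.size))
    if n_train == 0 or n_train == subjects.size:
        raise ValidationError(
            f"train_fraction {train_fraction} leaves an empty side for "
            f"{subjects.size} subjects"
        )
    train_mask = np.isin(data.subjects, shuffled[:n_train])
    for side, mask in (("training", train_mask), ("test", ~train_mask)):
        missing = np.setdiff1d(np.unique(data.labels), np.unique(data.labels[mask]))
        if missing.size:
            raise ValidationError(
                f"protocol error: classes {missing.tolist()} absent from the "
                f"{side} subjects; choose another seed or fraction"
            )
    train = data.restrict_to_subjects(shuffled[:n_train])
    test = data.restrict_to_subjects(shuffled[n_train:])
    return train, test


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> np.ndarray:
    """C x C integer confusion counts, rows = true class, cols = predicted."""
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    return np.bincount(
        (y - 1) * n_classes + (p - 1), minlength=n_classes * n_classes
    ).reshape(n_classes, n_classes)


def accuracy_score(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Fraction of predictions equal to the true label."""
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValidationError("label arrays must have equal length")
    return float(np.mean(y == p))


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix plus per-class, macro, micro and weighted metrics.

    Per-class arrays are indexed by class-1; NaN marks a metric undefined
    for a class (e.g. precision with no positive predictions), and
    undefined entries are excluded from the macro average.
    """

    confusion: np.ndarray
    accuracy: float
    per_class: dict = field(repr=False)
    macro: dict
    micro: dict
    weighted: dict

    def to_text(self, class_names: "list[str] | None" = None) -> str:
        """Human-readable report: key/value metrics + confusion block."""
        c = self.confusion.shape[0]
        names = class_names or [f"class_{j}" for j in range(1, c + 1)]
        lines = [f"accuracy\t{self.accuracy:.6f}"]
        for key in ("tp_rate", "fp_rate", "precision", "recall", "f_score", "auc"):
            value = self.macro.get(key, float("nan"))
            lines.append(f"macro_{key}\t{value:.6f}")
        lines.append("")
        lines.append("confusion matrix (rows = true, cols = predicted)")
        header = "\t".join([""] + names)
        lines.append(header)
        for j, row in enumerate(self.confusion):
            lines.append("\t".join([names[j]] + [str(int(v)) for v in row]))
        return "\n".join(lines) + "\n"


def _nanmean(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(finite.mean()) if finite.size else float("nan")


def evaluate(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    score_matrix: "np.ndarray | None" = None,
    *,
    n_classes: "int | None" = None,
) -> EvaluationReport:
    """Score predictions against ground truth.

    Parameters
    ----------
    true_labels, predicted_labels
        Equal-length integer arrays with values in ``1..C``.
    score_matrix
        Optional (N, C) per-class scores (column j-1 = class j), e.g. the
        negated nearest-distance scores of the NN classifier; enables
        one-vs-rest ROC AUC.  AUC is omitted when absent.
    n_classes
        Explicit C; inferred from the data (and the score matrix width)
        when omitted.
    """
    y = np.asarray(true_labels, dtype=np.int64).ravel()
    p = np.asarray(predicted_labels, dtype=np.int64).ravel()
    if y.shape != p.shape:
        raise ValidationError("true and predicted label lengths differ")
    if y.size == 0:
        raise ValidationError("no samples to evaluate")
    if y.min() < 1 or p.min() < 1:
        raise ValidationError("labels must be >= 1")
    c = int(max(y.max(), p.max()))
    if score_matrix is not None:
        score_matrix = np.asarray(score_matrix, dtype=np.float64)
        if score_matrix.shape[0] != y.size:
            raise ValidationError("score matrix row count mismatch")
        c = max(c, score_matrix.shape[1])
    if n_classes is not None:
        if n_classes < c:
            raise ValidationError(f"labels exceed declared n_classes={n_classes}")
        c = n_classes

    cm = confusion_matrix(y, p, c)
    n = cm.sum()
    support = cm.sum(axis=1).astype(np.float64)  # true count per class
    predicted = cm.sum(axis=0).astype(np.float64)
    tp = np.diag(cm).astype(np.float64)
    fp = predicted - tp
    fn = support - tp
    tn = n - tp - fp - fn

    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(support > 0, tp / support, np.nan)
        precision = np.where(predicted > 0, tp / predicted, np.nan)
        fp_rate = np.where((fp + tn) > 0, fp / (fp + tn), np.nan)
        f_score = np.where(
            (precision + recall) > 0,
            2 * precision * recall / (precision + recall),
            np.nan,
        )

    absent = np.flatnonzero(support == 0)
    if absent.size:
        warnings.warn(
            f"classes {(absent + 1).tolist()} absent from true labels; their "
            f"per-class metrics are undefined and excluded from macro averages",
            stacklevel=2,
        )

    auc = np.full(c, np.nan)
    if score_matrix is not None:
        for j in range(c):
            positives = y == j + 1
            if positives.any() and not positives.all():
                auc[j] = roc_auc_score(positives, score_matrix[:, j])

    per_class = {
        "support": support,
        "tp_rate": recall,
        "fp_rate": fp_rate,
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
        "auc": auc,
    }
    macro = {k: _nanmean(v) for k, v in per_class.items() if k != "support"}

    micro_precision = float(tp.sum() / n)  # multiclass micro P = R = accuracy
    micro = {
        "tp_rate": micro_precision,
        "fp_rate": float(fp.sum() / (fp.sum() + tn.sum())),
        "precision": micro_precision,
        "recall": micro_precision,
        "f_score": micro_precision,
    }

    weights = support / support.sum()

    def _weighted(values: np.ndarray) -> float:
        ok = np.isfinite(values) & (weights > 0)
        return float(np.sum(values[ok] * weights[ok]) / weights[ok].sum()) if ok.any() else float("nan")

    weighted = {
        k: _weighted(v) for k, v in per_class.items() if k != "support"
    }

    return EvaluationReport(
        confusion=cm,
        accuracy=float(tp.sum() / n),
        per_class=per_class,
        macro=macro,
        micro=micro,
        weighted=weighted,
    )
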