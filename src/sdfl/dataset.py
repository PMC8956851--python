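"""Labelled feature-set container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when input data violates a container or operation contract."""


class DegenerateClassError(ValidationError):
    """Raised when the class structure cannot support discriminant analysis."""


@dataclass(frozen=True)
class LabeledFeatureSet:
    """N x d feature matrix with integer activity labels and subject IDs.

    Parameters
    ----------
    features
        Real matrix of shape (N, d), one standardized feature vector per row.
    labels
        Length-N integer class labels in ``1..C``; every class must occur.
    subjects
        Length-N integer volunteer identifiers, used by the
        subject-independent evaluation protocol.
    """

    features: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64).ravel()
        s = np.asarray(self.subjects, dtype=np.int64).ravel()
        if X.ndim != 2:
            raise ValidationError(f"features must be 2-D, got ndim={X.ndim}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("features contain non-finite values")
        n = X.shape[0]
        if y.shape[0] != n or s.shape[0] != n:
            raise ValidationError(
                f"row-count mismatch: {n} feature rows, {y.shape[0]} labels, "
                f"{s.shape[0]} subjects"
            )
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateClassError("need at least 2 classes")
        expected = np.arange(1, classes.size + 1)
        if not np.array_equal(classes, expected):
            raise ValidationError(
                f"labels must be contiguous 1..C, got {classes.tolist()}"
            )
        if n < classes.size:
            raise ValidationError("fewer samples than classes")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "subjects", s)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def class_counts(self) -> np.ndarray:
        """Per-class sample counts m_j, index j-1 holds class j."""
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    @property
    def subject_ids(self) -> np.ndarray:
        return np.unique(self.subjects)

    def restrict_to_subjects(self, wanted: np.ndarray) -> "LabeledFeatureSet":
        mask = np.isin(self.subjects, wanted)
        return LabeledFeatureSet(
            self.features[mask], self.labels[mask], self.subjects[mask]
        )
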