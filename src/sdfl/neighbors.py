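"""Exact nearest-neighbour classification of stacked discriminant features.

The reference set is small (thousands of rows of L*(C-1)-dimensional
features), so an exact all-pairs distance scan is both the simplest and a
perfectly adequate implementation; no tree acceleration is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from sdfl.dataset import ValidationError

__all__ = ["NnModel", "fit_nn"]


@dataclass(frozen=True)
class NnModel:
    """k-nearest-neighbour classifier over a fixed reference set.

    Defaults to the single nearest neighbour under Euclidean distance.
    Distance ties are broken by the smallest reference row index, then the
    smallest class label; k > 1 votes are broken by the smallest label.
    """

    reference_features: np.ndarray
    reference_labels: np.ndarray
    k: int = 1
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        X = np.asarray(self.reference_features, dtype=np.float64)
        y = np.asarray(self.reference_labels, dtype=np.int64).ravel()
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValidationError("reference set must be a non-empty 2-D matrix")
        if X.shape[0] != y.shape[0]:
            raise ValidationError("reference features/labels length mismatch")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        object.__setattr__(self, "reference_features", X)
        object.__setattr__(self, "reference_labels", y)

    def _distances(self, queries: np.ndarray) -> np.ndarray:
        Q = np.asarray(queries, dtype=np.float64)
        if Q.ndim == 1:
            Q = Q[None, :]
        if Q.shape[1] != self.reference_features.shape[1]:
            raise ValidationError(
                f"query dimension {Q.shape[1]} != reference dimension "
                f"{self.reference_features.shape[1]}"
            )
        return cdist(Q, self.reference_features, metric=self.metric)

    def predict(self, queries: np.ndarray) -> np.ndarray:
        """Label each query row by its nearest reference sample(s)."""
        dist = self._distances(queries)
        if self.k == 1:
            # argmin returns the first minimum: smallest row index wins ties
            return self.reference_labels[np.argmin(dist, axis=1)]
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.k]
        votes = self.reference_labels[order]
        out = np.empty(votes.shape[0], dtype=np.int64)
        for i, row in enumerate(votes):
            counts = np.bincount(row)
            out[i] = np.argmax(counts)  # first (smallest) label wins ties
        return out

    def class_scores(self, queries: np.ndarray) -> np.ndarray:
        """Per-class affinity scores for one-vs-rest ROC analysis.

        The score of class j for a query is minus the distance to the
        nearest reference of class j, so ``argmax`` over classes
        reproduces :meth:`predict` (for k = 1).  Column j-1 holds class j.
        """
        dist = self._distances(queries)
        n_classes = int(self.reference_labels.max())
        scores = np.full((dist.shape[0], n_classes), -np.inf)
        for j in range(1, n_classes + 1):
            mask = self.reference_labels == j
            if mask.any():
                scores[:, j - 1] = -dist[:, mask].min(axis=1)
        return scores


def fit_nn(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    k: int = 1,
    metric: str = "euclidean",
) -> NnModel:
    """Build an :class:`NnModel` from reference features and labels."""
    return NnModel(
        reference_features=features, reference_labels=labels, k=k, metric=metric
    )
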