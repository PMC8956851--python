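"""Readers/writers for the whitespace-delimited feature-matrix layout.

The on-disk convention follows the common smartphone-HAR distribution
format: three parallel text files — a feature matrix (one sample per row,
whitespace-separated reals), a label file (one integer per row) and a
subject file (one integer per row).  Feature values are written with 8
significant digits, which keeps write/read round-trip drift far below the
pipeline's numeric tolerances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sdfl.dataset import LabeledFeatureSet, ValidationError

__all__ = ["DatasetLayout", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.8g"


@dataclass(frozen=True)
class DatasetLayout:
    """Paths of the three parallel files of one dataset split."""

    features_path: Path
    labels_path: Path
    subjects_path: Path

    @classmethod
    def in_directory(cls, directory: "str | Path") -> "DatasetLayout":
        d = Path(directory)
        return cls(d / "X_data.txt", d / "y_data.txt", d / "subject_data.txt")


def _load_matrix(path: Path, name: str) -> np.ndarray:
    if not path.exists():
        raise ValidationError(f"{name} file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty-file warning
            data = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"parse error in {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"{name} file is empty: {path}")
    return data


def read_dataset(layout: "DatasetLayout | str | Path") -> LabeledFeatureSet:
    """Read and validate one split from a :class:`DatasetLayout`.

    Labels with gaps (e.g. {1, 3}) are remapped to a contiguous ``1..C``
    range with a logged warning.  Row-count mismatches, non-numeric tokens
    and empty files raise descriptive errors.
    """
    if not isinstance(layout, DatasetLayout):
        layout = DatasetLayout.in_directory(layout)
    features = _load_matrix(layout.features_path, "feature")
    labels = _load_matrix(layout.labels_path, "label").ravel()
    subjects = _load_matrix(layout.subjects_path, "subject").ravel()

    n = features.shape[0]
    if labels.shape[0] != n or subjects.shape[0] != n:
        raise ValidationError(
            f"row-count mismatch: {n} rows in {layout.features_path}, "
            f"{labels.shape[0]} in {layout.labels_path}, "
            f"{subjects.shape[0]} in {layout.subjects_path}"
        )
    for name, values in (("label", labels), ("subject", subjects)):
        if not np.allclose(values, np.round(values)):
            raise ValidationError(f"non-integer value in {name} file")
    labels = labels.astype(np.int64)
    subjects = subjects.astype(np.int64)

    classes = np.unique(labels)
    contiguous = np.arange(1, classes.size + 1)
    if not np.array_equal(classes, contiguous):
        logger.warning(
            "labels %s are not contiguous 1..C; remapping to %s",
            classes.tolist(),
            contiguous.tolist(),
        )
        remap = {old: new for old, new in zip(classes.tolist(), contiguous)}
        labels = np.array([remap[v] for v in labels.tolist()], dtype=np.int64)

    data = LabeledFeatureSet(features, labels, subjects)
    logger.info(
        "read dataset: N=%d d=%d C=%d subjects=%d",
        data.n_samples,
        data.n_features,
        data.n_classes,
        data.subject_ids.size,
    )
    return data


def write_dataset(
    data: LabeledFeatureSet, layout: "DatasetLayout | str | Path"
) -> DatasetLayout:
    """Write a split to the three parallel text files; returns the layout."""
    if not isinstance(layout, DatasetLayout):
        directory = Path(layout)
        directory.mkdir(parents=True, exist_ok=True)
        layout = DatasetLayout.in_directory(directory)
    layout.features_path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(layout.features_path, data.features, fmt=FLOAT_FORMAT)
    np.savetxt(layout.labels_path, data.labels, fmt="%d")
    np.savetxt(layout.subjects_path, data.subjects, fmt="%d")
    return layout
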