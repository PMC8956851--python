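"""Stacked composition of discriminant layers.

Layer 1 learns on the raw feature vectors.  Every deeper layer l learns on
the stacking vector z^l = [x ; activated output of layer l-1] — the
ORIGINAL input concatenated with the previous layer's sigmoid features, so
each deep layer has input width d + (C-1).  The final representation
concatenates the activated outputs of all L layers (length L*(C-1)).
Fitting is greedy and feedforward: layers are solved one after another
with no global refit, so a depth-L model's first L-1 layers coincide with
the depth-(L-1) model.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sdfl.core import DiscriminantLayer, fit_layer, project, sigmoid_activate
from sdfl.dataset import LabeledFeatureSet, ValidationError

__all__ = [
    "SdflModel",
    "fit_sdfl",
    "select_depth",
    "depth_from_accuracies",
    "save_model",
    "load_model",
]

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SdflModel:
    """Ordered stack of fitted discriminant layers."""

    layers: tuple[DiscriminantLayer, ...]
    n_classes: int
    input_dim: int
    between_class_weighting: str = "count"

    @property
    def depth(self) -> int:
        return len(self.layers)

    @property
    def feature_length(self) -> int:
        """Length of the final concatenated feature, L*(C-1)."""
        return sum(layer.n_components for layer in self.layers)

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Map raw feature rows to the final stacked representation.

        Returns an (N, L*(C-1)) matrix with every entry strictly in (0, 1).
        """
        X = np.asarray(features, dtype=np.float64)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ValidationError(
                f"expected {self.input_dim} columns, got {X.shape[1]}"
            )
        blocks = []
        activated = None
        for depth, layer in enumerate(self.layers, start=1):
            z = X if depth == 1 else np.hstack([X, activated])
            activated = sigmoid_activate(project(layer, z))
            blocks.append(activated)
        out = np.hstack(blocks)
        return out[0] if single else out

    def truncate(self, depth: int) -> "SdflModel":
        """Model using only the first ``depth`` layers (greedy prefix)."""
        if not 1 <= depth <= self.depth:
            raise ValidationError(f"depth must be in 1..{self.depth}")
        return SdflModel(
            layers=self.layers[:depth],
            n_classes=self.n_classes,
            input_dim=self.input_dim,
            between_class_weighting=self.between_class_weighting,
        )


def fit_sdfl(
    data: LabeledFeatureSet,
    *,
    depth: int = 3,
    ridge: float | None = None,
    n_components: int | None = None,
    between_class_weighting: str = "count",
) -> SdflModel:
    """Fit a stacked discriminant model of the given depth.

    Parameters
    ----------
    data
        Training samples; labels drive the scatter matrices, subjects are
        carried along for protocol checks elsewhere.
    depth
        Number of stacked layers L (default 3).
    ridge
        Tikhonov strength forwarded to every layer; ``None`` lets each
        layer pick the trace-scaled default.
    n_components
        Per-layer output width; ``None`` means C-1.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    X = data.features
    y = data.labels
    layers: list[DiscriminantLayer] = []
    activated = None
    for level in range(1, depth + 1):
        z = X if level == 1 else np.hstack([X, activated])
        try:
            layer = fit_layer(
                z,
                y,
                n_components=n_components,
                ridge=ridge,
                between_class_weighting=between_class_weighting,
            )
        except Exception as exc:
            raise type(exc)(f"layer {level}: {exc}") from exc
        activated = sigmoid_activate(project(layer, z))
        layers.append(layer)
    return SdflModel(
        layers=tuple(layers),
        n_classes=data.n_classes,
        input_dim=data.n_features,
        between_class_weighting=between_class_weighting,
    )


def depth_from_accuracies(accuracies: "list[float] | np.ndarray") -> int:
    """Smallest depth whose accuracy the next depth does not exceed.

    Implements the stopping heuristic "grow until performance stops
    improving"; returns the deepest evaluated depth if accuracy is still
    strictly improving at the end of the list.
    """
    accs = list(accuracies)
    if not accs:
        raise ValidationError("need at least one accuracy")
    for depth in range(1, len(accs)):
        if accs[depth] <= accs[depth - 1]:
            return depth
    return len(accs)


def select_depth(
    train: LabeledFeatureSet,
    validation: LabeledFeatureSet,
    *,
    max_depth: int = 5,
    ridge: float | None = None,
    between_class_weighting: str = "count",
) -> int:
    """Choose the stack depth on a subject-disjoint validation split.

    Fits a single depth-``max_depth`` model (greedy prefix property makes
    its truncations identical to shallower fits), scores each depth with
    the downstream 1-NN classifier on the validation subjects, and returns
    the smallest depth whose accuracy is not exceeded by the next one.

    Raises
    ------
    ValidationError
        If train and validation share any subject (protocol violation).
    """
    from sdfl.evaluation import accuracy_score
    from sdfl.neighbors import fit_nn

    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    overlap = np.intersect1d(train.subject_ids, validation.subject_ids)
    if overlap.size:
        raise ValidationError(
            f"protocol error: subjects {overlap.tolist()} appear in both "
            f"train and validation"
        )
    model = fit_sdfl(
        train,
        depth=max_depth,
        ridge=ridge,
        between_class_weighting=between_class_weighting,
    )
    accuracies = []
    for depth in range(1, max_depth + 1):
        sub = model.truncate(depth)
        train_feats = sub.transform(train.features)
        val_feats = sub.transform(validation.features)
        nn = fit_nn(train_feats, train.labels)
        accuracies.append(accuracy_score(validation.labels, nn.predict(val_feats)))
    return depth_from_accuracies(accuracies)


def save_model(model: SdflModel, path: "str | Path") -> None:
    """Serialize a fitted model to a single versioned ``.npz`` archive."""
    config = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "depth": model.depth,
        "n_classes": model.n_classes,
        "input_dim": model.input_dim,
        "between_class_weighting": model.between_class_weighting,
        "ridges": [layer.ridge for layer in model.layers],
    }
    arrays = {"config_json": np.frombuffer(json.dumps(config).encode(), dtype=np.uint8)}
    for i, layer in enumerate(model.layers):
        arrays[f"mapping_{i}"] = layer.mapping
        arrays[f"eigenvalues_{i}"] = layer.eigenvalues
    buffer = io.BytesIO()
    np.savez(buffer, **arrays)
    Path(path).write_bytes(buffer.getvalue())


def load_model(path: "str | Path") -> SdflModel:
    """Load a model archive written by :func:`save_model`."""
    with np.load(Path(path)) as archive:
        config = json.loads(bytes(archive["config_json"].tobytes()).decode())
        if config.get("format_version") != ARCHIVE_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model archive version {config.get('format_version')}"
            )
        layers = []
        for i in range(config["depth"]):
            mapping = archive[f"mapping_{i}"]
            layers.append(
                DiscriminantLayer(
                    mapping=mapping,
                    eigenvalues=archive[f"eigenvalues_{i}"],
                    ridge=float(config["ridges"][i]),
                    input_dim=mapping.shape[0],
                )
            )
    return SdflModel(
        layers=tuple(layers),
        n_classes=config["n_classes"],
        input_dim=config["input_dim"],
        between_class_weighting=config["between_class_weighting"],
    )
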