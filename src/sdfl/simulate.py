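"""Seeded synthetic data: Gaussian feature clusters and parametric activity signals.

Two generators make the whole pipeline testable without any external
download.  Both model the key difficulty of subject-independent activity
recognition — per-subject covariate shift: the same activity produces
systematically different signals on different people — via a per-subject
random offset (feature space) or gain/phase perturbation (signal space).

All randomness flows from a single spec seed through one child stream per
subject, so adding subjects never perturbs the data of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sdfl.dataset import LabeledFeatureSet, ValidationError

__all__ = [
    "SyntheticSpec",
    "ActivityTemplate",
    "generate_gaussian_features",
    "generate_activity_signals",
    "default_activity_templates",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study population.

    ``separation`` is the pairwise distance between class means in units
    of the (unit) within-class standard deviation; ``subject_shift`` is
    the scale of each subject's mean offset in the same units.  Defaults
    mirror a 6-activity, 30-volunteer cohort.
    """

    n_classes: int = 6
    dim: int = 20
    n_subjects: int = 30
    samples_per_subject_per_class: int = 10
    separation: float = 10.0
    subject_shift: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.dim, self.n_subjects,
               self.samples_per_subject_per_class) < 1:
            raise ValidationError("all counts must be positive")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.separation < 0 or self.subject_shift < 0:
            raise ValidationError("separation and subject_shift must be >= 0")
        if self.dim < self.n_classes - 1:
            raise ValidationError(
                "dim must be >= n_classes - 1 to embed a regular simplex"
            )


def _simplex_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """C class means at exact pairwise distance ``separation``.

    Builds a regular (C-1)-simplex, centres it, scales edges to the
    requested separation and embeds it at a seeded random orientation.
    """
    c, d = spec.n_classes, spec.dim
    vertices = np.eye(c) - 1.0 / c  # centred; pairwise distance sqrt(2)
    # coordinates of the simplex in its (c-1)-dimensional span
    u, s, _ = np.linalg.svd(vertices, full_matrices=False)
    coords = u[:, : c - 1] * s[: c - 1]
    coords *= spec.separation / np.sqrt(2.0)
    # random orthonormal embedding of that span into R^d
    basis, _ = np.linalg.qr(rng.standard_normal((d, c - 1)))
    return coords @ basis.T


def _subject_streams(spec: SyntheticSpec) -> list:
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects + 1)
    return [np.random.default_rng(child) for child in children]


def generate_gaussian_features(spec: SyntheticSpec) -> LabeledFeatureSet:
    """Labelled Gaussian clusters with per-subject covariate shift.

    Class means sit on a regular simplex of edge ``separation``; samples
    are unit-covariance Gaussians around them, and every subject adds one
    fixed offset vector of scale ``subject_shift`` to all of their
    samples.
    """
    streams = _subject_streams(spec)
    means = _simplex_means(spec, streams[0])

    blocks, labels, subjects = [], [], []
    m = spec.samples_per_subject_per_class
    for subject_id in range(1, spec.n_subjects + 1):
        rng = streams[subject_id]
        offset = spec.subject_shift * rng.standard_normal(spec.dim)
        for j in range(1, spec.n_classes + 1):
            samples = means[j - 1] + offset + rng.standard_normal((m, spec.dim))
            blocks.append(samples)
            labels.append(np.full(m, j))
            subjects.append(np.full(m, subject_id))
    return LabeledFeatureSet(
        np.vstack(blocks), np.concatenate(labels), np.concatenate(subjects)
    )


@dataclass(frozen=True)
class ActivityTemplate:
    """Parametric description of one activity's windowed signal.

    Dynamic activities are sinusoids with a gait frequency and per-axis
    amplitudes; static ones are constant orientation vectors whose
    ``gravity`` projection differs between postures (sitting vs standing
    vs laying), which the angle feature can separate.
    """

    name: str
    frequency_hz: float  # 0 for static postures
    amplitudes: tuple  # per-axis oscillation amplitude
    gravity: tuple  # constant per-axis offset (orientation loading)


def default_activity_templates(n_axes: int = 6) -> list:
    """Six templates mirroring common smartphone-HAR activity classes."""
    def pad(values: tuple) -> tuple:
        return tuple((list(values) + [0.0] * n_axes)[:n_axes])

    return [
        ActivityTemplate("walking", 1.8, pad((0.8, 0.4, 1.0, 0.3, 0.3, 0.2)),
                         pad((0.0, 0.0, 1.0))),
        ActivityTemplate("walking_upstairs", 1.4, pad((0.6, 0.5, 0.7, 0.4, 0.2, 0.3)),
                         pad((0.2, 0.0, 0.95))),
        ActivityTemplate("walking_downstairs", 2.2, pad((1.0, 0.6, 1.3, 0.5, 0.4, 0.3)),
                         pad((-0.2, 0.0, 0.95))),
        ActivityTemplate("sitting", 0.0, pad((0.0,) * n_axes),
                         pad((0.4, 0.1, 0.9))),
        ActivityTemplate("standing", 0.0, pad((0.0,) * n_axes),
                         pad((0.0, 0.0, 1.0))),
        ActivityTemplate("laying", 0.0, pad((0.0,) * n_axes),
                         pad((1.0, 0.1, 0.05))),
    ]


def generate_activity_signals(
    spec: SyntheticSpec,
    activity_templates: "list[ActivityTemplate] | None" = None,
    *,
    window_length: int = 128,
    sampling_rate: float = 50.0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw signal windows per (subject, activity) pair.

    Each window is the activity template evaluated with a subject-specific
    gain (1 + subject_shift * z) and phase, plus white Gaussian noise.

    Returns
    -------
    windows, labels, subjects
        ``windows`` has shape (N, T, A); labels index the template list
        from 1 in order.
    """
    templates = activity_templates or default_activity_templates()
    if len(templates) != spec.n_classes:
        raise ValidationError(
            f"{len(templates)} templates for {spec.n_classes} classes"
        )
    n_axes = len(templates[0].amplitudes)
    t = np.arange(window_length) / sampling_rate
    streams = _subject_streams(spec)

    windows, labels, subjects = [], [], []
    m = spec.samples_per_subject_per_class
    for subject_id in range(1, spec.n_subjects + 1):
        rng = streams[subject_id]
        gain = 1.0 + spec.subject_shift * rng.standard_normal()
        for j, tpl in enumerate(templates, start=1):
            for _ in range(m):
                phase = rng.uniform(0.0, 2.0 * np.pi)
                window = np.empty((window_length, n_axes))
                for a in range(n_axes):
                    window[:, a] = tpl.gravity[a] + gain * tpl.amplitudes[a] * np.sin(
                        2.0 * np.pi * tpl.frequency_hz * t + phase
                    )
                window += noise_sd * rng.standard_normal(window.shape)
                windows.append(window)
                labels.append(j)
                subjects.append(subject_id)
    return (
        np.asarray(windows),
        np.asarray(labels, dtype=np.int64),
        np.asarray(subjects, dtype=np.int64),
    )
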