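"""Time- and frequency-domain feature bank for windowed inertial signals.

Computes the classic hand-crafted HAR descriptors — mean, spread, signal
magnitude area, energy, entropy, autoregressive coefficients, inter-axis
correlation, dominant/mean frequency, spectral shape and band energies,
and the angle of the mean window vector against a reference (gravity)
direction — over fixed-length windows of tri-axial accelerometer and
gyroscope samples.

This is an approximate bank: window length, overlap and the exact
expansion into a fixed-width vector are configurable, and no attempt is
made to replicate any specific public dataset's 561-feature layout.  The
discriminant stack downstream accepts any feature matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from sdfl.dataset import ValidationError

__all__ = [
    "InertialWindow",
    "FeatureConfig",
    "extract_window_features",
    "feature_names",
    "extract_feature_matrix",
]


@dataclass(frozen=True)
class InertialWindow:
    """One fixed-length window of multi-axis inertial samples.

    ``samples`` has shape (T, A): T time steps by A signal axes (e.g. 3
    acceleration axes in g followed by 3 angular-velocity axes in rad/s).
    """

    samples: np.ndarray
    sampling_rate: float = 50.0

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not np.all(np.isfinite(x)):
            raise ValidationError("window contains non-finite samples")
        if x.shape[0] < 8:
            raise ValidationError(
                f"window too short: {x.shape[0]} samples, need >= 8"
            )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        object.__setattr__(self, "samples", x)


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature bank; output length is a pure function of these.

    ``axis_group_size`` controls how axes are bundled into sensor triples
    for magnitude, SMA, correlation and angle features; axes are grouped
    consecutively, and if the axis count is not divisible by the group
    size all axes form one group.  ``reference_vector`` is the gravity
    direction the angle feature measures against, expressed in group
    coordinates (padded/truncated to the group width).
    """

    ar_order: int = 4
    entropy_bins: int = 16
    n_energy_bands: int = 4
    axis_group_size: int = 3
    reference_vector: tuple = (0.0, 0.0, 1.0)


def _axis_groups(n_axes: int, config: FeatureConfig) -> list:
    g = config.axis_group_size
    if g >= 2 and n_axes % g == 0:
        return [list(range(i, i + g)) for i in range(0, n_axes, g)]
    return [list(range(n_axes))]


def _scalar_feature_names(config: FeatureConfig) -> list:
    names = ["mean", "std", "mad", "max", "min", "energy", "iqr", "entropy"]
    names += [f"arCoeff{k + 1}" for k in range(config.ar_order)]
    names += ["maxFreqInd", "meanFreq", "spectralSkewness", "spectralKurtosis"]
    names += [f"energyBand{k + 1}" for k in range(config.n_energy_bands)]
    return names


def feature_names(n_axes: int, config: FeatureConfig = FeatureConfig()) -> list:
    """Ordered feature names produced by :func:`extract_window_features`."""
    scalar = _scalar_feature_names(config)
    names = []
    for a in range(n_axes):
        names += [f"axis{a + 1}_{s}" for s in scalar]
    for gi, group in enumerate(_axis_groups(n_axes, config), start=1):
        names += [f"group{gi}Mag_{s}" for s in scalar]
    for gi, group in enumerate(_axis_groups(n_axes, config), start=1):
        names.append(f"group{gi}_sma")
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                names.append(f"group{gi}_corr{group[i] + 1}{group[j] + 1}")
        names.append(f"group{gi}_angle")
    return names


def _signal_entropy(x: np.ndarray, bins: int) -> float:
    # Shannon entropy (nats) of the normalized histogram of |x|
    counts, _ = np.histogram(np.abs(x), bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _ar_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    # least-squares AR fit: x[t] ~ sum_k a_k x[t-k]
    T = x.shape[0]
    design = np.column_stack([x[order - k - 1 : T - k - 1] for k in range(order)])
    target = x[order:]
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    return coeffs


def _scalar_features(x: np.ndarray, fs: float, config: FeatureConfig) -> list:
    feats = [
        float(np.mean(x)),
        float(np.std(x)),
        float(np.median(np.abs(x))),
        float(np.max(x)),
        float(np.min(x)),
        float(np.mean(x**2)),
        float(np.subtract(*np.percentile(x, [75, 25]))),
        _signal_entropy(x, config.entropy_bins),
    ]
    feats += list(_ar_coefficients(x, config.ar_order))

    spectrum = np.abs(np.fft.rfft(x))
    power = spectrum**2
    total = power.sum()
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / fs)
    feats.append(float(np.argmax(spectrum)))
    feats.append(float((freqs * power).sum() / total) if total > 0 else 0.0)
    if np.ptp(spectrum) > 0:
        feats.append(float(scipy.stats.skew(spectrum)))
        feats.append(float(scipy.stats.kurtosis(spectrum)))
    else:
        feats += [0.0, 0.0]
    bands = np.array_split(power, config.n_energy_bands)
    feats += [float(b.sum()) for b in bands]
    return feats


def extract_window_features(
    window: InertialWindow, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Compute the full feature vector of one window.

    Scalar descriptors are computed for every axis and for the Euclidean
    magnitude signal of each axis group; each group additionally yields
    SMA, the pairwise Pearson correlations of its axes, and the angle
    between its mean vector and the reference (gravity) direction.
    Ordering matches :func:`feature_names`.
    """
    x = window.samples
    T, n_axes = x.shape
    if T < config.ar_order + 1:
        raise ValidationError(
            f"window length {T} < AR order + 1 = {config.ar_order + 1}"
        )
    fs = window.sampling_rate
    groups = _axis_groups(n_axes, config)

    feats: list = []
    for a in range(n_axes):
        feats += _scalar_features(x[:, a], fs, config)
    for group in groups:
        magnitude = np.linalg.norm(x[:, group], axis=1)
        feats += _scalar_features(magnitude, fs, config)
    for group in groups:
        block = x[:, group]
        feats.append(float(np.mean(np.abs(block).sum(axis=1))))
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = block[:, i], block[:, j]
                if a.std() == 0 or b.std() == 0:
                    warnings.warn(
                        "zero-variance axis: correlation feature set to 0",
                        stacklevel=2,
                    )
                    feats.append(0.0)
                else:
                    feats.append(float(np.corrcoef(a, b)[0, 1]))
        mean_vec = block.mean(axis=0)
        ref = np.zeros(len(group))
        width = min(len(group), len(config.reference_vector))
        ref[:width] = config.reference_vector[:width]
        norms = np.linalg.norm(mean_vec) * np.linalg.norm(ref)
        if norms == 0:
            feats.append(0.0)
        else:
            cosine = np.clip(mean_vec @ ref / norms, -1.0, 1.0)
            feats.append(float(np.arccos(cosine)))
    return np.asarray(feats, dtype=np.float64)


def extract_feature_matrix(
    windows: "list[InertialWindow] | np.ndarray",
    config: FeatureConfig = FeatureConfig(),
    sampling_rate: float = 50.0,
) -> np.ndarray:
    """Stack per-window feature vectors into an (N, p) matrix.

    ``windows`` may be a list of :class:`InertialWindow` or a raw
    (N, T, A) array, in which case ``sampling_rate`` applies to all.
    """
    if isinstance(windows, np.ndarray):
        windows = [InertialWindow(w, sampling_rate) for w in windows]
    return np.vstack([extract_window_features(w, config) for w in windows])
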