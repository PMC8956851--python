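"""Single discriminant layer: scatter matrices, Rayleigh-coefficient solve.

A layer maximizes Fisher's criterion

    J(phi) = (phi^T S_b phi) / (phi^T S_w phi)

where S_w is the within-class ("intrapersonal") scatter and S_b the
between-class ("interpersonal") scatter of its input.  The maximizers are
the leading generalized eigenvectors of (S_b, S_w + ridge*I); at most C-1
of them carry discriminative information, so a layer projects to C-1
dimensions before the sigmoid nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import expit

from sdfl.dataset import DegenerateClassError, ValidationError

__all__ = [
    "ScatterPair",
    "DiscriminantLayer",
    "compute_scatter",
    "fit_layer",
    "project",
    "sigmoid_activate",
    "auto_ridge",
]


@dataclass(frozen=True)
class ScatterPair:
    """Within- and between-class scatter matrices of one layer's input.

    ``sigma_intra + sigma_inter`` equals the total scatter
    ``sum_i (x_i - mu)(x_i - mu)^T`` when the count-weighted between-class
    form is used (the default), which the constructor does not enforce but
    tests rely on.
    """

    sigma_intra: np.ndarray  # (d, d) within-class scatter
    sigma_inter: np.ndarray  # (d, d) between-class scatter
    class_means: np.ndarray  # (C, d), row j-1 is mu_j
    total_mean: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        for name in ("sigma_intra", "sigma_inter"):
            m = getattr(self, name)
            scale = max(np.abs(m).max(), 1.0)
            if not np.allclose(m, m.T, rtol=0.0, atol=1e-10 * scale):
                raise ValidationError(f"{name} is not symmetric")


@dataclass(frozen=True)
class DiscriminantLayer:
    """Fitted discriminant mapping for one stacking level.

    ``mapping`` holds unit-norm generalized eigenvectors as columns, ordered
    by descending eigenvalue, each sign-fixed so its largest-magnitude entry
    is positive.
    """

    mapping: np.ndarray  # (d_l, n_components)
    eigenvalues: np.ndarray  # (n_components,), non-increasing
    ridge: float
    input_dim: int

    @property
    def n_components(self) -> int:
        return self.mapping.shape[1]


def _check_features_labels(
    features: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64).ravel()
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels disagree on sample count")
    classes = np.unique(y)
    expected = np.arange(1, classes.size + 1)
    if not np.array_equal(classes, expected):
        raise DegenerateClassError(
            f"degenerate class structure: labels {classes.tolist()} are not "
            f"a contiguous 1..C set"
        )
    if X.shape[0] < classes.size:
        raise DegenerateClassError("fewer samples than classes")
    return X, y, classes


def compute_scatter(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    between_class_weighting: str = "count",
) -> ScatterPair:
    """Compute the within/between-class scatter pair of a labelled matrix.

    Parameters
    ----------
    features
        (N, d) matrix; at deeper stacking levels this is the stacking
        vector ``z^l = [x ; activated features of layer l-1]``.
    labels
        Length-N class labels, contiguous ``1..C``.
    between_class_weighting
        ``"count"`` (default) weights each class-mean deviation by its
        sample count m_j, which makes within + between equal the total
        scatter; ``"uniform"`` drops the m_j weight.

    Returns
    -------
    ScatterPair
        With ``total_mean`` the ordinary sample mean ``(1/N) sum_i x_i``.
    """
    if between_class_weighting not in ("count", "uniform"):
        raise ValidationError(
            f"unknown between_class_weighting {between_class_weighting!r}"
        )
    X, y, classes = _check_features_labels(features, labels)
    n, d = X.shape
    n_classes = classes.size

    mu = X.mean(axis=0)
    class_means = np.empty((n_classes, d))
    sigma_intra = np.zeros((d, d))
    sigma_inter = np.zeros((d, d))
    for j in range(1, n_classes + 1):
        Xj = X[y == j]
        mu_j = Xj.mean(axis=0)
        class_means[j - 1] = mu_j
        centred = Xj - mu_j
        sigma_intra += centred.T @ centred
        dev = mu_j - mu
        weight = Xj.shape[0] if between_class_weighting == "count" else 1.0
        sigma_inter += weight * np.outer(dev, dev)

    # enforce exact symmetry against accumulated round-off
    sigma_intra = 0.5 * (sigma_intra + sigma_intra.T)
    sigma_inter = 0.5 * (sigma_inter + sigma_inter.T)
    return ScatterPair(sigma_intra, sigma_inter, class_means, mu)


def auto_ridge(sigma_intra: np.ndarray, scale: float = 1e-6) -> float:
    """Default Tikhonov strength: ``scale * trace(S_w) / d``.

    Keeps S_w + ridge*I invertible in small-sample regimes (n < d) where
    the within-class scatter is rank deficient; negligible otherwise.
    """
    d = sigma_intra.shape[0]
    return float(scale * np.trace(sigma_intra) / d)


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| coefficient is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit_layer(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    n_components: int | None = None,
    ridge: float | None = None,
    between_class_weighting: str = "count",
) -> DiscriminantLayer:
    """Fit one discriminant layer by solving the generalized eigenproblem.

    Solves ``S_b phi = lambda (S_w + ridge*I) phi`` and keeps the
    ``n_components`` eigenvectors of largest eigenvalue (default C-1, the
    rank bound of S_b).

    Parameters
    ----------
    ridge
        Non-negative Tikhonov term added to S_w.  ``None`` selects
        :func:`auto_ridge`.

    Raises
    ------
    ValidationError
        If ``n_components > C - 1`` or ``ridge < 0``.
    numpy.linalg.LinAlgError
        If S_w + ridge*I is numerically singular (raise ``ridge``).
    """
    X, y, classes = _check_features_labels(features, labels)
    n_classes = classes.size
    max_components = n_classes - 1
    if n_components is None:
        n_components = max_components
    if not 1 <= n_components <= max_components:
        raise ValidationError(
            f"n_components must be in 1..C-1={max_components}, got {n_components}"
        )

    pair = compute_scatter(X, y, between_class_weighting=between_class_weighting)
    if ridge is None:
        ridge = auto_ridge(pair.sigma_intra)
    if ridge < 0:
        raise ValidationError("ridge must be non-negative")

    d = X.shape[1]
    regularized = pair.sigma_intra + ridge * np.eye(d)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(pair.sigma_inter, regularized)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "within-class scatter plus ridge is numerically singular; "
            "increase the ridge parameter"
        ) from exc

    order = np.argsort(eigvals)[::-1][:n_components]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvecs /= np.linalg.norm(eigvecs, axis=0)
    eigvecs = _sign_fix(eigvecs)

    # deterministic order under exactly tied eigenvalues: lexicographic on
    # the sign-fixed coefficient vectors
    for start in range(n_components - 1):
        if eigvals[start] == eigvals[start + 1]:
            tied = np.flatnonzero(eigvals == eigvals[start])
            perm = np.lexsort(eigvecs[::-1, tied])
            eigvecs[:, tied] = eigvecs[:, tied[perm]]

    return DiscriminantLayer(
        mapping=eigvecs,
        eigenvalues=eigvals,
        ridge=float(ridge),
        input_dim=d,
    )


def project(layer: DiscriminantLayer, features: np.ndarray) -> np.ndarray:
    """Project rows onto the discriminant subspace: ``x_hat = Phi^T x``."""
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != layer.input_dim:
        raise ValidationError(
            f"expected {layer.input_dim} columns, got {X.shape[1]}"
        )
    out = X @ layer.mapping
    return out[0] if single else out


def sigmoid_activate(values: np.ndarray) -> np.ndarray:
    """Elementwise logistic activation ``1 / (1 + exp(-x))``.

    Saturates gracefully for large |x|; outputs are strictly inside (0, 1).
    """
    return expit(np.asarray(values, dtype=np.float64))
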