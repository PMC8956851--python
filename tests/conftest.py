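"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized code paths:
scatter matrices are accumulated sample by sample with explicit Python
loops, the Fisher subspace is recovered from eig(S_w^-1 S_b), and metrics
are counted pairwise — so agreement with the library is a genuine
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from sdfl import LabeledFeatureSet


def brute_force_scatter(X: np.ndarray, y: np.ndarray):
    """Per-sample-loop within/between scatter (count-weighted between)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    classes = sorted(set(y.tolist()))
    mu = np.zeros(d)
    for i in range(n):
        mu += X[i]
    mu /= n
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    for j in classes:
        rows = [X[i] for i in range(n) if y[i] == j]
        mu_j = np.zeros(d)
        for r in rows:
            mu_j += r
        mu_j /= len(rows)
        for r in rows:
            dev = r - mu_j
            s_w += np.outer(dev, dev)
        dev = mu_j - mu
        s_b += len(rows) * np.outer(dev, dev)
    return s_w, s_b


def brute_force_fisher_subspace(
    X: np.ndarray, y: np.ndarray, n_components: int, ridge: float = 0.0
) -> np.ndarray:
    """Leading Fisher directions from eig(S_w^-1 S_b), unit-normalized."""
    s_w, s_b = brute_force_scatter(X, y)
    s_w = s_w + ridge * np.eye(s_w.shape[0])
    eigvals, eigvecs = np.linalg.eig(np.linalg.inv(s_w) @ s_b)
    order = np.argsort(eigvals.real)[::-1][:n_components]
    basis = eigvecs[:, order].real
    return basis / np.linalg.norm(basis, axis=0)


def principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spans of a and b."""
    qa, _ = np.linalg.qr(a)
    qb, _ = np.linalg.qr(b)
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(sv, -1.0, 1.0))


def rayleigh_quotient(v: np.ndarray, s_b: np.ndarray, s_w: np.ndarray) -> float:
    return float((v @ s_b @ v) / (v @ s_w @ v))


def random_labeled_dataset(
    rng: np.random.Generator,
    n_classes: int,
    dim: int,
    n_per_class: int,
    separation: float = 3.0,
    n_subjects: int = 4,
) -> LabeledFeatureSet:
    """Small Gaussian dataset with all classes present, built inline."""
    means = separation * rng.standard_normal((n_classes, dim))
    features, labels = [], []
    for j in range(1, n_classes + 1):
        features.append(means[j - 1] + rng.standard_normal((n_per_class, dim)))
        labels.append(np.full(n_per_class, j))
    features = np.vstack(features)
    labels = np.concatenate(labels)
    subjects = rng.integers(1, n_subjects + 1, size=labels.size)
    return LabeledFeatureSet(features, labels, subjects)


def counting_metric_oracle(true_labels, predicted_labels, n_classes: int) -> dict:
    """Independent per-class metric computation by explicit counting."""
    y = list(map(int, true_labels))
    p = list(map(int, predicted_labels))
    out = {"accuracy": sum(a == b for a, b in zip(y, p)) / len(y)}
    per = {"tp_rate": [], "fp_rate": [], "precision": [], "recall": [], "f_score": []}
    for j in range(1, n_classes + 1):
        tp = sum(1 for a, b in zip(y, p) if a == j and b == j)
        fp = sum(1 for a, b in zip(y, p) if a != j and b == j)
        fn = sum(1 for a, b in zip(y, p) if a == j and b != j)
        tn = len(y) - tp - fp - fn
        recall = tp / (tp + fn) if tp + fn else float("nan")
        precision = tp / (tp + fp) if tp + fp else float("nan")
        fp_rate = fp / (fp + tn) if fp + tn else float("nan")
        f = (2 * precision * recall / (precision + recall)
             if precision + recall > 0 else float("nan"))
        per["tp_rate"].append(recall)
        per["recall"].append(recall)
        per["precision"].append(precision)
        per["fp_rate"].append(fp_rate)
        per["f_score"].append(f)
    for key, vals in per.items():
        defined = [v for v in vals if v == v]
        out[f"macro_{key}"] = sum(defined) / len(defined)
        out[f"per_class_{key}"] = vals
    return out


def mann_whitney_auc(positive_scores, negative_scores) -> float:
    """AUC by direct pair counting with half-credit for ties."""
    wins = ties = 0
    for sp in positive_scores:
        for sn in negative_scores:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(positive_scores) * len(negative_scores))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_two_class() -> LabeledFeatureSet:
    """Four points in 2-D with hand-computable scatter matrices."""
    X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
    y = np.array([1, 1, 2, 2])
    return LabeledFeatureSet(X, y, np.array([1, 2, 1, 2]))


@pytest.fixture
def gaussian_six_class(rng) -> LabeledFeatureSet:
    return random_labeled_dataset(rng, n_classes=6, dim=8, n_per_class=20,
                                  separation=4.0, n_subjects=6)
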