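"""Closed-form training and prediction for Extreme Learning Machine variants.

Three variants of the single-output binary classifier are provided:

``full_kernel``
    Kernel ELM using every training sample as a reference point.  With kernel
    matrix D over the training set and targets C in {+1, -1}^N, the output
    weights S solve the ridge-regularised system (I/E + D) S = C, and the
    decision score of a new point r is u(r) = [b(r, x_1), ..., b(r, x_N)] S.

``center_subset``
    Kernel-neuron ELM with K centers drawn from the training rows by a seeded
    shuffle.  With the N-by-K kernel activation matrix A (A_ik = b(x_i, c_k)),
    S = A^T (I/E + A A^T)^{-1} C — the standard regularised ELM solution with
    A as the hidden-layer output matrix.  This is the variant whose
    hidden-neuron count a hyperparameter search can tune.

``random_feature``
    The classic ELM baseline: random input weights and biases drawn uniform
    on (-1, 1), a fixed nonlinear activation, and output weights given by the
    Moore-Penrose pseudoinverse of the hidden-layer matrix.

E is the regulation coefficient (ridge constant); larger E means weaker
regularisation.  Features are z-scored with statistics fit on the training
split only, because voice features span orders of magnitude (Hz vs. ratios).
Labels are encoded +1/-1 with decision threshold 0; ties go to the positive
class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg

from .data import standardize_apply, standardize_fit
from .kernels import KernelSpec, kernel_matrix

__all__ = [
    "TrainConfig",
    "WKELMModel",
    "ACTIVATIONS",
    "fit",
    "decision_scores",
    "predict",
    "save_model",
    "load_model",
]

VARIANTS = ("full_kernel", "center_subset", "random_feature")

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tangent_sigmoid": np.tanh,
    "triangular_basis": lambda z: np.maximum(0.0, 1.0 - np.abs(z)),
    "radial_basis": lambda z: np.exp(-(z**2)),
    "hard_limit": lambda z: (z >= 0).astype(float),
}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    E: regulation coefficient (> 0).  n_hidden: number of kernel centers
    (center_subset) or random hidden neurons (random_feature); ignored by
    full_kernel.  activation applies to random_feature only.
    """

    E: float = 1.0
    variant: str = "full_kernel"
    n_hidden: int = 40
    activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"regulation coefficient E must be > 0, got {self.E}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected {VARIANTS}")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; expected {tuple(ACTIVATIONS)}"
            )


@dataclass
class WKELMModel:
    """A fitted ELM classifier."""

    variant: str
    kernel: KernelSpec | None
    reference_points: np.ndarray | None  # standardized training samples / centers
    output_weights: np.ndarray
    input_weights: np.ndarray | None  # random_feature only, shape (p, K)
    biases: np.ndarray | None  # random_feature only, shape (K,)
    activation: str | None  # random_feature only
    mean: np.ndarray
    sd: np.ndarray
    positive_label: object
    negative_label: object
    E: float = 1.0

    # convenience delegates so a model works as a pipeline product
    def decision_scores(self, X) -> np.ndarray:
        return decision_scores(self, X)

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def _encode_labels(labels, positive_label=None):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.shape[0] != 2:
        raise ValueError(
            f"training requires exactly two classes, found {classes.shape[0]}"
        )
    if positive_label is None:
        positive_label = classes[-1]
    elif positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not present in labels")
    negative_label = classes[0] if classes[1] == positive_label else classes[1]
    C = np.where(labels == positive_label, 1.0, -1.0)
    return C, positive_label, negative_label


def _solve_sym(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Solve M s = C for symmetric M, falling back to least squares."""
    try:
        s = scipy.linalg.solve(M, C, assume_a="sym")
        if not np.all(np.isfinite(s)):
            raise np.linalg.LinAlgError("non-finite solution")
        return s
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
        warnings.warn(
            "ill-conditioned system; falling back to least squares", RuntimeWarning
        )
        s, *_ = np.linalg.lstsq(M, C, rcond=None)
        return s


def fit(
    X,
    labels,
    kernel: KernelSpec | None = None,
    config: TrainConfig | None = None,
    positive_label=None,
) -> WKELMModel:
    """Train an ELM classifier in closed form.

    Standardizes features (z-score fit on ``X``), encodes labels as +1/-1 and
    solves the variant's defining linear system.  Deterministic given
    ``(X, labels, kernel, config)`` including the seed.
    """
    config = config or TrainConfig()
    if kernel is None and config.variant != "random_feature":
        kernel = KernelSpec()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    n = X.shape[0]
    C, pos, neg = _encode_labels(labels, positive_label)

    stats = standardize_fit(X)
    Z = standardize_apply(stats, X)

    common = dict(
        kernel=kernel,
        input_weights=None,
        biases=None,
        activation=None,
        mean=stats[0],
        sd=stats[1],
        positive_label=pos,
        negative_label=neg,
        E=config.E,
    )

    if config.variant == "full_kernel":
        D = kernel_matrix(Z, Z, kernel)
        S = _solve_sym(np.eye(n) / config.E + D, C)
        return WKELMModel("full_kernel", reference_points=Z, output_weights=S, **common)

    if config.variant == "center_subset":
        if config.n_hidden > n:
            raise ValueError(
                f"n_hidden ({config.n_hidden}) exceeds training-set size ({n})"
            )
        rng = np.random.default_rng(config.seed)
        centers = Z[rng.permutation(n)[: config.n_hidden]]
        A = kernel_matrix(Z, centers, kernel)  # N x K hidden-layer output matrix
        S = A.T @ _solve_sym(np.eye(n) / config.E + A @ A.T, C)
        return WKELMModel(
            "center_subset", reference_points=centers, output_weights=S, **common
        )

    # random_feature: H_ik = f(l_k . x_i + b_k), beta = pinv(H) C
    rng = np.random.default_rng(config.seed)
    p = X.shape[1]
    l = rng.uniform(-1.0, 1.0, size=(p, config.n_hidden))
    b = rng.uniform(-1.0, 1.0, size=config.n_hidden)
    H = ACTIVATIONS[config.activation](Z @ l + b)
    beta = np.linalg.pinv(H) @ C
    common.update(input_weights=l, biases=b, activation=config.activation, kernel=None)
    return WKELMModel(
        "random_feature", reference_points=None, output_weights=beta, **common
    )


def decision_scores(model: WKELMModel, X) -> np.ndarray:
    """Real-valued decision scores u(r), one per row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    Z = standardize_apply((model.mean, model.sd), X)
    if model.variant == "random_feature":
        H = ACTIVATIONS[model.activation](Z @ model.input_weights + model.biases)
        return H @ model.output_weights
    return kernel_matrix(Z, model.reference_points, model.kernel) @ model.output_weights


def predict(model: WKELMModel, X) -> np.ndarray:
    """Class labels: positive class iff the decision score is >= 0."""
    u = decision_scores(model, X)
    out = np.where(u >= 0, model.positive_label, model.negative_label)
    return out


_FORMAT_VERSION = 1


def _arr(a):
    return None if a is None else np.asarray(a).tolist()


def save_model(model: WKELMModel, path) -> None:
    """Serialize a fitted model to a JSON document (round-trip exact)."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "variant": model.variant,
        "kernel": None if model.kernel is None else model.kernel.to_dict(),
        "reference_points": _arr(model.reference_points),
        "output_weights": _arr(model.output_weights),
        "input_weights": _arr(model.input_weights),
        "biases": _arr(model.biases),
        "activation": model.activation,
        "mean": _arr(model.mean),
        "sd": _arr(model.sd),
        "positive_label": np.asarray(model.positive_label).item(),
        "negative_label": np.asarray(model.negative_label).item(),
        "E": model.E,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> WKELMModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")

    def arr(key):
        v = doc[key]
        return None if v is None else np.asarray(v, dtype=float)

    return WKELMModel(
        variant=doc["variant"],
        kernel=None if doc["kernel"] is None else KernelSpec.from_dict(doc["kernel"]),
        reference_points=arr("reference_points"),
        output_weights=arr("output_weights"),
        input_weights=arr("input_weights"),
        biases=arr("biases"),
        activation=doc["activation"],
        mean=arr("mean"),
        sd=arr("sd"),
        positive_label=doc["positive_label"],
        negative_label=doc["negative_label"],
        E=doc["E"],
    )
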