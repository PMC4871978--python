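"""Kernel functions for kernel-ELM classification.

The workhorse here is a translation-invariant *wavelet kernel*: the product
of an oscillatory cosine factor and a Gaussian envelope,

    b(r, g) = cos(w * ||r - g|| / x) * exp(-||r - g||**2 / y),

parameterised by an oscillation frequency ``w``, an oscillation scale ``x``
and an envelope width ``y`` (all dimensionless; ``y > 0``).  An alternative
per-dimension product form,

    b(r, g) = prod_k cos(w * (r_k - g_k) / x) * exp(-(r_k - g_k)**2 / y),

is available via ``KernelSpec(form="product")``; the norm-based form is the
default everywhere.  Classical kernels (linear, polynomial, Gaussian,
exponential) are provided for baseline comparisons.

Note that the norm-based wavelet kernel is not guaranteed positive
semidefinite; downstream solvers must not rely on PSD-ness.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "wavelet_kernel", "kernel_value", "kernel_matrix"]

FAMILIES = ("wavelet", "linear", "polynomial", "gaussian", "exponential")

#: families for which k(r, r) == 1 and k depends only on r - g
TRANSLATION_INVARIANT = ("wavelet", "gaussian", "exponential")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its parameters.

    Parameters
    ----------
    family
        One of ``wavelet``, ``linear``, ``polynomial``, ``gaussian``,
        ``exponential``.
    w, x, y
        Wavelet-kernel parameters (ignored by other families).  When produced
        by the genetic-algorithm decoder each lies in ``[1, 16]``.  Defaults
        (w=1, x=16, y=16) suit z-scored inputs of a couple of dozen features,
        where typical squared distances are around twice the dimension: the
        envelope stays informative and the cosine varies slowly.
    degree
        Polynomial degree (polynomial family only).
    gamma
        Width parameter for the gaussian/exponential families.
    form
        ``"norm"`` (default) or ``"product"`` — which wavelet reading to use.
    """

    family: str = "wavelet"
    w: float = 1.0
    x: float = 16.0
    y: float = 16.0
    degree: int = 2
    gamma: float = 1.0
    form: str = "norm"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.form not in ("norm", "product"):
            raise ValueError(f"unknown wavelet form {self.form!r}")
        if self.family == "wavelet":
            if not self.y > 0:
                raise ValueError(f"wavelet parameter y must be > 0, got {self.y}")
            if self.x == 0:
                raise ValueError("wavelet parameter x must be nonzero")
        if self.family == "polynomial" and self.degree < 1:
            raise ValueError(f"polynomial degree must be >= 1, got {self.degree}")
        if self.family in ("gaussian", "exponential") and not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    @classmethod
    def from_dict(cls, mapping: dict) -> "KernelSpec":
        """Build a spec from a config mapping, rejecting unknown keys."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown kernel config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _as_vectors(r, g) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    if r.shape != g.shape:
        raise ValueError(f"vector dimensions differ: {r.shape[0]} vs {g.shape[0]}")
    return r, g


def wavelet_kernel(r, g, spec: KernelSpec) -> float:
    """Evaluate the wavelet kernel between two feature vectors.

    Returns a value in ``[-1, 1]``, symmetric in ``(r, g)`` and equal to 1
    when ``r == g``.
    """
    if spec.family != "wavelet":
        raise ValueError(f"wavelet_kernel called with family {spec.family!r}")
    r, g = _as_vectors(r, g)
    delta = r - g
    if spec.form == "product":
        return float(
            np.prod(np.cos(spec.w * delta / spec.x) * np.exp(-(delta**2) / spec.y))
        )
    d = float(np.linalg.norm(delta))
    return float(np.cos(spec.w * d / spec.x) * np.exp(-(d * d) / spec.y))


def kernel_value(r, g, spec: KernelSpec) -> float:
    """Evaluate the kernel named by ``spec.family`` between two vectors."""
    if spec.family == "wavelet":
        return wavelet_kernel(r, g, spec)
    r, g = _as_vectors(r, g)
    if spec.family == "linear":
        return float(r @ g)
    if spec.family == "polynomial":
        return float((r @ g + 1.0) ** spec.degree)
    d = float(np.linalg.norm(r - g))
    if spec.family == "gaussian":
        return float(np.exp(-spec.gamma * d * d))
    if spec.family == "exponential":
        return float(np.exp(-spec.gamma * d))
    raise ValueError(f"unknown kernel family {spec.family!r}")  # pragma: no cover


def kernel_matrix(X1, X2, spec: KernelSpec) -> np.ndarray:
    """Pairwise kernel matrix: entry (i, j) = k(X1[i], X2[j]).

    Vectorised; agrees with the scalar :func:`kernel_value` double loop.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {X1.shape[1]} vs {X2.shape[1]}"
        )
    if spec.family == "linear":
        return X1 @ X2.T
    if spec.family == "polynomial":
        return (X1 @ X2.T + 1.0) ** spec.degree
    if spec.family == "wavelet" and spec.form == "product":
        diff = X1[:, None, :] - X2[None, :, :]
        return np.prod(
            np.cos(spec.w * diff / spec.x) * np.exp(-(diff**2) / spec.y), axis=2
        )
    d = cdist(X1, X2)
    if spec.family == "wavelet":
        return np.cos(spec.w * d / spec.x) * np.exp(-(d**2) / spec.y)
    if spec.family == "gaussian":
        return np.exp(-spec.gamma * d**2)
    if spec.family == "exponential":
        return np.exp(-spec.gamma * d)
    raise ValueError(f"unknown kernel family {spec.family!r}")  # pragma: no cover
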