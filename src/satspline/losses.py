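"""Pointwise convex losses with values and first derivatives.

All losses are convex and differentiable in the prediction argument; the
outer solver only ever needs values and gradients.  (A private curvature
helper exists for the 1-D intercept Newton step and the test oracle.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["LossSpec", "loss_value_grad", "dataset_loss_grad"]

KINDS = ("squared", "logistic", "pseudo_huber")

#: pseudo-Huber transition parameter used in the robust-regression example
DEFAULT_DELTA = 0.0015


@dataclass(frozen=True)
class LossSpec:
    """Loss selector: ``kind`` in {squared, logistic, pseudo_huber}."""

    kind: str
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; choose from {KINDS}")
        if self.kind == "pseudo_huber" and not self.delta > 0:
            raise ValueError("pseudo_huber requires delta > 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "delta": self.delta}

    @classmethod
    def from_dict(cls, doc: dict) -> "LossSpec":
        return cls(kind=doc["kind"], delta=doc.get("delta", DEFAULT_DELTA))


def _check_logistic_labels(y: np.ndarray) -> None:
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("logistic loss requires labels in {-1, +1}")


def loss_value_grad(spec: LossSpec, z, y):
    """Pointwise loss value and derivative w.r.t. the prediction ``z``.

    Vectorized over ``z`` and ``y``; scalar inputs give scalar outputs.
    """
    z_arr = np.asarray(z, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("nonfinite prediction passed to loss")
    if spec.kind == "squared":
        u = z_arr - y_arr
        val, grad = 0.5 * u * u, u
    elif spec.kind == "logistic":
        _check_logistic_labels(y_arr)
        m = z_arr * y_arr
        # log(1 + e^{-m}) and -y * sigma(-m), both overflow-safe
        val = np.logaddexp(0.0, -m)
        grad = -y_arr * expit(-m)
    else:  # pseudo_huber
        u = z_arr - y_arr
        r = np.sqrt(1.0 + u * u / spec.delta)
        val = spec.delta * (r - 1.0)
        grad = u / r
    if np.isscalar(z) and np.isscalar(y):
        return float(val), float(grad)
    return val, grad


def dataset_loss_grad(spec: LossSpec, z: np.ndarray, y: np.ndarray):
    """Total loss over a dataset and its gradient vector in prediction space."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    if z.shape != y.shape:
        raise ValueError(f"length mismatch: predictions {z.shape} vs responses {y.shape}")
    val, grad = loss_value_grad(spec, z, y)
    return float(np.sum(val)), grad


def _second_derivative(spec: LossSpec, z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d^2/dz^2 of the pointwise loss.  Internal: intercept Newton + oracle."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.kind == "squared":
        return np.ones_like(z)
    if spec.kind == "logistic":
        m = z * y
        return expit(m) * expit(-m)
    u = z - y
    return (1.0 + u * u / spec.delta) ** -1.5
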