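"""Atomic measures and saturating degree-one spline models.

A fitted spline is stored through its "second derivative": a finitely
supported signed measure on ``{0..D-1} x [0, 1]``.  Each atom contributes a
hinge basis function ``x -> (x - t)_+`` on one coordinate; requiring the
atom weights of every coordinate to sum to zero makes the spline extend as
a constant outside the scaled data range (saturation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "KnotAtom",
    "AtomicMeasure",
    "SplineModel",
    "eval_basis",
    "eval_spline",
    "tv_norm",
    "net_mass",
    "prune_merge",
    "validate_model",
]

MODEL_FILE_VERSION = 1


@dataclass(frozen=True)
class KnotAtom:
    """A single weighted knot: coordinate index, location in [0, 1], weight."""

    coord: int
    t: float
    w: float

    def __post_init__(self) -> None:
        if self.coord < 0:
            raise ValueError(f"coord must be nonnegative, got {self.coord}")
        if not (0.0 <= self.t <= 1.0):
            raise ValueError(f"knot location t={self.t} outside [0, 1]")
        if not math.isfinite(self.w):
            raise ValueError("atom weight must be finite")


@dataclass
class AtomicMeasure:
    """Finitely supported signed measure on ``{0..D-1} x [0, 1]``.

    Atoms sharing a ``(coord, t)`` pair are merged (weights summed) on
    construction, and atoms are kept sorted by ``(coord, t)`` so that equal
    measures have identical representations.
    """

    atoms: list[KnotAtom]
    D: int

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")
        for a in self.atoms:
            if a.coord >= self.D:
                raise ValueError(f"atom coord {a.coord} out of range for D={self.D}")
        merged: dict[tuple[int, float], float] = {}
        for a in self.atoms:
            key = (a.coord, a.t)
            merged[key] = merged.get(key, 0.0) + a.w
        self.atoms = [KnotAtom(c, t, w) for (c, t), w in sorted(merged.items())]

    @classmethod
    def empty(cls, D: int) -> "AtomicMeasure":
        return cls([], D)

    @classmethod
    def from_arrays(cls, coords, ts, ws, D: int) -> "AtomicMeasure":
        atoms = [
            KnotAtom(int(c), float(t), float(w))
            for c, t, w in zip(coords, ts, ws, strict=True)
        ]
        return cls(atoms, D)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (coords, ts, ws) as parallel numpy arrays."""
        if not self.atoms:
            return (np.zeros(0, dtype=int), np.zeros(0), np.zeros(0))
        coords = np.array([a.coord for a in self.atoms], dtype=int)
        ts = np.array([a.t for a in self.atoms])
        ws = np.array([a.w for a in self.atoms])
        return coords, ts, ws

    def tv(self) -> float:
        return float(sum(abs(a.w) for a in self.atoms))

    def net_mass(self, coord: int) -> float:
        return float(sum(a.w for a in self.atoms if a.coord == coord))

    def prune_merge(self, w_tol: float = 0.0) -> "AtomicMeasure":
        """Merge duplicate knots and drop atoms with ``|w| <= w_tol``."""
        if w_tol < 0:
            raise ValueError("w_tol must be >= 0")
        kept = [a for a in self.atoms if abs(a.w) > w_tol]
        return AtomicMeasure(kept, self.D)

    def active_coords(self) -> set[int]:
        return {a.coord for a in self.atoms if a.w != 0.0}

    def __len__(self) -> int:
        return len(self.atoms)


def eval_basis(t: float, coord: int, X: np.ndarray) -> np.ndarray:
    """Hinge column ``((x_i[coord] - t)_+)_i`` of a scaled design matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (n, D) array")
    if not (0 <= coord < X.shape[1]):
        raise IndexError(f"coord {coord} out of range for D={X.shape[1]}")
    return np.maximum(X[:, coord] - t, 0.0)


def tv_norm(measure: AtomicMeasure) -> float:
    """Total variation of the measure: sum of absolute atom weights."""
    return measure.tv()


def net_mass(measure: AtomicMeasure, coord: int) -> float:
    """Signed sum of atom weights on one coordinate (zero iff saturating)."""
    return measure.net_mass(coord)


def prune_merge(measure: AtomicMeasure, w_tol: float = 0.0) -> AtomicMeasure:
    return measure.prune_merge(w_tol)


@dataclass
class SplineModel:
    """Saturating additive spline: intercept + hinge expansion of a measure.

    ``scaling`` holds per-coordinate ``(shift, range)`` pairs mapping raw
    features into the scaled [0, 1] knot domain; a zero range marks a
    constant training column, which maps to the constant 0.5.
    """

    measure: AtomicMeasure
    intercept: float
    scaling: np.ndarray  # (D, 2): columns shift, range
    tau: float | None = None
    loss: dict | None = None
    gap: float | None = None

    def __post_init__(self) -> None:
        self.scaling = np.asarray(self.scaling, dtype=float)
        if self.scaling.shape != (self.measure.D, 2):
            raise ValueError(
                f"scaling must have shape ({self.measure.D}, 2), got {self.scaling.shape}"
            )

    @property
    def D(self) -> int:
        return self.measure.D

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        """Apply the stored affine scaling; outputs may exit [0, 1]."""
        X = np.asarray(X_raw, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1) if self.D == 1 else X.reshape(1, -1)
        if X.shape[1] != self.D:
            raise ValueError(f"expected {self.D} columns, got {X.shape[1]}")
        shift = self.scaling[:, 0]
        rng = self.scaling[:, 1]
        out = np.empty_like(X)
        for d in range(self.D):
            if rng[d] == 0.0:
                out[:, d] = 0.5
            else:
                out[:, d] = (X[:, d] - shift[d]) / rng[d]
        return out

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        Xs = self.transform(X_raw)
        z = np.full(Xs.shape[0], self.intercept, dtype=float)
        for a in self.measure.atoms:
            z += a.w * np.maximum(Xs[:, a.coord] - a.t, 0.0)
        return z

    def coordinate_function(self, coord: int, x_scaled: np.ndarray) -> np.ndarray:
        """Evaluate the coordinate component f_d on scaled inputs (no intercept)."""
        x = np.asarray(x_scaled, dtype=float)
        z = np.zeros_like(x)
        for a in self.measure.atoms:
            if a.coord == coord:
                z += a.w * np.maximum(x - a.t, 0.0)
        return z

    def active_coords(self) -> set[int]:
        return self.measure.active_coords()

    # -- serialization ----------------------------------------------------
    # Python's json writes floats via repr (shortest round-trip form), so
    # the document is bit-faithful for doubles.

    def to_dict(self) -> dict:
        return {
            "version": MODEL_FILE_VERSION,
            "D": self.D,
            "intercept": self.intercept,
            "scaling": [
                {"shift": float(s), "range": float(r)} for s, r in self.scaling
            ],
            "atoms": [
                {"coord": a.coord, "t": a.t, "w": a.w} for a in self.measure.atoms
            ],
            "tau": self.tau,
            "loss": self.loss,
            "gap": self.gap,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SplineModel":
        if doc.get("version") != MODEL_FILE_VERSION:
            raise ValueError(f"unsupported model file version {doc.get('version')!r}")
        D = int(doc["D"])
        measure = AtomicMeasure(
            [KnotAtom(int(a["coord"]), float(a["t"]), float(a["w"])) for a in doc["atoms"]],
            D,
        )
        scaling = np.array([[s["shift"], s["range"]] for s in doc["scaling"]], dtype=float)
        return cls(
            measure=measure,
            intercept=float(doc["intercept"]),
            scaling=scaling,
            tau=doc.get("tau"),
            loss=doc.get("loss"),
            gap=doc.get("gap"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SplineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def eval_spline(model: SplineModel, X_raw: np.ndarray) -> np.ndarray:
    """Predictions of a saturating spline model at raw (unscaled) points."""
    return model.predict(X_raw)


def validate_model(model: SplineModel, tau: float | None = None, rtol: float = 1e-9) -> None:
    """Check the saturating-spline invariants; raise ValueError on violation.

    Per-coordinate net mass must vanish (relative to max(1, TV)) and, when a
    budget is known, TV must not exceed ``tau`` beyond rounding slack.
    """
    tv = model.measure.tv()
    for d in range(model.D):
        nm = abs(model.measure.net_mass(d))
        if nm > rtol * max(1.0, tv):
            raise ValueError(f"coordinate {d} net mass {nm} violates saturation")
    if tau is None:
        tau = model.tau
    if tau is not None and tv > tau * (1.0 + rtol):
        raise ValueError(f"TV {tv} exceeds budget {tau}")
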