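"""Synthetic data with known saturating ground truth, and a brute-force
reference solver.

``gridded_oracle`` fixes the full candidate knot set per coordinate and
solves the resulting finite convex program with a generic constrained
optimizer (scipy trust-constr).  It shares no code path with the
production Frank-Wolfe solver, so errors cannot cancel between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize
from scipy.special import expit

from .corrective import _optimal_intercept
from .losses import LossSpec, dataset_loss_grad, _second_derivative
from .measures import AtomicMeasure, KnotAtom, SplineModel

__all__ = ["SyntheticSpec", "gen_dataset", "gridded_oracle", "OracleResult"]

ORACLE_MAX_N = 50


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a dataset with a saturating piecewise-linear ground truth."""

    n: int = 100
    D: int = 1
    active_coords: tuple[int, ...] = (0,)
    knots_per_active: int = 4
    noise_kind: str = "gaussian"  # or "outlier_mix"
    noise_sd: float = 0.1
    outlier_frac: float = 0.1
    outlier_scale: float = 5.0
    label_kind: str = "real"  # or "logistic"
    tv_per_active: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.active_coords) <= set(range(self.D)):
            raise ValueError("active_coords must be a subset of {0..D-1}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.knots_per_active > 0 and not self.active_coords and self.D > 0:
            pass  # empty active set simply yields a constant truth
        if self.knots_per_active % 2 != 0:
            raise ValueError("knots_per_active must be even (weights come in +/- pairs)")
        if self.noise_kind not in ("gaussian", "outlier_mix"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.label_kind not in ("real", "logistic"):
            raise ValueError(f"unknown label_kind {self.label_kind!r}")


def gen_dataset(spec: SyntheticSpec):
    """Draw ``(X_raw, y, truth)``; a pure function of ``spec.seed``.

    The truth is a feasible saturating additive spline: per active
    coordinate the weights come in exactly cancelling ``(+a, -a)`` pairs,
    so every coordinate's net mass is zero in exact arithmetic, and the
    coordinate TV is normalized to ``tv_per_active``.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(size=(spec.n, spec.D))
    atoms: list[KnotAtom] = []
    for d in spec.active_coords:
        k = spec.knots_per_active
        ts = np.sort(rng.uniform(0.05, 0.95, size=k))
        mags = rng.uniform(0.5, 1.5, size=k // 2)
        ws = np.empty(k)
        ws[0::2] = mags
        ws[1::2] = -mags
        scale = spec.tv_per_active / np.sum(np.abs(ws))
        ws *= scale
        atoms.extend(KnotAtom(int(d), float(t), float(w)) for t, w in zip(ts, ws))
    scaling = np.column_stack((np.zeros(spec.D), np.ones(spec.D)))
    truth = SplineModel(
        measure=AtomicMeasure(atoms, spec.D), intercept=0.0, scaling=scaling
    )
    f = truth.predict(X)
    if spec.label_kind == "logistic":
        y = np.where(rng.uniform(size=spec.n) < expit(f), 1.0, -1.0)
        return X, y, truth
    y = f + rng.normal(0.0, spec.noise_sd, size=spec.n)
    if spec.noise_kind == "outlier_mix":
        m = int(round(spec.outlier_frac * spec.n))
        idx = rng.choice(spec.n, size=m, replace=False)
        y[idx] += spec.outlier_scale * rng.normal(size=m)
    return X, y, truth


@dataclass
class OracleResult:
    obj: float
    w: np.ndarray
    c: float
    knots: list[tuple[int, float]] = field(repr=False)

    def measure(self, D: int) -> AtomicMeasure:
        return AtomicMeasure(
            [KnotAtom(d, t, float(wj)) for (d, t), wj in zip(self.knots, self.w)], D
        )


def gridded_oracle(
    X: np.ndarray,
    y: np.ndarray,
    loss: LossSpec,
    tau: float,
    tol: float = 1e-14,
    max_iter: int = 10000,
) -> OracleResult:
    """Reference solve with the full candidate knot grid per coordinate.

    ``X`` must already live in [0, 1].  The split-sign program over
    ``w = p - q`` with bounds, per-coordinate zero sums, and the l1 budget
    is handed to scipy's trust-constr with analytic gradient and Hessian,
    then the solution is repaired to exact feasibility (so the returned
    objective is always attainable, i.e. an upper bound on the optimum).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    n, D = X.shape
    if n > ORACLE_MAX_N:
        raise ValueError(
            f"gridded_oracle is a test oracle for n <= {ORACLE_MAX_N}, got n={n}"
        )
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("gridded_oracle expects a scaled design in [0, 1]")
    if tau < 0:
        raise ValueError("tau must be >= 0")

    knots: list[tuple[int, float]] = []
    for d in range(D):
        for t in np.unique(np.concatenate(([0.0], X[:, d]))):
            knots.append((d, float(t)))
    K = len(knots)
    B = np.column_stack([np.maximum(X[:, d] - t, 0.0) for d, t in knots])
    coords = np.array([d for d, _ in knots], dtype=int)

    c0 = _optimal_intercept(loss, np.zeros(n), y, 0.0)
    if tau == 0.0:
        obj, _ = dataset_loss_grad(loss, np.full(n, c0), y)
        return OracleResult(obj=obj, w=np.zeros(K), c=c0, knots=knots)

    # variables v = [p (K), q (K), c]; w = p - q
    def split(v):
        return v[:K], v[K : 2 * K], v[2 * K]

    def fun(v):
        p, q, c = split(v)
        L, _ = dataset_loss_grad(loss, B @ (p - q) + c, y)
        return L

    def jac(v):
        p, q, c = split(v)
        _, g = dataset_loss_grad(loss, B @ (p - q) + c, y)
        gB = B.T @ g
        return np.concatenate((gB, -gB, [np.sum(g)]))

    def hess(v):
        p, q, c = split(v)
        h = _second_derivative(loss, B @ (p - q) + c, y)
        M = B.T @ (h[:, None] * B)
        col = B.T @ h
        H = np.empty((2 * K + 1, 2 * K + 1))
        H[:K, :K] = M
        H[:K, K : 2 * K] = -M
        H[K : 2 * K, :K] = -M
        H[K : 2 * K, K : 2 * K] = M
        H[:K, 2 * K] = col
        H[K : 2 * K, 2 * K] = -col
        H[2 * K, :K] = col
        H[2 * K, K : 2 * K] = -col
        H[2 * K, 2 * K] = np.sum(h)
        return H

    A_eq = np.zeros((D, 2 * K + 1))
    for d in range(D):
        ind = (coords == d).astype(float)
        A_eq[d, :K] = ind
        A_eq[d, K : 2 * K] = -ind
    A_l1 = np.concatenate((np.ones(2 * K), [0.0]))[None, :]

    lb = np.concatenate((np.zeros(2 * K), [-np.inf]))
    ub = np.full(2 * K + 1, np.inf)
    v0 = np.zeros(2 * K + 1)
    v0[-1] = c0
    res = minimize(
        fun,
        v0,
        method="trust-constr",
        jac=jac,
        hess=hess,
        bounds=Bounds(lb, ub),
        constraints=[
            LinearConstraint(A_eq, 0.0, 0.0),
            LinearConstraint(A_l1, -np.inf, tau),
        ],
        options={"gtol": tol, "xtol": 1e-14, "barrier_tol": tol, "maxiter": max_iter},
    )

    p, q, c = split(res.x)
    w = np.clip(p, 0, None) - np.clip(q, 0, None)
    # repair to *exact* feasibility so the objective is attainable: dump each
    # coordinate's net-mass residual onto its zero basis column (t = max x_d)
    for d in range(D):
        idx = np.flatnonzero(coords == d)
        r = float(np.sum(w[idx]))
        if r != 0.0:
            tmax = float(np.max(X[:, d]))
            j = idx[[knots[i][1] for i in idx].index(tmax)]
            w[j] -= r
    l1 = float(np.sum(np.abs(w)))
    if l1 > tau:
        w *= tau / l1
    c = _optimal_intercept(loss, B @ w, y, float(c))
    obj, _ = dataset_loss_grad(loss, B @ w + c, y)
    return OracleResult(obj=float(obj), w=w, c=float(c), knots=knots)
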