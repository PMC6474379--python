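"""Outer fitting loops: univariate, additive-model, and warm-started paths.

Each outer iteration evaluates the loss gradient at the current
predictions, asks the LMO for the best two-point measure, records the
duality-gap certificate, enlarges the knot set, and re-solves the
restricted weight problem.  Stopping is certificate-driven:
``gap <= tol_gap * max(1, |objective|)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corrective import (
    MAX_INNER_DEFAULT,
    build_restricted,
    restricted_solve,
    _optimal_intercept,
)
from .io import scale_fit_transform
from .lmo import duality_gap, lmo_gam
from .losses import LossSpec, dataset_loss_grad
from .measures import AtomicMeasure, KnotAtom, SplineModel

__all__ = [
    "FitOptions",
    "FitResult",
    "PathResult",
    "fit_univariate",
    "fit_gam",
    "fit_path",
    "refine_knots",
    "default_tau_grid",
    "cv_select_tau",
]

logger = logging.getLogger("satspline")

TRACE_DTYPE = np.dtype(
    [("objective", float), ("gap", float), ("knot_count", int)]
)


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the outer conditional-gradient loop."""

    tau: float = 1.0
    max_outer: int = 500
    tol_gap: float = 1e-6
    tol_inner: float = 1e-8
    w_tol: float | None = None  # default 1e-8 * tau, below certificate resolution
    max_inner: int = MAX_INNER_DEFAULT
    refine: bool = False
    seed: int = 0  # reserved for stochastic refinement; default algorithm is deterministic

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.tol_gap <= 0 or self.tol_inner <= 0:
            raise ValueError("tolerances must be > 0")
        if self.w_tol is not None and self.w_tol < 0:
            raise ValueError("w_tol must be >= 0")

    @property
    def effective_w_tol(self) -> float:
        return 1e-8 * self.tau if self.w_tol is None else self.w_tol


@dataclass
class FitResult:
    model: SplineModel
    trace: np.ndarray  # structured: objective, gap, knot_count
    converged: bool
    final_gap: float

    @property
    def objective(self) -> float:
        return float(self.trace["objective"][-1])

    @property
    def n_knots(self) -> int:
        return len(self.model.measure)


@dataclass
class PathResult:
    taus: np.ndarray
    fits: list[FitResult]
    summary: pd.DataFrame = field(repr=False)


def _prune_and_repair(
    knots: list[tuple[int, float]],
    w: np.ndarray,
    tau: float,
    w_tol: float,
) -> tuple[list[tuple[int, float]], np.ndarray]:
    """Drop tiny weights, restore exact per-coordinate zero sums and TV <= tau.

    The net-mass residual left by pruning is folded into the largest
    surviving atom of the coordinate; if that pushes the l1 norm over the
    budget the whole vector is rescaled (which preserves the zero sums).
    """
    keep = np.abs(w) > w_tol
    knots2 = [k for k, m in zip(knots, keep) if m]
    w2 = w[keep].copy()
    coords = np.array([c for c, _ in knots2], dtype=int)
    for d in np.unique(coords):
        idx = np.flatnonzero(coords == d)
        r = float(np.sum(w2[idx]))
        if r != 0.0:
            j = idx[np.argmax(np.abs(w2[idx]))]
            w2[j] -= r
    l1 = float(np.sum(np.abs(w2)))
    if l1 > tau > 0:
        w2 *= tau / l1
    return knots2, w2


def _fit_scaled(
    Xs: np.ndarray,
    y: np.ndarray,
    loss: LossSpec,
    options: FitOptions,
    transforms: np.ndarray,
    warm: tuple[list[tuple[int, float]], np.ndarray, float] | None = None,
) -> FitResult:
    n, D = Xs.shape
    tau = options.tau
    # the restricted gap upper-bounds the outer gap on a shared knot set, so
    # the inner solve must be held to a stricter tolerance than the stop rule
    tol_inner = min(options.tol_inner, 0.1 * options.tol_gap)
    orders = [np.argsort(Xs[:, d], kind="stable") for d in range(D)]

    if warm is not None:
        knots, w, c = list(warm[0]), np.asarray(warm[1], dtype=float).copy(), warm[2]
    else:
        knots, w, c = [], np.zeros(0), 0.0

    def basis_of(kn: list[tuple[int, float]]) -> np.ndarray:
        cols = [np.maximum(Xs[:, d] - t, 0.0) for d, t in kn]
        return np.column_stack(cols) if cols else np.zeros((n, 0))

    B = basis_of(knots)
    pm = B @ w
    c = _optimal_intercept(loss, pm, y, c)

    trace: list[tuple[float, float, int]] = []
    converged = False
    final_gap = 0.0

    if tau == 0.0:
        obj, _ = dataset_loss_grad(loss, pm + c, y)
        trace.append((obj, 0.0, 0))
        converged = True
    else:
        for m in range(options.max_outer):
            obj, g = dataset_loss_grad(loss, pm + c, y)
            res = lmo_gam(g, Xs, tau, orders=orders)
            if res.optimal_flag:
                preds_sstar = np.zeros(n)
            else:
                col = Xs[:, res.coord]
                preds_sstar = 0.5 * tau * (
                    np.maximum(col - res.t_plus, 0.0) - np.maximum(col - res.t_minus, 0.0)
                )
            gap = duality_gap(g, pm, res, preds_sstar)
            final_gap = gap
            trace.append((obj, gap, len(knots)))
            logger.info(
                "outer %3d: objective %.6e  gap %.3e  knots %d", m, obj, gap, len(knots)
            )
            if res.optimal_flag or gap <= options.tol_gap * max(1.0, abs(obj)):
                converged = True
                break

            for t in (res.t_plus, res.t_minus):
                key = (res.coord, float(t))
                if key not in knots:
                    knots.append(key)
                    w = np.append(w, 0.0)
            problem = build_restricted(knots, Xs, tau)
            B = problem.basis
            w, c, obj, _ = restricted_solve(
                problem, y, loss, w, c, tol_inner, options.max_inner
            )
            knots, w = _prune_and_repair(knots, w, tau, options.effective_w_tol)
            B = basis_of(knots)
            pm = B @ w
            c = _optimal_intercept(loss, pm, y, c)
        else:
            # iteration cap: record one last certified state
            obj, g = dataset_loss_grad(loss, pm + c, y)
            res = lmo_gam(g, Xs, tau, orders=orders)
            if res.optimal_flag:
                preds_sstar = np.zeros(n)
            else:
                col = Xs[:, res.coord]
                preds_sstar = 0.5 * tau * (
                    np.maximum(col - res.t_plus, 0.0) - np.maximum(col - res.t_minus, 0.0)
                )
            gap = duality_gap(g, pm, res, preds_sstar)
            final_gap = gap
            trace.append((obj, gap, len(knots)))
            converged = res.optimal_flag or gap <= options.tol_gap * max(1.0, abs(obj))

    measure = AtomicMeasure(
        [KnotAtom(d, t, float(wj)) for (d, t), wj in zip(knots, w)], D
    )
    model = SplineModel(
        measure=measure,
        intercept=float(c),
        scaling=transforms,
        tau=tau,
        loss=loss.to_dict(),
        gap=final_gap,
    )
    result = FitResult(
        model=model,
        trace=np.array(trace, dtype=TRACE_DTYPE),
        converged=converged,
        final_gap=final_gap,
    )
    if options.refine:
        result = refine_knots(result, Xs, y, loss, options, scaled=True)
    return result


def fit_gam(
    X_raw: np.ndarray,
    y: np.ndarray,
    loss: LossSpec,
    options: FitOptions,
    feature_names: list[str] | None = None,
) -> FitResult:
    """Fit a saturating-spline additive model to raw multivariate data."""
    y = np.asarray(y, dtype=float)
    sd = scale_fit_transform(X_raw, feature_names)
    if sd.X_scaled.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of rows")
    if y.size < 1:
        raise ValueError("need at least one observation")
    return _fit_scaled(sd.X_scaled, y, loss, options, sd.transforms)


def fit_univariate(
    x: np.ndarray, y: np.ndarray, loss: LossSpec, options: FitOptions
) -> FitResult:
    """Fit a univariate saturating spline (the D=1 additive model)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fit_univariate expects a 1-D feature vector")
    return fit_gam(x.reshape(-1, 1), y, loss, options)


def fit_path(
    X_raw: np.ndarray,
    y: np.ndarray,
    loss: LossSpec,
    taus: np.ndarray | None = None,
    options: FitOptions = FitOptions(),
    feature_names: list[str] | None = None,
) -> PathResult:
    """Warm-started regularization path over an increasing tau grid.

    The solution at each tau is feasible for the next (budgets nest), so it
    seeds the next fit; every fit carries its own gap certificate.
    """
    y = np.asarray(y, dtype=float)
    sd = scale_fit_transform(X_raw, feature_names)
    if taus is None:
        taus = default_tau_grid(X_raw, y)
    taus = np.asarray(taus, dtype=float)
    if taus.size == 0 or np.any(np.diff(taus) <= 0):
        raise ValueError("taus must be strictly increasing")
    if taus[0] < 0:
        raise ValueError("taus must be >= 0")

    fits: list[FitResult] = []
    warm = None
    rows = []
    for tau in taus:
        opt_k = replace(options, tau=float(tau))
        fit = _fit_scaled(sd.X_scaled, y, loss, opt_k, sd.transforms, warm=warm)
        fits.append(fit)
        _, _, ws = fit.model.measure.arrays()
        warm = (
            [(a.coord, a.t) for a in fit.model.measure.atoms],
            ws,
            fit.model.intercept,
        )
        rows.append(
            {
                "tau": float(tau),
                "objective": fit.objective,
                "gap": fit.final_gap,
                "n_knots": len(fit.model.measure),
                "n_active_features": len(fit.model.active_coords()),
            }
        )
    return PathResult(taus=taus, fits=fits, summary=pd.DataFrame(rows))


def refine_knots(
    fit: FitResult,
    X: np.ndarray,
    y: np.ndarray,
    loss: LossSpec,
    options: FitOptions | None = None,
    scaled: bool = False,
) -> FitResult:
    """Discrete knot-location refinement (optional post-processing).

    Each knot in turn is tentatively moved to the adjacent data values of
    its coordinate and the weights re-solved; a move is kept only if the
    objective does not increase, so the output objective never exceeds the
    input objective.
    """
    options = options or FitOptions(tau=fit.model.tau or 0.0)
    model = fit.model
    tau = model.tau if model.tau is not None else options.tau
    y = np.asarray(y, dtype=float)
    Xs = np.asarray(X, dtype=float) if scaled else model.transform(X)
    if Xs.ndim == 1:
        Xs = Xs.reshape(-1, 1)
    n, D = Xs.shape

    knots = [(a.coord, a.t) for a in model.measure.atoms]
    w = np.array([a.w for a in model.measure.atoms])
    c = model.intercept
    if not knots or tau == 0.0:
        return fit

    def solve(kn, w0, c0):
        problem = build_restricted(kn, Xs, tau)
        return restricted_solve(
            problem, y, loss, w0, c0, options.tol_inner, options.max_inner
        )

    w, c, best_obj, _ = solve(knots, w, c)
    cand_per_coord = {
        d: np.unique(np.concatenate(([0.0], Xs[:, d]))) for d in range(D)
    }
    improved = True
    passes = 0
    while improved and passes < 3:
        improved = False
        passes += 1
        for j in range(len(knots)):
            d, t = knots[j]
            cands = cand_per_coord[d]
            pos = int(np.searchsorted(cands, t))
            for np_pos in (pos - 1, pos + 1):
                if not (0 <= np_pos < cands.size):
                    continue
                t_new = float(cands[np_pos])
                if (d, t_new) in knots:
                    continue
                trial = list(knots)
                trial[j] = (d, t_new)
                w_t, c_t, obj_t, _ = solve(trial, w, c)
                if obj_t <= best_obj:
                    knots, w, c, best_obj = trial, w_t, c_t, obj_t
                    improved = True
                    break

    knots, w = _prune_and_repair(
        knots, w, tau, options.effective_w_tol
    )
    problem = build_restricted(knots, Xs, tau)
    pm = problem.basis @ w if knots else np.zeros(n)
    c = _optimal_intercept(loss, pm, y, c)
    obj, _ = dataset_loss_grad(loss, pm + c, y)
    measure = AtomicMeasure([KnotAtom(d, t, float(wj)) for (d, t), wj in zip(knots, w)], D)
    new_model = SplineModel(
        measure=measure,
        intercept=float(c),
        scaling=model.scaling,
        tau=tau,
        loss=model.loss,
        gap=fit.final_gap,
    )
    trace = fit.trace.copy()
    trace["objective"][-1] = min(trace["objective"][-1], obj)
    return FitResult(
        model=new_model, trace=trace, converged=fit.converged, final_gap=fit.final_gap
    )


def interpolant_derivative_tv(x_scaled: np.ndarray, y: np.ndarray) -> float:
    """TV of the derivative of the saturating interpolant of (x, mean-y).

    Duplicate x values are collapsed to their mean response.  Any budget at
    least this large admits a zero-residual univariate fit.
    """
    xu, inv = np.unique(x_scaled, return_inverse=True)
    if xu.size < 2:
        return 0.0
    ybar = np.bincount(inv, weights=y) / np.bincount(inv)
    slopes = np.diff(ybar) / np.diff(xu)
    return float(abs(slopes[0]) + np.sum(np.abs(np.diff(slopes))) + abs(slopes[-1]))


def _binned_interpolant_tv(x_scaled: np.ndarray, y: np.ndarray) -> float:
    """Interpolant-derivative TV estimated on binned means.

    Raw interpolant TV explodes with noise (slopes scale like noise/spacing),
    which would anchor the default grid absurdly high, so the estimate
    averages y within ~sqrt(n) equal-width bins first.
    """
    x = np.asarray(x_scaled, dtype=float)
    y = np.asarray(y, dtype=float)
    n_bins = max(2, int(round(np.sqrt(x.size))))
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    keep = counts > 0
    xb = np.bincount(which, weights=x, minlength=n_bins)[keep] / counts[keep]
    yb = np.bincount(which, weights=y, minlength=n_bins)[keep] / counts[keep]
    return interpolant_derivative_tv(xb, yb)


def default_tau_grid(
    X_raw: np.ndarray,
    y: np.ndarray,
    n_taus: int = 16,
    lower_frac: float = 1e-3,
) -> np.ndarray:
    """Geometric tau grid anchored at twice an interpolant-derivative TV estimate.

    The anchor sums a binned-mean estimate of each coordinate's interpolant
    TV; the lower end is ``lower_frac`` times the upper end.
    """
    y = np.asarray(y, dtype=float)
    sd = scale_fit_transform(X_raw)
    total = sum(
        _binned_interpolant_tv(sd.X_scaled[:, d], y)
        for d in range(sd.X_scaled.shape[1])
    )
    tau_max = 2.0 * total
    if tau_max <= 0:
        tau_max = 1.0
    return np.geomspace(tau_max * lower_frac, tau_max, n_taus)


def cv_select_tau(
    X_raw: np.ndarray,
    y: np.ndarray,
    loss: LossSpec,
    taus: np.ndarray,
    n_folds: int = 5,
    options: FitOptions = FitOptions(),
    seed: int = 0,
) -> float:
    """Thin K-fold helper returning the tau with the best held-out loss.

    Convenience only; no statistical guarantees are attached to it.
    """
    X = np.asarray(X_raw, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(y.size)
    folds = np.array_split(idx, n_folds)
    taus = np.asarray(taus, dtype=float)
    scores = np.zeros(taus.size)
    for f in folds:
        mask = np.ones(y.size, dtype=bool)
        mask[f] = False
        path = fit_path(X[mask], y[mask], loss, taus, options)
        for k, fit in enumerate(path.fits):
            z = fit.model.predict(X[~mask])
            L, _ = dataset_loss_grad(loss, z, y[~mask])
            scores[k] += L
    return float(taus[int(np.argmin(scores))])
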