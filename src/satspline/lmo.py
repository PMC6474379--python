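"""Exact linear minimization oracle over the saturating-measure ball.

The linearized objective over measures with per-coordinate zero net mass
and TV at most tau is minimized by a two-point measure
``(tau/2) delta_{t+} - (tau/2) delta_{t-}`` supported on one coordinate.
Because the score ``h(t) = <g, psi(t)>`` is piecewise linear with
breakpoints at the data values and vanishes beyond the largest one, both
knots can be found exactly in one pass over the sorted column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LMOResult",
    "hinge_score_profile",
    "lmo_coordinate",
    "lmo_gam",
    "duality_gap",
]


@dataclass
class LMOResult:
    """Two-point conditional gradient and its certificate ingredients.

    ``o_star`` is the linearized objective of the returned atom pair (zero
    when the zero measure is itself a conditional gradient, which certifies
    block optimality via ``optimal_flag``).
    """

    coord: int
    t_plus: float
    t_minus: float
    h_plus: float
    h_minus: float
    o_star: float
    optimal_flag: bool
    gap: float | None = None


def hinge_score_profile(g: np.ndarray, x_sorted: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Values of ``h(t) = sum_{i: x_i >= t} g_i (x_i - t)`` at each candidate.

    ``g`` must be aligned with the ascending ``x_sorted``.  Runs in O(n)
    via suffix sums of ``g`` and ``g * x``; ``h`` is identically zero for
    ``t >= max(x)`` and that is enforced exactly.
    """
    x = np.asarray(x_sorted, dtype=float)
    g = np.asarray(g, dtype=float)
    if x.size == 0:
        raise ValueError("empty data column")
    if x.shape != g.shape:
        raise ValueError("g and x_sorted must have equal length")
    if np.any(np.diff(x) < 0):
        raise ValueError("x_sorted must be ascending (sorting is the caller's job)")
    c = np.asarray(candidates, dtype=float)
    suf_g = np.concatenate((np.cumsum(g[::-1])[::-1], [0.0]))
    suf_gx = np.concatenate((np.cumsum((g * x)[::-1])[::-1], [0.0]))
    idx = np.searchsorted(x, c, side="left")
    h = suf_gx[idx] - c * suf_g[idx]
    h[c >= x[-1]] = 0.0
    return h


def _candidates(x_sorted: np.ndarray) -> np.ndarray:
    return np.unique(np.concatenate(([0.0], x_sorted)))


def lmo_coordinate(
    g: np.ndarray,
    x_d: np.ndarray,
    tau: float,
    order: np.ndarray | None = None,
    coord: int = 0,
) -> LMOResult:
    """Best two-point measure on one coordinate, with deterministic ties.

    ``t_plus`` minimizes and ``t_minus`` maximizes the hinge score over the
    candidate set ``{0} union {x_i}``; ties break to the smallest t.
    """
    x_d = np.asarray(x_d, dtype=float)
    g = np.asarray(g, dtype=float)
    if not tau > 0:
        raise ValueError("tau must be > 0 for the LMO")
    if x_d.size == 0:
        raise ValueError("empty data column")
    if order is None:
        order = np.argsort(x_d, kind="stable")
    xs = x_d[order]
    gs = g[order]
    cands = _candidates(xs)
    h = hinge_score_profile(gs, xs, cands)
    ip = int(np.argmin(h))
    im = int(np.argmax(h))
    h_plus = float(h[ip])
    h_minus = float(h[im])
    optimal = h_plus - h_minus >= 0.0
    o_star = 0.0 if optimal else 0.5 * tau * (h_plus - h_minus)
    return LMOResult(
        coord=coord,
        t_plus=float(cands[ip]),
        t_minus=float(cands[im]),
        h_plus=h_plus,
        h_minus=h_minus,
        o_star=o_star,
        optimal_flag=optimal,
    )


def lmo_gam(
    g: np.ndarray,
    X: np.ndarray,
    tau: float,
    orders: list[np.ndarray] | None = None,
) -> LMOResult:
    """Run the coordinate LMO on every column, keep the best (smallest o_star).

    Ties break to the smallest coordinate index; the flag is true only when
    every coordinate certifies block optimality.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a 2-D design with D >= 1 columns")
    best: LMOResult | None = None
    all_optimal = True
    for d in range(X.shape[1]):
        res = lmo_coordinate(
            g, X[:, d], tau, order=None if orders is None else orders[d], coord=d
        )
        all_optimal = all_optimal and res.optimal_flag
        if best is None or res.o_star < best.o_star:
            best = res
    assert best is not None
    return replace(best, optimal_flag=all_optimal)


def duality_gap(
    g: np.ndarray,
    preds_mu: np.ndarray,
    lmo: LMOResult,
    preds_sstar: np.ndarray,
) -> float:
    """Suboptimality certificate ``<g, E_x mu> - <g, E_x s*>`` (>= 0 feasible).

    ``preds_sstar`` must be the training-point evaluation of the two-point
    conditional gradient, or the zero vector when ``optimal_flag`` is set.
    Stores the value on ``lmo.gap`` and returns it.
    """
    gap = float(np.dot(g, preds_mu) - np.dot(g, preds_sstar))
    lmo.gap = gap
    return gap
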