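"""Fully-corrective step: weights at fixed knots, plus the free intercept.

The feasible set for the weight vector is the polytope with per-coordinate
zero sums and an l1 budget; its extreme points are the zero vector and the
paired vertices ``(tau/2)(e_i - e_j)`` with i, j in the same coordinate
group.  We solve over it with pairwise-vertex Frank-Wolfe and exact line
search, re-optimizing the unpenalized intercept after every move so the
outer duality-gap certificate stays valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .losses import LossSpec, dataset_loss_grad, loss_value_grad, _second_derivative

__all__ = [
    "RestrictedProblem",
    "VertexDirection",
    "build_restricted",
    "inner_vertex_lmo",
    "line_search",
    "restricted_solve",
]

logger = logging.getLogger("satspline")

MAX_INNER_DEFAULT = 10_000


@dataclass
class RestrictedProblem:
    """Finite problem over hinge columns at the knots collected so far."""

    knots: list[tuple[int, float]]  # (coord, t) per basis column
    basis: np.ndarray  # (n, K) hinge columns
    tau: float
    groups: dict[int, np.ndarray]  # coord -> column indices


def build_restricted(
    knots: list[tuple[int, float]], X_scaled: np.ndarray, tau: float
) -> RestrictedProblem:
    X_scaled = np.asarray(X_scaled, dtype=float)
    n = X_scaled.shape[0]
    cols = [np.maximum(X_scaled[:, c] - t, 0.0) for c, t in knots]
    basis = np.column_stack(cols) if cols else np.zeros((n, 0))
    groups: dict[int, list[int]] = {}
    for j, (c, _) in enumerate(knots):
        groups.setdefault(c, []).append(j)
    return RestrictedProblem(
        knots=list(knots),
        basis=basis,
        tau=float(tau),
        groups={c: np.asarray(idx, dtype=int) for c, idx in sorted(groups.items())},
    )


@dataclass
class VertexDirection:
    """An extreme point of the weight polytope: a (+, -) column pair or zero."""

    pair: tuple[int, int] | None  # (i, j) for (tau/2)(e_i - e_j); None = zero vertex
    score: float  # <grad_w, v>
    tau: float

    def as_vector(self, K: int) -> np.ndarray:
        v = np.zeros(K)
        if self.pair is not None:
            i, j = self.pair
            v[i] += 0.5 * self.tau
            v[j] -= 0.5 * self.tau
        return v


def inner_vertex_lmo(
    grad_w: np.ndarray, tau: float, groups: dict[int, np.ndarray]
) -> VertexDirection:
    """Vertex minimizing ``<grad_w, v>``; the zero vertex keeps the gap valid.

    Ties break to the smallest column indices, then the smallest coordinate.
    """
    grad_w = np.asarray(grad_w, dtype=float)
    best_pair: tuple[int, int] | None = None
    best_score = 0.0  # zero vertex
    for coord in sorted(groups):
        idx = groups[coord]
        if idx.size < 2:
            continue  # a lone column cannot carry weight under the zero-sum rule
        sub = grad_w[idx]
        i = int(idx[np.argmin(sub)])
        j = int(idx[np.argmax(sub)])
        score = 0.5 * tau * (grad_w[i] - grad_w[j])
        if score < best_score:
            best_pair, best_score = (i, j), score
    return VertexDirection(pair=best_pair, score=float(best_score), tau=tau)


class _SegmentLMO:
    """Vertex LMO over coordinate groups via segment reductions.

    Same result as :func:`inner_vertex_lmo` (identical tie-breaking), but
    the per-group argmin/argmax run as two ``reduceat`` calls instead of a
    Python loop, which matters inside the inner solve's hot loop.
    """

    def __init__(self, groups: dict[int, np.ndarray], tau: float):
        self.tau = tau
        sizes = []
        perm = []
        for coord in sorted(groups):
            idx = groups[coord]
            if idx.size < 2:
                continue
            perm.append(np.sort(idx))
            sizes.append(idx.size)
        if perm:
            self.perm = np.concatenate(perm)
            self.starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
            self.ends = np.cumsum(sizes)
        else:
            self.perm = np.zeros(0, dtype=int)
            self.starts = np.zeros(0, dtype=int)
            self.ends = np.zeros(0, dtype=int)

    def __call__(self, grad_w: np.ndarray) -> VertexDirection:
        if self.perm.size == 0:
            return VertexDirection(pair=None, score=0.0, tau=self.tau)
        gs = grad_w[self.perm]
        mins = np.minimum.reduceat(gs, self.starts)
        maxs = np.maximum.reduceat(gs, self.starts)
        scores = 0.5 * self.tau * (mins - maxs)
        k = int(np.argmin(scores))
        if scores[k] >= 0.0:
            return VertexDirection(pair=None, score=0.0, tau=self.tau)
        seg = self.perm[self.starts[k] : self.ends[k]]
        sub = grad_w[seg]
        i = int(seg[np.argmin(sub)])
        j = int(seg[np.argmax(sub)])
        return VertexDirection(pair=(i, j), score=float(scores[k]), tau=self.tau)


def line_search(
    loss: LossSpec,
    y: np.ndarray,
    preds: np.ndarray,
    direction_preds: np.ndarray,
    gamma_max: float = 1.0,
) -> float:
    """Exact 1-D minimization of the loss along a feasible FW direction.

    Closed form for the squared loss; bisection on the derivative otherwise.
    The returned step never increases the objective.
    """
    d = np.asarray(direction_preds, dtype=float)
    if gamma_max <= 0 or not np.any(d):
        return 0.0
    if loss.kind == "squared":
        denom = float(d @ d)
        if denom == 0.0:
            return 0.0
        num = float((y - preds) @ d)
        return float(min(max(num / denom, 0.0), gamma_max))

    def phi_prime(gamma: float) -> float:
        _, g = loss_value_grad(loss, preds + gamma * d, y)
        return float(g @ d)

    lo, hi = 0.0, float(gamma_max)
    dlo = phi_prime(lo)
    if dlo >= 0.0:
        return 0.0
    dhi = phi_prime(hi)
    if dhi <= 0.0:
        return hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        dm = phi_prime(mid)
        if abs(dm) <= 1e-10:
            return mid
        if dm < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _optimal_intercept(
    loss: LossSpec, preds_measure: np.ndarray, y: np.ndarray, c0: float = 0.0
) -> float:
    """Exact 1-D minimization of the dataset loss over the intercept."""
    if loss.kind == "squared":
        return float(np.mean(y - preds_measure))
    c = float(c0)
    # safeguarded Newton; the 1-D derivative is nondecreasing by convexity
    lo, hi = -60.0, 60.0
    for _ in range(100):
        _, g = dataset_loss_grad(loss, preds_measure + c, y)
        gsum = float(np.sum(g))
        if abs(gsum) <= 1e-10 * max(1.0, y.size):
            break
        if gsum > 0:
            hi = min(hi, c)
        else:
            lo = max(lo, c)
        h = float(np.sum(_second_derivative(loss, preds_measure + c, y)))
        step = -gsum / h if h > 0 else 0.0
        c_new = c + step
        if not (lo < c_new < hi):
            c_new = 0.5 * (lo + hi)
        c = c_new
    return c


def _project_feasible(
    w: np.ndarray, tau: float, groups: dict[int, np.ndarray]
) -> np.ndarray:
    """Repair per-group sums and rescale into the l1 budget (warning path)."""
    w = w.astype(float).copy()
    for idx in groups.values():
        s = float(np.sum(w[idx]))
        if s != 0.0:
            w[idx] -= s / idx.size
    l1 = float(np.sum(np.abs(w)))
    if l1 > tau:
        w *= 0.0 if tau == 0 else tau / l1
    return w


def _newton_candidate(
    B: np.ndarray,
    w: np.ndarray,
    c: float,
    y: np.ndarray,
    g: np.ndarray,
    loss: LossSpec,
    groups: dict[int, np.ndarray],
    tau: float | None = None,
) -> np.ndarray | None:
    """Equality-constrained Newton step on the support of ``w``.

    Solves the KKT system of ``min_v L(B_S v + c)`` subject to per-group
    zero sums over the active columns; when ``tau`` is given the linearized
    budget row ``sign(w_S) . v = tau`` is added so the step can slide along
    the l1 sphere instead of being clipped at it.  Vertex exchanges alone
    crawl once the right support is identified; a Newton step then jumps to
    the face optimum.  The caller line-searches the returned candidate, so
    it only ever helps.
    """
    S = np.flatnonzero(w)
    if S.size == 0:
        return None
    Bs = B[:, S]
    h = _second_derivative(loss, B @ w + c, y)
    H = Bs.T @ (h[:, None] * Bs)
    grad = Bs.T @ g
    coords_of = np.empty(w.size, dtype=int)
    for coord, idx in groups.items():
        coords_of[idx] = coord
    cons = []
    rhs_eq = []
    for coord in np.unique(coords_of[S]):
        row = (coords_of[S] == coord).astype(float)
        cons.append(row)
        rhs_eq.append(-float(row @ w[S]))
    sgn = np.sign(w[S])
    if tau is not None:
        cons.append(sgn)
        rhs_eq.append(tau - float(sgn @ w[S]))
    C = np.array(cons)
    m, k = C.shape[0], S.size
    KKT = np.zeros((k + m, k + m))
    KKT[:k, :k] = H
    KKT[:k, k:] = C.T
    KKT[k:, :k] = C
    rhs = np.concatenate((-grad, rhs_eq))
    try:
        sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
    except np.linalg.LinAlgError:
        return None
    d = sol[:k]
    if not np.all(np.isfinite(d)) or not np.any(d):
        return None
    vs = w[S] + d
    if tau is not None:
        vs[np.sign(vs) * sgn < 0] = 0.0  # sign flip voids the budget row
    v_hat = w.copy()
    v_hat[S] = vs
    return v_hat


def _l1_clip_step(w: np.ndarray, direction: np.ndarray, tau: float) -> float:
    """Largest step in [0, 1] keeping ``||w + gamma*direction||_1 <= tau``."""

    def l1(gamma):
        return float(np.sum(np.abs(w + gamma * direction)))

    if l1(1.0) <= tau:
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if l1(mid) <= tau:
            lo = mid
        else:
            hi = mid
    return lo


def _decompose(
    w: np.ndarray, tau: float, groups: dict[int, np.ndarray]
) -> dict[tuple[int, int], float]:
    """Greedy pairing of a feasible weight vector into polytope vertices.

    Each pairing step zeroes one entry exactly, so the loop terminates; the
    leftover convex weight sits on the zero vertex implicitly.
    """
    alphas: dict[tuple[int, int], float] = {}
    half = 0.5 * tau
    for coord in sorted(groups):
        idx = groups[coord]
        vals = w[idx].astype(float).copy()
        while True:
            ip = int(np.argmax(vals))
            im = int(np.argmin(vals))
            if vals[ip] <= 0.0 or vals[im] >= 0.0:
                break
            m = min(vals[ip], -vals[im])
            key = (int(idx[ip]), int(idx[im]))
            alphas[key] = alphas.get(key, 0.0) + m / half
            vals[ip] -= m
            vals[im] += m
    total = sum(alphas.values())
    if total > 1.0:  # floating-point overshoot only
        for k in alphas:
            alphas[k] /= total
    return alphas


def _reconstruct(alphas: dict[tuple[int, int], float], tau: float, K: int) -> np.ndarray:
    w = np.zeros(K)
    half = 0.5 * tau
    for (i, j), a in alphas.items():
        w[i] += a * half
        w[j] -= a * half
    return w


def restricted_solve(
    problem: RestrictedProblem,
    y: np.ndarray,
    loss: LossSpec,
    w0: np.ndarray | None = None,
    c0: float | None = None,
    tol_inner: float = 1e-8,
    max_inner: int = MAX_INNER_DEFAULT,
) -> tuple[np.ndarray, float, float, float]:
    """Solve the restricted problem to an inner FW gap of ``tol_inner``.

    Returns ``(w, c, objective, inner_gap)``.  Feasibility is maintained by
    construction: every iterate is a convex combination of polytope
    vertices, and moves are pairwise vertex exchanges with step in
    ``[0, alpha_away]``.
    """
    B = problem.basis
    tau = problem.tau
    n, K = B.shape
    y = np.asarray(y, dtype=float)
    half = 0.5 * tau

    if tau == 0.0 or K == 0:
        c = _optimal_intercept(loss, np.zeros(n), y, 0.0 if c0 is None else c0)
        obj, _ = dataset_loss_grad(loss, np.full(n, c), y)
        return np.zeros(K), c, obj, 0.0

    w = np.zeros(K) if w0 is None else np.asarray(w0, dtype=float).copy()
    bad_group = any(
        abs(float(np.sum(w[idx]))) > 1e-9 * max(1.0, tau)
        for idx in problem.groups.values()
    )
    if bad_group or float(np.sum(np.abs(w))) > tau * (1.0 + 1e-9):
        logger.warning("infeasible warm start; projecting onto the constraint set")
        w = _project_feasible(w, tau, problem.groups)

    alphas = _decompose(w, tau, problem.groups)
    w = _reconstruct(alphas, tau, K)
    pm = B @ w
    c = _optimal_intercept(loss, pm, y, 0.0 if c0 is None else c0)

    obj, g = dataset_loss_grad(loss, pm + c, y)
    fast_lmo = _SegmentLMO(problem.groups, tau)
    gap = np.inf
    for it in range(max_inner):
        grad_w = B.T @ g
        v_fw = fast_lmo(grad_w)
        gap = float(w @ grad_w) - v_fw.score
        if gap <= tol_inner * max(1.0, obj):
            break

        # away vertex: worst active vertex (zero vertex scores 0)
        alpha0 = max(0.0, 1.0 - sum(alphas.values()))
        away_pair: tuple[int, int] | None = None
        away_score = -np.inf
        for (i, j), a in alphas.items():
            if a <= 0.0:
                continue
            s = half * (grad_w[i] - grad_w[j])
            if s > away_score:
                away_pair, away_score = (i, j), s
        if alpha0 > 0.0 and (away_pair is None or away_score <= 0.0):
            away_pair, away_score = None, 0.0

        gamma_max = alpha0 if away_pair is None else alphas[away_pair]
        dpreds = np.zeros(n)
        if v_fw.pair is not None:
            i, j = v_fw.pair
            dpreds += half * (B[:, i] - B[:, j])
        if away_pair is not None:
            i, j = away_pair
            dpreds -= half * (B[:, i] - B[:, j])
        gamma = line_search(loss, y, pm + c, dpreds, gamma_max)
        if gamma <= 0.0:
            break  # floating-point stall; gap is still a valid certificate

        if v_fw.pair is not None:
            alphas[v_fw.pair] = alphas.get(v_fw.pair, 0.0) + gamma
            i, j = v_fw.pair
            w[i] += gamma * half
            w[j] -= gamma * half
        if away_pair is not None:
            left = alphas[away_pair] - gamma
            if left <= 1e-15:
                del alphas[away_pair]
            else:
                alphas[away_pair] = left
            i, j = away_pair
            w[i] -= gamma * half
            w[j] += gamma * half

        pm += gamma * dpreds
        if (it + 1) % 256 == 0:
            pm = B @ w  # shed accumulated drift

        # periodic Newton acceleration on the current support: vertex steps
        # identify the face, the Newton step jumps to (or slides along) its
        # optimum; accepted only through the descent line search below
        if (it + 1) % 25 == 0:
            tight = float(np.sum(np.abs(w))) >= tau * (1.0 - 1e-10)
            v_hat = _newton_candidate(
                B, w, c, y, g, loss, problem.groups, tau=tau if tight else None
            )
            if v_hat is not None:
                d_w = v_hat - w
                g_clip = _l1_clip_step(w, d_w, tau)
                if g_clip > 0.0:
                    d_preds_nw = B @ d_w
                    g_nw = line_search(loss, y, pm + c, d_preds_nw, g_clip)
                    if g_nw > 0.0:
                        w = w + g_nw * d_w
                        pm = pm + g_nw * d_preds_nw
                        alphas = _decompose(w, tau, problem.groups)
                        w = _reconstruct(alphas, tau, w.size)
                        pm = B @ w

        # radial rescale: uniform scaling of the decomposition stays in the
        # polytope and fixes magnitude misfit in one cheap 1-D solve, which
        # plain vertex steps do very slowly when tau dwarfs the solution
        asum = sum(alphas.values())
        if asum > 0.0 and np.any(pm):
            f_max = 1.0 / asum
            f = line_search(loss, y, np.full(n, c), pm, f_max)
            if f != 1.0:
                w *= f
                pm *= f
                for key in list(alphas):
                    alphas[key] *= f
                    if alphas[key] <= 1e-18:
                        del alphas[key]
        c = _optimal_intercept(loss, pm, y, c)
        obj, g = dataset_loss_grad(loss, pm + c, y)
    else:
        logger.warning(
            "restricted solve hit the %d-iteration cap (gap %.3e)", max_inner, gap
        )
    return w, c, obj, gap
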