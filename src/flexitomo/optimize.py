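"""Derivative-free quadratic-model trust-region minimization.

A compact UOBYQA-style optimizer for small dimensions (the elastic
alignment uses 2-6 normal-mode amplitudes): a full quadratic model is fit by
least squares to an interpolation set of (n+1)(n+2)/2 points, minimized
exactly inside the trust region (More-Sorensen for the tiny subproblem), and
the radius grows or shrinks with the agreement between predicted and actual
reduction.  Iterations stop when the radius falls below ``final_radius`` or
the evaluation budget is spent.  Fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OptimizeResult", "minimize_trust_region"]


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    converged: bool
    history: list = field(default_factory=list)  # best-so-far f after each eval


def _quad_features(X: np.ndarray) -> np.ndarray:
    """[1, x, upper-triangle xx^T] features for quadratic least squares."""
    n = X.shape[1]
    cols = [np.ones(len(X))]
    cols += [X[:, i] for i in range(n)]
    for i in range(n):
        for j in range(i, n):
            cols.append(X[:, i] * X[:, j])
    return np.stack(cols, axis=1)


def _unpack_model(beta: np.ndarray, n: int):
    c = beta[0]
    g = beta[1:1 + n].copy()
    H = np.zeros((n, n))
    k = 1 + n
    for i in range(n):
        for j in range(i, n):
            if i == j:
                H[i, i] = 2.0 * beta[k]
            else:
                H[i, j] = H[j, i] = beta[k]
            k += 1
    return c, g, H


def _solve_trs(g: np.ndarray, H: np.ndarray, radius: float) -> np.ndarray:
    """Minimize g.p + 0.5 p.H.p subject to |p| <= radius (More-Sorensen)."""
    w, V = np.linalg.eigh(H)
    gt = V.T @ g
    lam_min = w.min()

    def step_norm(lam):
        denom = w + lam
        p = -gt / denom
        return np.linalg.norm(p)

    if lam_min > 1e-12:
        p = V @ (-gt / w)
        if np.linalg.norm(p) <= radius:
            return p
    # find lam > max(0, -lam_min) with |p(lam)| = radius by bisection
    lo = max(0.0, -lam_min) + 1e-12
    hi = lo + max(1.0, np.linalg.norm(g) / radius)
    while step_norm(hi) > radius and hi < 1e12:
        hi *= 4.0
    if step_norm(lo) < radius:
        # hard case: gradient has no component along the flattest direction
        i = int(np.argmin(w))
        p = V @ (-gt / np.maximum(w + lo, 1e-12))
        norm = np.linalg.norm(p)
        if norm < radius:
            tau = np.sqrt(max(0.0, radius**2 - norm**2))
            p = p + tau * V[:, i]
        return p
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if step_norm(mid) > radius:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    return V @ (-gt / (w + lam))


def minimize_trust_region(
    fun,
    x0,
    initial_radius: float = 100.0,
    final_radius: float = 1.0,
    max_evaluations: int = 60,
    tie_break=None,
) -> OptimizeResult:
    """Minimize ``fun`` from ``x0`` with a quadratic-model trust region.

    Parameters
    ----------
    tie_break : callable, optional
        ``tie_break(x)`` returns a secondary key; among points with equal
        function value (to 1e-12) the smaller key wins.  Used to prefer
        smaller deformations at equal correlation.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n = len(x0)
    if tie_break is None:
        tie_break = lambda x: 0.0

    X: list[np.ndarray] = []
    F: list[float] = []
    history: list[float] = []
    best = {"x": None, "f": np.inf, "key": np.inf}

    def evaluate(x):
        f = float(fun(np.asarray(x, dtype=float)))
        X.append(np.asarray(x, dtype=float).copy())
        F.append(f)
        key = tie_break(x)
        if f < best["f"] - 1e-12 or (abs(f - best["f"]) <= 1e-12 and key < best["key"]):
            best["x"], best["f"], best["key"] = np.asarray(x, dtype=float).copy(), f, key
        history.append(best["f"])
        return f

    radius = float(initial_radius)
    evaluate(x0)
    # initial interpolation set: +/- radius along axes, plus diagonal pairs
    for i in range(n):
        for s in (+1.0, -1.0):
            if len(X) >= max_evaluations:
                break
            p = x0.copy()
            p[i] += s * radius
            evaluate(p)
    for i in range(n):
        for j in range(i + 1, n):
            if len(X) >= max_evaluations:
                break
            p = x0.copy()
            p[i] += radius
            p[j] += radius
            evaluate(p)

    n_params = (n + 1) * (n + 2) // 2
    converged = False
    while len(X) < max_evaluations:
        if radius < final_radius:
            converged = True
            break
        center = best["x"]
        # fit the quadratic model on the points nearest the current best
        pts = np.array(X)
        vals = np.array(F)
        d = np.linalg.norm(pts - center, axis=1)
        take = np.argsort(d)[: max(n_params, n + 2)]
        A = _quad_features(pts[take] - center)
        # mild ridge for stability when points are near-coplanar
        beta, *_ = np.linalg.lstsq(
            A.T @ A + 1e-10 * np.eye(A.shape[1]), A.T @ vals[take], rcond=None
        )
        _, g, H = _unpack_model(beta, n)
        if np.linalg.norm(g) < 1e-14 and np.all(np.abs(H) < 1e-14):
            radius *= 0.5
            continue
        step = _solve_trs(g, H, radius)
        predicted = -(g @ step + 0.5 * step @ H @ step)
        trial = center + step
        f_old = best["f"]
        f_new = evaluate(trial)
        actual = f_old - f_new
        if predicted <= 1e-15:
            radius *= 0.5
            continue
        rho = actual / predicted
        if rho < 0.1:
            radius *= 0.5
        elif rho > 0.7 and np.linalg.norm(step) > 0.9 * radius:
            radius = min(radius * 2.0, initial_radius * 4.0)

    return OptimizeResult(
        x=best["x"], fun=best["f"], n_evaluations=len(X),
        converged=converged, history=history,
    )
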