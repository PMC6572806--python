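"""Damped Newton iteration for nonlinear systems with banded Jacobians.

The steady-state diagenetic equations discretize to a nonlinear system whose
Jacobian is banded when unknowns are interleaved node-by-node.  The Jacobian is
formed by finite differences with column grouping (columns further apart than
the bandwidth are perturbed together), so one Jacobian costs ``lower+upper+1``
residual evaluations regardless of problem size.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.linalg import solve_banded


class ConvergenceError(RuntimeError):
    """Raised when the nonlinear iteration fails to reach tolerance."""


def banded_fd_jacobian(
    fun: Callable[[np.ndarray], np.ndarray],
    u: np.ndarray,
    f0: np.ndarray,
    lower: int,
    upper: int,
    typ: np.ndarray,
) -> np.ndarray:
    """Finite-difference Jacobian in LAPACK banded storage ``ab[u+i-j, j]``.

    ``typ`` sets the perturbation floor per unknown so that near-zero
    concentrations still receive a meaningful step.
    """
    n = u.size
    width = lower + upper + 1
    ab = np.zeros((width, n))
    eps = np.sqrt(np.finfo(float).eps)
    for color in range(width):
        cols = np.arange(color, n, width)
        if cols.size == 0:
            continue
        h = eps * np.maximum(np.abs(u[cols]), typ[cols])
        up = u.copy()
        up[cols] += h
        df = fun(up) - f0
        for j, hj in zip(cols, h):
            rows = np.arange(max(0, j - upper), min(n, j + lower + 1))
            ab[upper + rows - j, j] = df[rows] / hj
    return ab


def _norm(f: np.ndarray) -> float:
    return float(np.max(np.abs(f)))


def newton_banded(
    fun: Callable[[np.ndarray], np.ndarray],
    u0: np.ndarray,
    lower: int,
    upper: int,
    typ: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> tuple[np.ndarray, float, bool]:
    """Damped Newton on a scaled residual; returns ``(u, residual_norm, ok)``.

    The residual function is expected to return equations scaled to O(1) so
    that the max-norm is meaningful across species.  A geometric line search
    backs off steps that do not reduce the 2-norm; if the search stalls the
    caller may fall back to :func:`pseudo_transient`.
    """
    u = u0.copy()
    f = fun(u)
    if not np.all(np.isfinite(f)):
        raise ConvergenceError("non-finite residual at initial guess")
    for _ in range(max_iter):
        nf = _norm(f)
        if nf <= tol:
            return u, nf, True
        ab = banded_fd_jacobian(fun, u, f, lower, upper, typ)
        try:
            du = solve_banded((lower, upper), ab, -f)
        except np.linalg.LinAlgError:
            return u, nf, False
        if not np.all(np.isfinite(du)):
            return u, nf, False
        f2 = np.linalg.norm(f)
        lam = 1.0
        accepted = False
        while lam >= 2.0**-24:
            u_try = u + lam * du
            f_try = fun(u_try)
            if np.all(np.isfinite(f_try)) and np.linalg.norm(f_try) <= (1 - 1e-4 * lam) * f2:
                u, f = u_try, f_try
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            return u, _norm(f), False
    return u, _norm(f), _norm(f) <= tol


def pseudo_transient(
    fun: Callable[[np.ndarray], np.ndarray],
    u0: np.ndarray,
    lower: int,
    upper: int,
    typ: np.ndarray,
    tol: float = 1e-10,
    max_steps: int = 400,
    dt0: float = 1.0,
) -> tuple[np.ndarray, float, bool]:
    """Pseudo-transient continuation: backward-Euler steps on ``dw/dτ = f``.

    Works in the scaled variable ``w = u/typ`` so the artificial time step is
    dimensionless.  The step grows on success and shrinks on failure; once the
    residual is small the final polish is plain Newton.
    """
    u = u0.copy()
    f = fun(u)
    dt = dt0
    for _ in range(max_steps):
        nf = _norm(f)
        if nf <= tol:
            return u, nf, True
        if nf < 1e-4:
            return newton_banded(fun, u, lower, upper, typ, tol=tol)
        ab = banded_fd_jacobian(fun, u, f, lower, upper, typ)
        # Jacobian w.r.t. scaled variable: multiply column j by typ[j].
        n = u.size
        ab_w = ab * typ[np.newaxis, :]
        m = -ab_w
        m[upper, :] += 1.0 / dt
        try:
            dw = solve_banded((lower, upper), m, f)
        except np.linalg.LinAlgError:
            dt *= 0.25
            continue
        u_try = u + typ * dw
        f_try = fun(u_try)
        if np.all(np.isfinite(f_try)) and _norm(f_try) <= max(nf, 1.05 * nf):
            u, f = u_try, f_try
            dt = min(dt * 2.0, 1e8)
        else:
            dt *= 0.25
            if dt < 1e-12:
                return u, nf, False
    return u, _norm(f), _norm(f) <= tol
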