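"""Proximal-gradient machinery for the l1-penalised least-squares subproblems.

All subproblems solved here have the form

    minimise_x  x' H x - 2 b' x + c + g(x)

with ``H`` positive semi-definite (a Gram matrix ``G'G`` of a stacked linear
design) and ``g`` a separable-or-simple penalty with a cheap prox.  FISTA with
the exact Lipschitz constant ``L = 2 lambda_max(H)`` is used, tracking the
best-so-far iterate so a warm-started call can never return a worse objective
than its starting point (this is what makes the outer alternation in
``sysid.fit_unknown_inputs`` provably monotone).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "soft_threshold",
    "prox_l1_masked",
    "prox_l1_squared",
    "prox_l21_columns",
    "penalty_value",
    "make_prox",
    "fista_quadratic",
]


def soft_threshold(v: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)


def prox_l1_masked(v: np.ndarray, tau: float, mask: np.ndarray | None = None) -> np.ndarray:
    """Soft threshold the entries selected by ``mask`` (all entries if None)."""
    if mask is None:
        return soft_threshold(v, tau)
    out = v.copy()
    out[mask] = soft_threshold(v[mask], tau)
    return out


def prox_l1_squared(v: np.ndarray, tau: float) -> np.ndarray:
    """Prox of ``tau * (||v||_1)**2``.

    The minimiser is a soft threshold ``x = S(v, theta)`` whose level
    ``theta = 2 tau ||x||_1`` solves a piecewise-linear fixed point; it is
    found exactly by scanning the sorted magnitudes.
    """
    a = np.abs(v).ravel()
    if a.size == 0 or tau == 0 or not np.any(a > 0):
        return v if tau == 0 else np.zeros_like(v)
    srt = np.sort(a)[::-1]
    csum = np.cumsum(srt)
    j = np.arange(1, a.size + 1)
    theta = 2.0 * tau * csum / (1.0 + 2.0 * tau * j)
    # valid support size: largest j with srt[j-1] > theta[j-1]
    valid = srt > theta
    if not np.any(valid):
        return np.zeros_like(v)
    jstar = int(np.nonzero(valid)[0][-1])
    return soft_threshold(v, float(theta[jstar]))


def prox_l21_columns(v: np.ndarray, tau: float, shape: tuple[int, int]) -> np.ndarray:
    """Column-group soft threshold for a flattened (Fortran-order) matrix."""
    M = v.reshape(shape, order="F")
    norms = np.linalg.norm(M, axis=0)
    scale = np.maximum(1.0 - tau / np.maximum(norms, 1e-300), 0.0)
    return (M * scale[None, :]).ravel(order="F")


def penalty_value(x: np.ndarray, lam: float, kind: str, shape: tuple[int, int] | None = None,
                  mask: np.ndarray | None = None) -> float:
    xs = x[mask] if mask is not None else x
    if lam == 0:
        return 0.0
    if kind == "l1":
        return lam * float(np.abs(xs).sum())
    if kind == "l1_squared":
        return lam * float(np.abs(xs).sum()) ** 2
    if kind == "l21":
        assert shape is not None
        return lam * float(np.linalg.norm(xs.reshape(shape, order="F"), axis=0).sum())
    raise ValueError(f"unknown penalty kind {kind!r}")


def make_prox(lam: float, kind: str, shape: tuple[int, int] | None = None,
              mask: np.ndarray | None = None) -> Callable[[np.ndarray, float], np.ndarray]:
    """Return ``prox(v, step)`` for ``step * lam``-scaled penalty ``kind``."""

    def prox(v: np.ndarray, step: float) -> np.ndarray:
        tau = lam * step
        if tau == 0:
            return v
        if kind == "l1":
            return prox_l1_masked(v, tau, mask)
        if kind == "l1_squared":
            if mask is None:
                return prox_l1_squared(v, tau)
            out = v.copy()
            out[mask] = prox_l1_squared(v[mask], tau)
            return out
        if kind == "l21":
            assert shape is not None and mask is None
            return prox_l21_columns(v, tau, shape)
        raise ValueError(f"unknown penalty kind {kind!r}")

    return prox


def fista_quadratic(
    H: np.ndarray,
    b: np.ndarray,
    c: float,
    x0: np.ndarray,
    lam: float,
    penalty: str = "l1",
    pen_shape: tuple[int, int] | None = None,
    pen_mask: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, int]:
    """Minimise ``x'Hx - 2b'x + c + penalty`` starting from ``x0``.

    Returns ``(x_best, objective_best, n_iterations)``.  The returned
    objective is never worse than the starting objective (monotone via
    best-iterate tracking), and iterations stop once the relative objective
    improvement falls below ``tol``.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    evals = np.linalg.eigvalsh(H)
    L = 2.0 * max(float(evals[-1]), 1e-300)
    step = 1.0 / L
    prox = make_prox(lam, penalty, pen_shape, pen_mask)

    def quad(x: np.ndarray) -> float:
        return float(x @ (H @ x) - 2.0 * b @ x + c)

    def full(x: np.ndarray) -> float:
        return quad(x) + penalty_value(x, lam, penalty, pen_shape, pen_mask)

    x = x0.copy()
    y = x0.copy()
    t = 1.0
    best_x, best_f = x0.copy(), full(x0)
    prev_f = best_f
    it = 0
    for it in range(1, max_iter + 1):
        grad = 2.0 * (H @ y - b)
        x_new = prox(y - step * grad, step)
        f_new = full(x_new)
        if f_new > prev_f:  # adaptive restart on non-monotone step
            y = x.copy()
            t = 1.0
            grad = 2.0 * (H @ y - b)
            x_new = prox(y - step * grad, step)
            f_new = full(x_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        if f_new < best_f:
            best_x, best_f = x_new.copy(), f_new
        if abs(prev_f - f_new) <= tol * max(abs(prev_f), 1.0):
            prev_f = f_new
            break
        prev_f = f_new
    return best_x, best_f, it
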