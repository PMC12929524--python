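"""LTI system identification with unknown external inputs.

Model:  x[k+1] = A x[k] + B u[k] + w[k],  k = 0..T-1, with only x observed.
A is estimated first from input-free (resting) data — either by the
closed-form one-step least squares or by quasi-Newton minimisation of the
free-run (simulated-trajectory) group cost — because unaccounted external
inputs bias the estimate of A.  Holding A fixed, the sparse inputs U and
their spatial map B are then estimated on stimulus runs by alternating
convex l1-penalised least-squares steps on the objective

    sum_k ||z[k] - x[k]||^2 + lambda ||U||_1 + lambda pen(B),
    z[k+1] = A z[k] + B u[k],   z[0] = z0,

where ``pen`` is elementwise l1 by default (``l1_squared`` and column-group
``l21`` dialects are available).  Both alternating steps are exact convex
minimisations of this single objective (z is linear in U for fixed B and
linear in B for fixed U), so the objective trace is non-increasing by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from ._opt import fista_quadratic, penalty_value
from .errors import (
    DegenerateDesignError,
    DimensionError,
    DomainError,
    InternalConsistencyError,
    OptimizationFailureError,
    SingularDataError,
)
from .panels import TimeSeriesPanel

__all__ = [
    "LTIModel",
    "EstimationResult",
    "estimate_A_onestep",
    "estimate_A_group",
    "estimate_inputs",
    "estimate_B",
    "fit_unknown_inputs",
    "onestep_residuals",
    "select_input_dim",
    "input_support",
]


def input_support(U: np.ndarray, rel_threshold: float = 0.1) -> np.ndarray:
    """Boolean support of an estimated input matrix.

    The l1 solution carries small spurious activations from fitting noise;
    the conventional support keeps entries above ``rel_threshold`` times the
    largest estimated magnitude (default 10%).
    """
    U = np.asarray(U)
    peak = np.abs(U).max()
    if peak == 0:
        return np.zeros_like(U, dtype=bool)
    return np.abs(U) > rel_threshold * peak


@dataclass(frozen=True)
class LTIModel:
    """Fitted system: coupling matrix A, input map B, sparsity weight."""

    A: np.ndarray
    B: np.ndarray
    p: int
    reg_weight: float = 0.0
    penalty_b: str = "l1"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise DimensionError(f"A must be square, got {A.shape}")
        if B.shape != (A.shape[0], self.p):
            raise DimensionError(f"B must be {A.shape[0]}x{self.p}, got {B.shape}")
        if self.reg_weight < 0:
            raise DomainError("reg_weight must be >= 0")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)


@dataclass(frozen=True)
class EstimationResult:
    """Output of :func:`fit_unknown_inputs`.

    ``Z_by_subject[i]`` satisfies the constraint dynamics exactly for the
    stored A, B and U, and ``objective_trace`` recomputes exactly from the
    stored quantities (see :meth:`objective`).
    """

    model: LTIModel
    U_by_subject: list[np.ndarray]
    Z_by_subject: list[np.ndarray]
    z0_by_subject: list[np.ndarray]
    objective_trace: list[float]
    converged: bool
    n_iterations: int
    panels: tuple[TimeSeriesPanel, ...] = ()

    def objective(self) -> float:
        """Recompute the full regularised objective from stored A, B, U, Z."""
        lam = self.model.reg_weight
        J = 0.0
        for panel, U, z0 in zip(self.panels, self.U_by_subject, self.z0_by_subject):
            Z = _simulate(self.model.A, self.model.B, U, z0)
            J += float(((Z - panel.data) ** 2).sum()) + lam * float(np.abs(U).sum())
        J += penalty_value(
            self.model.B.ravel(order="F"), lam, self.model.penalty_b,
            shape=self.model.B.shape,
        )
        return J

    def normalized(self) -> "EstimationResult":
        """Gauge-fixed copy: unit-norm B columns, scale absorbed into U.

        The product ``B U`` and hence every latent trajectory is unchanged;
        PCA/ANOVA on B requires this fixed gauge.  Columns with negligible
        norm are left untouched (their input rows are uninformative).
        """
        B = self.model.B.copy()
        norms = np.linalg.norm(B, axis=0)
        scale = np.where(norms > 1e-12, norms, 1.0)
        if np.any(norms <= 1e-12):
            warnings.warn("B has near-zero columns; gauge left unchanged for them", RuntimeWarning)
        B = B / scale[None, :]
        U = [u * scale[:, None] for u in self.U_by_subject]
        return replace(self, model=replace(self.model, B=B), U_by_subject=U)


# ---------------------------------------------------------------------------
# A estimation

def _check_panels(panels: list[TimeSeriesPanel]) -> int:
    if not panels:
        raise DimensionError("need at least one panel")
    n = panels[0].n
    for p in panels:
        if p.n != n:
            raise DimensionError("panels disagree on ROI count")
    return n


def _pooled_onestep(panels: list[TimeSeriesPanel]) -> np.ndarray:
    """Closed-form minimiser of sum_i sum_k ||x[k+1] - A x[k]||^2."""
    n = _check_panels(panels)
    Xm = np.hstack([p.data[:, :-1] for p in panels])
    Xp = np.hstack([p.data[:, 1:] for p in panels])
    s = np.linalg.svd(Xm, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-12:
        cond = np.inf if s[-1] == 0 else s[0] / s[-1]
        raise SingularDataError(
            f"lag-regressor matrix is rank deficient (condition number {cond:.3g}); "
            "the series do not excite all ROI directions"
        )
    # minimum-norm least squares on X-' (SVD; equals the normal-equations
    # solution but does not square the conditioning)
    return np.linalg.lstsq(Xm.T, Xp.T, rcond=None)[0].T


def estimate_A_onestep(panel: TimeSeriesPanel) -> np.ndarray:
    """One-step least-squares estimate of A from a single run.

    Exact normal-equations solution of
    ``argmin_A sum_k ||x[k+1] - A x[k]||^2`` — the closed-form initialiser
    obtained by setting the inputs to zero.
    """
    return _pooled_onestep([panel])


def _freerun_value_grad(avec: np.ndarray, panels: list[TimeSeriesPanel], n: int):
    """Free-run group cost J(A) and its gradient by reverse accumulation.

    The predicted trajectory evolves autonomously from each run's first
    sample: xhat[k+1] = A xhat[k], xhat[0] = x[0].
    """
    A = avec.reshape(n, n)
    J = 0.0
    G = np.zeros((n, n))
    for panel in panels:
        x = panel.data
        T = panel.T
        xhat = np.empty_like(x)
        xhat[:, 0] = x[:, 0]
        for k in range(T):
            xhat[:, k + 1] = A @ xhat[:, k]
            if np.abs(xhat[:, k + 1]).max() > 1e100:
                return np.inf, np.zeros(n * n)
        e = xhat - x
        J += float((e * e).sum())
        p = 2.0 * e[:, T]
        for k in range(T - 1, -1, -1):
            G += np.outer(p, xhat[:, k])
            p = 2.0 * e[:, k] + A.T @ p
    return J, G.ravel()


def estimate_A_group(
    panels: list[TimeSeriesPanel],
    objective: str = "freerun",
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> np.ndarray:
    """Group-level A minimising the summed prediction error across runs.

    ``objective='onestep'`` predicts each sample from the measured previous
    sample; the minimiser is the pooled closed-form least squares.
    ``objective='freerun'`` predicts by autonomous simulation from each
    run's first sample (the simulated-trajectory reading of the group cost)
    and is minimised by a quasi-Newton (L-BFGS) iteration started from
    ``init`` (default: the pooled one-step estimate).
    """
    n = _check_panels(panels)
    if objective == "onestep":
        return _pooled_onestep(panels)
    if objective != "freerun":
        raise DomainError(f"objective must be 'onestep' or 'freerun', got {objective!r}")
    A0 = _pooled_onestep(panels) if init is None else np.asarray(init, dtype=float)
    if A0.shape != (n, n):
        raise DimensionError(f"init must be {n}x{n}")
    res = minimize(
        _freerun_value_grad,
        A0.ravel(),
        args=(panels, n),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise OptimizationFailureError(
            f"free-run optimisation diverged (status {res.status}: {res.message})"
        )
    return res.x.reshape(n, n)


# ---------------------------------------------------------------------------
# Input / input-map estimation (A fixed)

def _simulate(A: np.ndarray, B: np.ndarray, U: np.ndarray, z0: np.ndarray) -> np.ndarray:
    T = U.shape[1]
    n = A.shape[0]
    Z = np.empty((n, T + 1))
    Z[:, 0] = z0
    for k in range(T):
        Z[:, k + 1] = A @ Z[:, k] + B @ U[:, k]
    return Z


def _free_traj(A: np.ndarray, z0: np.ndarray, T: int) -> np.ndarray:
    n = A.shape[0]
    Z = np.empty((n, T + 1))
    Z[:, 0] = z0
    for k in range(T):
        Z[:, k + 1] = A @ Z[:, k]
    return Z


def _input_design(A: np.ndarray, B: np.ndarray, T: int) -> np.ndarray:
    """Stacked linear map from vec(U) (time-major blocks of p) to vec(z),
    zero initial state: block (k', j) of G is A^{k'-1-j} B."""
    n, p = B.shape
    H = np.empty((T, n, p))
    H[0] = B
    for m in range(1, T):
        H[m] = A @ H[m - 1]
    G = np.zeros(((T + 1) * n, T * p))
    for kp in range(1, T + 1):
        for j in range(kp):
            G[kp * n : (kp + 1) * n, j * p : (j + 1) * p] = H[kp - 1 - j]
    return G


def _state_powers(A: np.ndarray, T: int) -> np.ndarray:
    n = A.shape[0]
    P = np.empty((T + 1, n, n))
    P[0] = np.eye(n)
    for m in range(1, T + 1):
        P[m] = A @ P[m - 1]
    return P


def estimate_inputs(
    panel: TimeSeriesPanel,
    A: np.ndarray,
    B: np.ndarray,
    reg_weight: float,
    z0_free: bool = False,
    max_iter: int = 500,
    tol: float = 1e-12,
    U0: np.ndarray | None = None,
    z00: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse input trajectories for one run, A and B fixed.

    Solves the convex problem

        min_{U (, z0)}  sum_k ||z[k] - x[k]||^2 + lambda ||U||_1
        s.t. z[k+1] = A z[k] + B u[k],  z[0] = z0  (default z0 = x[0])

    as an l1-penalised least squares in the stacked unknowns (FISTA on the
    Gram form of the impulse-response design).  Returns ``(U, z0)`` with
    ``U`` of shape ``(p, T)``.
    """
    if reg_weight < 0:
        raise DomainError("reg_weight must be >= 0")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n, T = panel.n, panel.T
    if A.shape != (n, n):
        raise DimensionError(f"A must be {n}x{n}, got {A.shape}")
    if B.shape[0] != n:
        raise DimensionError(f"B must have {n} rows, got {B.shape}")
    p = B.shape[1]
    x = panel.data
    G = _input_design(A, B, T)
    nu = T * p
    if z0_free:
        P = _state_powers(A, T)
        G = np.hstack([G, np.vstack(list(P))])  # extra n columns carry z0 through A^k
        y = x.T.ravel()
        mask = np.zeros(nu + n, dtype=bool)
        mask[:nu] = True
    else:
        z0 = x[:, 0].copy()
        y = (x - _free_traj(A, z0, T)).T.ravel()
        mask = None
    if reg_weight == 0.0:
        sol = np.linalg.lstsq(G, y, rcond=None)[0]
        U = sol[:nu].reshape(T, p).T
        z0 = sol[nu:] if z0_free else x[:, 0].copy()
        return U, z0
    H = G.T @ G
    b = G.T @ y
    c = float(y @ y)
    x0 = np.zeros(H.shape[0])
    if U0 is not None:
        x0[:nu] = np.asarray(U0, dtype=float).T.ravel()
    if z0_free:
        x0[nu:] = x[:, 0] if z00 is None else np.asarray(z00, dtype=float)
    sol, _, _ = fista_quadratic(
        H, b, c, x0, reg_weight, penalty="l1", pen_mask=mask, max_iter=max_iter, tol=tol
    )
    U = sol[:nu].reshape(T, p).T
    z0 = sol[nu:] if z0_free else x[:, 0].copy()
    return U, z0


def estimate_B(
    Z_by_subject: list[np.ndarray],
    U_by_subject: list[np.ndarray],
    A: np.ndarray,
    reg_weight: float = 0.0,
    penalty: str = "l1",
    X_by_subject: list[np.ndarray] | None = None,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> np.ndarray:
    """Input spatial map from approximated latent trajectories and inputs.

    Minimises the stacked one-step reconstruction error

        sum_i sum_k ||z_i[k+1] - A z_i[k] - B u_i[k]||^2 + lambda pen(B)

    (``X_by_subject`` is accepted for interface completeness; the fit uses
    the latent trajectories).  Deterministic; with ``reg_weight = 0`` the
    solution is the exact least-squares map.
    """
    del X_by_subject
    if reg_weight < 0:
        raise DomainError("reg_weight must be >= 0")
    A = np.asarray(A, dtype=float)
    if len(Z_by_subject) != len(U_by_subject) or not Z_by_subject:
        raise DimensionError("need matching, non-empty Z and U lists")
    M = np.hstack(U_by_subject)
    R = np.hstack([Z[:, 1:] - A @ Z[:, :-1] for Z in Z_by_subject])
    if R.shape[1] != M.shape[1]:
        raise DimensionError("Z and U disagree on sample counts")
    if not np.any(M):
        raise DegenerateDesignError("all input trajectories are zero; B is unidentifiable")
    n = A.shape[0]
    p = M.shape[0]
    if reg_weight == 0.0:
        return np.linalg.lstsq(M.T, R.T, rcond=None)[0].T
    # quadratic in vec(B), Fortran order (columns stacked): ||R - B M||_F^2
    H = np.kron(M @ M.T, np.eye(n))
    b = (R @ M.T).ravel(order="F")
    c = float((R * R).sum())
    x0 = np.zeros(n * p)
    sol, _, _ = fista_quadratic(
        H, b, c, x0, reg_weight, penalty=penalty, pen_shape=(n, p),
        max_iter=max_iter, tol=tol,
    )
    return sol.reshape(n, p, order="F")


def _b_step_grams(
    panels: list[TimeSeriesPanel],
    A: np.ndarray,
    U_by_subject: list[np.ndarray],
    z0_by_subject: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gram accumulation for the B block of the simulated-trajectory
    objective: z is linear in vec(B) with per-sample coefficient matrices
    C_j[k+1] = A C_j[k] + u_j[k] I."""
    n = A.shape[0]
    p = U_by_subject[0].shape[0]
    H = np.zeros((n * p, n * p))
    b = np.zeros(n * p)
    c = 0.0
    eye = np.eye(n)
    for panel, U, z0 in zip(panels, U_by_subject, z0_by_subject):
        T = panel.T
        y = (panel.data - _free_traj(A, z0, T)).T.ravel()
        Gm = np.zeros(((T + 1) * n, n * p))
        C = np.zeros((p, n, n))
        for k in range(T):
            C = A[None] @ C + U[:, k][:, None, None] * eye[None]
            row = (k + 1) * n
            for j in range(p):
                Gm[row : row + n, j * n : (j + 1) * n] = C[j]
        H += Gm.T @ Gm
        b += Gm.T @ y
        c += float(y @ y)
    return H, b, c


def fit_unknown_inputs(
    panels: list[TimeSeriesPanel],
    A: np.ndarray,
    p: int,
    reg_weight: float = 0.5,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: int | None = 0,
    penalty_b: str = "l1",
    z0_free: bool = False,
    inner_max_iter: int = 400,
) -> EstimationResult:
    """Alternating estimation of sparse inputs U and spatial map B, A fixed.

    B is initialised with seeded random orthonormal columns; the U step and
    the B step are each exact convex minimisations (warm started, monotone)
    of the shared objective, so the recorded objective trace never
    increases.  Convergence is declared when the relative objective change
    falls below ``tol``; an increase beyond numerical tolerance raises
    :class:`InternalConsistencyError`.
    """
    n = _check_panels(panels)
    A = np.asarray(A, dtype=float)
    if A.shape != (n, n):
        raise DimensionError(f"A must be {n}x{n}")
    if p < 1:
        raise DomainError("p must be >= 1")
    if reg_weight < 0:
        raise DomainError("reg_weight must be >= 0")
    rng = np.random.default_rng(seed)
    Bmat = np.linalg.qr(rng.standard_normal((n, p)))[0]
    U_list = [np.zeros((p, panel.T)) for panel in panels]
    z0_list = [panel.data[:, 0].copy() for panel in panels]

    def full_objective(B: np.ndarray, Us: list[np.ndarray], z0s: list[np.ndarray]) -> float:
        J = 0.0
        for panel, U, z0 in zip(panels, Us, z0s):
            Z = _simulate(A, B, U, z0)
            J += float(((Z - panel.data) ** 2).sum()) + reg_weight * float(np.abs(U).sum())
        return J + penalty_value(B.ravel(order="F"), reg_weight, penalty_b, shape=B.shape)

    trace = [full_objective(Bmat, U_list, z0_list)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i, panel in enumerate(panels):
            U_list[i], z0_list[i] = estimate_inputs(
                panel, A, Bmat, reg_weight, z0_free=z0_free,
                max_iter=inner_max_iter, U0=U_list[i], z00=z0_list[i],
            )
        H, b, c = _b_step_grams(panels, A, U_list, z0_list)
        bvec, _, _ = fista_quadratic(
            H, b, c, Bmat.ravel(order="F"), reg_weight, penalty=penalty_b,
            pen_shape=(n, p), max_iter=inner_max_iter, tol=1e-12,
        )
        Bmat = bvec.reshape(n, p, order="F")
        J = full_objective(Bmat, U_list, z0_list)
        if J > trace[-1] * (1.0 + 1e-7) + 1e-9:
            raise InternalConsistencyError(
                f"objective increased at alternation {it}: {trace[-1]:.6g} -> {J:.6g}"
            )
        J = min(J, trace[-1])  # clip sub-roundoff wiggle so the trace is monotone
        trace.append(J)
        if abs(trace[-2] - trace[-1]) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    Z_list = [_simulate(A, Bmat, U, z0) for U, z0 in zip(U_list, z0_list)]
    model = LTIModel(A=A, B=Bmat, p=p, reg_weight=reg_weight, penalty_b=penalty_b)
    return EstimationResult(
        model=model,
        U_by_subject=U_list,
        Z_by_subject=Z_list,
        z0_by_subject=z0_list,
        objective_trace=trace,
        converged=converged,
        n_iterations=it,
        panels=tuple(panels),
    )


# ---------------------------------------------------------------------------
# Residual analysis / input-dimension selection

def onestep_residuals(panels: list[TimeSeriesPanel], A: np.ndarray) -> np.ndarray:
    """Concatenated one-step residuals r[k] = x[k+1] - A x[k] across runs
    (shape ``n x sum_i T_i``)."""
    n = _check_panels(panels)
    A = np.asarray(A, dtype=float)
    if A.shape != (n, n):
        raise DimensionError(f"A must be {n}x{n}")
    return np.hstack([p.data[:, 1:] - A @ p.data[:, :-1] for p in panels])


def select_input_dim(residuals: np.ndarray, variance_target: float) -> int:
    """Smallest number of principal components of the residuals whose
    cumulative explained variance reaches ``variance_target``.

    Uncentred PCA (SVD of the residual matrix): model residuals are
    nominally zero-mean, and the uncentred convention makes constructed
    spectra exact.
    """
    if not (0.0 < variance_target < 1.0):
        raise DomainError(f"variance_target must lie in (0, 1), got {variance_target}")
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise DegenerateDesignError("need a residual matrix with at least 2 samples")
    s = np.linalg.svd(R, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise DegenerateDesignError("residuals are identically zero")
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, variance_target - 1e-12) + 1)
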