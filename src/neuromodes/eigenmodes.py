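"""Eigenmode decomposition of fitted system matrices.

An eigenmode is an eigenvalue-eigenvector pair (lambda_i, v_i) of the
system matrix A.  In polar form lambda_i = |lambda_i| e^{i theta_i} the
angle gives the oscillation frequency

    f_i = theta_i / (2 pi dt)        [Hz]

and the magnitude the damping rate (stability)

    rho_i = ln|lambda_i| / dt        [1/s]

with |lambda| < 1 a stable (decaying) mode, > 1 unstable (growing) and
approximately 1 meta-stable.  All n modes are retained, conjugate pairs
included; angles are folded to [0, pi] so a conjugate pair shares its
frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, DomainError
from .panels import TimeSeriesPanel

__all__ = [
    "Eigenmode",
    "ModalProjection",
    "decompose",
    "classify_stability",
    "modal_projection",
    "modes_table",
]

#: Modes with ``| |lambda| - 1 | <= META_TOL`` are classified meta-stable.
META_TOL = 0.01


@dataclass(frozen=True)
class Eigenmode:
    eigenvalue: complex
    eigenvector: np.ndarray  # unit Euclidean norm, complex
    frequency_hz: float
    stability_per_s: float
    magnitude: float
    angle: float
    stability_class: str
    state_label: str = ""


@dataclass(frozen=True)
class ModalProjection:
    """Data expressed in the eigenvector basis: z = V* x."""

    z: np.ndarray
    basis: np.ndarray


def classify_stability(magnitude: float, meta_tol: float = META_TOL) -> str:
    """Classify a mode from |lambda|: stable / unstable / metastable."""
    if magnitude <= 0:
        raise DomainError(f"magnitude must be > 0, got {magnitude}")
    if meta_tol < 0:
        raise DomainError("meta_tol must be >= 0")
    if abs(magnitude - 1.0) <= meta_tol:
        return "metastable"
    return "stable" if magnitude < 1.0 else "unstable"


def decompose(
    A: np.ndarray,
    dt: float,
    meta_tol: float = META_TOL,
    state_label: str = "",
) -> list[Eigenmode]:
    """All ``n`` eigenmodes of ``A`` with physical frequency and stability.

    Modes are returned in a canonical order (descending magnitude, ties by
    ascending angle) so repeated decompositions of the same matrix are
    reproducible regardless of the eigensolver's internal ordering.  A
    near-defective eigenvector matrix triggers a warning; eigenvalue-based
    statistics remain valid.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError(f"A must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise DomainError("A contains non-finite entries")
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    lam, V = np.linalg.eig(A)
    if np.linalg.cond(V) > 1e8:
        warnings.warn(
            "eigenvector matrix is ill-conditioned (near-defective A); "
            "modal projections are unreliable, eigenvalue statistics remain valid",
            RuntimeWarning,
            stacklevel=2,
        )
    mags = np.abs(lam)
    angles = np.abs(np.angle(lam))  # folded to [0, pi]
    order = np.lexsort((angles, -mags))
    modes = []
    for i in order:
        m = float(mags[i])
        th = float(angles[i])
        v = V[:, i]
        v = v / np.linalg.norm(v)
        modes.append(
            Eigenmode(
                eigenvalue=complex(lam[i]),
                eigenvector=v,
                frequency_hz=th / (2.0 * np.pi * dt),
                stability_per_s=float(np.log(m) / dt),
                magnitude=m,
                angle=th,
                stability_class=classify_stability(m, meta_tol),
                state_label=state_label,
            )
        )
    return modes


def modal_projection(V: np.ndarray, panel: TimeSeriesPanel) -> ModalProjection:
    """Project a panel into the eigenvector basis, ``z[k] = V* x[k]``.

    No dimensionality reduction is applied: ``V`` must be the full square
    eigenvector matrix.
    """
    V = np.asarray(V)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise DimensionError(f"V must be square, got shape {V.shape}")
    if V.shape[0] != panel.n:
        raise DimensionError(f"V is {V.shape[0]}x{V.shape[0]} but panel has {panel.n} ROIs")
    return ModalProjection(z=V.conj().T @ panel.data, basis=V)


def modes_table(modes: list[Eigenmode]) -> pd.DataFrame:
    """Tabulate modes: state, index, re, im, magnitude, angle, frequency,
    stability, class (one row per mode, canonical order preserved)."""
    return pd.DataFrame(
        {
            "state": [m.state_label for m in modes],
            "mode_index": np.arange(len(modes)),
            "re": [m.eigenvalue.real for m in modes],
            "im": [m.eigenvalue.imag for m in modes],
            "magnitude": [m.magnitude for m in modes],
            "angle": [m.angle for m in modes],
            "frequency_hz": [m.frequency_hz for m in modes],
            "stability_per_s": [m.stability_per_s for m in modes],
            "class": [m.stability_class for m in modes],
        }
    )
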