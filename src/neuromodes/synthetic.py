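"""Ground-truth cohort generator.

Builds multi-subject, multi-state cohorts from known linear time-invariant
(LTI) systems so that every downstream stage — system identification,
eigenmode statistics, input-pattern analysis, state classification — has a
recoverable truth.  The generator emulates the shape of a propofol-sedation
fMRI study: N subjects scanned in four consciousness states (awake, light,
deep, recovery), each contributing a resting-state run (no external input)
and a stimulus run driven by sparse low-dimensional inputs, sampled at
TR = 2 s with 256 rest / 155 task samples.

The dynamics are ``x[k+1] = A x[k] + B u[k] + w[k]`` with state-specific
``A`` sharing a common eigenvector basis, so consciousness states differ
only through planted eigenvalue (magnitude/angle) shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ortho_group

from .errors import DimensionError, DomainError
from .panels import TimeSeriesPanel

__all__ = [
    "ModeSpec",
    "GroundTruthSystem",
    "InputConfig",
    "SyntheticCohort",
    "make_stable_system",
    "make_modular_system",
    "simulate_run",
    "make_sparse_inputs",
    "make_state_ensemble",
    "rademacher_map",
    "flip_rois",
    "demo_cohort",
]

#: Default burn-in used to draw the initial state from (approximate)
#: stationarity, discarding the transient.
BURN_IN = 100


@dataclass(frozen=True)
class ModeSpec:
    """One planted eigenvalue: polar magnitude/angle plus multiplicity.

    ``angle`` in ``(0, pi)`` denotes a complex-conjugate pair (each unit of
    multiplicity occupies two real dimensions); ``angle`` equal to 0 or pi a
    real eigenvalue (one dimension per unit).
    """

    magnitude: float
    angle: float
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise DomainError(f"mode magnitude must be > 0, got {self.magnitude}")
        if not (0.0 <= self.angle <= math.pi):
            raise DomainError(f"mode angle must lie in [0, pi], got {self.angle}")
        if self.multiplicity < 1:
            raise DomainError("mode multiplicity must be >= 1")

    @property
    def dims(self) -> int:
        """Real dimensions occupied (2 per conjugate pair)."""
        per = 1 if self.angle in (0.0, math.pi) else 2
        return per * self.multiplicity


def _as_mode_specs(mode_spec) -> tuple[ModeSpec, ...]:
    out = []
    for m in mode_spec:
        out.append(m if isinstance(m, ModeSpec) else ModeSpec(*m))
    return tuple(out)


def _real_block_diagonal(specs: tuple[ModeSpec, ...]) -> np.ndarray:
    """Real canonical form: 2x2 rotation-scaling blocks for conjugate pairs."""
    n = sum(s.dims for s in specs)
    D = np.zeros((n, n))
    i = 0
    for s in specs:
        for _ in range(s.multiplicity):
            if s.angle in (0.0, math.pi):
                D[i, i] = s.magnitude * math.cos(s.angle)
                i += 1
            else:
                c, sn = s.magnitude * math.cos(s.angle), s.magnitude * math.sin(s.angle)
                D[i : i + 2, i : i + 2] = [[c, -sn], [sn, c]]
                i += 2
    return D


@dataclass(frozen=True)
class GroundTruthSystem:
    """A known LTI system with planted eigenstructure.

    ``A_true = V D V^{-1}`` where ``D`` is the real canonical form of
    ``mode_spec`` and ``V`` a real well-conditioned basis (orthogonal by
    default, so the eigenvector basis is unitary and modal projections are
    exact isometries).
    """

    n: int
    A_true: np.ndarray
    mode_spec: tuple[ModeSpec, ...]
    V_true: np.ndarray
    dt: float = 2.0

    def planted_eigenvalues(self) -> np.ndarray:
        """All n planted eigenvalues, conjugates included."""
        vals: list[complex] = []
        for s in self.mode_spec:
            lam = s.magnitude * np.exp(1j * s.angle)
            for _ in range(s.multiplicity):
                if s.angle in (0.0, math.pi):
                    vals.append(lam.real + 0j)
                else:
                    vals.extend([lam, lam.conjugate()])
        return np.asarray(vals)


def make_stable_system(
    n: int,
    mode_spec,
    seed: int | None = None,
    dt: float = 2.0,
    basis: np.ndarray | None = None,
    nonnormality: float = 0.0,
) -> GroundTruthSystem:
    """Construct a real system matrix with the requested eigenvalues.

    Parameters
    ----------
    n
        ROI count.
    mode_spec
        Iterable of ``(magnitude, angle, multiplicity)`` triples (or
        :class:`ModeSpec`); total real dimension must equal ``n``.
    seed
        Seeds the random eigenvector basis (ignored when ``basis`` given).
    basis
        Optional explicit real basis ``V`` (columns span mode subspaces in
        spec order).
    nonnormality
        0 gives an orthogonal basis (normal ``A``); larger values mix in a
        Gaussian perturbation for robustness experiments.
    """
    specs = _as_mode_specs(mode_spec)
    total = sum(s.dims for s in specs)
    if total != n:
        raise DimensionError(f"mode multiplicities occupy {total} dimensions, expected n={n}")
    if basis is not None:
        V = np.asarray(basis, dtype=float)
        if V.shape != (n, n):
            raise DimensionError(f"basis must be {n}x{n}, got {V.shape}")
    else:
        rng = np.random.default_rng(seed)
        V = np.eye(n) if n == 1 else ortho_group.rvs(n, random_state=rng)
        if nonnormality > 0:
            V = V + nonnormality * rng.standard_normal((n, n))
            if np.linalg.cond(V) > 1e6:
                raise DomainError("nonnormality produced an ill-conditioned basis")
    D = _real_block_diagonal(specs)
    A = V @ D @ np.linalg.inv(V)
    return GroundTruthSystem(n=n, A_true=A, mode_spec=specs, V_true=V, dt=dt)


def make_modular_system(
    n_blocks: int = 5,
    block_size: int = 6,
    block_magnitudes=(0.78, 0.815, 0.85, 0.885, 0.92),
    magnitude_spread: float = 0.01,
    angle_min: float = 0.2,
    angle_step: float = 0.19,
    seed: int | None = None,
    dt: float = 2.0,
) -> tuple[GroundTruthSystem, np.ndarray]:
    """System whose eigenvector support is confined to disjoint ROI blocks.

    Each block hosts ``block_size // 2`` conjugate pairs near the block's
    magnitude (within a small ``magnitude_spread``), mixed by a block-local
    orthogonal basis, so eigenvector-magnitude features cluster perfectly by
    block.  Every pair receives a unique angle (``angle_min`` stepping by
    ``angle_step``): well-separated eigenvalues keep the fitted eigenvectors
    from mixing across blocks under estimation noise.  Returns the system
    and the block index of every mode-spec entry.
    """
    if block_size % 2:
        raise DomainError("block_size must be even (conjugate pairs)")
    pairs = block_size // 2
    block_magnitudes = np.asarray(block_magnitudes, dtype=float)
    if block_magnitudes.shape != (n_blocks,):
        raise DimensionError(f"need one magnitude per block ({n_blocks})")
    if angle_min + angle_step * (n_blocks * pairs - 1) >= math.pi:
        raise DomainError("angle grid exceeds pi; reduce angle_step or angle_min")
    deltas = np.linspace(-magnitude_spread, magnitude_spread, pairs)
    n = n_blocks * block_size
    rng = np.random.default_rng(seed)
    V = np.zeros((n, n))
    specs: list[ModeSpec] = []
    block_of_spec: list[int] = []
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        V[sl, sl] = ortho_group.rvs(block_size, random_state=rng)
        for j in range(pairs):
            specs.append(
                ModeSpec(float(block_magnitudes[b] + deltas[j]),
                         float(angle_min + angle_step * (b * pairs + j)), 1)
            )
            block_of_spec.append(b)
    sys = make_stable_system(n, specs, dt=dt, basis=V)
    return sys, np.asarray(block_of_spec)


def simulate_run(
    system: GroundTruthSystem,
    T: int,
    B_true: np.ndarray | None = None,
    U: np.ndarray | None = None,
    noise_sd: float = 0.0,
    x0: np.ndarray | None = None,
    seed: int | None = None,
    subject_id: str = "",
    state_label: str = "",
    run_type: str = "",
) -> TimeSeriesPanel:
    """Simulate ``x[k+1] = A x[k] + B u[k] + w[k]`` for ``k = 0..T-1``.

    Returns an ``n x (T+1)`` panel.  With ``x0`` absent and ``noise_sd > 0``
    the initial state is drawn from approximate stationarity via a
    ``BURN_IN``-sample discarded transient; deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    A = system.A_true
    n = system.n
    rng = np.random.default_rng(seed)
    if (B_true is None) != (U is None):
        raise DimensionError("B_true and U must be given together")
    if U is not None:
        B_true = np.asarray(B_true, dtype=float)
        U = np.asarray(U, dtype=float)
        if B_true.shape[0] != n:
            raise DimensionError(f"B has {B_true.shape[0]} rows, expected {n}")
        if B_true.shape[1] != U.shape[0]:
            raise DimensionError(
                f"B has {B_true.shape[1]} columns but U has {U.shape[0]} rows"
            )
        if U.shape[1] != T:
            raise DimensionError(f"U has {U.shape[1]} columns, expected T={T}")
    if x0 is None:
        x = np.zeros(n)
        if noise_sd > 0:
            for _ in range(BURN_IN):
                x = A @ x + noise_sd * rng.standard_normal(n)
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.shape != (n,):
            raise DimensionError(f"x0 must have shape ({n},)")
    X = np.empty((n, T + 1))
    X[:, 0] = x
    for k in range(T):
        x = A @ x
        if U is not None:
            x = x + B_true @ U[:, k]
        if noise_sd > 0:
            x = x + noise_sd * rng.standard_normal(n)
        X[:, k + 1] = x
    return TimeSeriesPanel(
        data=X, dt=system.dt, subject_id=subject_id, state_label=state_label, run_type=run_type
    )


def make_sparse_inputs(
    p: int, T: int, density: float, amplitude: float, seed: int | None = None
) -> np.ndarray:
    """Sparse ``p x T`` input matrix with exactly ``round(density*p*T)``
    nonzero entries of value ``+-amplitude``; reproducible by seed."""
    if not (0.0 < density < 1.0):
        raise DomainError(f"density must lie in (0, 1), got {density}")
    k = int(round(density * p * T))
    if k < 1:
        raise DomainError("density * p * T must be at least 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(p * T, size=k, replace=False)
    U = np.zeros(p * T)
    U[idx] = amplitude * rng.choice([-1.0, 1.0], size=k)
    return U.reshape(p, T)


@dataclass(frozen=True)
class InputConfig:
    """Task-run driver configuration: dimension, sparsity, spatial maps.

    ``B`` is the shared ``n x p`` spatial map; ``B_by_state`` overrides it
    for specific states (how state-dependent stimulus propagation is
    planted).  When both are None a random unit-column map is drawn.
    """

    p: int = 3
    density: float = 0.05
    amplitude: float = 1.0
    B: np.ndarray | None = None
    B_by_state: dict[str, np.ndarray] | None = None

    def map_for(self, state: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.B_by_state is not None and state in self.B_by_state:
            return np.asarray(self.B_by_state[state], dtype=float)
        if self.B is not None:
            return np.asarray(self.B, dtype=float)
        B = rng.standard_normal((n, self.p))
        return B / np.linalg.norm(B, axis=0, keepdims=True)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated multi-subject multi-state cohort with its ground truth."""

    states: tuple[str, ...]
    systems: dict[str, GroundTruthSystem]
    subjects_per_state: int
    rest: dict[str, list[TimeSeriesPanel]]
    task: dict[str, list[TimeSeriesPanel]]
    B_true: dict[str, np.ndarray] = field(default_factory=dict)
    U_true: dict[str, list[np.ndarray]] = field(default_factory=dict)
    noise_sd: float = 0.1
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def rest_panels(self, state: str) -> list[TimeSeriesPanel]:
        return self.rest[state]

    def task_panels(self, state: str) -> list[TimeSeriesPanel]:
        return self.task[state]

    @property
    def all_panels(self) -> list[TimeSeriesPanel]:
        out: list[TimeSeriesPanel] = []
        for s in self.states:
            out.extend(self.rest[s])
            out.extend(self.task[s])
        return out


def _perturbed_specs(
    base: tuple[ModeSpec, ...], pert: dict[int, tuple[float, float]]
) -> tuple[ModeSpec, ...]:
    out = list(base)
    for idx, (dmag, dang) in pert.items():
        s = base[idx]
        mag = s.magnitude + dmag
        if mag <= 0:
            raise DomainError(f"perturbation drives mode {idx} magnitude to {mag} <= 0")
        ang = min(max(s.angle + dang, 0.0), math.pi)
        out[idx] = ModeSpec(mag, ang, s.multiplicity)
    return tuple(out)


def make_state_ensemble(
    base: GroundTruthSystem,
    perturbations: dict[str, dict[int, tuple[float, float]]],
    n_subjects: int,
    T_rest: int = 255,
    T_task: int = 154,
    noise_sd: float = 0.1,
    input_config: InputConfig | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a cohort of ``n_subjects`` per state.

    All states share the base eigenvector basis ``V_true``; each state's
    system differs only by the planted ``(magnitude delta, angle delta)``
    shifts keyed by mode-spec index — mirroring a single group-level system
    per consciousness level with state-dependent eigenvalue shifts.  Rest
    runs are input free; task runs are driven by per-subject sparse inputs
    through the state's spatial map.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    states = tuple(perturbations.keys())
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    systems = {
        st: make_stable_system(
            base.n, _perturbed_specs(base.mode_spec, perturbations[st]), dt=base.dt, basis=base.V_true
        )
        for st in states
    }
    rest: dict[str, list[TimeSeriesPanel]] = {st: [] for st in states}
    task: dict[str, list[TimeSeriesPanel]] = {st: [] for st in states}
    B_true: dict[str, np.ndarray] = {}
    U_true: dict[str, list[np.ndarray]] = {st: [] for st in states}
    cfg = input_config
    child = iter(ss.spawn(len(states) * n_subjects * 3 + len(states)))
    for st in states:
        if cfg is not None:
            B_true[st] = cfg.map_for(st, base.n, np.random.default_rng(next(child)))
        else:
            next(child)
        for i in range(n_subjects):
            sid = f"sub-{i + 1:02d}"
            rest[st].append(
                simulate_run(
                    systems[st], T_rest, noise_sd=noise_sd, seed=next(child),
                    subject_id=sid, state_label=st, run_type="rest",
                )
            )
            if cfg is not None:
                U = make_sparse_inputs(cfg.p, T_task, cfg.density, cfg.amplitude, seed=next(child))
                U_true[st].append(U)
                task[st].append(
                    simulate_run(
                        systems[st], T_task, B_true=B_true[st], U=U, noise_sd=noise_sd,
                        seed=next(child), subject_id=sid, state_label=st, run_type="task",
                    )
                )
            else:
                next(child)
                task[st].append(
                    simulate_run(
                        systems[st], T_task, noise_sd=noise_sd, seed=next(child),
                        subject_id=sid, state_label=st, run_type="task",
                    )
                )
    return SyntheticCohort(
        states=states, systems=systems, subjects_per_state=n_subjects,
        rest=rest, task=task, B_true=B_true, U_true=U_true,
        noise_sd=noise_sd, seed=seed,
    )


def rademacher_map(n: int, seed: int | None = None) -> np.ndarray:
    """Unit-norm spatial map with entries ``+-1/sqrt(n)`` (every ROI loaded
    equally in magnitude, so planted sign flips shift each flipped ROI by the
    same amount)."""
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=n) / math.sqrt(n)


def flip_rois(v: np.ndarray, rois) -> np.ndarray:
    """Sign-flip the listed ROI entries (exactly norm preserving)."""
    out = np.asarray(v, dtype=float).copy()
    out[np.asarray(rois, dtype=int)] *= -1.0
    return out


def make_block_inputs(
    p: int, T: int, n_events: int, duration: int, amplitude: float,
    seed: int | None = None,
) -> np.ndarray:
    """Stimulus-like sustained drivers: ``n_events`` boxcar events of
    ``duration`` samples at ``+-amplitude``, random onsets/channels.

    Unlike the white impulses of :func:`make_sparse_inputs`, sustained
    inputs are autocorrelated and therefore correlate with the lagged state
    — the regime in which unaccounted inputs genuinely bias one-step
    least-squares estimation of A.
    """
    if duration < 1 or n_events < 1:
        raise DomainError("duration and n_events must be >= 1")
    if duration > T:
        raise DomainError("duration exceeds run length")
    rng = np.random.default_rng(seed)
    U = np.zeros((p, T))
    for _ in range(n_events):
        j = int(rng.integers(p))
        k0 = int(rng.integers(T - duration + 1))
        U[j, k0 : k0 + duration] += amplitude * float(rng.choice([-1.0, 1.0]))
    return U


def planted_input_profiles(
    n: int = 30,
    n_subjects: int = 15,
    planted_rois=range(10),
    subject_sd: float = 0.05,
    secondary_sd: float = 0.25,
    shifted_state: str = "deep",
    states=("awake", "light", "deep", "recovery"),
    shift: bool = True,
    seed: int | None = 0,
) -> tuple[dict[str, list[np.ndarray]], np.ndarray]:
    """Per-subject input spatial maps with a planted state-specific change.

    Emulates the population structure the input-pattern statistics consume:
    every subject carries one dominant stimulus-locked map ``w1`` (tight
    across subjects, ``subject_sd``) plus two shared secondary
    co-activation patterns ``w2, w3`` with higher inter-subject variability
    (``secondary_sd``).  The variability asymmetry is what makes ``w1`` the
    unambiguous leading principal component (unit-norm columns split their
    energy between pattern and noise, so noisier patterns carry less
    second-moment weight), and the secondary patterns anchor the
    cross-state component matching.  In the shifted state ``w1`` is sign
    flipped on the planted ROIs — ``w1`` is a Rademacher pattern, so each
    planted ROI moves by exactly ``2/sqrt(n)`` and the flip preserves the
    unit norm (untouched ROIs are bit-identical under the unit-column
    gauge).

    Returns ``(maps_by_state, planted_mask)``; feed the maps to
    :func:`neuromodes.input_patterns.profiles_from_maps`.
    """
    rng = np.random.default_rng(seed)
    w1 = rademacher_map(n, seed=int(rng.integers(2**31)))
    planted = np.zeros(n, dtype=bool)
    planted[np.asarray(list(planted_rois), dtype=int)] = True
    # the flipped map is w1 - 2 d with d = w1 restricted to the planted ROIs;
    # secondary patterns are orthogonalised against BOTH w1 and d so they
    # stay orthogonal to the dominant map in every state (otherwise an
    # unlucky overlap with d mixes them into the shifted state's leading
    # component and corrupts the cross-state match)
    d = np.where(planted, w1, 0.0)
    basis = [w1]
    if shift:
        b2 = d - (d @ w1) * w1
        basis.append(b2 / np.linalg.norm(b2))
    secondary = []
    for _ in range(2):
        w = rng.standard_normal(n)
        for b in basis + secondary:
            w = w - (w @ b) * b
        w /= np.linalg.norm(w)
        secondary.append(w)
    w2, w3 = secondary
    maps: dict[str, list[np.ndarray]] = {}
    for st in states:
        w1_st = flip_rois(w1, np.nonzero(planted)[0]) if (shift and st == shifted_state) else w1
        subj = []
        for _ in range(n_subjects):
            cols = [
                w1_st + subject_sd * rng.standard_normal(n),
                w2 + secondary_sd * rng.standard_normal(n),
                w3 + secondary_sd * rng.standard_normal(n),
            ]
            subj.append(np.column_stack(cols))
        maps[st] = subj
    return maps, planted


# Demo/study-scale default conditions -------------------------------------

DEFAULT_STATES = ("awake", "light", "deep", "recovery")


def demo_cohort(
    n_blocks: int = 5,
    block_size: int = 6,
    n_subjects: int = 8,
    T_rest: int = 255,
    T_task: int = 154,
    noise_sd: float = 0.1,
    p: int = 3,
    density: float = 0.05,
    amplitude: float = 1.0,
    stability_shift: float = 0.15,
    shifted_block: int = 2,
    input_flip_rois: int = 10,
    seed: int | None = 0,
) -> SyntheticCohort:
    """The standard desk-scale study emulation (n = 30 ROIs).

    Plants two effects for the pipeline to find:

    * a ``-stability_shift`` eigenvalue-magnitude reduction in the deep
      state, confined to one eigenvector block (mode stabilisation under
      deep sedation is the harder-damped direction of the shift);
    * a sign flip of the leading input spatial-map column on the first
      ``input_flip_rois`` ROIs in the deep state (state-dependent stimulus
      propagation), exactly norm preserving.
    """
    ss = np.random.SeedSequence(seed)
    s_sys, s_b = ss.spawn(2)
    base, block_of_spec = make_modular_system(n_blocks, block_size, seed=s_sys)
    n = base.n
    pert: dict[str, dict[int, tuple[float, float]]] = {st: {} for st in DEFAULT_STATES}
    for idx in np.nonzero(block_of_spec == shifted_block)[0]:
        pert["deep"][int(idx)] = (-stability_shift, 0.0)
    rng_b = np.random.default_rng(s_b)
    B = rng_b.standard_normal((n, p))
    B /= np.linalg.norm(B, axis=0, keepdims=True)
    B[:, 0] = rademacher_map(n, seed=np.random.default_rng(s_b).integers(2**31))
    B_deep = B.copy()
    B_deep[:, 0] = flip_rois(B[:, 0], np.arange(input_flip_rois))
    cfg = InputConfig(p=p, density=density, amplitude=amplitude, B=B, B_by_state={"deep": B_deep})
    cohort = make_state_ensemble(
        base, pert, n_subjects, T_rest=T_rest, T_task=T_task,
        noise_sd=noise_sd, input_config=cfg, seed=seed,
    )
    cohort.metadata.update(
        base_system=base,
        block_of_spec=block_of_spec,
        shifted_block=shifted_block,
        planted_rois=list(range(input_flip_rois)),
        stability_shift=stability_shift,
    )
    return cohort
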