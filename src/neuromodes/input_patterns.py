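"""State-wise PCA of estimated input spatial maps and per-ROI state tests.

For each condition group (consciousness state) the unit-norm columns of
every subject's estimated input matrix B are concatenated and decomposed
by PCA over the ROI dimension.  Components are matched one-to-one across
states by Hungarian assignment on absolute Pearson correlation (with sign
alignment).  For a matched component, each subject contributes the single
B column with the highest absolute PC loading (negative-loading columns
are sign flipped), and a per-ROI one-way ANOVA with BH-FDR across ROIs
flags regions whose group means differ across states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .cluster_stats import fdr_correct
from .errors import DataError, DimensionError, DomainError
from .sysid import EstimationResult

__all__ = [
    "InputProfileSet",
    "StatePCA",
    "ComponentMatch",
    "ComponentReport",
    "profiles_from_results",
    "pca_per_state",
    "match_components_across_states",
    "select_max_loading_inputs",
    "roi_state_anova",
    "component_state_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InputProfileSet:
    """Concatenated per-subject B columns for every state.

    ``by_state[state]`` is ``n x (N * p)`` with unit-norm columns;
    ``subject_of_col[state]`` maps each column to its subject index.
    """

    by_state: dict[str, np.ndarray]
    subject_of_col: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = None
        for st, M in self.by_state.items():
            M = np.asarray(M, dtype=float)
            if n is None:
                n = M.shape[0]
            elif M.shape[0] != n:
                raise DimensionError("states disagree on ROI count")
            if M.shape[1] != self.subject_of_col[st].shape[0]:
                raise DimensionError(f"column/subject bookkeeping mismatch in state {st!r}")

    @property
    def states(self) -> list[str]:
        return list(self.by_state.keys())

    @property
    def n(self) -> int:
        return next(iter(self.by_state.values())).shape[0]

    def n_subjects(self, state: str) -> int:
        return int(self.subject_of_col[state].max()) + 1


def profiles_from_results(results_by_state: dict[str, list[EstimationResult]]) -> InputProfileSet:
    """Build profiles from fitted models, applying the unit-column gauge."""
    by_state: dict[str, np.ndarray] = {}
    subj: dict[str, np.ndarray] = {}
    for st, results in results_by_state.items():
        cols, owner = [], []
        for i, res in enumerate(results):
            B = res.normalized().model.B
            cols.append(B)
            owner.extend([i] * B.shape[1])
        by_state[st] = np.hstack(cols)
        subj[st] = np.asarray(owner, dtype=int)
    return InputProfileSet(by_state=by_state, subject_of_col=subj)


def profiles_from_maps(maps_by_state: dict[str, list[np.ndarray]]) -> InputProfileSet:
    """Build profiles from raw per-subject ``n x p`` maps (unit-normalised)."""
    by_state: dict[str, np.ndarray] = {}
    subj: dict[str, np.ndarray] = {}
    for st, maps in maps_by_state.items():
        cols, owner = [], []
        for i, B in enumerate(maps):
            B = np.asarray(B, dtype=float)
            norms = np.linalg.norm(B, axis=0, keepdims=True)
            cols.append(B / np.where(norms > 1e-12, norms, 1.0))
            owner.extend([i] * B.shape[1])
        by_state[st] = np.hstack(cols)
        subj[st] = np.asarray(owner, dtype=int)
    return InputProfileSet(by_state=by_state, subject_of_col=subj)


@dataclass(frozen=True)
class StatePCA:
    """PCA of one state's concatenated profiles over the ROI dimension."""

    state: str
    components: np.ndarray  # (n_components, n), sign-canonicalised
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_columns, n_components)
    mean: np.ndarray


def _canonical_sign(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-|entry| coordinate positive."""
    comps = components.copy()
    sc = scores.copy()
    for i, w in enumerate(comps):
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            comps[i] = -w
            sc[:, i] = -sc[:, i]
    return comps, sc


def pca_per_state(profiles: InputProfileSet, n_components: int = 10) -> dict[str, StatePCA]:
    """Per-state PCA of the concatenated B columns over the ROI dimension.

    The decomposition is *uncentred* (SVD of the column matrix, i.e.
    principal axes of the second moment): the unit-column gauge only fixes
    each input map up to sign, and an uncentred decomposition is exactly
    invariant under flipping any column, which the downstream sign-flip
    selection rule then absorbs.  Deterministic up to the sign
    canonicalisation applied here.
    """
    out: dict[str, StatePCA] = {}
    for st, M in profiles.by_state.items():
        cols = M.shape[1]
        if cols < 2:
            raise DomainError(f"state {st!r} has {cols} columns; need >= 2 for PCA")
        ncomp = min(n_components, cols, M.shape[0])
        if ncomp < n_components:
            raise DomainError(
                f"state {st!r} supports only {ncomp} components, {n_components} requested"
            )
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        comps = U[:, :ncomp].T
        scores = M.T @ comps.T
        comps, scores = _canonical_sign(comps, scores)
        out[st] = StatePCA(
            state=st, components=comps,
            explained_variance_ratio=(s**2 / (s**2).sum())[:ncomp],
            scores=scores, mean=np.zeros(M.shape[0]),
        )
    return out


@dataclass(frozen=True)
class ComponentMatch:
    """Cross-state component correspondence (reference state's indexing)."""

    reference_state: str
    index_map: dict[str, np.ndarray]  # state -> component index per reference component
    sign_map: dict[str, np.ndarray]  # state -> +-1 per reference component
    correlations: dict[str, np.ndarray]

    def component(self, pcas: dict[str, StatePCA], state: str, ref_component: int) -> np.ndarray:
        idx = int(self.index_map[state][ref_component])
        return self.sign_map[state][ref_component] * pcas[state].components[idx]


def match_components_across_states(
    pcas: dict[str, StatePCA], reference_state: str
) -> ComponentMatch:
    """One-to-one matching of components to the reference state's by maximal
    |Pearson correlation| (Hungarian assignment), with sign alignment."""
    if reference_state not in pcas:
        raise DataError(f"reference state {reference_state!r} not present")
    ref = pcas[reference_state].components
    index_map: dict[str, np.ndarray] = {}
    sign_map: dict[str, np.ndarray] = {}
    corrs: dict[str, np.ndarray] = {}
    for st, sp in pcas.items():
        cur = sp.components
        if cur.shape[1] != ref.shape[1]:
            raise DimensionError("states disagree on ROI count")
        k = min(ref.shape[0], cur.shape[0])
        C = np.corrcoef(ref[:k], cur[:k])[:k, k:]
        rows, cols = linear_sum_assignment(-np.abs(C))
        idx = np.empty(k, dtype=int)
        idx[rows] = cols
        signs = np.sign(C[np.arange(k), idx])
        signs[signs == 0] = 1.0
        index_map[st] = idx
        sign_map[st] = signs
        corrs[st] = np.abs(C[np.arange(k), idx])
    return ComponentMatch(
        reference_state=reference_state, index_map=index_map,
        sign_map=sign_map, correlations=corrs,
    )


def select_max_loading_inputs(
    profiles: InputProfileSet,
    pcas: dict[str, StatePCA],
    state: str,
    component_idx: int,
) -> np.ndarray:
    """Per subject, the B column with the highest |PC loading|, sign flipped
    when the loading is negative.  Ties break to the lowest column index
    (logged).  Returns an ``(N, n)`` array."""
    M = profiles.by_state[state]
    owner = profiles.subject_of_col[state]
    scores = pcas[state].scores[:, component_idx]
    n_subj = profiles.n_subjects(state)
    out = np.empty((n_subj, profiles.n))
    for s in range(n_subj):
        cols = np.nonzero(owner == s)[0]
        if cols.size == 0:
            raise DataError(f"subject {s} has no columns in state {state!r}")
        mag = np.abs(scores[cols])
        best = cols[int(np.argmax(mag))]  # argmax returns the first maximum
        if np.sum(mag == mag.max()) > 1:
            logger.warning(
                "loading tie for subject %d in state %s; lowest column index wins", s, state
            )
        v = M[:, best]
        out[s] = -v if scores[best] < 0 else v
    return out


def roi_state_anova(
    selected_by_state: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-ROI one-way ANOVA across states with BH-FDR across ROIs.

    ``selected_by_state[state]`` is ``(N_state, n)``.  Returns the per-ROI
    table (F, p, q, significant) and the per-state group-average vectors.
    """
    states = list(selected_by_state.keys())
    if len(states) < 2:
        raise DomainError("need >= 2 states")
    mats = [np.atleast_2d(np.asarray(selected_by_state[st], dtype=float)) for st in states]
    n = mats[0].shape[1]
    for M in mats:
        if M.shape[1] != n:
            raise DimensionError("states disagree on ROI count")
        if M.shape[0] < 2:
            raise DataError("each state needs >= 2 subjects for the ANOVA")
    F = np.empty(n)
    p = np.empty(n)
    for roi in range(n):
        groups = [M[:, roi] for M in mats]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            F[roi], p[roi] = np.nan, 1.0
        else:
            F[roi], p[roi] = stats.f_oneway(*groups)
    p = np.nan_to_num(p, nan=1.0)
    reject, q = fdr_correct(p, alpha=alpha)
    table = pd.DataFrame(
        {
            "roi": np.arange(n),
            "F": F,
            "p": p,
            "q": q,
            "significant": reject.astype(int),
        }
    )
    means = {st: M.mean(axis=0) for st, M in zip(states, mats)}
    return table, means


@dataclass(frozen=True)
class ComponentReport:
    """Everything derived from one matched component."""

    reference_state: str
    component: int
    match: ComponentMatch
    selected_by_state: dict[str, np.ndarray]
    anova: pd.DataFrame
    group_means: dict[str, np.ndarray] = field(default_factory=dict)


def component_state_report(
    profiles: InputProfileSet,
    reference_state: str,
    component_idx: int,
    n_components: int = 10,
    alpha: float = 0.05,
    pcas: dict[str, StatePCA] | None = None,
    match: ComponentMatch | None = None,
) -> ComponentReport:
    """Full per-component pipeline: PCA -> cross-state match -> per-subject
    selection -> per-ROI ANOVA."""
    if pcas is None:
        pcas = pca_per_state(profiles, n_components=n_components)
    if match is None:
        match = match_components_across_states(pcas, reference_state)
    selected: dict[str, np.ndarray] = {}
    for st in profiles.states:
        idx = int(match.index_map[st][component_idx])
        vecs = select_max_loading_inputs(profiles, pcas, st, idx)
        selected[st] = match.sign_map[st][component_idx] * vecs
    anova, means = roi_state_anova(selected, alpha=alpha)
    return ComponentReport(
        reference_state=reference_state, component=component_idx, match=match,
        selected_by_state=selected, anova=anova, group_means=means,
    )
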