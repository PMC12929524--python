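"""Repeated k-means over eigenvector profiles with state-effect statistics.

Eigenmodes from all condition groups (consciousness states) are pooled and
clustered by the elementwise magnitude of their unit-norm eigenvectors — a
sign/phase-gauge-invariant real feature under which a conjugate pair maps
to the same point.  k-means is repeated many times; each run's centroids
are aligned to a reference run (the first) by the Hungarian algorithm on a
negated-Pearson-correlation cost, resolving label switching.  Per cluster
and iteration, one-way ANOVA tests whether eigenvalue stability and
frequency differ across states; Benjamini-Hochberg FDR is applied across
all iterations and clusters per (k, measure), and the percentage of
iterations that remain significant is reported as a reliability proxy,
together with centroid-consistency metrics (PC1 variance of matched
centroids, centroid-reference correlations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from statsmodels.stats.multitest import multipletests

from .eigenmodes import Eigenmode
from .errors import DataError, DimensionError, DomainError

__all__ = [
    "ClusterRun",
    "StateEffectReport",
    "mode_features",
    "run_kmeans",
    "match_centroids",
    "state_anova",
    "fdr_correct",
    "repeated_cluster_anova",
    "cluster_quality",
]


@dataclass(frozen=True)
class ClusterRun:
    k: int
    centroids: np.ndarray  # (k, n)
    labels: np.ndarray  # one label in 0..k-1 per mode
    iteration_index: int
    seed: int


@dataclass(frozen=True)
class StateEffectReport:
    """Per (k, cluster, measure) significance rates and reliability metrics."""

    summary: pd.DataFrame
    k_values: tuple[int, ...]
    n_iterations: int
    alpha: float
    reference_centroids: dict[int, np.ndarray] = field(default_factory=dict)
    n_skipped: dict[int, int] = field(default_factory=dict)


def mode_features(modes: list[Eigenmode]) -> tuple[np.ndarray, np.ndarray]:
    """One row per mode: |v| of its unit-norm eigenvector.

    Returns ``(features, state_labels)``; rows are nonnegative and unit
    Euclidean norm, and conjugate-pair modes yield identical rows.
    """
    if not modes:
        raise DataError("no modes given")
    n = modes[0].eigenvector.shape[0]
    for m in modes:
        if m.eigenvector.shape[0] != n:
            raise DimensionError("modes disagree on ROI count")
    F = np.abs(np.stack([m.eigenvector for m in modes]))
    states = np.asarray([m.state_label for m in modes])
    return F, states


def run_kmeans(features: np.ndarray, k: int, seed: int, iteration_index: int = 0) -> ClusterRun:
    """One k-means solution (squared-Euclidean, k-means++ seeding)."""
    features = np.asarray(features, dtype=float)
    if k < 2:
        raise DomainError("k must be >= 2")
    if k > features.shape[0]:
        raise DomainError(f"k={k} exceeds number of modes {features.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=int(seed))
    labels = km.fit_predict(features)
    return ClusterRun(
        k=k, centroids=km.cluster_centers_, labels=labels,
        iteration_index=iteration_index, seed=int(seed),
    )


def _safe_centroid_corr(current: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix ref x cur; constant rows correlate 0."""
    ref = reference - reference.mean(axis=1, keepdims=True)
    cur = current - current.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(ref, axis=1)
    cn = np.linalg.norm(cur, axis=1)
    ref_bad = rn < 1e-12
    cur_bad = cn < 1e-12
    if np.any(ref_bad) or np.any(cur_bad):
        warnings.warn("constant centroid row; correlation treated as 0", RuntimeWarning)
    C = (ref / np.where(ref_bad, 1.0, rn)[:, None]) @ (cur / np.where(cur_bad, 1.0, cn)[:, None]).T
    C[ref_bad, :] = 0.0
    C[:, cur_bad] = 0.0
    return C


def match_centroids(current: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal one-to-one alignment of centroids to a reference set.

    Returns ``perm`` with ``perm[i]`` the row of ``current`` assigned to
    reference row ``i``, maximising the total Pearson correlation of
    matched pairs (Hungarian algorithm on the negated correlations).
    """
    current = np.asarray(current, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if current.shape != reference.shape:
        raise DimensionError(f"centroid shapes differ: {current.shape} vs {reference.shape}")
    C = _safe_centroid_corr(current, reference)
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(current.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def state_anova(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """One-way fixed-effects ANOVA across condition groups.

    Returns ``(F, p, cohens_f)`` with Cohen's f = sqrt(eta2 / (1 - eta2)),
    eta2 = SS_between / SS_total.  Identically constant data (SS_total = 0)
    is the degenerate convention ``(nan, 1, 0)`` — flagged non-significant.
    """
    if len(groups) < 2:
        raise DomainError("need >= 2 groups")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in groups:
        if g.size < 2:
            raise DataError("each group needs >= 2 samples")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0.0:
        return float("nan"), 1.0, 0.0
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    F, p = stats.f_oneway(*groups)
    eta2 = min(ss_between / ss_total, 1.0 - 1e-15)
    cohens_f = float(np.sqrt(eta2 / (1.0 - eta2)))
    return float(F), float(p), cohens_f


def fdr_correct(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (reject decisions, q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def repeated_cluster_anova(
    modes_by_state: dict[str, list[Eigenmode]],
    k_values,
    n_iterations: int,
    alpha: float = 0.05,
    seed: int | None = 0,
    min_per_state: int = 2,
    conjugate_pairs_as_one: bool = True,
) -> StateEffectReport:
    """The composite repeated-clustering state-effect procedure.

    For each k and iteration: k-means on the pooled eigenvector-magnitude
    features; Hungarian matching to the first iteration's centroids; per
    matched cluster, ANOVA of stability and of frequency across states.
    BH-FDR is applied across all iterations x clusters per (k, measure).
    A cluster-iteration with fewer than ``min_per_state`` modes from some
    state is skipped (counted, never imputed).

    With ``conjugate_pairs_as_one`` (default) each conjugate pair enters
    the ANOVA as a single observation: the twins share stability and
    frequency exactly, and counting both would double every group size
    without adding information, inflating F statistics and breaking the
    test's null calibration.  Clustering itself always uses all modes.
    """
    if n_iterations < 1:
        raise DomainError("n_iterations must be >= 1")
    states = list(modes_by_state.keys())
    if len(states) < 2:
        raise DomainError("need >= 2 states")
    pooled: list[Eigenmode] = [m for st in states for m in modes_by_state[st]]
    F, state_arr = mode_features(pooled)
    stab = np.asarray([m.stability_per_s for m in pooled])
    freq = np.asarray([m.frequency_hz for m in pooled])
    measures = {"stability": stab, "frequency": freq}
    if conjugate_pairs_as_one:
        anova_keep = np.asarray([m.eigenvalue.imag >= 0 for m in pooled])
    else:
        anova_keep = np.ones(len(pooled), dtype=bool)
    ss = np.random.SeedSequence(seed)
    rows = []
    ref_centroids: dict[int, np.ndarray] = {}
    n_skipped: dict[int, int] = {}
    for k in k_values:
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_iterations)]
        ref = run_kmeans(F, k, seeds[0], iteration_index=0)
        ref_centroids[k] = ref.centroids
        # per measure: lists of (iteration, cluster, F, p, cohens_f)
        tests: dict[str, list[tuple[int, int, float, float, float]]] = {m: [] for m in measures}
        centroid_stacks: list[list[np.ndarray]] = [[] for _ in range(k)]
        ref_corrs: list[list[float]] = [[] for _ in range(k)]
        skipped = 0
        for it in range(n_iterations):
            run = ref if it == 0 else run_kmeans(F, k, seeds[it], iteration_index=it)
            perm = match_centroids(run.centroids, ref.centroids)
            centroids = run.centroids[perm]
            relabel = np.empty(k, dtype=int)
            relabel[perm] = np.arange(k)
            labels = relabel[run.labels]
            corr = _safe_centroid_corr(centroids, ref.centroids)
            for c in range(k):
                centroid_stacks[c].append(centroids[c])
                ref_corrs[c].append(float(corr[c, c]))
                members = (labels == c) & anova_keep
                groups_ok = True
                gidx = []
                for st in states:
                    sel = members & (state_arr == st)
                    if sel.sum() < min_per_state:
                        groups_ok = False
                        break
                    gidx.append(sel)
                if not groups_ok:
                    skipped += 1
                    continue
                for mname, vals in measures.items():
                    f_stat, p_val, coh = state_anova([vals[g] for g in gidx])
                    if np.isnan(f_stat):
                        p_val, coh = 1.0, 0.0
                    tests[mname].append((it, c, f_stat, p_val, coh))
        n_skipped[k] = skipped
        for mname, recs in tests.items():
            if not recs:
                continue
            pvals = np.asarray([r[3] for r in recs])
            reject, qvals = fdr_correct(pvals, alpha=alpha)
            per_cluster: dict[int, dict] = {}
            for (it, c, f_stat, p_val, coh), rej, q in zip(recs, reject, qvals):
                d = per_cluster.setdefault(
                    c, {"n": 0, "n_sig": 0, "F": [], "p": [], "q": [], "coh": []}
                )
                d["n"] += 1
                d["n_sig"] += int(rej)
                d["F"].append(f_stat)
                d["p"].append(p_val)
                d["q"].append(q)
                d["coh"].append(coh)
            for c, d in sorted(per_cluster.items()):
                stack = np.asarray(centroid_stacks[c])
                pc1 = _pc1_variance_pct(stack)
                rc = np.asarray(ref_corrs[c])
                rows.append(
                    {
                        "k": k,
                        "cluster": c,
                        "measure": mname,
                        "n_tested": d["n"],
                        "significance_rate": 100.0 * d["n_sig"] / d["n"],
                        "mean_F": float(np.nanmean(d["F"]))
                        if np.any(np.isfinite(d["F"])) else float("nan"),
                        "median_p": float(np.median(d["p"])),
                        "median_q": float(np.median(d["q"])),
                        "mean_cohens_f": float(np.mean(d["coh"])),
                        "pc1_variance_pct": pc1,
                        "ref_corr_mean": float(rc.mean()),
                        "ref_corr_std": float(rc.std()),
                    }
                )
    summary = pd.DataFrame(rows)
    return StateEffectReport(
        summary=summary,
        k_values=tuple(k_values),
        n_iterations=n_iterations,
        alpha=alpha,
        reference_centroids=ref_centroids,
        n_skipped=n_skipped,
    )


def _pc1_variance_pct(stack: np.ndarray) -> float:
    """Percent variance of the first principal component of matched
    centroids; 100 when centroids never vary across iterations."""
    X = stack - stack.mean(axis=0, keepdims=True)
    tot = float((X * X).sum())
    if tot < 1e-24:
        return 100.0
    s = np.linalg.svd(X, compute_uv=False)
    return float(100.0 * s[0] ** 2 / (s**2).sum())


def cluster_quality(features: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Diagnostic-only cluster-quality indices (no single optimum exists
    for eigenvector clusters; reported for completeness)."""
    return {
        "calinski_harabasz": float(calinski_harabasz_score(features, labels)),
        "davies_bouldin": float(davies_bouldin_score(features, labels)),
        "silhouette": float(silhouette_score(features, labels)),
    }
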