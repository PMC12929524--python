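"""Reproducible study-condition experiments on synthetic cohorts.

Each function generates its inputs from the package's own synthetic-data
generator at the default study conditions, runs one stage of the method,
and measures recovery or calibration against the planted ground truth.
They back both the validation test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import subspace_angles
from scipy.stats import binomtest

from .cluster_stats import repeated_cluster_anova
from .eigenmodes import Eigenmode, decompose
from .input_patterns import component_state_report, profiles_from_maps
from .sysid import (
    estimate_A_group,
    estimate_A_onestep,
    estimate_inputs,
    fit_unknown_inputs,
    input_support,
)
from .synthetic import (
    make_block_inputs,
    make_modular_system,
    make_sparse_inputs,
    make_stable_system,
    make_state_ensemble,
    planted_input_profiles,
    simulate_run,
)

__all__ = [
    "random_stable_spec",
    "eigenmode_closed_form_check",
    "a_recovery_noisefree",
    "group_vs_single_recovery",
    "unaccounted_input_bias",
    "input_recovery",
    "modular_state_modes",
    "cluster_null_calibration",
    "cluster_power",
    "input_pattern_power",
]

STATES = ("awake", "light", "deep", "recovery")


def random_stable_spec(n: int, rng: np.random.Generator,
                       mag_range=(0.8, 0.96), ang_range=(0.15, 2.9)):
    """Distinct, well-separated conjugate-pair eigenvalues (identifiable
    from a single trajectory; near-degenerate eigenvalues are not)."""
    pairs = n // 2
    mags = np.sort(rng.uniform(*mag_range, pairs))
    angs = np.linspace(*ang_range, pairs) + rng.uniform(-0.04, 0.04, pairs)
    spec = [(float(m), float(a), 1) for m, a in zip(mags, angs)]
    if n % 2:
        spec.append((float(rng.uniform(*mag_range)), 0.0, 1))
    return spec


def eigenmode_closed_form_check(n_eigenvalues: int = 1000, dt: float = 2.0,
                                seed: int = 0) -> dict:
    """Frequency/stability of random eigenvalues vs independent evaluation
    of the polar closed forms; plus the quarter-turn rotation case."""
    rng = np.random.default_rng(seed)
    max_f_err = 0.0
    max_s_err = 0.0
    n_pairs = (n_eigenvalues + 1) // 2
    for _ in range(n_pairs):
        r = float(rng.uniform(0.2, 1.1))
        th = float(rng.uniform(1e-3, math.pi - 1e-3))
        c, s = r * math.cos(th), r * math.sin(th)
        A = np.array([[c, -s], [s, c]])
        for m in decompose(A, dt):
            # closed forms evaluated directly from the raw eigenvalue
            lam = m.eigenvalue
            f_ref = abs(np.angle(lam)) / (2.0 * math.pi * dt)
            s_ref = math.log(abs(lam)) / dt
            max_f_err = max(max_f_err, abs(m.frequency_hz - f_ref))
            max_s_err = max(max_s_err, abs(m.stability_per_s - s_ref))
            # and against the planted polar parameters
            max_f_err = max(max_f_err, abs(m.frequency_hz - th / (2 * math.pi * dt)))
            max_s_err = max(max_s_err, abs(m.stability_per_s - math.log(r) / dt))
    rot = np.array([[math.cos(math.pi / 4), -math.sin(math.pi / 4)],
                    [math.sin(math.pi / 4), math.cos(math.pi / 4)]])
    rot_f = decompose(rot, dt)[0].frequency_hz
    return {
        "max_frequency_err": max_f_err,
        "max_stability_err": max_s_err,
        "rotation_quarter_pi_frequency_hz": rot_f,
        "n_eigenvalues": 2 * n_pairs,
    }


def a_recovery_noisefree(n: int = 20, T: int = 500, n_subjects: int = 3,
                         seed: int = 0) -> float:
    """Frobenius error of the one-step estimator on a noise-free,
    input-free cohort."""
    rng = np.random.default_rng(seed)
    sys_ = make_stable_system(n, random_stable_spec(n, rng), seed=int(rng.integers(2**31)))
    panels = [
        simulate_run(sys_, T, noise_sd=0.0, x0=rng.standard_normal(n))
        for _ in range(n_subjects)
    ]
    A_hat = estimate_A_group(panels, objective="onestep")
    return float(np.linalg.norm(A_hat - sys_.A_true))


def group_vs_single_recovery(n: int = 20, T: int = 255, n_subjects: int = 10,
                             noise_sd: float = 0.1, n_replicates: int = 20,
                             seed: int = 0) -> dict:
    """Does pooled group estimation beat the median single-subject error?"""
    ss = np.random.SeedSequence(seed)
    wins = 0
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        sys_ = make_stable_system(n, random_stable_spec(n, rng),
                                  seed=int(rng.integers(2**31)))
        panels = [
            simulate_run(sys_, T, noise_sd=noise_sd, seed=int(rng.integers(2**31)))
            for _ in range(n_subjects)
        ]
        singles = [np.linalg.norm(estimate_A_onestep(p) - sys_.A_true) for p in panels]
        group = np.linalg.norm(estimate_A_group(panels, objective="onestep") - sys_.A_true)
        wins += int(group < np.median(singles))
    return {"wins": wins, "n_replicates": n_replicates}


def unaccounted_input_bias(n: int = 20, T: int = 154, p: int = 3,
                           n_subjects: int = 8, density: float = 0.05,
                           amplitude: float = 1.0, duration: int = 5,
                           noise_sd: float = 0.1,
                           n_replicates: int = 20, seed: int = 0) -> dict:
    """A estimated from stimulus runs with unmodelled planted inputs vs
    from matched resting runs: error difference and one-sided sign test.

    A is fitted at group level (pooled over subjects, the study setting)
    and the planted drivers are sustained boxcar events: temporally
    autocorrelated inputs correlate with the lagged state and genuinely
    bias the one-step estimator (white impulses mostly just add excitation).
    """
    ss = np.random.SeedSequence(seed)
    worse = 0
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        sys_ = make_stable_system(n, random_stable_spec(n, rng),
                                  seed=int(rng.integers(2**31)))
        B = rng.standard_normal((n, p))
        B /= np.linalg.norm(B, axis=0)
        rest_panels, task_panels = [], []
        n_events = max(1, int(round(density * p * T / duration)))
        for _ in range(n_subjects):
            U = make_block_inputs(p, T, n_events, duration, amplitude,
                                  seed=int(rng.integers(2**31)))
            rest_panels.append(
                simulate_run(sys_, T, noise_sd=noise_sd, seed=int(rng.integers(2**31)))
            )
            task_panels.append(
                simulate_run(sys_, T, B_true=B, U=U, noise_sd=noise_sd,
                             seed=int(rng.integers(2**31)))
            )
        e_rest = np.linalg.norm(
            estimate_A_group(rest_panels, objective="onestep") - sys_.A_true
        )
        e_task = np.linalg.norm(
            estimate_A_group(task_panels, objective="onestep") - sys_.A_true
        )
        worse += int(e_task > e_rest)
    pval = binomtest(worse, n_replicates, 0.5, alternative="greater").pvalue
    return {"n_task_worse": worse, "n_replicates": n_replicates, "sign_test_p": float(pval)}


def input_recovery(n: int = 30, p: int = 3, T: int = 154, n_subjects: int = 8,
                   density: float = 0.05, amplitude: float = 1.0,
                   noise_sd: float = 0.02, reg_weight: float = 0.5,
                   seed: int = 0) -> dict:
    """Sparse-input support recovery with the true model given, and
    input-subspace recovery by the full alternating fit."""
    rng = np.random.default_rng(seed)
    sys_ = make_stable_system(n, random_stable_spec(n, rng), seed=int(rng.integers(2**31)))
    B = rng.standard_normal((n, p))
    B /= np.linalg.norm(B, axis=0)
    panels, U_true = [], []
    for _ in range(n_subjects):
        U = make_sparse_inputs(p, T, density, amplitude, seed=int(rng.integers(2**31)))
        U_true.append(U)
        panels.append(simulate_run(sys_, T, B_true=B, U=U, noise_sd=noise_sd,
                                   seed=int(rng.integers(2**31))))
    # (i) support recovery, true A and B given
    tp = fp = fn = 0
    for panel, U in zip(panels[:3], U_true[:3]):
        U_hat, _ = estimate_inputs(panel, sys_.A_true, B, reg_weight)
        est = input_support(U_hat)
        tru = U != 0
        tp += int((est & tru).sum())
        fp += int((est & ~tru).sum())
        fn += int((~est & tru).sum())
    f1 = 2 * tp / (2 * tp + fp + fn)
    # (ii) full alternating fit, B unknown
    res = fit_unknown_inputs(panels, sys_.A_true, p=p, reg_weight=reg_weight,
                             seed=int(rng.integers(2**31)))
    angle = float(np.degrees(subspace_angles(res.model.B, B).max()))
    trace = np.asarray(res.objective_trace)
    return {
        "support_f1": float(f1),
        "principal_angle_deg": angle,
        "trace_nonincreasing": bool(np.all(np.diff(trace) <= 0)),
    }


def modular_state_modes(seed: int, stability_shift: float = 0.0,
                        n_subjects: int = 8, T_rest: int = 255,
                        noise_sd: float = 0.1,
                        shifted_block: int = 2) -> tuple[dict[str, list[Eigenmode]], int]:
    """Fitted per-state eigenmodes of a modular cohort with an optional
    planted deep-state stability reduction in one eigenvector block."""
    ss = np.random.SeedSequence(seed)
    base, block_of_spec = make_modular_system(seed=ss.spawn(1)[0])
    pert: dict[str, dict[int, tuple[float, float]]] = {st: {} for st in STATES}
    if stability_shift:
        for idx in np.nonzero(block_of_spec == shifted_block)[0]:
            pert["deep"][int(idx)] = (-stability_shift, 0.0)
    cohort = make_state_ensemble(base, pert, n_subjects, T_rest=T_rest,
                                 noise_sd=noise_sd, seed=seed)
    modes_by_state = {}
    for st in cohort.states:
        A = estimate_A_group([p.zscored() for p in cohort.rest[st]], objective="onestep")
        modes_by_state[st] = decompose(A, base.dt, state_label=st)
    return modes_by_state, shifted_block


def cluster_null_calibration(n_cohorts: int = 4, iterations: int = 50,
                             k_values=(5, 8), alpha: float = 0.05,
                             seed: int = 0) -> dict:
    """Overall percentage of FDR-significant cluster x measure tests on
    cohorts with zero planted state effect, averaged over independent
    cohorts (within one cohort every iteration re-clusters the same fitted
    eigenvalues, so independent cohorts carry the calibration information)."""
    ss = np.random.SeedSequence(seed)
    fractions = []
    for child in ss.spawn(n_cohorts):
        sub_seed = int(child.generate_state(1)[0] % 2**31)
        modes_by_state, _ = modular_state_modes(sub_seed, stability_shift=0.0)
        rep = repeated_cluster_anova(modes_by_state, k_values, iterations,
                                     alpha=alpha, seed=sub_seed + 1)
        s = rep.summary
        fractions.append(float((s["significance_rate"] * s["n_tested"]).sum()
                               / s["n_tested"].sum()))
    return {"significant_pct": float(np.mean(fractions)),
            "per_cohort_pct": fractions,
            "n_tests": n_cohorts * iterations}


def cluster_power(iterations: int = 200, stability_shift: float = 0.15,
                  k: int = 5, alpha: float = 0.05, seed: int = 0) -> dict:
    """Significance rates of the planted cluster: stability should light up,
    frequency should stay at the null."""
    modes_by_state, shifted_block = modular_state_modes(seed, stability_shift)
    rep = repeated_cluster_anova(modes_by_state, [k], iterations, alpha=alpha,
                                 seed=seed + 1)
    # the planted cluster = reference centroid supported on the shifted block
    n_block = 6
    ref = rep.reference_centroids[k]
    sl = slice(shifted_block * n_block, (shifted_block + 1) * n_block)
    overlap = ref[:, sl].sum(axis=1) / np.linalg.norm(ref, axis=1)
    planted_cluster = int(np.argmax(overlap))
    s = rep.summary
    sel = (s["k"] == k) & (s["cluster"] == planted_cluster)
    stab = float(s[sel & (s["measure"] == "stability")]["significance_rate"].iloc[0])
    freq = float(s[sel & (s["measure"] == "frequency")]["significance_rate"].iloc[0])
    return {"planted_cluster": planted_cluster,
            "stability_rate_pct": stab, "frequency_rate_pct": freq}


def input_pattern_power(n_replicates: int = 20, n: int = 30, n_subjects: int = 15,
                        n_planted: int = 10, subject_sd: float = 0.05,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Sensitivity and empirical false-discovery proportion of the per-ROI
    state ANOVA on the matched leading component, planted-map cohorts."""
    ss = np.random.SeedSequence(seed)
    sens, fdp = [], []
    for child in ss.spawn(n_replicates):
        maps, planted = planted_input_profiles(
            n=n, n_subjects=n_subjects, planted_rois=range(n_planted),
            subject_sd=subject_sd, seed=int(child.generate_state(1)[0] % 2**31),
        )
        report = component_state_report(profiles_from_maps(maps), "awake", 0,
                                        n_components=3, alpha=alpha)
        sig = report.anova["significant"].to_numpy().astype(bool)
        sens.append((sig & planted).sum() / planted.sum())
        fdp.append((sig & ~planted).sum() / max(int(sig.sum()), 1))
    return {"sensitivity": float(np.mean(sens)),
            "empirical_fdr": float(np.mean(fdp)),
            "n_replicates": n_replicates}
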