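"""Configuration and the end-to-end pipeline driver.

Stage order mirrors the analysis: (optional) simulate a synthetic cohort ->
group A per state from resting runs -> eigenmode decomposition -> repeated
clustering with state-effect ANOVA -> unknown-input estimation on task runs
-> state-wise input PCA with per-ROI ANOVA -> state classification.  Every
artifact is a deterministic TSV/JSON (or versioned npz) stamped with the
config hash and seed; a run log records stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .classify import build_features, train_and_validate
from .cluster_stats import repeated_cluster_anova
from .eigenmodes import decompose, modes_table
from .errors import ConfigError
from .input_patterns import component_state_report, pca_per_state, profiles_from_results
from .input_patterns import match_components_across_states
from .sysid import estimate_A_group, fit_unknown_inputs
from .synthetic import demo_cohort

logger = logging.getLogger("neuromodes.pipeline")

__all__ = [
    "PipelineConfig",
    "SimulateConfig",
    "ModelConfig",
    "StatsConfig",
    "InputPCAConfig",
    "ClassifyConfig",
    "load_config",
    "dump_config",
    "config_hash",
    "run_pipeline",
]


@dataclass(frozen=True)
class SimulateConfig:
    n_blocks: int = 5
    block_size: int = 6
    n_subjects: int = 8
    T_rest: int = 255
    T_task: int = 154
    noise_sd: float = 0.1
    p: int = 3
    density: float = 0.05
    amplitude: float = 1.0
    stability_shift: float = 0.15
    shifted_block: int = 2
    input_flip_rois: int = 10


@dataclass(frozen=True)
class ModelConfig:
    p: int = 10
    reg_weight: float = 0.5
    objective: str = "onestep"  # group-A dialect; 'freerun' also available
    penalty_b: str = "l1"
    tol: float = 1e-6
    max_iter: int = 50
    inner_max_iter: int = 400
    standardize: bool = True
    meta_tol: float = 0.01


@dataclass(frozen=True)
class StatsConfig:
    k_min: int = 3
    k_max: int = 20
    iterations: int = 100_000
    alpha: float = 0.05


@dataclass(frozen=True)
class InputPCAConfig:
    n_components: int = 10
    reference_state: str = "awake"
    alpha: float = 0.05
    classifier_components: int = 4


@dataclass(frozen=True)
class ClassifyConfig:
    folds: int = 5
    variance_target: float = 0.95
    C: float = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "neuromodes_out"
    dt: float = 2.0
    input_manifest: str | None = None
    simulate: SimulateConfig | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    input_pca: InputPCAConfig = field(default_factory=InputPCAConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_manifest is None:
            raise ConfigError("config needs either a 'simulate' section or an 'input_manifest'")
        m = self.model
        if m.objective not in ("onestep", "freerun"):
            raise ConfigError(f"model.objective must be onestep|freerun, got {m.objective!r}")
        if m.penalty_b not in ("l1", "l1_squared", "l21"):
            raise ConfigError(f"model.penalty_b must be l1|l1_squared|l21, got {m.penalty_b!r}")
        if m.reg_weight < 0 or m.p < 1 or m.tol <= 0 or m.max_iter < 1:
            raise ConfigError("invalid model section")
        s = self.stats
        if not (2 <= s.k_min <= s.k_max) or s.iterations < 1 or not (0 < s.alpha < 1):
            raise ConfigError("invalid stats section")
        c = self.classify
        if c.folds < 2 or not (0 < c.variance_target <= 1):
            raise ConfigError("invalid classify section")


_SECTION_TYPES = {
    "simulate": SimulateConfig,
    "model": ModelConfig,
    "stats": StatsConfig,
    "input_pca": InputPCAConfig,
    "classify": ClassifyConfig,
}


def _build_dataclass(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {path!r}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    for key, cls in _SECTION_TYPES.items():
        if key in data and data[key] is not None:
            if not isinstance(data[key], dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            data[key] = _build_dataclass(cls, data[key], key)
    return PipelineConfig(**data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path) -> PipelineConfig:
    """Load a JSON or YAML pipeline configuration, rejecting unknown keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: PipelineConfig, path) -> None:
    nio.dump_json(config_to_dict(cfg), path)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(seed: int = 0, out_dir: str = "neuromodes_demo") -> PipelineConfig:
    """Desk-scale end-to-end configuration (n = 30 ROIs, N = 8 subjects,
    4 states, 200 clustering iterations): every stage runs in minutes on one
    CPU while exercising the identical code paths as a full-scale run."""
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        simulate=SimulateConfig(),
        model=ModelConfig(p=3, reg_weight=0.5, max_iter=15, inner_max_iter=300),
        stats=StatsConfig(k_min=3, k_max=10, iterations=200),
        input_pca=InputPCAConfig(n_components=4),
    )


# ---------------------------------------------------------------------------
# Stages

def _seed_for(cfg: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % 2**31


def stage_simulate(cfg: PipelineConfig, out: Path) -> Path:
    sc = cfg.simulate
    cohort = demo_cohort(
        n_blocks=sc.n_blocks, block_size=sc.block_size, n_subjects=sc.n_subjects,
        T_rest=sc.T_rest, T_task=sc.T_task, noise_sd=sc.noise_sd, p=sc.p,
        density=sc.density, amplitude=sc.amplitude, stability_shift=sc.stability_shift,
        shifted_block=sc.shifted_block, input_flip_rois=sc.input_flip_rois,
        seed=_seed_for(cfg, "simulate"),
    )
    return nio.write_cohort(cohort, out / "cohort")


def stage_fit_a(cfg: PipelineConfig, data: dict, out: Path) -> dict[str, np.ndarray]:
    A_by_state = {}
    for st in data["states"]:
        panels = data["rest"][st]
        if cfg.model.standardize:
            panels = [p.zscored() for p in panels]
        A_by_state[st] = estimate_A_group(panels, objective=cfg.model.objective)
    nio.save_model_archive(out / "models" / "systems.npz", A_by_state)
    nio.dump_json(
        {
            "objective": cfg.model.objective,
            "states": sorted(A_by_state),
            "spectral_radius": {st: float(np.abs(np.linalg.eigvals(A)).max())
                                for st, A in A_by_state.items()},
        },
        out / "models" / "summary.json",
    )
    return A_by_state


def stage_eigenmodes(cfg: PipelineConfig, A_by_state: dict, dt: float, out: Path) -> dict:
    modes_by_state = {
        st: decompose(A, dt, meta_tol=cfg.model.meta_tol, state_label=st)
        for st, A in sorted(A_by_state.items())
    }
    table = modes_table([m for st in sorted(modes_by_state) for m in modes_by_state[st]])
    tdir = out / "modes"
    tdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(tdir / "modes.tsv", sep="\t", index=False, float_format="%.12g")
    return modes_by_state


def stage_cluster_stats(cfg: PipelineConfig, modes_by_state: dict, out: Path):
    report = repeated_cluster_anova(
        modes_by_state,
        k_values=range(cfg.stats.k_min, cfg.stats.k_max + 1),
        n_iterations=cfg.stats.iterations,
        alpha=cfg.stats.alpha,
        seed=_seed_for(cfg, "cluster"),
    )
    cdir = out / "cluster_stats"
    cdir.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(cdir / "state_effects.tsv", sep="\t", index=False, float_format="%.12g")
    nio.dump_json(
        {"k_values": list(report.k_values), "n_iterations": report.n_iterations,
         "alpha": report.alpha, "n_skipped": report.n_skipped},
        cdir / "manifest.json",
    )
    return report


def stage_fit_inputs(cfg: PipelineConfig, data: dict, A_by_state: dict, out: Path) -> dict:
    results_by_state: dict[str, list] = {}
    idir = out / "inputs"
    idir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for st in data["states"]:
        results = []
        for i, panel in enumerate(data["task"][st]):
            run = panel.zscored() if cfg.model.standardize else panel
            res = fit_unknown_inputs(
                [run], A_by_state[st], p=cfg.model.p, reg_weight=cfg.model.reg_weight,
                max_iter=cfg.model.max_iter, tol=cfg.model.tol,
                seed=_seed_for(cfg, f"inputs:{st}:{i}"),
                penalty_b=cfg.model.penalty_b, inner_max_iter=cfg.model.inner_max_iter,
            )
            results.append(res)
        results_by_state[st] = results
        B_stack = np.stack([r.normalized().model.B for r in results])
        np.savez(
            idir / f"state-{st}.npz",
            B=B_stack,
            U=np.stack([r.U_by_subject[0] for r in results]),
            objective=np.asarray([r.objective_trace[-1] for r in results]),
        )
        summary[st] = {
            "n_subjects": len(results),
            "converged": int(sum(r.converged for r in results)),
            "mean_final_objective": float(np.mean([r.objective_trace[-1] for r in results])),
        }
    nio.dump_json(summary, idir / "summary.json")
    return results_by_state


def stage_input_pca(cfg: PipelineConfig, results_by_state: dict, out: Path):
    profiles = profiles_from_results(results_by_state)
    ncomp = min(cfg.input_pca.n_components,
                min(M.shape[1] for M in profiles.by_state.values()), profiles.n)
    pcas = pca_per_state(profiles, n_components=ncomp)
    match = match_components_across_states(pcas, cfg.input_pca.reference_state)
    pdir = out / "input_patterns"
    pdir.mkdir(parents=True, exist_ok=True)
    reports = []
    n_report = min(cfg.input_pca.classifier_components, ncomp)
    for comp in range(n_report):
        rep = component_state_report(
            profiles, cfg.input_pca.reference_state, comp,
            alpha=cfg.input_pca.alpha, pcas=pcas, match=match,
        )
        rep.anova.to_csv(pdir / f"component-{comp + 1}_roi_anova.tsv",
                         sep="\t", index=False, float_format="%.12g")
        reports.append(rep)
    for st, sp in sorted(pcas.items()):
        np.savez(pdir / f"state-{st}_pca.npz", components=sp.components,
                 explained_variance_ratio=sp.explained_variance_ratio)
    nio.dump_json(
        {st: {"matched_index": match.index_map[st],
              "correlation": match.correlations[st]} for st in sorted(match.index_map)},
        pdir / "component_match.json",
    )
    return reports


def stage_classify(cfg: PipelineConfig, reports, out: Path):
    table = build_features(reports)
    rep = train_and_validate(
        table, folds=cfg.classify.folds, variance_target=cfg.classify.variance_target,
        C=cfg.classify.C, seed=_seed_for(cfg, "classify"),
    )
    cdir = out / "classify"
    cdir.mkdir(parents=True, exist_ok=True)
    rep.confusion.to_csv(cdir / "confusion.tsv", sep="\t")
    rep.per_class_rates.to_csv(cdir / "class_rates.tsv", sep="\t", float_format="%.12g")
    for cls, r in rep.roc.items():
        np.savetxt(
            cdir / f"roc_{cls}.tsv",
            np.column_stack([r["fpr"], r["tpr"]]),
            delimiter="\t", header="fpr\ttpr", comments="", fmt="%.12g",
        )
    nio.dump_json(
        {"cv_accuracy_pct": rep.cv_accuracy,
         "auc": {cls: r["auc"] for cls, r in rep.roc.items()},
         "seed": rep.seed},
        cdir / "report.json",
    )
    return rep


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> Path:
    """Execute every stage; returns the output directory.

    Any stage failure aborts with the stage name and cause; artifacts of
    completed stages are retained.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("neuromodes")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    chash = config_hash(cfg)
    nio.dump_json({"config": config_to_dict(cfg), "config_hash": chash, "seed": cfg.seed},
                  out / "run.json")
    logger.info("run starting; config hash %s seed %d", chash, cfg.seed)
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if cfg.simulate is not None:
            manifest = stage_simulate(cfg, out)
        else:
            manifest = Path(cfg.input_manifest)
        data = nio.read_cohort(manifest)
        logger.info("stage simulate/load done in %.1fs", time.perf_counter() - t0)

        stage = "fit_a"
        t0 = time.perf_counter()
        A_by_state = stage_fit_a(cfg, data, out)
        logger.info("stage fit_a done in %.1fs", time.perf_counter() - t0)

        stage = "eigenmodes"
        t0 = time.perf_counter()
        modes_by_state = stage_eigenmodes(cfg, A_by_state, data["dt"], out)
        logger.info("stage eigenmodes done in %.1fs", time.perf_counter() - t0)

        stage = "cluster_stats"
        t0 = time.perf_counter()
        stage_cluster_stats(cfg, modes_by_state, out)
        logger.info("stage cluster_stats done in %.1fs", time.perf_counter() - t0)

        stage = "fit_inputs"
        t0 = time.perf_counter()
        results_by_state = stage_fit_inputs(cfg, data, A_by_state, out)
        logger.info("stage fit_inputs done in %.1fs", time.perf_counter() - t0)

        stage = "input_pca"
        t0 = time.perf_counter()
        reports = stage_input_pca(cfg, results_by_state, out)
        logger.info("stage input_pca done in %.1fs", time.perf_counter() - t0)

        stage = "classify"
        t0 = time.perf_counter()
        stage_classify(cfg, reports, out)
        logger.info("stage classify done in %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
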