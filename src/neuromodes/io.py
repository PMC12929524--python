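"""On-disk formats: TSV time series, JSON manifests, model archives.

Time-series files follow the XCP-D parcellated-output convention: a header
row of ROI labels and one tab-separated row per sample.  A JSON manifest
maps files to subject / state / run-type and carries the sampling interval
plus (for synthetic cohorts) the ground truth.  Fitted models are stored in
a versioned NumPy archive with a human-readable JSON summary.

All writers are deterministic: fixed float formatting, sorted JSON keys, no
timestamps — re-running a seeded pipeline reproduces artifacts byte for
byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .panels import TimeSeriesPanel
from .synthetic import SyntheticCohort

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_cohort",
    "read_cohort",
    "save_model_archive",
    "load_model_archive",
    "dump_json",
]

FLOAT_FMT = "%.17g"  # lossless for float64
ARCHIVE_VERSION = 1


def read_timeseries(
    path,
    dt: float = 2.0,
    subject_id: str = "",
    state_label: str = "",
    run_type: str = "",
) -> TimeSeriesPanel:
    """Read one ``*_timeseries.tsv`` file (header = ROI labels, one row per
    sample) into a panel.  Raises :class:`FormatError` naming the offending
    cell for NaN/inf values, ragged rows, non-numeric cells or a missing
    header."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # ragged rows, empty file ...
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise FormatError(f"{path}: expected a header row of ROI labels and numeric rows")
    header_numeric = all(_is_number(c) for c in df.columns)
    if header_numeric:
        raise FormatError(f"{path}: missing header row of ROI labels")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(coerced.to_numpy(dtype=float))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        cell = df.iat[i, j]
        col = df.columns[j]
        if _is_number(cell):
            raise FormatError(f"{path}: non-finite value at row {i + 1}, column {col!r}")
        raise FormatError(f"{path}: non-numeric cell at row {i + 1}, column {col!r}: {cell!r}")
    # numpy's parser round-trips %.17g exactly (pandas' fast parser does not)
    values = df.to_numpy(dtype=float)
    return TimeSeriesPanel(
        data=values.T, dt=dt, roi_labels=tuple(df.columns),
        subject_id=subject_id, state_label=state_label, run_type=run_type,
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def write_timeseries(panel: TimeSeriesPanel, path) -> None:
    """Write a panel (transposed to rows-as-samples) as TSV; round-trips
    bit-identically through :func:`read_timeseries`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(panel.data.T, columns=list(panel.roi_labels))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def dump_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a synthetic cohort as a directory of TSV runs plus a JSON
    manifest carrying the ground truth (per-state A, B, input supports)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runs = []
    for st in cohort.states:
        for kind, panels in (("rest", cohort.rest[st]), ("audio", cohort.task[st])):
            for panel in panels:
                fname = f"{panel.subject_id}_state-{st}_task-{kind}_timeseries.tsv"
                write_timeseries(panel, out_dir / fname)
                runs.append(
                    {
                        "file": fname,
                        "subject": panel.subject_id,
                        "state": st,
                        "run_type": "rest" if kind == "rest" else "task",
                        "dt": panel.dt,
                    }
                )
    truth = {
        "A_by_state": {st: cohort.systems[st].A_true for st in cohort.states},
        "B_by_state": {st: cohort.B_true[st] for st in cohort.B_true},
        "U_by_state": {st: [u for u in us] for st, us in cohort.U_true.items()},
        "noise_sd": cohort.noise_sd,
        "seed": cohort.seed,
    }
    manifest = {
        "dt": cohort.rest[cohort.states[0]][0].dt,
        "states": list(cohort.states),
        "subjects_per_state": cohort.subjects_per_state,
        "runs": runs,
        "ground_truth": truth,
    }
    dump_json(manifest, out_dir / "manifest.json")
    return out_dir / "manifest.json"


def read_cohort(manifest_path) -> dict:
    """Load a cohort directory via its manifest.

    Returns ``{"states", "dt", "rest": {state: [panels]},
    "task": {state: [panels]}, "ground_truth": ...}``.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    rest: dict[str, list[TimeSeriesPanel]] = {}
    task: dict[str, list[TimeSeriesPanel]] = {}
    for run in manifest["runs"]:
        fpath = root / run["file"]
        if not fpath.exists():
            raise FormatError(f"run file listed in manifest is missing: {fpath}")
        panel = read_timeseries(
            fpath, dt=run.get("dt", manifest.get("dt", 2.0)),
            subject_id=run["subject"], state_label=run["state"], run_type=run["run_type"],
        )
        (rest if run["run_type"] == "rest" else task).setdefault(run["state"], []).append(panel)
    gt = manifest.get("ground_truth", {})
    for key in ("A_by_state", "B_by_state"):
        if key in gt:
            gt[key] = {st: np.asarray(v) for st, v in gt[key].items()}
    if "U_by_state" in gt:
        gt["U_by_state"] = {st: [np.asarray(u) for u in us] for st, us in gt["U_by_state"].items()}
    return {
        "states": manifest["states"],
        "dt": manifest.get("dt", 2.0),
        "subjects_per_state": manifest.get("subjects_per_state"),
        "rest": rest,
        "task": task,
        "ground_truth": gt,
    }


def save_model_archive(path, A_by_state: dict[str, np.ndarray], extra: dict | None = None) -> None:
    """Versioned NumPy archive of fitted system matrices (plus arbitrary
    named arrays in ``extra``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"version": np.asarray(ARCHIVE_VERSION)}
    payload["states"] = np.asarray(sorted(A_by_state.keys()))
    for st, A in A_by_state.items():
        payload[f"A__{st}"] = np.asarray(A)
    for key, val in (extra or {}).items():
        payload[key] = np.asarray(val)
    np.savez(path, **payload)


def load_model_archive(path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        version = int(z["version"])
        if version != ARCHIVE_VERSION:
            raise FormatError(f"{path}: unsupported archive version {version}")
        A_by_state = {}
        extra = {}
        for key in z.files:
            if key.startswith("A__"):
                A_by_state[key[3:]] = z[key]
            elif key not in ("version", "states"):
                extra[key] = z[key]
    return A_by_state, extra
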