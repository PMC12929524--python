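"""ROI-by-time BOLD panels.

A :class:`TimeSeriesPanel` holds one subject-run's parcellated BOLD matrix
with its sampling interval.  Samples are indexed ``k = 0..T``, so the data
matrix has ``T + 1`` columns; on disk the convention is transposed (one row
per sample, one column per ROI, matching XCP-D ``*_timeseries.tsv`` output).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError, DomainError

__all__ = ["TimeSeriesPanel"]


@dataclass(frozen=True)
class TimeSeriesPanel:
    """One subject-run's ROI x time BOLD matrix.

    Parameters
    ----------
    data
        Real matrix of shape ``(n, T + 1)``: one row per ROI, one column per
        sample.
    dt
        Sampling interval (repetition time) in seconds.
    roi_labels
        ``n`` ROI names; defaults to ``ROI001..``.
    subject_id, state_label, run_type
        Free-form identifiers (``run_type`` is conventionally ``"rest"`` or
        ``"task"``).
    """

    data: np.ndarray
    dt: float = 2.0
    roi_labels: tuple[str, ...] = field(default=())
    subject_id: str = ""
    state_label: str = ""
    run_type: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise DimensionError(f"panel data must be 2-D, got shape {data.shape}")
        n, cols = data.shape
        if n < 2:
            raise DimensionError(f"panel needs at least 2 ROIs, got {n}")
        if cols < 3:  # T >= 2 transitions
            raise DimensionError(f"panel needs at least 3 samples (T >= 2), got {cols}")
        if not np.all(np.isfinite(data)):
            bad = np.argwhere(~np.isfinite(data))[0]
            raise DomainError(f"panel contains a non-finite value at ROI {bad[0]}, sample {bad[1]}")
        if self.dt <= 0:
            raise DomainError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "data", data)
        labels = tuple(self.roi_labels) if self.roi_labels else tuple(f"ROI{i + 1:03d}" for i in range(n))
        if len(labels) != n:
            raise DimensionError(f"{len(labels)} ROI labels for {n} ROIs")
        object.__setattr__(self, "roi_labels", labels)

    @property
    def n(self) -> int:
        """Number of ROIs."""
        return self.data.shape[0]

    @property
    def T(self) -> int:
        """Number of transitions (samples minus one)."""
        return self.data.shape[1] - 1

    def zscored(self, eps: float = 1e-12) -> "TimeSeriesPanel":
        """Per-ROI z-scored copy (mean 0, unit variance along time)."""
        m = self.data.mean(axis=1, keepdims=True)
        s = self.data.std(axis=1, keepdims=True)
        s = np.where(s < eps, 1.0, s)
        return replace(self, data=(self.data - m) / s)
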