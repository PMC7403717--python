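"""Per-cell time-series container for apical-area dynamics.

A :class:`CellTrace` holds one segmented cell's measurements over time:
apical area (μm², NaN marks frames where segmentation failed) and,
optionally, a fluorescent-reporter intensity and a shape-anisotropy value
per frame. Times are in seconds and must be strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["CellTrace", "EmptyTraceError"]


class EmptyTraceError(ValueError):
    """Raised when an operation receives a trace with no usable samples."""


@dataclass
class CellTrace:
    """One cell's apical-surface time series.

    Parameters
    ----------
    embryo_id, cell_id
        Identifiers; a cohort is a plain list of traces carrying these.
    times_s
        Acquisition times in seconds, strictly increasing.
    area_um2
        Apical area in μm². ``NaN`` marks missing frames; present values
        must be positive.
    intensity
        Optional reporter intensity (a.u.), same length as ``times_s``.
    anisotropy
        Optional A-P/D-V elongation ratio, same length as ``times_s``.
    """

    embryo_id: str
    cell_id: str
    times_s: np.ndarray
    area_um2: np.ndarray
    intensity: Optional[np.ndarray] = None
    anisotropy: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.area_um2 = np.asarray(self.area_um2, dtype=float)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if self.anisotropy is not None:
            self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = self.times_s.size
        if self.area_um2.size != n:
            raise ValueError("times_s and area_um2 must have equal length")
        for name in ("intensity", "anisotropy"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ValueError(f"{name} must have length {n}")
        if n >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        present = self.area_um2[np.isfinite(self.area_um2)]
        if present.size and np.any(present <= 0):
            raise ValueError("present area values must be positive")

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of frames with a measured area."""
        return np.isfinite(self.area_um2)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    @property
    def duration_s(self) -> float:
        """Tracked duration: last minus first frame with a measured area."""
        idx = np.flatnonzero(self.present)
        if idx.size == 0:
            return 0.0
        return float(self.times_s[idx[-1]] - self.times_s[idx[0]])

    @property
    def initial_area_um2(self) -> float:
        """Area at the first frame with a measurement."""
        idx = np.flatnonzero(self.present)
        if idx.size == 0:
            raise EmptyTraceError("trace has no measured area values")
        return float(self.area_um2[idx[0]])

    def take(self, index: np.ndarray) -> "CellTrace":
        """Return a copy restricted to the given sample indices."""
        return replace(
            self,
            times_s=self.times_s[index],
            area_um2=self.area_um2[index],
            intensity=None if self.intensity is None else self.intensity[index],
            anisotropy=None if self.anisotropy is None else self.anisotropy[index],
            meta=dict(self.meta),
        )

    def with_area(self, area_um2: np.ndarray) -> "CellTrace":
        return replace(self, area_um2=np.asarray(area_um2, dtype=float), meta=dict(self.meta))
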