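"""Containers for MRI volumes and integer parcellations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeSeries:
    """3D volume or 4D volume series (x, y, z[, t]), arbitrary intensity units."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.6, 1.6, 1.6)
    tr: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3D or 4D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite intensities")
        if self.data.ndim == 4 and self.data.shape[3] > 1:
            if self.tr is None or self.tr <= 0:
                raise ValueError("tr must be > 0 for a time series")

    @property
    def is_series(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[3] if self.data.ndim == 4 else 1

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def frame(self, t: int) -> np.ndarray:
        return self.data[..., t] if self.data.ndim == 4 else self.data

    def copy(self) -> "VolumeSeries":
        return VolumeSeries(self.data.copy(), tuple(self.voxel_size), self.tr)


@dataclass
class Parcellation:
    """Integer ROI label volume with a name map; label 0 is background by default."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    background_label: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")

    def check_grid(self, vol: VolumeSeries) -> None:
        if tuple(self.labels.shape) != vol.shape3d:
            raise ValueError("parcellation grid does not match the volume")

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(name)

    def mask(self, roi: int | str) -> np.ndarray:
        lab = self.label_of(roi) if isinstance(roi, str) else int(roi)
        return self.labels == lab

    def roi_labels(self, include_background: bool = False) -> list[int]:
        labs = sorted(int(v) for v in np.unique(self.labels))
        if not include_background:
            labs = [v for v in labs if v != self.background_label]
        return labs
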