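"""In-memory container for multichannel EEG with events, roles and provenance.

The :class:`EEGRecording` is the carrier object passed through the artifact
correction cascade.  Channels carry a *role* — ``scalp`` (EEG proper),
``ecg`` (the electrocardiogram channel used for pulse-artifact trigger
estimation) or ``reference_sensor`` (carbon-wire-loop / diverted-electrode
artifact sensors used for motion-artifact regression).  Events are
``(sample_index, type)`` pairs with 0-based sample indices.

Correction stages append themselves to ``history``; the canonical stage
order of the correction cascade is enforced (a stage applied out of order
raises :class:`PipelineOrderError` unless ``force=True`` is passed to the
stage).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

SCALP = "scalp"
ECG = "ecg"
REFERENCE_SENSOR = "reference_sensor"

VALID_ROLES = (SCALP, ECG, REFERENCE_SENSOR)

#: Event types understood by the pipeline.
VOLUME_TRIGGER = "volume_trigger"
R_PEAK = "r_peak"
BLOCK_OPEN = "block_open"
BLOCK_CLOSED = "block_closed"

#: Canonical order of the artifact-correction cascade.  Stages must be
#: applied in non-decreasing index order.
CASCADE_ORDER = [
    "estimate_triggers",
    "aas",
    "obs",
    "detect_r_peaks",
    "kmeans_pa",
    "downsample",
    "reference_regression",
    "bandpass",
    "interpolate_bad",
    "rereference",
    "ica",
]


class PipelineOrderError(RuntimeError):
    """A correction stage was applied out of cascade order."""


def spherical_montage(n_channels: int) -> np.ndarray:
    """Analytic electrode montage on the unit sphere.

    Channels are laid out on a golden-angle spiral over the upper spherical
    cap (10-20-like head coverage, from the vertex down to slightly below
    the equator), giving a roughly uniform, deterministic layout for any
    channel count.  Coordinates: +x right, +y anterior, +z superior.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    k = np.arange(n_channels)
    # z from vertex (1) down to -0.15 (just below the equator, like T7/O1)
    z = 1.0 - 1.15 * (k + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = k * golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pos


@dataclass
class EEGRecording:
    """Multichannel EEG time series (channels x samples, microvolts)."""

    data: np.ndarray
    rate: float
    labels: list[str]
    roles: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    bad_channels: set[str] = field(default_factory=set)
    montage: np.ndarray | None = None
    reference: str = "recording"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        n_ch = self.data.shape[0]
        if len(self.labels) != n_ch or len(self.roles) != n_ch:
            raise ValueError("labels/roles must match channel count")
        for role in self.roles:
            if role not in VALID_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if self.montage is not None:
            self.montage = np.asarray(self.montage, dtype=np.float64)
            if self.montage.shape != (n_ch, 3):
                raise ValueError("montage must be channels x 3")
        for s, _t in self.events:
            if not (0 <= s < self.n_samples):
                raise ValueError(f"event sample {s} out of range")

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    # -- channel selection ----------------------------------------------
    def picks(self, role: str) -> np.ndarray:
        """Indices of channels with the given role."""
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    @property
    def scalp_picks(self) -> np.ndarray:
        return self.picks(SCALP)

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_picks)

    def scalp_montage(self) -> np.ndarray:
        if self.montage is None:
            raise ValueError("recording has no montage")
        return self.montage[self.scalp_picks]

    # -- events ----------------------------------------------------------
    def event_samples(self, etype: str) -> np.ndarray:
        return np.array(sorted(s for s, t in self.events if t == etype), dtype=int)

    def drop_events(self, etype: str) -> None:
        self.events = [(s, t) for s, t in self.events if t != etype]

    def add_events(self, samples, etype: str) -> None:
        for s in np.asarray(samples, dtype=int):
            if not (0 <= s < self.n_samples):
                raise ValueError(f"event sample {s} out of range")
            self.events.append((int(s), etype))
        self.events.sort()

    # -- provenance ------------------------------------------------------
    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            rate=self.rate,
            labels=list(self.labels),
            roles=list(self.roles),
            events=list(self.events),
            bad_channels=set(self.bad_channels),
            montage=None if self.montage is None else self.montage.copy(),
            reference=self.reference,
            history=list(self.history),
        )

    def _cascade_position(self) -> int:
        pos = -1
        for entry in self.history:
            name = entry.split("(", 1)[0]
            if name in CASCADE_ORDER:
                pos = max(pos, CASCADE_ORDER.index(name))
        return pos

    def mark_stage(self, name: str, params: str = "", force: bool = False) -> None:
        """Record a cascade stage, enforcing canonical order."""
        base = name.split("(", 1)[0]
        if base in CASCADE_ORDER and not force:
            if CASCADE_ORDER.index(base) < self._cascade_position():
                raise PipelineOrderError(
                    f"stage {base!r} applied after a later cascade stage; "
                    "pass force=True to override"
                )
        self.history.append(f"{name}({params})" if params else name)

    def has_stage(self, name: str) -> bool:
        return any(e.split("(", 1)[0] == name for e in self.history)

    # -- channel mutation ------------------------------------------------
    def append_channel(
        self, data: np.ndarray, label: str, role: str, position=None
    ) -> None:
        data = np.asarray(data, dtype=np.float64)
        if data.shape != (self.n_samples,):
            raise ValueError("channel length mismatch")
        if role not in VALID_ROLES:
            raise ValueError(f"unknown channel role {role!r}")
        self.data = np.vstack([self.data, data[None, :]])
        self.labels.append(label)
        self.roles.append(role)
        if self.montage is not None:
            pos = np.zeros(3) if position is None else np.asarray(position, float)
            self.montage = np.vstack([self.montage, pos[None, :]])


@dataclass
class EpochSet:
    """Equal-length epochs cut around anchor events (epochs x channels x samples)."""

    tensor: np.ndarray
    anchors: np.ndarray
    window: tuple[float, float]
    rate: float

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be epochs x channels x samples")
        anchors = np.asarray(self.anchors, dtype=int)
        if np.any(np.diff(anchors) <= 0):
            raise ValueError("anchors must be strictly increasing")
        self.anchors = anchors

    @property
    def n_epochs(self) -> int:
        return self.tensor.shape[0]


def extract_epochs(
    rec: EEGRecording,
    anchors: np.ndarray,
    window: tuple[float, float],
    picks: np.ndarray | None = None,
) -> EpochSet:
    """Cut equal-length epochs around ``anchors`` (seconds relative window).

    Anchors whose window falls outside the recording are dropped.
    """
    pre = int(round(window[0] * rec.rate))
    post = int(round(window[1] * rec.rate))
    length = post - pre
    if length <= 0:
        raise ValueError("window must have positive length")
    if picks is None:
        picks = np.arange(rec.n_channels)
    keep, chunks = [], []
    for a in np.asarray(anchors, dtype=int):
        lo, hi = a + pre, a + pre + length
        if lo < 0 or hi > rec.n_samples:
            continue
        keep.append(a)
        chunks.append(rec.data[picks, lo:hi])
    if not chunks:
        raise ValueError("no epoch fits inside the recording")
    return EpochSet(
        tensor=np.stack(chunks), anchors=np.array(keep), window=window, rate=rec.rate
    )
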