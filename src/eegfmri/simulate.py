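"""Synthetic simultaneous EEG-fMRI data with full ground-truth bookkeeping.

This module generates EEG and fMRI inputs carrying the statistical
structure that the downstream analyses assume, so every stage of the
correction and evaluation pipeline can be tested against known truth:

* clean EEG = 1/f background + block-modulated occipital alpha + a
  4-state Markov sequence of smooth scalp topographies (microstates);
* gradient artifacts (GA): a fixed multi-lobed waveform repeating at the
  slice-excitation period, plus a distinct lobe at each volume boundary —
  exactly periodic by construction, so average-artifact-subtraction
  residuals measure the implementation, not the simulation;
* pulse artifacts (PA): cardiac-locked templates with several distinct
  beat shapes, plus a synthetic ECG channel with sharp R-peaks;
* motion artifacts (MA): low-frequency processes mixed into the scalp
  through a (possibly slowly time-varying) mixing matrix, also carried by
  appended reference-sensor channels;
* environment artifacts (EA): narrowband sinusoids on all channels;
* fMRI series with network-structured low-frequency signals, drift,
  motion-coupled nuisance, a negative alpha-coupled visual ROI, and a
  Rician-magnitude background of known sigma.

Everything added to the data is recorded in a :class:`GroundTruth` whose
additivity is exact: contaminated = clean + sum of stored components,
per sample and channel, bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .hrf import hrf_kernel
from .recording import (
    BLOCK_CLOSED,
    BLOCK_OPEN,
    ECG,
    REFERENCE_SENSOR,
    SCALP,
    VOLUME_TRIGGER,
    EEGRecording,
    spherical_montage,
)
from .topographies import canonical_maps, occipital_topography
from .volumes import Parcellation, VolumeSeries

__all__ = [
    "ProtocolSpec",
    "BlockDesign",
    "SimulationConfig",
    "GroundTruth",
    "FMRISimConfig",
    "PROTOCOL_1P6MM",
    "PROTOCOL_0P8MM",
    "gen_clean_eeg",
    "add_gradient_artifact",
    "add_pulse_artifact",
    "add_motion_environment",
    "simulate_eeg",
    "gen_fmri_series",
    "gen_quality_volume",
    "demo_parcellation",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolSpec:
    """fMRI protocol geometry as seen by the EEG: repetition structure.

    ``volume_tr / excitations_per_volume`` defines the slice-artifact
    period; its inverse is the fundamental slice-GA frequency (20 Hz for
    the 1.6 mm protocol, 12.5 Hz for the 0.8 mm protocol).
    """

    volume_tr: float
    n_volumes: int
    excitations_per_volume: int
    eeg_rate: float = 5000.0
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.volume_tr <= 0:
            raise ValueError("volume_tr must be > 0")
        if self.excitations_per_volume < 1:
            raise ValueError("excitations_per_volume must be >= 1")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")

    @property
    def slice_period(self) -> float:
        return self.volume_tr / self.excitations_per_volume

    @property
    def slice_freq(self) -> float:
        return self.excitations_per_volume / self.volume_tr

    @property
    def volume_freq(self) -> float:
        return 1.0 / self.volume_tr

    @property
    def scan_duration(self) -> float:
        return self.volume_tr * self.n_volumes


#: 1.6 mm fMRI protocol: TR = 1.05 s, 300 volumes (slice GA at 20 Hz).
PROTOCOL_1P6MM = ProtocolSpec(1.05, 300, 21, label="1.6mm")
#: 0.8 mm fMRI protocol: TR = 3.52 s, 85 volumes (slice GA at 12.5 Hz).
PROTOCOL_0P8MM = ProtocolSpec(3.52, 85, 44, label="0.8mm")


@dataclass(frozen=True)
class BlockDesign:
    """Eyes-open / eyes-closed block paradigm (default 5 x (32 s + 32 s))."""

    block_len_open: float = 32.0
    block_len_closed: float = 32.0
    n_blocks: int = 5
    onset: float = 0.0

    def __post_init__(self) -> None:
        if min(self.block_len_open, self.block_len_closed) <= 0 or self.n_blocks < 1:
            raise ValueError("block lengths and count must be positive")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    @property
    def cycle(self) -> float:
        return self.block_len_open + self.block_len_closed

    @property
    def end(self) -> float:
        return self.onset + self.n_blocks * self.cycle

    def closed_intervals(self) -> list[tuple[float, float]]:
        return [
            (
                self.onset + k * self.cycle + self.block_len_open,
                self.onset + (k + 1) * self.cycle,
            )
            for k in range(self.n_blocks)
        ]

    def open_intervals(self) -> list[tuple[float, float]]:
        return [
            (self.onset + k * self.cycle, self.onset + k * self.cycle + self.block_len_open)
            for k in range(self.n_blocks)
        ]

    def closing_times(self) -> np.ndarray:
        """Times of eyes-closing transitions (starts of closed blocks)."""
        return np.array([a for a, _ in self.closed_intervals()])

    def opening_times(self) -> np.ndarray:
        """Times of eyes-opening transitions (ends of closed blocks)."""
        return np.array([b for _, b in self.closed_intervals()])

    def closed_mask(self, times: np.ndarray) -> np.ndarray:
        mask = np.zeros(times.shape, dtype=bool)
        for a, b in self.closed_intervals():
            mask |= (times >= a) & (times < b)
        return mask


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EEG session.

    Amplitudes are in microvolts.  Defaults emulate the study conditions:
    63 scalp channels, 4 reference sensors, 5 kHz sampling, GA roughly
    three orders of magnitude above the neural background, PA in the
    hundred-microvolt range, and a 5-block 32 s + 32 s eyes-open/closed
    paradigm when ``alpha_block`` is set.
    """

    protocol: ProtocolSpec = PROTOCOL_1P6MM
    n_scalp_channels: int = 63
    n_reference_sensors: int = 4
    duration: float | None = None  # seconds; defaults to the scan duration
    # gradient artifact
    ga_amplitude: float = 5000.0
    ga_volume_amplitude: float | None = None  # defaults to 0.5 * ga_amplitude
    ga_channel_spread: float = 0.15
    # pulse artifact
    pa_amplitude: float = 150.0
    pa_heart_rate: float = 60.0
    pa_hrv_jitter_sd: float = 0.05
    pa_n_shape_clusters: int = 2
    # motion + environment artifacts
    ma_amplitude: float = 30.0
    ma_n_processes: int | None = None  # default: n_reference_sensors - 1
    ma_mixing_period: float | None = None  # seconds; None = static mixing
    ma_mixing_depth: float = 0.5
    ma_sensor_noise: float = 0.5
    ea_peak_freqs: tuple[float, ...] = (33.0, 47.0)
    ea_amplitude: float = 3.0
    # neural content
    alpha_block: BlockDesign | None = None
    alpha_amplitude: float = 6.0
    noise_1f_scale: float = 8.0
    microstate_amplitude: float = 7.0
    microstate_dwell_mean: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "ga_amplitude",
            "pa_amplitude",
            "ma_amplitude",
            "ea_amplitude",
            "alpha_amplitude",
            "noise_1f_scale",
            "microstate_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def eeg_rate(self) -> float:
        return self.protocol.eeg_rate

    def effective_duration(self) -> float:
        dur = self.duration if self.duration is not None else self.protocol.scan_duration
        if self.alpha_block is not None:
            if self.alpha_block.end > dur + 1e-9:
                raise ValueError("block design exceeds the recording duration")
        return dur


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle-based testing.

    ``components`` holds, per artifact class, the exact array added to the
    data (rows aligned with the channel order at the time of addition; the
    first ``n_scalp`` rows always correspond to scalp channels).  Summing
    ``clean_eeg`` and the scalp rows of each component *in insertion
    order* reproduces the contaminated scalp data exactly.
    """

    clean_eeg: np.ndarray | None = None
    components: dict[str, np.ndarray] = field(default_factory=dict)
    r_peak_samples: np.ndarray | None = None
    pa_cluster_ids: np.ndarray | None = None
    pa_templates: np.ndarray | None = None  # clusters x channels x window samples
    pa_window: tuple[float, float] | None = None
    microstate_labels: np.ndarray | None = None
    microstate_maps: np.ndarray | None = None
    alpha_envelope: np.ndarray | None = None  # uV, at the EEG rate
    alpha_topography: np.ndarray | None = None
    ma_processes: np.ndarray | None = None
    ma_mixing: dict | None = None
    ea_freqs: tuple[float, ...] | None = None
    network_timecourses: np.ndarray | None = None
    network_labels: list[int] | None = None
    alpha_coupling_beta: dict[int, float] | None = None
    alpha_regressor: np.ndarray | None = None
    background_sigma: float | None = None
    motion_params: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def contaminated_scalp(self) -> np.ndarray:
        """Rebuild clean + artifacts over scalp channels, in insertion order."""
        if self.clean_eeg is None:
            raise ValueError("no clean EEG stored")
        n_scalp = self.clean_eeg.shape[0]
        acc = self.clean_eeg.copy()
        for comp in self.components.values():
            acc += comp[:n_scalp]
        return acc


# ---------------------------------------------------------------------------
# clean EEG
# ---------------------------------------------------------------------------


def _one_over_f(rng: np.random.Generator, n_ch: int, n: int, rate: float) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise, flattened below 0.5 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    f_lo = 0.5
    w = 1.0 / np.sqrt(np.maximum(freqs, f_lo))
    w[0] = 0.0
    out = np.empty((n_ch, n))
    for c in range(n_ch):  # channel loop keeps peak memory low
        spec = np.fft.rfft(rng.standard_normal(n))
        x = np.fft.irfft(spec * w, n)
        out[c] = x / x.std()
    return out


def _markov_labels(
    rng: np.random.Generator, n: int, n_states: int, dwell_samples: float
) -> np.ndarray:
    """State sequence with geometric run lengths of the given mean."""
    p = min(1.0, 1.0 / max(dwell_samples, 1.0))
    labels = np.empty(n, dtype=np.int16)
    pos = 0
    state = int(rng.integers(n_states))
    while pos < n:
        run = int(rng.geometric(p))
        labels[pos : pos + run] = state
        pos += run
        step = int(rng.integers(1, n_states))
        state = (state + step) % n_states
    return labels


def _bandpassed_noise(
    rng: np.random.Generator, n: int, rate: float, lo: float, hi: float
) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def gen_clean_eeg(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[EEGRecording, GroundTruth]:
    """Generate artifact-free EEG plus ground truth.

    Content: per-channel 1/f background; a 10 Hz occipital alpha
    oscillator with a slow random envelope, doubled in amplitude during
    eyes-closed blocks when a :class:`BlockDesign` is configured; and a
    4-state Markov sequence of smooth topographies driven by a broadband
    source, with mean dwell time ``microstate_dwell_mean``.
    """
    if config.n_scalp_channels < 8:
        raise ValueError("need >= 8 scalp channels for topography/ICA stages")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rate = config.eeg_rate
    duration = config.effective_duration()
    n = int(round(duration * rate))
    n_ch = config.n_scalp_channels
    montage = spherical_montage(n_ch)
    times = np.arange(n) / rate

    data = config.noise_1f_scale * _one_over_f(rng, n_ch, n, rate)

    # occipital alpha with slow random envelope and block modulation
    alpha_topo = occipital_topography(montage)
    slow = signal.sosfiltfilt(
        signal.butter(2, 0.3, btype="lowpass", fs=rate, output="sos"),
        rng.standard_normal(n),
    )
    env = 1.0 + 0.4 * slow / max(slow.std(), 1e-12)
    env = np.clip(env, 0.1, None)
    if config.alpha_block is not None:
        env = env * (1.0 + config.alpha_block.closed_mask(times))
    # narrowband (8.5-11.5 Hz) carrier: realistic alpha bandwidth rather
    # than a pure tone
    carrier = _bandpassed_noise(rng, n, rate, 8.5, 11.5) * np.sqrt(2.0)
    alpha_sig = config.alpha_amplitude * env * carrier
    data += np.outer(alpha_topo, alpha_sig)

    # microstate topography sequence
    maps = canonical_maps(montage)
    labels = _markov_labels(rng, n, maps.shape[0], config.microstate_dwell_mean * rate)
    source = config.microstate_amplitude * _bandpassed_noise(rng, n, rate, 1.0, 30.0)
    data += maps.T[:, labels] * source

    events: list[tuple[int, str]] = []
    if config.alpha_block is not None:
        for a, b in config.alpha_block.closed_intervals():
            sa, sb = int(round(a * rate)), int(round(b * rate))
            if sa < n:
                events.append((sa, BLOCK_CLOSED))
            if sb < n:
                events.append((sb, BLOCK_OPEN))

    rec = EEGRecording(
        data=data,
        rate=rate,
        labels=[f"EEG{i + 1:03d}" for i in range(n_ch)],
        roles=[SCALP] * n_ch,
        events=sorted(events),
        montage=montage,
        history=["simulated_clean"],
    )
    gt = GroundTruth(
        clean_eeg=data.copy(),
        microstate_labels=labels,
        microstate_maps=maps,
        alpha_envelope=config.alpha_amplitude * env,
        alpha_topography=alpha_topo,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# gradient artifact
# ---------------------------------------------------------------------------

# Fixed lobe tables (center, width, amplitude).  Slice lobes are expressed
# as fractions of the excitation period; volume lobes in seconds relative
# to the volume onset.  Narrow lobes put harmonics out to ~2 kHz while the
# broad first lobe keeps the fundamental dominant.
_GA_SLICE_LOBES = (
    (0.30, 0.070, 1.00),
    (0.52, 0.012, -0.25),
    (0.66, 0.008, 0.15),
    (0.80, 0.014, -0.12),
    (0.90, 0.006, 0.08),
)
_GA_VOLUME_LOBES = (
    (0.012, 0.0045, 1.00),
    (0.024, 0.0030, -0.60),
    (0.040, 0.0065, 0.35),
)


def _lobe_sum(x: np.ndarray, lobes) -> np.ndarray:
    out = np.zeros_like(x)
    for c, w, a in lobes:
        out += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    return out


def add_gradient_artifact(
    rec: EEGRecording,
    protocol: ProtocolSpec,
    amplitude: float,
    volume_amplitude: float | None = None,
    gt: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
    channel_spread: float = 0.15,
) -> EEGRecording:
    """Add the slice- and volume-periodic gradient artifact in place.

    A fixed multi-lobed waveform repeats every ``volume_tr /
    excitations_per_volume`` seconds, with a distinct extra lobe at each
    volume boundary; per-channel gains are drawn once.  Volume-trigger
    events are appended at every volume onset (also when amplitude is 0,
    mirroring a scan with negligible pickup).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    rate = rec.rate
    if rec.duration + 0.5 / rate < protocol.scan_duration:
        raise ValueError("recording shorter than the scan")
    period_samples = protocol.slice_period * rate
    if period_samples < 2:
        raise ValueError("excitation period shorter than 2 samples")

    times = rec.times
    scan = times < protocol.scan_duration
    t = times[scan]

    gains = 1.0 + channel_spread * rng.standard_normal(rec.n_channels)
    if amplitude > 0 or (volume_amplitude or 0) > 0:
        # quarter-sample offset: keeps samples off the modulo boundary,
        # where floating-point rounding would otherwise break the exact
        # sample-level periodicity of the artifact
        teps = t + 0.25 / rate
        phase = (teps / protocol.slice_period) % 1.0
        slice_wave = _lobe_sum(phase, _GA_SLICE_LOBES)
        tau = teps % protocol.volume_tr
        vol_wave = _lobe_sum(tau, _GA_VOLUME_LOBES)
        v_amp = 0.5 * amplitude if volume_amplitude is None else volume_amplitude
        wave = amplitude * slice_wave + v_amp * vol_wave
        comp = np.zeros_like(rec.data)
        comp[:, scan] = np.outer(gains, wave)
        rec.data += comp
        if gt is not None:
            gt.components["ga"] = comp
            gt.extras["ga_gains"] = gains
    elif gt is not None:
        gt.components["ga"] = np.zeros_like(rec.data)

    trig = np.round(np.arange(protocol.n_volumes) * protocol.volume_tr * rate).astype(int)
    rec.add_events(trig[trig < rec.n_samples], VOLUME_TRIGGER)
    rec.history.append(f"simulated_ga({protocol.label})")
    return rec


# ---------------------------------------------------------------------------
# pulse artifact
# ---------------------------------------------------------------------------

_PA_BASE_LOBES = (
    (0.02, 0.015, -0.35),
    (0.16, 0.045, 1.00),
    (0.30, 0.040, -0.50),
    (0.52, 0.120, 0.30),
)
_ECG_LOBES = (
    (-0.010, 0.0040, -0.15),
    (0.000, 0.0060, 1.00),
    (0.012, 0.0050, -0.25),
    (0.250, 0.0500, 0.12),
)

PA_WINDOW = (-0.25, 0.75)


def add_pulse_artifact(
    rec: EEGRecording,
    config: SimulationConfig,
    gt: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Add beat-locked pulse artifacts and a synthetic ECG channel in place.

    Inter-beat intervals are 60/HR seconds plus Gaussian jitter; each beat
    uses one of ``pa_n_shape_clusters`` distinct template shapes, applied
    through a smooth channel-loading pattern.  R-peak samples and cluster
    ids go to the ground truth.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    hr = config.pa_heart_rate
    if not (30.0 <= hr <= 150.0):
        raise ValueError("heart rate must lie in [30, 150] bpm")
    ibi = 60.0 / hr
    if config.pa_hrv_jitter_sd > ibi / 4:
        raise ValueError("HRV jitter SD above IBI/4: trigger estimation ill-posed")
    rate = rec.rate
    n = rec.n_samples

    # beat times
    t = 0.5 + rng.uniform(0.0, 0.3)
    beats = []
    while t < rec.duration - PA_WINDOW[1] - 0.05:
        beats.append(t)
        t += ibi + rng.normal(0.0, config.pa_hrv_jitter_sd)
    beat_samples = np.round(np.array(beats) * rate).astype(int)
    n_beats = len(beat_samples)
    n_clusters = max(1, int(config.pa_n_shape_clusters))
    cluster_ids = rng.integers(n_clusters, size=n_beats)

    # distinct cluster shapes: perturbed copies of the base lobe table
    win = np.arange(int(round(PA_WINDOW[0] * rate)), int(round(PA_WINDOW[1] * rate)))
    twin = win / rate
    shapes = np.empty((n_clusters, len(win)))
    for c in range(n_clusters):
        lobes = []
        for (ctr, wid, amp) in _PA_BASE_LOBES:
            lobes.append(
                (
                    ctr + 0.05 * rng.uniform(-1, 1),
                    wid * (1.0 + 0.30 * rng.uniform(-1, 1)),
                    amp * (1.0 + 0.40 * rng.uniform(-1, 1)),
                )
            )
        shape = _lobe_sum(twin, tuple(lobes))
        shapes[c] = shape - shape.mean()  # AC-coupled: zero-mean over the window

    # smooth positive channel loadings over the montage
    if rec.montage is not None:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        loading = 1.0 + 0.5 * rec.montage @ direction
    else:
        loading = np.ones(rec.n_channels)
    loading = np.clip(loading, 0.2, None) * config.pa_amplitude

    comp = np.zeros_like(rec.data)
    templates = loading[None, :, None] * shapes[:, None, :]  # clusters x ch x samp
    for s, c in zip(beat_samples, cluster_ids):
        lo, hi = s + win[0], s + win[-1] + 1
        if lo < 0 or hi > n:
            continue
        comp[:, lo:hi] += templates[c]
    rec.data += comp

    # synthetic ECG channel with sharp R-peaks
    ecg = np.zeros(n)
    espan = np.arange(int(-0.05 * rate), int(0.35 * rate))
    ewave = 800.0 * _lobe_sum(espan / rate, _ECG_LOBES)
    for s in beat_samples:
        lo, hi = s + espan[0], s + espan[-1] + 1
        if lo < 0 or hi > n:
            continue
        ecg[lo:hi] += ewave
    ecg += 3.0 * rng.standard_normal(n)
    rec.append_channel(ecg, "ECG", ECG)

    if gt is not None:
        gt.components["pa"] = comp
        gt.r_peak_samples = beat_samples
        gt.pa_cluster_ids = cluster_ids
        gt.pa_templates = templates
        gt.pa_window = PA_WINDOW
    rec.history.append("simulated_pa")
    return rec


# ---------------------------------------------------------------------------
# motion + environment artifacts
# ---------------------------------------------------------------------------


def add_motion_environment(
    rec: EEGRecording,
    config: SimulationConfig,
    gt: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Add motion artifacts with reference sensors, and environment peaks.

    MA: a small set of low-frequency (< 8 Hz) motion processes (default
    ``n_reference_sensors - 1``, so the artifact subspace stays
    identifiable from the sensors) is mixed into the scalp channels
    through a mixing matrix that is static or slowly sinusoidally
    time-varying (``ma_mixing_period``); the appended reference channels
    carry their own well-conditioned mixtures of the same processes plus
    sensor noise, so per sliding window the scalp MA is a linear
    combination of the reference channels.  The reference sensors also
    pick up a scaled copy of the mean scalp pulse artifact when one is
    present.  EA: pure sinusoids at ``ea_peak_freqs`` on all channels.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if config.n_reference_sensors < 1:
        raise ValueError("need at least one reference sensor")
    nyq = rec.rate / 2
    for f in config.ea_peak_freqs:
        if f >= nyq:
            raise ValueError(f"EA frequency {f} Hz at or above Nyquist")
    n = rec.n_samples
    n_ref = config.n_reference_sensors
    n_proc = (
        config.ma_n_processes
        if config.ma_n_processes is not None
        else max(1, n_ref - 1)
    )
    scalp = rec.scalp_picks
    times = rec.times

    # low-frequency motion processes
    sos = signal.butter(4, 8.0, btype="lowpass", fs=rec.rate, output="sos")
    procs = np.stack(
        [signal.sosfiltfilt(sos, rng.standard_normal(n)) for _ in range(n_proc)]
    )
    procs /= procs.std(axis=1, keepdims=True)
    procs *= config.ma_amplitude

    mix0 = rng.standard_normal((len(scalp), n_proc)) / np.sqrt(n_proc)
    ma = np.zeros_like(rec.data)
    if config.ma_amplitude > 0:
        if config.ma_mixing_period is None:
            ma[scalp] = mix0 @ procs
        else:
            phases = rng.uniform(0, 2 * np.pi, size=(len(scalp), n_proc))
            omega = 2 * np.pi / config.ma_mixing_period
            for r in range(n_proc):  # keep peak memory bounded
                gain = 1.0 + config.ma_mixing_depth * np.sin(
                    omega * times[None, :] + phases[:, r : r + 1]
                )
                ma[scalp] += (mix0[:, r : r + 1] * gain) * procs[r]
        rec.data += ma

    # reference-sensor channels: well-conditioned process mixtures + noise
    # (+ scaled PA copy); sensor gains are stable over time
    pa_ref = None
    if gt is not None and "pa" in gt.components:
        pa_ref = gt.components["pa"][: len(scalp)].mean(axis=0)
    ref_mix = np.eye(n_ref, n_proc) + 0.3 * rng.standard_normal((n_ref, n_proc))
    for r in range(n_ref):
        chan = ref_mix[r] @ procs + config.ma_sensor_noise * rng.standard_normal(n)
        if pa_ref is not None:
            chan = chan + 0.5 * pa_ref
        rec.append_channel(chan, f"Ref{r + 1}", REFERENCE_SENSOR)

    # environment sinusoids on every channel (including the new refs)
    ea = np.zeros_like(rec.data)
    if config.ea_amplitude > 0 and config.ea_peak_freqs:
        for f in config.ea_peak_freqs:
            amps = config.ea_amplitude * (0.5 + rng.uniform(0, 1, rec.n_channels))
            ph = rng.uniform(0, 2 * np.pi, rec.n_channels)
            ea += amps[:, None] * np.sin(2 * np.pi * f * times[None, :] + ph[:, None])
        rec.data += ea

    if gt is not None:
        gt.components["ma"] = ma
        gt.components["ea"] = ea
        gt.ma_processes = procs
        gt.ma_mixing = {
            "static": mix0,
            "ref_mixing": ref_mix,
            "period": config.ma_mixing_period,
            "depth": config.ma_mixing_depth,
        }
        gt.ea_freqs = tuple(config.ea_peak_freqs)
    rec.history.append("simulated_ma_ea")
    return rec


def simulate_eeg(config: SimulationConfig) -> tuple[EEGRecording, GroundTruth]:
    """Full contaminated EEG session: clean + GA + PA + MA/EA, one seed."""
    rng = np.random.default_rng(config.seed)
    rec, gt = gen_clean_eeg(config, rng=rng)
    add_gradient_artifact(
        rec,
        config.protocol,
        config.ga_amplitude,
        config.ga_volume_amplitude,
        gt=gt,
        rng=rng,
        channel_spread=config.ga_channel_spread,
    )
    add_pulse_artifact(rec, config, gt=gt, rng=rng)
    add_motion_environment(rec, config, gt=gt, rng=rng)
    return rec, gt


# ---------------------------------------------------------------------------
# fMRI
# ---------------------------------------------------------------------------


@dataclass
class FMRISimConfig:
    """Parameters of the synthetic fMRI series on a small demo grid."""

    shape: tuple[int, int, int] = (24, 24, 14)
    voxel_size: tuple[float, float, float] = (1.6, 1.6, 1.6)
    tr: float = 1.05
    n_volumes: int = 300
    baseline: float = 200.0
    shared_sd: float = 2.0  # network-shared signal SD
    noise_sd: float = 2.0  # voxelwise white-noise SD
    alpha_beta: float = 3.0  # negative alpha coupling amplitude, visual ROI
    drift_amp: float = 3.0
    motion_amp: float = 0.3
    background_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be > 0")


def demo_parcellation(shape: tuple[int, int, int] = (24, 24, 14)) -> Parcellation:
    """Small box parcellation: 3 network ROIs, WM, CSF, and background.

    The brain occupies an inner box; outside it is background (label 0),
    thick enough on the x/y faces for 5-cube noise windows.  The visual
    ROI sits posterior (low y), mirroring where alpha-coupled BOLD is
    expected.
    """
    nx, ny, nz = shape
    if min(nx, ny) < 16 or nz < 10:
        raise ValueError("grid too small for the demo parcellation")
    labels = np.zeros(shape, dtype=np.int16)
    x0, x1 = 5, nx - 5
    y0, y1 = 5, ny - 5
    z0, z1 = 3, nz - 3
    ys = np.linspace(y0, y1, 5).astype(int)
    labels[x0:x1, ys[0] : ys[1], z0:z1] = 1  # visual (posterior)
    labels[x0:x1, ys[1] : ys[2], z0:z1] = 2  # somatomotor
    labels[x0:x1, ys[2] : ys[3], z0:z1] = 3  # default mode
    zmid = (z0 + z1) // 2
    labels[x0:x1, ys[3] : ys[4], z0:zmid] = 4  # white matter
    labels[x0:x1, ys[3] : ys[4], zmid:z1] = 5  # csf
    names = {
        0: "background",
        1: "visual",
        2: "somatomotor",
        3: "default_mode",
        4: "white_matter",
        5: "csf",
    }
    return Parcellation(labels=labels, names=names, background_label=0)


def _band_limited(
    rng: np.random.Generator, n: int, tr: float, lo: float = 0.01, hi: float = 0.08
) -> np.ndarray:
    fs = 1.0 / tr
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def gen_fmri_series(
    config: FMRISimConfig,
    blocks: BlockDesign | None = None,
    alpha_envelope: np.ndarray | None = None,
    alpha_rate: float | None = None,
) -> tuple[VolumeSeries, Parcellation, GroundTruth]:
    """Synthetic 4D fMRI with network structure and known truths.

    Each network ROI shares a band-limited (0.01-0.08 Hz) latent
    timecourse; voxels add white noise, a common drift pattern with
    per-voxel gain, and motion-coupled nuisance courses.  Visual-ROI
    voxels add ``-alpha_beta`` times the HRF-convolved, standardized
    alpha-power envelope (negative coupling).  The background is Rician
    magnitude noise of known sigma.
    """
    rng = np.random.default_rng(config.seed)
    parc = demo_parcellation(config.shape)
    nt = config.n_volumes
    tr = config.tr
    frame_t = np.arange(nt) * tr

    # alpha-power envelope on the frame grid
    if alpha_envelope is not None:
        if alpha_rate is None:
            raise ValueError("alpha_rate required with alpha_envelope")
        idx = np.minimum((frame_t * alpha_rate).astype(int), len(alpha_envelope) - 1)
        env = alpha_envelope[idx].astype(float)
    elif blocks is not None:
        env = 1.0 + blocks.closed_mask(frame_t).astype(float)
        env += 0.1 * rng.standard_normal(nt)
    else:
        env = _band_limited(rng, nt, tr, 0.01, 0.08)
    _, h, _ = hrf_kernel(tr)
    conv = signal.fftconvolve(env - env.mean(), h)[:nt]
    conv_sd = conv.std()
    alpha_reg = conv / conv_sd if conv_sd > 0 else conv

    net_labels = [1, 2, 3]
    latents = np.stack([_band_limited(rng, nt, tr) for _ in net_labels])

    motion = np.cumsum(0.01 * rng.standard_normal((nt, 6)), axis=0)
    motion = signal.sosfiltfilt(
        signal.butter(2, min(0.1, 0.4 / tr), fs=1.0 / tr, output="sos"),
        motion,
        axis=0,
    )

    drift_course = np.linspace(-1.0, 1.0, nt) + 0.5 * np.cos(
        2 * np.pi * 0.004 * frame_t
    )

    data = np.zeros(config.shape + (nt,))
    beta_map: dict[int, float] = {}
    brain = parc.labels != parc.background_label
    nb = int(brain.sum())
    noise = config.noise_sd * rng.standard_normal((nb, nt))
    drift_gain = config.drift_amp * (0.5 + rng.uniform(0, 1, nb))
    mot_coupling = config.motion_amp * rng.standard_normal((nb, 6))
    vox_sig = (
        config.baseline
        + noise
        + drift_gain[:, None] * drift_course[None, :]
        + mot_coupling @ motion.T
    )
    flat_labels = parc.labels[brain]
    for i, lab in enumerate(net_labels):
        vox_sig[flat_labels == lab] += config.shared_sd * latents[i]
    beta_map = {lab: 0.0 for lab in parc.roi_labels()}
    if config.alpha_beta != 0:
        vox_sig[flat_labels == 1] += -config.alpha_beta * alpha_reg
        beta_map[1] = -config.alpha_beta
    data[brain] = vox_sig

    # Rician background: magnitude of two independent Gaussians (sigma each)
    bg = parc.labels == parc.background_label
    nbg = int(bg.sum())
    re = config.background_sigma * rng.standard_normal((nbg, nt))
    im = config.background_sigma * rng.standard_normal((nbg, nt))
    data[bg] = np.hypot(re, im)

    vol = VolumeSeries(data=data, voxel_size=config.voxel_size, tr=tr)
    gt = GroundTruth(
        network_timecourses=latents,
        network_labels=net_labels,
        alpha_coupling_beta=beta_map,
        alpha_regressor=alpha_reg,
        background_sigma=config.background_sigma,
        motion_params=motion,
        extras={
            "drift_course": drift_course,
            "alpha_envelope_frames": env,
            "shared_sd": config.shared_sd,
            "noise_sd": config.noise_sd,
        },
    )
    return vol, parc, gt


def gen_quality_volume(
    shape: tuple[int, int, int] = (24, 24, 14),
    roi_means: dict[int, float] | None = None,
    within_sd: float = 5.0,
    background_sigma: float = 10.0,
    voxel_size: tuple[float, float, float] = (1.6, 1.6, 1.6),
    seed: int = 0,
) -> tuple[VolumeSeries, Parcellation, dict]:
    """Single quality-control frame: piecewise-constant ROI means with
    Gaussian within-ROI spread and a Rician background of known sigma."""
    rng = np.random.default_rng(seed)
    parc = demo_parcellation(shape)
    if roi_means is None:
        roi_means = {1: 200.0, 2: 180.0, 3: 220.0, 4: 160.0, 5: 140.0}
    data = np.zeros(shape)
    for lab, mean in roi_means.items():
        m = parc.labels == lab
        data[m] = mean + within_sd * rng.standard_normal(int(m.sum()))
    bg = parc.labels == parc.background_label
    nbg = int(bg.sum())
    data[bg] = np.hypot(
        background_sigma * rng.standard_normal(nbg),
        background_sigma * rng.standard_normal(nbg),
    )
    truth = {
        "roi_means": dict(roi_means),
        "within_sd": within_sd,
        "background_sigma": background_sigma,
    }
    return VolumeSeries(data=data, voxel_size=voxel_size, tr=None), parc, truth
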