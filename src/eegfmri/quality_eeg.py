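"""EEG quality evaluation: spectra, band magnitudes, microstates, alpha.

Spectral metrics use Welch's method with a 10 s Hann window and 50 %
overlap, reported as *amplitude* (magnitude) spectra in microvolts; band
magnitudes are means over the fixed band grid delta 0.75-4, theta 4-7,
alpha 7-13, beta 13-30, gamma 30-70 and full 0.75-70 Hz.  Spatial and
temporal structure is summarized with a 4-class microstate analysis:
polarity-invariant modified k-means on the maps at global-field-power
peaks, canonical A-D labeling by spatial correlation with template maps,
and back-fitting to obtain duration, occurrence and coverage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import EEGRecording
from .simulate import BlockDesign
from .topographies import MICROSTATE_NAMES, canonical_maps

__all__ = [
    "BANDS",
    "SpectrumSet",
    "BandTable",
    "MicrostateModel",
    "MicrostateMetrics",
    "welch_spectrum",
    "band_magnitudes",
    "gfp_peaks",
    "fit_microstates",
    "match_canonical",
    "backfit",
    "microstate_metrics",
    "alpha_block_modulation",
]

#: Band edges (Hz); lower edge inclusive, upper exclusive.
BANDS = {
    "delta": (0.75, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (7.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 70.0),
    "full": (0.75, 70.0),
}


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectrumSet:
    """Per-channel amplitude spectra (microvolts) on a common frequency grid."""

    freqs: np.ndarray
    magnitude: np.ndarray  # channels x freqs
    labels: list[str]
    window_len: float
    overlap: float

    def channel_average(self) -> np.ndarray:
        return self.magnitude.mean(axis=0)

    def peak_frequency(self, fmin: float = 0.0, fmax: float | None = None) -> float:
        """Frequency of the largest channel-average peak in [fmin, fmax]."""
        avg = self.channel_average()
        sel = self.freqs >= fmin
        if fmax is not None:
            sel &= self.freqs <= fmax
        idx = np.flatnonzero(sel)
        return float(self.freqs[idx[np.argmax(avg[idx])]])

    def lowest_local_maximum(self, fmin: float = 0.0, rel_height: float = 1e-3) -> float:
        """Frequency of the lowest-frequency local maximum above ``fmin``.

        Peaks below ``rel_height`` of the global maximum are ignored
        (guards against numerical ripples in near-zero regions).
        """
        avg = self.channel_average()
        sel = self.freqs >= fmin
        f, a = self.freqs[sel], avg[sel]
        locs, _ = signal.find_peaks(a, height=rel_height * a.max())
        if len(locs) == 0:
            raise ValueError("no local maximum found")
        return float(f[locs[0]])


def welch_spectrum(
    rec: EEGRecording,
    window_len: float = 10.0,
    overlap: float = 0.5,
    picks: np.ndarray | None = None,
) -> SpectrumSet:
    """Welch amplitude spectrum per channel (Hann window).

    The magnitude convention recovers the amplitude of a sinusoid at its
    peak bin: ``sqrt(2 * P)`` with ``scaling='spectrum'``.
    """
    if picks is None:
        picks = rec.scalp_picks
    nper = int(round(window_len * rec.rate))
    if rec.n_samples < nper:
        raise ValueError("recording shorter than one Welch window")
    freqs, pxx = signal.welch(
        rec.data[picks],
        fs=rec.rate,
        window="hann",
        nperseg=nper,
        noverlap=int(nper * overlap),
        scaling="spectrum",
        detrend="constant",
        axis=1,
    )
    return SpectrumSet(
        freqs=freqs,
        magnitude=np.sqrt(2.0 * pxx),
        labels=[rec.labels[i] for i in picks],
        window_len=window_len,
        overlap=overlap,
    )


@dataclass
class BandTable:
    """Mean band magnitudes per channel plus the channel average."""

    table: pd.DataFrame  # channels x bands
    average: pd.Series  # per band

    def profile(self, bands=("delta", "theta", "alpha", "beta", "gamma")) -> np.ndarray:
        return self.average[list(bands)].to_numpy()


def band_magnitudes(spec: SpectrumSet, bands: dict | None = None) -> BandTable:
    """Average spectral magnitude in each frequency band (lower edge
    inclusive, upper exclusive)."""
    bands = BANDS if bands is None else bands
    cols = {}
    for name, (lo, hi) in bands.items():
        if hi > spec.freqs[-1] + 1e-9:
            raise ValueError(f"band {name} exceeds the spectrum range")
        sel = (spec.freqs >= lo) & (spec.freqs < hi)
        cols[name] = spec.magnitude[:, sel].mean(axis=1)
    table = pd.DataFrame(cols, index=spec.labels)
    return BandTable(table=table, average=table.mean(axis=0))


# ---------------------------------------------------------------------------
# microstates
# ---------------------------------------------------------------------------


def gfp_peaks(rec: EEGRecording, min_separation: float = 0.01) -> np.ndarray:
    """Sample indices of global-field-power peaks.

    GFP is the per-sample standard deviation across scalp channels; the
    input must be average-referenced (and is expected 1-40 Hz filtered).
    """
    if rec.reference != "average":
        raise ValueError("gfp_peaks expects an average-referenced recording")
    gfp = rec.data[rec.scalp_picks].std(axis=0)
    if gfp.max() < 1e-12:
        warnings.warn("flat recording: no GFP peaks")
        return np.array([], dtype=int)
    locs, _ = signal.find_peaks(gfp, distance=max(1, int(min_separation * rec.rate)))
    return locs


@dataclass
class MicrostateModel:
    """k unit-norm microstate topographies with optional A-D assignment."""

    topographies: np.ndarray  # k x channels, unit norm
    gev: float
    canonical_assignment: dict[int, str] | None = None
    polarity_invariant: bool = True

    @property
    def k(self) -> int:
        return self.topographies.shape[0]

    def ordered_maps(self) -> np.ndarray:
        """Maps reordered A, B, C, D (requires an assignment)."""
        if self.canonical_assignment is None:
            raise ValueError("no canonical assignment")
        order = sorted(self.canonical_assignment, key=lambda i: self.canonical_assignment[i])
        return self.topographies[order]


def _normalize_maps(V: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(V, axis=1, keepdims=True)
    return V / np.maximum(nrm, 1e-24)


def _modified_kmeans(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Polarity-invariant k-means on unit-norm maps.

    Distance is 1 - squared spatial correlation; centroids are updated as
    the first principal direction of their assigned maps.
    """
    n = V.shape[0]
    T = V[rng.choice(n, size=k, replace=False)].copy()
    prev = None
    for _ in range(max_iter):
        corr = V @ T.T  # both unit norm
        assign = np.argmax(corr**2, axis=1)
        if prev is not None and np.array_equal(assign, prev):
            break
        prev = assign
        for j in range(k):
            sel = V[assign == j]
            if len(sel) == 0:
                T[j] = V[rng.integers(n)]
                continue
            # dominant eigenvector of sel^T sel (sign-invariant mean map)
            _, vecs = np.linalg.eigh(sel.T @ sel)
            T[j] = vecs[:, -1]
    corr = V @ T.T
    gev = float(np.mean(np.max(corr**2, axis=1)))
    return T, gev


def fit_microstates(
    recs: list[EEGRecording] | EEGRecording,
    k: int = 4,
    n_restarts: int = 20,
    seed: int = 0,
    min_separation: float = 0.01,
) -> MicrostateModel:
    """Group-level microstate topographies from GFP-peak maps.

    Each recording is GFP-normalized (divided by its mean GFP), its maps
    at GFP peaks extracted, and the concatenated peak maps clustered with
    polarity-invariant modified k-means; the best of ``n_restarts``
    seeded restarts by global explained variance is returned.
    """
    if isinstance(recs, EEGRecording):
        recs = [recs]
    maps = []
    montage_ref = None
    for rec in recs:
        scalp = rec.scalp_picks
        if montage_ref is None:
            montage_ref = rec.montage[scalp] if rec.montage is not None else None
        elif rec.montage is not None and not np.allclose(
            rec.montage[scalp], montage_ref
        ):
            raise ValueError("recordings have different montages")
        gfp = rec.data[scalp].std(axis=0)
        peaks = gfp_peaks(rec, min_separation)
        if len(peaks) == 0:
            continue
        X = rec.data[scalp] / max(gfp.mean(), 1e-24)
        maps.append(X[:, peaks].T)
    if not maps:
        raise ValueError("no GFP peaks available")
    V = np.concatenate(maps)
    if len(V) < 10 * k:
        raise ValueError(f"need >= {10 * k} GFP-peak maps, got {len(V)}")
    V = _normalize_maps(V - V.mean(axis=1, keepdims=True))
    best: tuple[np.ndarray, float] | None = None
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    for ss in seeds:
        T, gev = _modified_kmeans(V, k, np.random.default_rng(ss))
        if best is None or gev > best[1]:
            best = (T, gev)
    return MicrostateModel(topographies=_normalize_maps(best[0]), gev=best[1])


def match_canonical(
    model: MicrostateModel, templates: np.ndarray | None = None, montage=None
) -> MicrostateModel:
    """Assign canonical labels A-D by optimal bijective map matching.

    Exhaustive over the k! permutations, maximizing the total absolute
    spatial correlation with the template maps (polarity ignored).
    """
    if templates is None:
        if montage is None:
            raise ValueError("provide templates or a montage")
        templates = canonical_maps(montage)
    templates = _normalize_maps(
        np.asarray(templates, float) - np.asarray(templates, float).mean(axis=1, keepdims=True)
    )
    k = model.k
    if templates.shape[0] != k:
        raise ValueError("template count must equal k")
    C = np.abs(model.topographies @ templates.T)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(C[i, perm[i]] for i in range(k))
        if score > best_score:
            best_perm, best_score = perm, score
    assignment = {i: MICROSTATE_NAMES[best_perm[i]] for i in range(k)}
    return MicrostateModel(
        topographies=model.topographies,
        gev=model.gev,
        canonical_assignment=assignment,
    )


def backfit(rec: EEGRecording, model: MicrostateModel) -> np.ndarray:
    """Per-sample microstate labels: argmax absolute spatial correlation."""
    X = rec.data[rec.scalp_picks]
    X = X - X.mean(axis=0, keepdims=True)
    nrm = np.linalg.norm(X, axis=0, keepdims=True)
    Xn = X / np.maximum(nrm, 1e-24)
    corr = model.topographies @ Xn  # k x samples
    return np.argmax(np.abs(corr), axis=0)


@dataclass
class MicrostateMetrics:
    """Duration (s), occurrence (1/s) and coverage per state."""

    table: pd.DataFrame

    def coverages(self) -> np.ndarray:
        return self.table["coverage"].to_numpy()


def microstate_metrics(
    labels: np.ndarray, rate: float, k: int | None = None
) -> MicrostateMetrics:
    """Summarize a label sequence into per-state temporal metrics.

    Metrics are computed on label runs: duration is the mean run length,
    occurrence the number of runs per second, coverage the fraction of
    samples; coverages sum to 1.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k is None:
        k = int(labels.max()) + 1
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [n]])
    run_states = labels[starts]
    run_lens = (stops - starts) / rate
    total_time = n / rate
    rows = []
    for s in range(k):
        sel = run_states == s
        rows.append(
            {
                "state": s,
                "duration": float(run_lens[sel].mean()) if sel.any() else 0.0,
                "occurrence": float(sel.sum() / total_time),
                "coverage": float((labels == s).mean()),
            }
        )
    return MicrostateMetrics(table=pd.DataFrame(rows).set_index("state"))


# ---------------------------------------------------------------------------
# alpha block modulation
# ---------------------------------------------------------------------------


def alpha_power_envelope(
    x: np.ndarray, rate: float, band: tuple[float, float] = (7.0, 13.0), smooth: float = 2.0
) -> np.ndarray:
    """Alpha-band power envelope: squared zero-phase bandpass, smoothed."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    win = max(1, int(round(smooth * rate)))
    return np.convolve(bp**2, np.ones(win) / win, mode="same")


def alpha_block_modulation(
    source: EEGRecording | np.ndarray,
    blocks: BlockDesign,
    rate: float | None = None,
    band: tuple[float, float] = (7.0, 13.0),
    smooth: float = 2.0,
) -> float:
    """Eyes-closed vs eyes-open alpha contrast score.

    score = (mean closed - mean open) / pooled SD of the alpha power
    envelope.  Accepts a recording (envelope averaged over scalp
    channels) or a single timecourse with its sampling rate.
    """
    if isinstance(source, EEGRecording):
        rate = source.rate
        env = np.mean(
            [
                alpha_power_envelope(source.data[i], rate, band, smooth)
                for i in source.scalp_picks
            ],
            axis=0,
        )
    else:
        if rate is None:
            raise ValueError("rate required for a bare timecourse")
        env = alpha_power_envelope(np.asarray(source, float), rate, band, smooth)
    times = np.arange(len(env)) / rate
    if blocks.end > times[-1] + 1.0 / rate:
        raise ValueError("block design extends beyond the recording")
    closed = blocks.closed_mask(times)
    open_mask = np.zeros_like(closed)
    for a, b in blocks.open_intervals():
        open_mask |= (times >= a) & (times < b)
    ec, eo = env[closed], env[open_mask]
    n_c, n_o = len(ec), len(eo)
    pooled = np.sqrt(
        ((n_c - 1) * ec.var(ddof=1) + (n_o - 1) * eo.var(ddof=1)) / (n_c + n_o - 2)
    )
    return float((ec.mean() - eo.mean()) / max(pooled, 1e-24))
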