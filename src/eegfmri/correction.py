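"""MRI-induced EEG artifact correction cascade.

Implements, in pipeline order, each stage applied to EEG recorded during
fMRI: trigger estimation, gradient-artifact correction (sliding-window
average artifact subtraction followed by optimal-basis-set removal),
R-peak detection and k-means-clustered pulse-artifact template
subtraction, downsampling, adaptive reference-sensor regression for
motion artifacts, bandpass filtering, spherical-spline bad-channel
interpolation, average re-referencing, and criterion-based ICA denoising.
Each stage is separately callable and testable; the canonical order is
enforced through the recording's history (see :mod:`eegfmri.recording`).

All stages operate on a copy of the input recording and return the
corrected copy, so intermediate results can be kept for quality
evaluation after each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import eval_legendre
from sklearn.cluster import KMeans

from .recording import (
    ECG,
    R_PEAK,
    REFERENCE_SENSOR,
    SCALP,
    VOLUME_TRIGGER,
    EEGRecording,
)

__all__ = [
    "estimate_triggers",
    "aas_correct",
    "obs_correct",
    "detect_r_peaks",
    "kmeans_pa_correct",
    "downsample",
    "adaptive_reference_regression",
    "bandpass_filter",
    "interpolate_bad_channels",
    "rereference_average",
    "ica_denoise",
    "detect_saturation",
    "ComponentReport",
    "SaturationReport",
]


# ---------------------------------------------------------------------------
# trigger estimation
# ---------------------------------------------------------------------------


def estimate_triggers(
    rec: EEGRecording,
    period: float | None = None,
    max_missing_frac: float = 0.1,
    force: bool = False,
) -> tuple[EEGRecording, dict]:
    """Verify volume triggers against a periodic grid; repair deviations.

    Recorded triggers are fitted to ``t_k = a + b k`` by least squares
    (b = volume period); jittered triggers are snapped to the grid and
    missing ones inserted by periodic extrapolation.  Fails if more than
    ``max_missing_frac`` of the expected triggers are absent and no
    period was supplied.
    """
    rec = rec.copy()
    trig = rec.event_samples(VOLUME_TRIGGER).astype(float)
    if len(trig) < 2 and period is None:
        raise ValueError("need >= 2 volume triggers or an explicit period")
    if period is not None:
        p = period * rec.rate
    else:
        p = float(np.median(np.diff(trig)))
    # assign integer grid indices, then refine (a, b) by least squares
    k = np.round((trig - trig[0]) / p)
    for _ in range(3):
        A = np.column_stack([np.ones_like(k), k])
        (a, b), *_ = np.linalg.lstsq(A, trig, rcond=None)
        k = np.round((trig - a) / b)
    k = k.astype(int)
    k_full = np.arange(k.min(), k.max() + 1)
    missing = np.setdiff1d(k_full, k)
    frac_missing = len(missing) / len(k_full)
    if frac_missing > max_missing_frac and period is None:
        raise ValueError(
            f"{frac_missing:.0%} of triggers missing and no period supplied"
        )
    grid = np.round(a + b * k_full).astype(int)
    grid = grid[(grid >= 0) & (grid < rec.n_samples)]
    old = rec.event_samples(VOLUME_TRIGGER)
    n_moved = int(np.sum(np.abs(np.round(a + b * k) - trig) > 0.5))
    rec.drop_events(VOLUME_TRIGGER)
    rec.add_events(grid, VOLUME_TRIGGER)
    report = {
        "period_samples": float(b),
        "n_input": int(len(old)),
        "n_output": int(len(grid)),
        "n_inserted": int(len(missing)),
        "n_moved": n_moved,
    }
    rec.mark_stage("estimate_triggers", force=force)
    return rec, report


# ---------------------------------------------------------------------------
# gradient artifact: AAS + OBS
# ---------------------------------------------------------------------------


def _epoch_grid(rec: EEGRecording, level: str, excitations_per_volume: int | None):
    """Anchors and epoch length for volume- or slice-level epoching."""
    trig = rec.event_samples(VOLUME_TRIGGER)
    if len(trig) < 2:
        raise ValueError("volume triggers required")
    if level == "volume":
        anchors = trig
    elif level == "slice":
        if excitations_per_volume is None:
            raise ValueError("slice-level epoching needs excitations_per_volume")
        period = float(np.median(np.diff(trig))) / excitations_per_volume
        anchors = np.concatenate(
            [
                np.round(t + period * np.arange(excitations_per_volume))
                for t in trig
            ]
        ).astype(int)
    else:
        raise ValueError("level must be 'volume' or 'slice'")
    diffs = np.diff(anchors)
    length = int(np.round(np.median(diffs)))
    if np.any(np.abs(diffs - length) > 1):
        raise ValueError("epoch length varies by more than 1 sample")
    anchors = anchors[anchors + length <= rec.n_samples]
    return anchors, length


def aas_correct(
    rec: EEGRecording,
    level: str = "volume",
    window_k: int | None = 25,
    excitations_per_volume: int | None = None,
    exclude_self: bool = True,
    template_rank: int | None = None,
    force: bool = False,
) -> EEGRecording:
    """Average artifact subtraction over trigger-locked epochs.

    For each epoch the mean of the ``window_k`` nearest epochs (excluding
    the epoch itself by default) is subtracted as the artifact template;
    ``window_k=None`` uses all available epochs (the optimal template
    when the artifact does not drift over the run).  Samples outside the
    scan epochs are untouched.

    ``template_rank`` optionally projects each template onto its top
    spatial components before subtraction: the gradient artifact is
    driven by a handful of gradient axes and is spatially low-rank, so
    the projection suppresses the background noise frozen into the
    averaged template without touching the artifact.
    """
    rec = rec.copy()
    anchors, length = _epoch_grid(rec, level, excitations_per_volume)
    n_ep = len(anchors)
    if window_k is None:
        window_k = n_ep - 1 if exclude_self else n_ep
    if n_ep < window_k:
        raise ValueError(f"need >= {window_k} epochs, got {n_ep}")
    k = min(window_k, n_ep - 1 if exclude_self else n_ep)
    epochs = np.stack([rec.data[:, a : a + length] for a in anchors])  # ep x ch x s
    csum = np.concatenate(
        [np.zeros((1,) + epochs.shape[1:]), np.cumsum(epochs, axis=0)]
    )
    half = k // 2
    for i in range(n_ep):
        lo = max(0, min(i - half, n_ep - (k + (1 if exclude_self else 0))))
        hi = min(n_ep, lo + k + (1 if exclude_self else 0))
        total = csum[hi] - csum[lo]
        cnt = hi - lo
        if exclude_self and lo <= i < hi:
            total = total - epochs[i]
            cnt -= 1
        template = total / cnt
        if template_rank is not None:
            U, s, Vt = np.linalg.svd(template, full_matrices=False)
            r_keep = min(template_rank, len(s))
            template = (U[:, :r_keep] * s[:r_keep]) @ Vt[:r_keep]
        rec.data[:, anchors[i] : anchors[i] + length] -= template
    rec.mark_stage("aas", f"level={level},window_k={window_k}", force=force)
    return rec


def _ga_like(v: np.ndarray, comb_step: float) -> bool:
    """Does a basis waveform look like a gradient-artifact residual?

    Either its spectrum concentrates on the slice-frequency harmonic
    comb, or its energy concentrates in a few sharp lobes (as at volume
    boundaries).  Smooth broadband waveforms (pulse artifact, neural
    rhythms) match neither.
    """
    L = len(v)
    p = np.abs(np.fft.rfft(v)) ** 2
    tot = p[1:].sum() + 1e-24
    comb = 0.0
    step = comb_step
    k = step
    while k < len(p):
        j = int(round(k))
        comb += p[max(1, j - 1) : j + 2].sum()
        k += step
    if comb / tot > 0.5:
        return True
    # temporal concentration: energy fraction in the top-10% samples
    e = v**2
    top = np.sort(e)[::-1][: max(1, L // 10)].sum()
    return top / (e.sum() + 1e-24) > 0.6


def obs_correct(
    rec: EEGRecording,
    n_basis: int = 4,
    level: str = "volume",
    excitations_per_volume: int | None = None,
    artifact_gate: bool = False,
    force: bool = False,
) -> tuple[EEGRecording, dict]:
    """Optimal-basis-set removal of epoch-varying artifact residuals.

    Per channel, the principal components of the (mean-removed) residual
    epoch matrix are computed; the top ``n_basis`` components are fitted
    to and subtracted from each epoch.  ``n_basis = 0`` is the identity.

    With ``artifact_gate=True`` (requires ``excitations_per_volume``),
    only basis components that look like gradient-artifact residuals —
    spectra on the slice-frequency harmonic comb, or sharply
    concentrated lobes — are subtracted.  Ungated principal components
    of post-correction epochs are dominated by whatever is largest in
    the data (often the pulse artifact), and subtracting those erodes
    signal that later stages are designed to handle; the gate keeps the
    stage specific to its target.
    """
    rec = rec.copy()
    anchors, length = _epoch_grid(rec, level, excitations_per_volume)
    if n_basis >= length:
        raise ValueError("n_basis must be smaller than the epoch length")
    if artifact_gate and excitations_per_volume is None:
        raise ValueError("artifact_gate requires excitations_per_volume")
    # slice harmonics fall on periodogram bins spaced by the number of
    # excitations per epoch (volume-level epochs span one TR)
    comb_step = float(excitations_per_volume) if artifact_gate else 1.0
    var_explained: list[np.ndarray] = []
    n_gated = 0
    if n_basis > 0:
        for ch in range(rec.n_channels):
            E = np.stack([rec.data[ch, a : a + length] for a in anchors])
            mean = E.mean(axis=0)
            R = E - mean
            # principal directions of the residual epoch matrix
            _, s, Vt = np.linalg.svd(R, full_matrices=False)
            basis = Vt[:n_basis]  # n_basis x length, orthonormal
            if artifact_gate:
                keep = np.array([_ga_like(b, comb_step) for b in basis])
                n_gated += int((~keep).sum())
                basis = basis[keep]
            if len(basis):
                coef = R @ basis.T
                fit = coef @ basis
                for i, a in enumerate(anchors):
                    rec.data[ch, a : a + length] -= fit[i]
            tot = float(np.sum(s**2))
            var_explained.append(
                (s[:n_basis] ** 2) / tot if tot > 0 else np.zeros(n_basis)
            )
    report = {
        "n_basis": n_basis,
        "variance_explained": np.array(var_explained) if var_explained else None,
        "n_gated_out": n_gated,
    }
    rec.mark_stage("obs", f"n_basis={n_basis}", force=force)
    return rec, report


# ---------------------------------------------------------------------------
# cardiac: R-peak detection + k-means PA correction
# ---------------------------------------------------------------------------


def detect_r_peaks(
    rec: EEGRecording,
    true_peaks: np.ndarray | None = None,
    match_tol: float = 0.02,
    refractory: float = 0.3,
    force: bool = False,
) -> tuple[EEGRecording, dict]:
    """Detect R-peaks on the ECG channel and append ``r_peak`` events.

    Algorithm: 5-30 Hz bandpass, squared derivative, 150 ms moving-window
    integration, adaptive threshold with a 300 ms refractory period; each
    detection is refined to the local extremum of the bandpassed ECG.
    When ground-truth peaks are supplied, sensitivity and precision
    against them (within ``match_tol`` seconds) are reported.
    """
    rec = rec.copy()
    ecg_idx = rec.picks(ECG)
    if len(ecg_idx) == 0:
        raise ValueError("no channel with role 'ecg'")
    x = rec.data[ecg_idx[0]]
    fs = rec.rate
    sos = signal.butter(4, [5.0, min(30.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    d = np.gradient(bp)
    sq = d * d
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    peak_level = np.quantile(integ, 0.995)
    if peak_level <= 1e-12 or bp.std() < 1e-9:
        warnings.warn("flat or near-flat ECG: no R-peaks detected")
        rec.mark_stage("detect_r_peaks", force=force)
        return rec, {"n_peaks": 0}
    thr = 0.25 * peak_level
    locs, _ = signal.find_peaks(integ, height=thr, distance=int(refractory * fs))
    if len(locs) == 0:
        warnings.warn("no R-peaks detected")
        rec.mark_stage("detect_r_peaks", force=force)
        return rec, {"n_peaks": 0}
    # refine to the dominant extremum of the bandpassed ECG
    half = int(round(0.05 * fs))
    refined = []
    sign = np.sign(bp[locs][np.argmax(np.abs(bp[locs]))]) or 1.0
    for p in locs:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(sign * bp[lo:hi])))
    peaks = np.unique(refined)
    rec.drop_events(R_PEAK)
    rec.add_events(peaks, R_PEAK)
    report: dict = {"n_peaks": int(len(peaks))}
    if true_peaks is not None and len(true_peaks):
        tol = match_tol * fs
        hits = sum(np.min(np.abs(peaks - t)) <= tol for t in true_peaks) if len(peaks) else 0
        report["sensitivity"] = hits / len(true_peaks)
        report["precision"] = (
            sum(np.min(np.abs(true_peaks - p)) <= tol for p in peaks) / len(peaks)
            if len(peaks)
            else 0.0
        )
    rec.mark_stage("detect_r_peaks", force=force)
    return rec, report


def kmeans_pa_correct(
    rec: EEGRecording,
    k: int = 5,
    window: tuple[float, float] = (-0.25, 0.75),
    template_rank: int | None = 3,
    joint_scale: bool = True,
    random_state: int = 0,
    force: bool = False,
) -> tuple[EEGRecording, dict]:
    """Pulse-artifact correction by k-means-clustered template subtraction.

    Epochs around R-peaks are baseline-removed (per-channel demeaned) and
    clustered by k-means on the channel-concatenated epoch vectors; each
    epoch is corrected by subtracting its cluster-mean template scaled by
    a least-squares fit.  With ``k = 1`` this reduces to plain
    beat-averaged template subtraction.  Scalp and reference-sensor
    channels are both corrected (the sensors pick up the
    ballistocardiogram too); clustering uses the scalp channels.

    Robustness choices (each stated here because it shapes what is
    subtracted): clustering and scale fitting use >8 Hz content, so
    slow residual drifts neither drive the beat-shape assignment nor
    bias the fitted amplitude; the scale is fitted jointly across
    channels by default (beat-strength variation is global, and a common
    scale keeps the subtraction spatially coherent for the later
    reference-sensor regression); templates are reduced to
    ``template_rank`` spatial components (the ballistocardiogram has a
    low-rank scalp distribution), which suppresses background noise
    frozen into the cluster means.
    """
    rec = rec.copy()
    peaks = rec.event_samples(R_PEAK)
    fs = rec.rate
    pre = int(round(window[0] * fs))
    post = int(round(window[1] * fs))
    length = post - pre
    scalp = np.concatenate([rec.scalp_picks, rec.picks(REFERENCE_SENSOR)])
    n_scalp_only = rec.n_scalp
    anchors = [p for p in peaks if p + pre >= 0 and p + pre + length <= rec.n_samples]
    n_ep = len(anchors)
    if n_ep < k:
        raise ValueError(f"fewer epochs ({n_ep}) than clusters ({k})")
    epochs = np.stack([rec.data[scalp, p + pre : p + pre + length] for p in anchors])
    means = epochs.mean(axis=2)  # ep x ch (per-epoch baselines)
    demeaned = epochs - means[..., None]
    hp_lo = min(8.0, 0.2 * fs)
    sos = signal.butter(4, hp_lo, btype="highpass", fs=fs, output="sos")
    hp = signal.sosfiltfilt(sos, rec.data[scalp], axis=1)
    hp_epochs = np.stack([hp[:, p + pre : p + pre + length] for p in anchors])
    if k == 1:
        assign = np.zeros(n_ep, dtype=int)
    else:
        feats = hp_epochs[:, :n_scalp_only].reshape(n_ep, -1)
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        assign = km.fit_predict(feats)
    templates = np.stack(
        [demeaned[assign == c].mean(axis=0) for c in range(k)]
    )  # k x ch x samp
    if template_rank is not None:
        for c in range(k):
            U, s, Vt = np.linalg.svd(templates[c], full_matrices=False)
            r_keep = min(template_rank, len(s))
            templates[c] = (U[:, :r_keep] * s[:r_keep]) @ Vt[:r_keep]
    # split-half reliability: a template estimated from background noise
    # alone is uncorrelated between epoch halves and is shrunk toward
    # zero, so the null case (no beat-locked artifact) subtracts nothing
    for c in range(k):
        idx = np.flatnonzero(assign == c)
        if len(idx) >= 4:
            t1 = demeaned[idx[::2]].mean(axis=0).ravel()
            t2 = demeaned[idx[1::2]].mean(axis=0).ravel()
            denom = np.linalg.norm(t1) * np.linalg.norm(t2)
            rho = float(t1 @ t2 / denom) if denom > 0 else 0.0
            templates[c] *= np.clip(rho, 0.0, 1.0)
    tmpl_hp = np.stack([hp_epochs[assign == c].mean(axis=0) for c in range(k)])
    scales = np.zeros((n_ep, len(scalp)))
    if joint_scale:
        den = np.sum(tmpl_hp[assign] ** 2, axis=(1, 2))
        num = np.sum(hp_epochs * tmpl_hp[assign], axis=(1, 2))
        sj = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
        # empirical-Bayes shrinkage toward the cluster-mean amplitude:
        # the fit-noise variance is estimated by a split-half fit, so
        # when the beat amplitude is stable the fitted scales collapse
        # to 1 instead of injecting fit noise
        half = length // 2
        d1 = np.sum(tmpl_hp[assign][..., :half] ** 2, axis=(1, 2))
        d2 = np.sum(tmpl_hp[assign][..., half:] ** 2, axis=(1, 2))
        n1 = np.sum(hp_epochs[..., :half] * tmpl_hp[assign][..., :half], axis=(1, 2))
        n2 = np.sum(hp_epochs[..., half:] * tmpl_hp[assign][..., half:], axis=(1, 2))
        ok = (d1 > 1e-12) & (d2 > 1e-12)
        if ok.any() and sj[ok].size > 3:
            s1 = n1[ok] / d1[ok]
            s2 = n2[ok] / d2[ok]
            noise_var = np.var(s1 - s2) / 4.0
            obs_var = max(np.var(sj[ok]), 1e-12)
            lam = max(0.0, 1.0 - noise_var / obs_var)
        else:
            lam = 1.0
        sj = 1.0 + lam * (sj - 1.0)
        scales[:] = sj[:, None]
    else:
        den = np.sum(tmpl_hp[assign] ** 2, axis=2)
        num = np.sum(hp_epochs * tmpl_hp[assign], axis=2)
        scales = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    for i, p in enumerate(anchors):
        rec.data[scalp, p + pre : p + pre + length] -= (
            scales[i][:, None] * templates[assign[i]]
        )
    report = {
        "assignments": assign,
        "anchors": np.array(anchors),
        "templates": templates,
        "k": k,
    }
    rec.mark_stage("kmeans_pa", f"k={k}", force=force)
    return rec, report


# ---------------------------------------------------------------------------
# downsampling, regression, filtering
# ---------------------------------------------------------------------------


def downsample(rec: EEGRecording, target_rate: float, force: bool = False) -> EEGRecording:
    """Anti-aliased downsampling; events re-indexed to the nearest sample.

    A zero-phase low-pass at 0.4 x target rate precedes decimation; for
    non-integer ratios polyphase resampling is used.
    """
    if target_rate > rec.rate:
        raise ValueError("target rate above current rate")
    if target_rate == rec.rate:
        return rec.copy()
    rec = rec.copy()
    ratio = rec.rate / target_rate
    sos = signal.butter(8, 0.4 * target_rate, btype="lowpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        newdata = filtered[:, ::q]
    else:
        from fractions import Fraction

        frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
        newdata = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    n_new = newdata.shape[1]
    scale = target_rate / rec.rate
    rec.events = [
        (min(int(round(s * scale)), n_new - 1), t) for s, t in rec.events
    ]
    rec.data = newdata
    rec.rate = float(target_rate)
    rec.mark_stage("downsample", f"to={target_rate}", force=force)
    return rec


def adaptive_reference_regression(
    rec: EEGRecording,
    window_len: float = 10.0,
    ridge: float = 1e-6,
    overlap: float = 0.5,
    drift_order: int = 1,
    force: bool = False,
) -> EEGRecording:
    """Sliding-window ridge regression of reference-sensor channels.

    In overlapping Hann-weighted windows (default 10 s, 50 % overlap),
    each scalp channel is fitted on the reference channels by ridge least
    squares and the fit subtracted; overlapping window estimates are
    recombined with Hann weights.  ``drift_order`` adds copies of the
    reference channels modulated by powers of a centered time ramp,
    letting the fit track slow within-window changes of the mixing.
    Reference channels are retained but marked consumed.  ``ridge``
    scales the mean diagonal of the windowed Gram matrix.
    """
    rec = rec.copy()
    refs = rec.picks(REFERENCE_SENSOR)
    if len(refs) == 0:
        raise ValueError("no reference-sensor channels")
    scalp = rec.scalp_picks
    fs = rec.rate
    L = int(round(window_len * fs))
    if L < 10 * len(refs):
        raise ValueError("window too short for the number of reference channels")
    n = rec.n_samples
    L = min(L, n)
    hop = max(1, int(round(L * (1 - overlap))))
    starts = list(range(0, max(n - L, 0) + 1, hop))
    if starts[-1] != n - L:
        starts.append(n - L)
    w = signal.windows.hann(L, sym=False)
    ramp = np.linspace(-1.0, 1.0, L)
    est_num = np.zeros((len(scalp), n))
    den = np.zeros(n)
    # pre-clean narrowband environment peaks from the regressors: the
    # sensors pick them up too, and coherent sinusoids in the regressors
    # bias the motion-artifact fit (scalp EA is left for the ICA stage)
    R_all = rec.data[refs].copy()
    peak_freqs: list[float] = []
    for row in R_all:
        # low threshold: sensor spectra are dominated by the motion
        # processes, so even strong peaks are a small power fraction
        peak_freqs.extend(_narrow_peaks(row, fs, min_fraction=0.002))
    peak_freqs = _merge_freqs(peak_freqs)
    if peak_freqs:
        t_full = np.arange(n) / fs
        basis = np.concatenate(
            [
                np.stack(
                    [np.sin(2 * np.pi * f * t_full), np.cos(2 * np.pi * f * t_full)]
                )
                for f in peak_freqs
            ]
        )
        Q, _ = np.linalg.qr(basis.T)
        R_all -= (R_all @ Q) @ Q.T
    Y_all = rec.data[scalp]
    n_reg = len(refs) * (drift_order + 1)
    for s0 in starts:
        sl = slice(s0, s0 + L)
        R = np.concatenate(
            [R_all[:, sl] * ramp[None, :] ** d for d in range(drift_order + 1)]
        )
        Rm = R - R.mean(axis=1, keepdims=True)
        Y = Y_all[:, sl]
        Ym = Y.mean(axis=1, keepdims=True)
        G = Rm @ Rm.T
        tr_g = np.trace(G)
        if tr_g < 1e-20:  # silent reference channels: nothing to regress
            den[sl] += w
            continue
        lam = ridge * tr_g / n_reg
        coef = np.linalg.solve(G + lam * np.eye(n_reg), Rm @ (Y - Ym).T)
        fit = coef.T @ R  # raw refs: removes the artifact's in-window mean too
        est_num[:, sl] += fit * w
        den[sl] += w
    # where a single tapered window contributes, (fit*w)/w == fit; guard w=0
    safe = den > 1e-12
    correction = np.zeros_like(est_num)
    correction[:, safe] = est_num[:, safe] / den[safe]
    if not np.all(safe):
        # fall back to the nearest covered sample (affects isolated endpoints)
        idx = np.where(safe)[0]
        for j in np.where(~safe)[0]:
            correction[:, j] = correction[:, idx[np.argmin(np.abs(idx - j))]]
    rec.data[scalp] -= correction
    rec.mark_stage(
        "reference_regression", f"window={window_len}s,ridge={ridge}", force=force
    )
    return rec


def bandpass_filter(
    rec: EEGRecording,
    lo: float = 0.75,
    hi: float = 70.0,
    order: int = 4,
    force: bool = False,
) -> EEGRecording:
    """Zero-phase Butterworth bandpass (forward-backward, order 4)."""
    if lo >= hi:
        raise ValueError("lo must be below hi")
    if hi >= rec.rate / 2:
        raise ValueError("hi must be below Nyquist")
    rec = rec.copy()
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    rec.data = signal.sosfiltfilt(sos, rec.data, axis=1)
    rec.mark_stage("bandpass", f"{lo}-{hi}Hz", force=force)
    return rec


# ---------------------------------------------------------------------------
# spherical-spline interpolation, re-referencing
# ---------------------------------------------------------------------------


def _g_legendre(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos) as a truncated Legendre series."""
    out = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * eval_legendre(n, cosang)
    return out / (4 * np.pi)


def interpolate_bad_channels(
    rec: EEGRecording,
    m: int = 4,
    reg: float = 1e-5,
    n_terms: int = 50,
    max_bad_frac: float = 0.2,
    force: bool = False,
) -> EEGRecording:
    """Replace bad scalp channels by spherical-spline interpolation.

    Uses the thin-plate spline on the sphere (order ``m = 4``,
    regularization 1e-5) fitted on the good scalp channels; the bad set
    is cleared afterwards and the originals noted in the history.  The
    interpolated values never depend on the bad channels' own data.
    """
    rec = rec.copy()
    if not rec.bad_channels:
        rec.mark_stage("interpolate_bad", "none", force=force)
        return rec
    if rec.montage is None:
        raise ValueError("montage required for interpolation")
    scalp = rec.scalp_picks
    labels = [rec.labels[i] for i in scalp]
    bad_mask = np.array([rec.labels[i] in rec.bad_channels for i in scalp])
    if bad_mask.mean() > max_bad_frac:
        raise ValueError("more than 20% of scalp channels marked bad")
    good = scalp[~bad_mask]
    bad = scalp[bad_mask]
    pos = rec.montage
    pg = pos[good] / np.linalg.norm(pos[good], axis=1, keepdims=True)
    pb = pos[bad] / np.linalg.norm(pos[bad], axis=1, keepdims=True)
    G = _g_legendre(np.clip(pg @ pg.T, -1, 1), m, n_terms)
    Gb = _g_legendre(np.clip(pb @ pg.T, -1, 1), m, n_terms)
    ng = len(good)
    C = np.zeros((ng + 1, ng + 1))
    C[:ng, :ng] = G + reg * np.eye(ng)
    C[:ng, ng] = 1.0
    C[ng, :ng] = 1.0
    rhs = np.vstack([rec.data[good], np.zeros((1, rec.n_samples))])
    sol = np.linalg.solve(C, rhs)
    rec.data[bad] = Gb @ sol[:ng] + sol[ng]
    interpolated = sorted(rec.bad_channels)
    rec.bad_channels = set()
    rec.mark_stage("interpolate_bad", ",".join(interpolated), force=force)
    return rec


def rereference_average(rec: EEGRecording, force: bool = False) -> EEGRecording:
    """Subtract the scalp-channel mean at every sample (average reference)."""
    rec = rec.copy()
    scalp = rec.scalp_picks
    if len(scalp) < 2:
        raise ValueError("need >= 2 scalp channels")
    rec.data[scalp] -= rec.data[scalp].mean(axis=0, keepdims=True)
    rec.reference = "average"
    rec.mark_stage("rereference", force=force)
    return rec


# ---------------------------------------------------------------------------
# ICA denoising
# ---------------------------------------------------------------------------


@dataclass
class ComponentReport:
    """Per-component flags and criterion scores from ICA denoising."""

    topographies: np.ndarray  # channels x components
    flags: list[str] = field(default_factory=list)
    scores: list[dict] = field(default_factory=list)
    removed: list[int] = field(default_factory=list)
    ea_frequencies: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.topographies.shape[1]

    @property
    def retained(self) -> list[int]:
        return [i for i in range(self.n_components) if i not in self.removed]


DEFAULT_ICA_CRITERIA = {
    "ga_comb_ratio": 0.5,  # power fraction at slice-frequency multiples
    "ea_bin_fraction": 0.80,  # single-bin concentration vs +-2 Hz neighborhood
    "pa_consistency": 0.5,  # R-peak-locked epoch phase locking
    "eye_frontal_loading": 0.40,
    "eye_lowfreq_fraction": 0.55,
    "muscle_highfreq_fraction": 0.70,
    "muscle_edge_fraction": 0.60,
}


def _psd(x: np.ndarray, fs: float):
    nper = int(min(len(x), 4 * fs))
    return signal.welch(x, fs=fs, nperseg=nper)


def _score_component(
    src: np.ndarray,
    topo: np.ndarray,
    rec: EEGRecording,
    criteria: dict,
    slice_freq: float | None,
) -> tuple[str, dict]:
    fs = rec.rate
    freqs, p = _psd(src, fs)
    tot = p[freqs > 0.5].sum() + 1e-24
    scores: dict = {}
    # GA residual: harmonic comb at multiples of the slice frequency
    if slice_freq is not None and slice_freq < fs / 2:
        comb = 0.0
        f = slice_freq
        while f < fs / 2:
            comb += p[(freqs > f - 0.4) & (freqs < f + 0.4)].sum()
            f += slice_freq
        scores["ga_comb_ratio"] = comb / tot
    # EA: single-bin concentration, judged against the +-2 Hz neighborhood
    # (a coherent sinusoid is one bin wide; band-limited neural rhythms
    # spread over many bins)
    ea_score = 0.0
    locs, _ = signal.find_peaks(p)
    for i in locs:
        if freqs[i] < 1.0:
            continue
        peak = p[max(0, i - 1) : i + 2].sum()
        local = p[np.abs(freqs - freqs[i]) < 2.0].sum() + 1e-24
        if peak / tot >= 0.08:
            ea_score = max(ea_score, peak / local)
    scores["ea_bin_fraction"] = float(ea_score)
    # PA residual: R-peak-locked consistency (variance of mean epoch / mean variance)
    peaks = rec.event_samples(R_PEAK)
    if len(peaks) >= 5:
        half = int(0.3 * fs)
        eps = [
            src[pk - half : pk + half]
            for pk in peaks
            if pk - half >= 0 and pk + half <= len(src)
        ]
        if len(eps) >= 5:
            E = np.stack(eps)
            scores["pa_consistency"] = float(
                E.mean(axis=0).var() / max(E.var(axis=1).mean(), 1e-24)
            )
    # eye: frontal-pole loading + sub-4 Hz dominance
    scalp_pos = rec.scalp_montage()
    absw = np.abs(topo) + 1e-24
    frontal = scalp_pos[:, 1] > 0.6
    scores["eye_frontal_loading"] = float(absw[frontal].sum() / absw.sum())
    scores["eye_lowfreq_fraction"] = float(p[freqs < 4.0].sum() / (p.sum() + 1e-24))
    # muscle: high-frequency dominance + focal edge topography
    scores["muscle_highfreq_fraction"] = float(p[freqs > 20.0].sum() / (p.sum() + 1e-24))
    edge = scalp_pos[:, 2] < 0.3
    scores["muscle_edge_fraction"] = (
        float(absw[edge].sum() / absw.sum()) if edge.any() else 0.0
    )

    flag = "neural"
    if scores.get("ga_comb_ratio", 0.0) > criteria["ga_comb_ratio"]:
        flag = "ga_residual"
    elif scores["ea_bin_fraction"] > criteria["ea_bin_fraction"]:
        flag = "ea"
    elif scores.get("pa_consistency", 0.0) > criteria["pa_consistency"]:
        flag = "pa_residual"
    elif (
        scores["eye_frontal_loading"] > criteria["eye_frontal_loading"]
        and scores["eye_lowfreq_fraction"] > criteria["eye_lowfreq_fraction"]
    ):
        flag = "eye"
    elif (
        scores["muscle_highfreq_fraction"] > criteria["muscle_highfreq_fraction"]
        and scores["muscle_edge_fraction"] > criteria["muscle_edge_fraction"]
    ):
        flag = "muscle"
    return flag, scores


def ica_denoise(
    rec: EEGRecording,
    n_components: int | None = None,
    criteria: dict | None = None,
    slice_freq: float | None = None,
    random_state: int = 0,
    fit_samples: int = 6000,
    force: bool = False,
) -> tuple[EEGRecording, ComponentReport]:
    """Extended-Infomax ICA denoising with automatic component criteria.

    Components are flagged as GA residual (harmonic comb at slice-
    frequency multiples), environment peak (single-bin concentration),
    PA residual (R-peak-locked consistency), eye (frontal loading plus
    sub-4 Hz dominance) or muscle (high-frequency power plus focal edge
    topography); flagged components are zeroed and the scalp data
    reconstructed.  Flags are mutually exclusive by the priority order
    GA > EA > PA > eye > muscle.
    """
    from mne.preprocessing import infomax

    rec = rec.copy()
    crit = dict(DEFAULT_ICA_CRITERIA)
    if criteria:
        crit.update(criteria)
    scalp = rec.scalp_picks
    X = rec.data[scalp]
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    n_comp = n_components if n_components is not None else len(scalp) - 1
    n_comp = min(n_comp, len(scalp), rec.n_samples)
    # PCA whitening
    U, s, _ = np.linalg.svd(Xc @ Xc.T / Xc.shape[1])
    keep = s[:n_comp] > 1e-15 * s[0]
    n_comp = int(keep.sum())
    W_white = (U[:, :n_comp] / np.sqrt(s[:n_comp])).T  # n_comp x n_ch
    Z = W_white @ Xc  # whitened, n_comp x t
    # the unmixing matrix is estimated on an even subsample (infomax cost
    # grows steeply with sample count); sources are then computed in full
    step = max(1, Z.shape[1] // fit_samples)
    try:
        unmix = infomax(
            Z[:, ::step].T,
            extended=True,
            rng=np.random.default_rng(random_state),
            max_iter=500,
            verbose="error",
        )
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"ICA failed to converge: {err}") from None
    sources = unmix @ Z  # n_comp x t
    # mixing back to channel space (least squares; sources span Z exactly)
    A = Xc @ sources.T @ np.linalg.pinv(sources @ sources.T)  # ch x comp

    flags, scores, removed = [], [], []
    for j in range(n_comp):
        flag, sc = _score_component(sources[j], A[:, j], rec, crit, slice_freq)
        flags.append(flag)
        scores.append(sc)
        # EA-flagged components are not zeroed: they identify the
        # interference frequencies, and the exact sinusoid projection
        # below removes the peak without the neural content that rides
        # the same component
        if flag not in ("neural", "ea"):
            removed.append(j)
    kept = np.ones(n_comp, dtype=bool)
    kept[removed] = False
    recon = A[:, kept] @ sources[kept] + mean
    residual = Xc - (A @ sources)  # variance outside the retained subspace
    rec.data[scalp] = recon + residual

    # environment peaks are coherent sinusoids; component zeroing leaves
    # the part smeared into other components.  The flagged components
    # identify the interference frequencies; the exact sin/cos pair at
    # each is then projected out of every scalp channel (a 2-dof removal
    # per frequency over the whole recording).
    ea_freqs: list[float] = []
    for j, flag in enumerate(flags):
        if flag == "ea":
            ea_freqs.extend(_narrow_peaks(sources[j], rec.rate))
    ea_freqs = _merge_freqs(ea_freqs)
    if ea_freqs:
        t = np.arange(rec.n_samples) / rec.rate
        basis = np.concatenate(
            [
                np.stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
                for f in ea_freqs
            ]
        )
        Q, _ = np.linalg.qr(basis.T)
        rec.data[scalp] -= (rec.data[scalp] @ Q) @ Q.T

    report = ComponentReport(
        topographies=A,
        flags=flags,
        scores=scores,
        removed=removed,
        ea_frequencies=ea_freqs,
    )
    rec.mark_stage("ica", f"n={n_comp},removed={len(removed)}", force=force)
    return rec, report


def _narrow_peaks(
    src: np.ndarray, fs: float, local_ratio: float = 0.7, min_fraction: float = 0.01
) -> list[float]:
    """Frequencies of single-bin spectral peaks in a component source.

    Candidate bins concentrate most of their +-2 Hz neighborhood in a
    3-bin peak; each is refined by quadratic interpolation on the
    full-length Hann periodogram (precision well below one bin, needed
    for exact sinusoidal regression over long recordings).
    """
    freqs, p = _psd(src, fs)
    tot = p[freqs > 0.5].sum() + 1e-24
    out = []
    locs, _ = signal.find_peaks(p)
    n = len(src)
    win = signal.windows.hann(n)
    spec = None
    for i in locs:
        if freqs[i] < 1.0:
            continue
        peak = p[max(0, i - 1) : i + 2].sum()
        local = p[np.abs(freqs - freqs[i]) < 2.0].sum() + 1e-24
        if peak / local < local_ratio or peak / tot < min_fraction:
            continue
        if spec is None:
            spec = np.abs(np.fft.rfft(src * win))
            ffull = np.fft.rfftfreq(n, 1.0 / fs)
        j = np.argmin(np.abs(ffull - freqs[i]))
        j0 = max(1, min(j, len(spec) - 2))
        j0 = j0 - 1 + int(np.argmax(spec[j0 - 1 : j0 + 2]))
        a, b, c = np.log(spec[j0 - 1 : j0 + 2] + 1e-30)
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if abs(denom) > 1e-12 else 0.0
        out.append(float(ffull[j0] + delta * (ffull[1] - ffull[0])))
    return out


def _merge_freqs(freqs: list[float], tol: float = 0.05) -> list[float]:
    merged: list[float] = []
    for f in sorted(freqs):
        if merged and f - merged[-1] < tol:
            merged[-1] = 0.5 * (merged[-1] + f)
        else:
            merged.append(f)
    return merged


# ---------------------------------------------------------------------------
# saturation check
# ---------------------------------------------------------------------------


@dataclass
class SaturationReport:
    """Per-channel clipping fractions and segments at the amplitude rails."""

    rail: float
    fractions: dict[str, float]
    segments: dict[str, list[tuple[int, int]]]

    @property
    def any_saturated(self) -> bool:
        return any(f > 0 for f in self.fractions.values())


def detect_saturation(
    rec: EEGRecording, rail: float, tol: float = 1e-9
) -> SaturationReport:
    """Report samples pinned at +/- rail microvolts, per channel.

    Consecutive clipped samples are collapsed into ``(start, stop)``
    segments (stop exclusive).  Intended for the raw, pre-correction
    recording.
    """
    fractions: dict[str, float] = {}
    segments: dict[str, list[tuple[int, int]]] = {}
    for i, lab in enumerate(rec.labels):
        clipped = np.abs(rec.data[i]) >= rail - tol
        fractions[lab] = float(clipped.mean())
        segs: list[tuple[int, int]] = []
        if clipped.any():
            edges = np.flatnonzero(np.diff(clipped.astype(np.int8)))
            starts = [0] if clipped[0] else []
            starts += list(edges[~clipped[edges]] + 1)
            stops = list(edges[clipped[edges]] + 1)
            if clipped[-1]:
                stops.append(len(clipped))
            segs = list(zip(starts, stops))
        segments[lab] = segs
    return SaturationReport(rail=rail, fractions=fractions, segments=segments)
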