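"""Shared fixtures: reduced-scale synthetic sessions and cascade runs.

The heavy fixtures are session-scoped so the contaminated session and
the full correction cascade are simulated once and reused by every test
that needs them.  Test scale: 1 kHz EEG (vs 5 kHz in a real session),
24 scalp channels, 360-volume 1.6 mm-geometry protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegfmri import correction as cx
from eegfmri.recording import SCALP, EEGRecording, spherical_montage
from eegfmri.simulate import (
    BlockDesign,
    ProtocolSpec,
    SimulationConfig,
    simulate_eeg,
)

TEST_PROTOCOL = ProtocolSpec(1.05, 360, 21, eeg_rate=1000.0, label="1.6mm-test")


def small_protocol(n_volumes=60, rate=1000.0):
    return ProtocolSpec(1.05, n_volumes, 21, eeg_rate=rate)


@pytest.fixture(scope="session")
def full_session():
    """Fully contaminated session at test scale, with ground truth."""
    cfg = SimulationConfig(
        protocol=TEST_PROTOCOL,
        n_scalp_channels=24,
        seed=0,
        alpha_block=BlockDesign(),
        ma_mixing_period=30.0,
    )
    rec, gt = simulate_eeg(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def corrected_session(full_session):
    """The complete correction cascade applied to the contaminated session."""
    cfg, rec, gt = full_session
    prot = cfg.protocol
    stages = {}
    r, trig_report = cx.estimate_triggers(rec)
    r = cx.aas_correct(r, window_k=None, template_rank=6)
    stages["aas"] = r
    r, _ = cx.obs_correct(
        r, n_basis=4, excitations_per_volume=prot.excitations_per_volume,
        artifact_gate=True,
    )
    stages["obs"] = r
    r, rpeak_report = cx.detect_r_peaks(r, true_peaks=gt.r_peak_samples)
    r, pa_report = cx.kmeans_pa_correct(r, k=5)
    stages["kmeans_pa"] = r
    r = cx.downsample(r, 200.0)
    r = cx.adaptive_reference_regression(r, drift_order=2)
    stages["reference_regression"] = r
    r = cx.bandpass_filter(r)
    r = cx.rereference_average(r)
    stages["rereference"] = r
    r, ica_report = cx.ica_denoise(r, slice_freq=prot.slice_freq)
    stages["ica"] = r
    reports = {
        "triggers": trig_report,
        "r_peaks": rpeak_report,
        "pa": pa_report,
        "ica": ica_report,
    }
    return r, stages, reports


@pytest.fixture(scope="session")
def clean_reference(full_session):
    """Stored clean EEG processed like the corrected output (200 Hz,
    0.75-70 Hz, average reference)."""
    cfg, _, gt = full_session
    n = gt.clean_eeg.shape[0]
    cl = EEGRecording(
        gt.clean_eeg.copy(),
        cfg.eeg_rate,
        [f"EEG{i + 1:03d}" for i in range(n)],
        [SCALP] * n,
        montage=spherical_montage(n),
    )
    cl = cx.downsample(cl, 200.0, force=True)
    cl = cx.bandpass_filter(cl, force=True)
    cl = cx.rereference_average(cl, force=True)
    return cl


def make_recording(data, rate=1000.0, montage=True, roles=None):
    n = data.shape[0]
    return EEGRecording(
        data=data,
        rate=rate,
        labels=[f"E{i}" for i in range(n)],
        roles=roles or [SCALP] * n,
        montage=spherical_montage(n) if montage else None,
    )
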