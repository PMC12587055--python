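"""Generate a synthetic EEG-fMRI session and write it to standard formats.

Builds a short contaminated EEG recording (gradient, pulse, motion and
environment artifacts over a 1/f + alpha + microstate background) plus a
matching fMRI series, and writes BrainVision / NIfTI files.  The printed
numbers show how far the artifacts sit above the neural signal.
"""

import os

import numpy as np

from eegfmri import io as fio
from eegfmri.simulate import (
    FMRISimConfig,
    ProtocolSpec,
    SimulationConfig,
    gen_fmri_series,
    simulate_eeg,
)

cfg = SimulationConfig(
    protocol=ProtocolSpec(1.05, 60, 21, eeg_rate=1000.0),
    n_scalp_channels=24,
    seed=0,
)
rec, gt = simulate_eeg(cfg)
print(f"EEG: {rec.n_channels} channels x {rec.n_samples} samples at {rec.rate:g} Hz")
print(f"  clean neural RMS : {gt.clean_eeg.std():7.1f} uV")
for name, comp in gt.components.items():
    print(f"  {name.upper():>3} artifact RMS : {comp[:cfg.n_scalp_channels].std():7.1f} uV")
print(f"  planted R-peaks  : {len(gt.r_peak_samples)}")

vol, parc, fgt = gen_fmri_series(FMRISimConfig(n_volumes=80, seed=1))
print(f"fMRI: {vol.shape3d} voxels x {vol.n_frames} frames, TR {vol.tr} s")
print(f"  background sigma (truth): {fgt.background_sigma}")

out = os.path.join(os.path.dirname(__file__), "output")
os.makedirs(out, exist_ok=True)
fio.write_brainvision(rec, os.path.join(out, "session"))
fio.write_nifti(vol, os.path.join(out, "bold.nii.gz"))
fio.write_parcellation(parc, os.path.join(out, "parcellation.nii.gz"))
print(f"written to {out}/")
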