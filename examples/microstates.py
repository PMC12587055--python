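"""Microstate analysis: fit 4 topographies, label them A-D, back-fit.

The generator plants a 4-state Markov topography sequence; the analysis
recovers the maps by polarity-invariant clustering of the GFP-peak maps,
labels them by similarity to idealized canonical templates, and reports
duration / occurrence / coverage from the back-fitted label sequence.
"""

import numpy as np

from eegfmri import correction as cx
from eegfmri import quality_eeg as qe
from eegfmri.simulate import ProtocolSpec, SimulationConfig, gen_clean_eeg

cfg = SimulationConfig(
    protocol=ProtocolSpec(1.05, 280, 21, eeg_rate=200.0),
    n_scalp_channels=24, seed=6, duration=294.0,
    ga_amplitude=0, ga_volume_amplitude=0, pa_amplitude=0, ea_amplitude=0,
    ma_amplitude=0, noise_1f_scale=0.5, microstate_amplitude=6.0,
    alpha_amplitude=0,
)
rec, gt = gen_clean_eeg(cfg)
rec = cx.rereference_average(rec, force=True)
rec = cx.bandpass_filter(rec, 1.0, 40.0, force=True)

model = qe.fit_microstates(rec, k=4, seed=0)
model = qe.match_canonical(model, montage=rec.montage[rec.scalp_picks])
print(f"global explained variance of the 4-state model: {model.gev:.3f}")
C = np.abs(model.topographies @ gt.microstate_maps.T)
print("best |spatial corr| of each fitted map with a planted map:",
      np.round(C.max(axis=1), 3))
labels = qe.backfit(rec, model)
metrics = qe.microstate_metrics(labels, rec.rate, k=model.k)
table = metrics.table.copy()
table.index = [model.canonical_assignment[i] for i in table.index]
print(table.round(3))
print("coverages sum to", round(float(metrics.coverages().sum()), 6))
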