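"""MRI image-quality metrics over an ROI parcellation.

Heterogeneity is summarized as the full width at half maximum of the
within-ROI value distribution, FWHM = 2 sqrt(2 ln 2) x SD (optionally
normalized by the ROI mean, as used for transmit-field maps).  The
background noise SD is estimated Rician-aware from the background ROI:
local mean/STD/RMS statistics in a sliding cubic window classify
pure-noise windows by the Rayleigh mean/RMS ratio sqrt(pi/4), and sigma
is the mode over accepted windows of local RMS / sqrt(2), which is
robust to ghosting contamination.  Spatial SNR is ROI mean over
background sigma (frame-wise, then time-averaged for 4D); temporal SNR
is the voxelwise temporal mean over temporal SD averaged across an ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import Parcellation, VolumeSeries

__all__ = [
    "FWHM_FACTOR",
    "RAYLEIGH_MEAN_RMS",
    "roi_fwhm",
    "background_sigma",
    "spatial_snr",
    "temporal_snr",
    "QualityTable",
    "quality_table",
]

#: FWHM of a Gaussian in units of its SD.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: mean / RMS of a Rayleigh distribution: sqrt(pi/4).
RAYLEIGH_MEAN_RMS = float(np.sqrt(np.pi / 4.0))


def roi_fwhm(
    vol: VolumeSeries, parc: Parcellation, roi: int | str, normalized: bool = False
) -> float:
    """Heterogeneity of an ROI: 2 sqrt(2 ln 2) times the value SD.

    With ``normalized=True`` the FWHM is divided by the ROI mean (the
    convention for transmit-field maps, decoupling strength from
    heterogeneity).  Uses the first frame of a series.
    """
    parc.check_grid(vol)
    values = vol.frame(0)[parc.mask(roi)]
    if values.size < 2:
        raise ValueError("ROI smaller than 2 voxels: FWHM undefined")
    fwhm = FWHM_FACTOR * float(values.std(ddof=0))
    if normalized:
        mean = float(values.mean())
        if abs(mean) < 1e-24:
            raise ValueError("ROI mean is zero: normalized FWHM undefined")
        fwhm /= mean
    return fwhm


def background_sigma(
    vol: VolumeSeries,
    parc: Parcellation,
    window: int = 5,
    ratio_tol: float = 0.1,
    frame: int = 0,
) -> float:
    """Rician-aware noise SD from the background ROI.

    A cubic window slides over the background; windows whose local
    mean/RMS ratio is within ``ratio_tol`` of the Rayleigh value
    sqrt(pi/4) are classified pure-noise, and sigma is the mode (modal
    histogram bin center) of local RMS / sqrt(2) over those windows.
    Windows contaminated by ghosting fail the ratio gate and are
    excluded.  Falls back to the global RMS / sqrt(2) with a warning if
    no window passes.
    """
    parc.check_grid(vol)
    data = vol.frame(frame)
    bg = parc.mask(parc.background_label)
    if not bg.any():
        raise ValueError("empty background ROI")
    if float(data[bg].max()) < 1e-24:
        return 0.0
    w = window
    nx, ny, nz = data.shape
    sigmas = []
    for i in range(0, nx - w + 1, max(1, w // 2)):
        for j in range(0, ny - w + 1, max(1, w // 2)):
            for k in range(0, nz - w + 1, max(1, w // 2)):
                sub_bg = bg[i : i + w, j : j + w, k : k + w]
                if not sub_bg.all():
                    continue
                vals = data[i : i + w, j : j + w, k : k + w].ravel()
                rms = np.sqrt(np.mean(vals**2))
                if rms < 1e-24:
                    continue
                ratio = vals.mean() / rms
                if abs(ratio - RAYLEIGH_MEAN_RMS) <= ratio_tol:
                    sigmas.append(rms / np.sqrt(2.0))
    if not sigmas:
        warnings.warn("no pure-noise background window found; using global RMS")
        vals = data[bg]
        return float(np.sqrt(np.mean(vals**2)) / np.sqrt(2.0))
    sigmas = np.asarray(sigmas)
    if len(sigmas) < 5:
        return float(np.median(sigmas))
    # modal bin center (robust against contaminated outlier windows)
    hist, edges = np.histogram(sigmas, bins=max(5, int(np.sqrt(len(sigmas)))))
    b = int(np.argmax(hist))
    sel = (sigmas >= edges[b]) & (sigmas <= edges[b + 1])
    return float(sigmas[sel].mean())


def spatial_snr(
    vol: VolumeSeries,
    parc: Parcellation,
    roi: int | str,
    sigma: float | None = None,
) -> float:
    """ROI mean over background noise SD; frame-wise then time-averaged."""
    parc.check_grid(vol)
    mask = parc.mask(roi)
    snrs = []
    for t in range(vol.n_frames):
        s = background_sigma(vol, parc, frame=t) if sigma is None else sigma
        if s <= 0:
            raise ValueError("background sigma is zero: SNR undefined")
        snrs.append(float(vol.frame(t)[mask].mean()) / s)
    return float(np.mean(snrs))


def temporal_snr(
    series: VolumeSeries, parc: Parcellation, roi: int | str
) -> tuple[float, int]:
    """Voxelwise temporal mean / temporal SD, averaged over the ROI.

    Returns ``(tsnr, n_excluded)`` where excluded voxels had zero
    temporal SD.
    """
    if series.n_frames < 10:
        raise ValueError("need >= 10 frames for temporal SNR")
    parc.check_grid(series)
    tc = series.data[parc.mask(roi)]  # voxels x t
    sd = tc.std(axis=1, ddof=0)
    ok = sd > 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("all ROI voxels have zero temporal SD")
    tsnr = float(np.mean(tc[ok].mean(axis=1) / sd[ok]))
    return tsnr, n_excluded


@dataclass
class QualityTable:
    """Per-ROI quality metrics plus the background sigma."""

    table: pd.DataFrame
    background_sigma: float


def quality_table(
    vol: VolumeSeries,
    parc: Parcellation,
    normalized_fwhm: bool = False,
    tsnr_roi: int | str | None = None,
) -> QualityTable:
    """Compute mean, SD, FWHM and spatial SNR for every non-background ROI.

    Temporal SNR is computed only for ``tsnr_roi`` (by convention a
    white-matter ROI) when the input is a series.
    """
    sigma = background_sigma(vol, parc)
    rows = []
    tsnr_label = (
        parc.label_of(tsnr_roi) if isinstance(tsnr_roi, str) else tsnr_roi
    )
    for lab in parc.roi_labels():
        vals = vol.frame(0)[parc.mask(lab)]
        row = {
            "roi": parc.names.get(lab, str(lab)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)),
            "fwhm": FWHM_FACTOR * float(vals.std(ddof=0)),
        }
        if normalized_fwhm and abs(row["mean"]) > 1e-24:
            row["normalized_fwhm"] = row["fwhm"] / row["mean"]
        if sigma > 0:
            row["spatial_snr"] = spatial_snr(vol, parc, lab, sigma=sigma)
        if vol.is_series and tsnr_label is not None and lab == tsnr_label:
            row["temporal_snr"], _ = temporal_snr(vol, parc, lab)
        rows.append(row)
    return QualityTable(
        table=pd.DataFrame(rows).set_index("roi"), background_sigma=sigma
    )
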