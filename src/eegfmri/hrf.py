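"""Single-gamma hemodynamic response function.

The canonical single-gamma HRF is parameterized here by its peak latency
and full width at half maximum (defaults 5.4 s and 5.2 s), the form used
when convolving stimulus sticks and EEG-derived alpha power with the
hemodynamic response.  The gamma shape/scale are solved numerically from
(peak, fwhm) once and cached.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq


def _gamma_shape(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Unnormalized gamma density t^(alpha-1) exp(-t/beta), 0 for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    # log-domain for numerical stability at large alpha
    out[pos] = np.exp((alpha - 1.0) * np.log(tp) - tp / beta)
    return out


def _fwhm_of(alpha: float, beta: float) -> float:
    peak = (alpha - 1.0) * beta
    tgrid = np.linspace(0, peak + 30.0 * beta, 20000)
    h = _gamma_shape(tgrid, alpha, beta)
    h /= h.max()
    above = tgrid[h >= 0.5]
    return above[-1] - above[0]


@lru_cache(maxsize=8)
def gamma_params(peak: float = 5.4, fwhm: float = 5.2) -> tuple[float, float]:
    """Solve (shape, scale) of the gamma HRF for a given peak and FWHM."""

    def f(alpha: float) -> float:
        beta = peak / (alpha - 1.0)
        return _fwhm_of(alpha, beta) - fwhm

    alpha = brentq(f, 1.2, 200.0, xtol=1e-6)
    return alpha, peak / (alpha - 1.0)


def single_gamma_hrf(
    t: np.ndarray, peak: float = 5.4, fwhm: float = 5.2
) -> np.ndarray:
    """Evaluate the HRF at times ``t`` (s); unit peak amplitude."""
    alpha, beta = gamma_params(peak, fwhm)
    h = _gamma_shape(np.asarray(t, dtype=float), alpha, beta)
    hmax = h.max()
    return h / hmax if hmax > 0 else h


def hrf_kernel(dt: float, peak: float = 5.4, fwhm: float = 5.2, length: float = 30.0):
    """HRF and its temporal-derivative kernels sampled every ``dt`` seconds."""
    t = np.arange(0.0, length, dt)
    h = single_gamma_hrf(t, peak, fwhm)
    dh = np.gradient(h, dt)
    return t, h, dh
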