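"""Idealized scalp topographies.

``canonical_maps`` builds four smooth, mutually orthogonal, average-
referenced maps on a given montage, serving as the canonical microstate
templates A-D: A and B are the two left/right-anterior/posterior
diagonals, C is an anterior-posterior gradient and D a fronto-central
focus.  These are synthetic idealized stand-ins for the normative maps of
the microstate literature, built analytically so they exist for any
montage without external files.
"""

from __future__ import annotations

import numpy as np

MICROSTATE_NAMES = ("A", "B", "C", "D")


def _average_reference(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def canonical_maps(montage: np.ndarray) -> np.ndarray:
    """Return 4 x n_channels unit-norm, zero-mean template maps (A-D)."""
    montage = np.asarray(montage, dtype=float)
    if montage.ndim != 2 or montage.shape[1] != 3:
        raise ValueError("montage must be n_channels x 3")
    x, y, z = montage[:, 0], montage[:, 1], montage[:, 2]
    seeds = [
        x + y,  # A: left-posterior <-> right-anterior diagonal
        x - y,  # B: mirrored diagonal
        y**3,  # C: anterior-posterior gradient (cubic; survives A/B removal)
        z,  # D: fronto-central focus
    ]
    maps = []
    for seed in seeds:
        v = _average_reference(np.asarray(seed, dtype=float))
        for prev in maps:  # Gram-Schmidt: orthogonal, hence well-separated
            v = v - (v @ prev) * prev
        nrm = np.linalg.norm(v)
        if nrm < 1e-10:
            raise ValueError("degenerate montage for canonical maps")
        maps.append(v / nrm)
    return np.stack(maps)


def occipital_topography(montage: np.ndarray) -> np.ndarray:
    """Unit-norm map concentrated over the occipital pole (posterior, low)."""
    montage = np.asarray(montage, dtype=float)
    pole = np.array([0.0, -0.9, 0.35])
    pole /= np.linalg.norm(pole)
    d2 = ((montage - pole) ** 2).sum(axis=1)
    w = np.exp(-d2 / 0.35)
    return w / np.linalg.norm(w)
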