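"""Canonical double-gamma hemodynamic response function.

The BOLD response to a brief stimulus is modelled as the difference of two
gamma densities: a positive lobe peaking ~6 s after the event and a
negative undershoot peaking ~16 s, with a 1:6 peak-to-undershoot ratio.
Task regressors are the discrete convolution of the stimulus boxcar with
this kernel sampled on the frame grid.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Seconds of HRF support retained when building the discrete kernel.
HRF_DURATION = 32.0


def double_gamma_hrf(
    times: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Evaluate the double-gamma HRF at ``times`` (seconds post-stimulus).

    Gamma densities use unit scale, so a mode at ``peak`` seconds means a
    shape parameter of ``peak + 1``.  The curve is normalized to a maximum
    of 1 on the evaluated grid.
    """
    times = np.asarray(times, dtype=float)
    h = stats.gamma.pdf(times, peak + 1.0) - stats.gamma.pdf(times, undershoot + 1.0) / ratio
    m = h.max()
    if m > 0:
        h = h / m
    return h


def hrf_kernel(tr: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Discrete HRF kernel sampled every ``tr`` seconds."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    times = np.arange(0.0, duration, tr)
    return double_gamma_hrf(times)


def convolve_boxcar(boxcar: np.ndarray, tr: float) -> np.ndarray:
    """Convolve a per-frame stimulus boxcar with the canonical HRF.

    Returns a regressor of the same length as ``boxcar``; the causal kernel
    (zero at lag 0) guarantees the regressor is zero before the first onset.
    """
    boxcar = np.asarray(boxcar, dtype=float)
    kernel = hrf_kernel(tr)
    return np.convolve(boxcar, kernel)[: boxcar.size]
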