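"""Canonical double-gamma haemodynamic response function.

The kernel is the standard difference of two gamma densities: a response
peaking ~5 s after stimulus (delay 6 s, dispersion 1) minus an undershoot
(delay 16 s, dispersion 1) scaled by 1/6, truncated at 32 s and normalised
to a peak amplitude of 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

PEAK_DELAY = 6.0
UNDERSHOOT_DELAY = 16.0
DISPERSION = 1.0
UNDERSHOOT_RATIO = 1.0 / 6.0
LENGTH = 32.0


def _raw(t: np.ndarray) -> np.ndarray:
    g1 = stats.gamma.pdf(t, PEAK_DELAY / DISPERSION, scale=DISPERSION)
    g2 = stats.gamma.pdf(t, UNDERSHOOT_DELAY / DISPERSION, scale=DISPERSION)
    return g1 - UNDERSHOOT_RATIO * g2


# peak-normalisation constant from a dense grid over the support
_PEAK = float(_raw(np.arange(0.0, LENGTH, 1e-3)).max())


def canonical_hrf(t: float | np.ndarray) -> np.ndarray:
    """Evaluate the peak-normalised canonical HRF at time(s) ``t`` (s).

    Zero for t < 0 and t > 32 s; maximum value 1 at ~5 s.
    """
    t = np.asarray(t, dtype=float)
    out = np.where((t >= 0) & (t <= LENGTH), _raw(np.clip(t, 0, LENGTH)) / _PEAK, 0.0)
    return out if out.ndim else float(out)
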