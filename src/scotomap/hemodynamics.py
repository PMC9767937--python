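"""Canonical hemodynamic response function and causal convolution.

The BOLD response to a neural drive is modeled as convolution with a
double-gamma impulse response: a positive gamma peaking at ``delay_peak``
seconds minus a later undershoot gamma (peak ``delay_undershoot`` s) scaled by
``1/ratio``.  The same HRF object is shared between the forward simulator and
the fitter so that noiseless round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["HRFSpec", "convolve_hrf"]


@dataclass(frozen=True)
class HRFSpec:
    delay_peak: float = 5.0  # s, peak of the positive response
    delay_undershoot: float = 15.0  # s, peak of the undershoot
    ratio: float = 6.0  # positive-to-undershoot amplitude ratio
    length: float = 32.0  # s, support of the discretized kernel

    def __post_init__(self) -> None:
        if self.delay_peak <= 0 or self.delay_undershoot <= 0:
            raise ValueError("HRF delays must be positive")
        if self.ratio <= 0:
            raise ValueError("HRF ratio must be positive")

    def sample(self, tr: float) -> np.ndarray:
        """Kernel sampled at the repetition time, peak normalized to 1.

        Gamma shapes are ``delay + 1`` with unit scale so each component's
        mode sits exactly at its delay.
        """
        if tr <= 0:
            raise ValueError("tr must be positive")
        t = np.arange(0.0, self.length + tr / 2, tr)
        h = gamma_dist.pdf(t, self.delay_peak + 1.0) - gamma_dist.pdf(
            t, self.delay_undershoot + 1.0
        ) / self.ratio
        peak = np.max(np.abs(h))
        if peak == 0:
            raise ValueError("degenerate HRF: zero kernel")
        return h / peak


def convolve_hrf(drive: np.ndarray, hrf: HRFSpec, tr: float) -> np.ndarray:
    """Causal convolution of a neural drive with the HRF, truncated to len(drive).

    ``drive`` may be 1-D (T,) or 2-D (units, T); convolution runs along time
    with zero initial state.
    """
    h = hrf.sample(tr)
    drive = np.asarray(drive, dtype=float)
    if drive.ndim == 1:
        return np.convolve(drive, h)[: drive.shape[0]]
    out = np.apply_along_axis(lambda d: np.convolve(d, h)[: d.shape[0]], -1, drive)
    return out
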