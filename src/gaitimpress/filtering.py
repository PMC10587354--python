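"""Zero-phase Butterworth low-pass filtering of marker/joint-center series."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt


def lowpass_zero_phase(
    series: np.ndarray,
    rate: float,
    cutoff_hz: float = 6.0,
    order: int = 4,
) -> np.ndarray:
    """Forward-backward (zero phase lag) Butterworth low-pass filter.

    The two-pass application squares the magnitude response, so the
    effective attenuation at the cut-off is -6 dB rather than -3 dB, and
    the DC gain is exactly 1.

    Parameters
    ----------
    series : ndarray
        Shape (n,) or (n, k); filtering is applied along axis 0.
    rate : float
        Sampling rate in Hz; must exceed twice the cut-off.
    """
    series = np.asarray(series, dtype=float)
    if rate <= 2 * cutoff_hz:
        raise ValueError(f"rate {rate} Hz must exceed 2 x cutoff {cutoff_hz} Hz")
    b, a = butter(order, cutoff_hz / (rate / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[0] <= padlen:
        raise ValueError(
            f"series of {series.shape[0]} frames too short for zero-phase "
            f"filtering (needs > {padlen})"
        )
    return filtfilt(b, a, series, axis=0)
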