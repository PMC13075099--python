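"""Sampling-rate unification and the fixed filtering chain.

Every signal entering decomposition passes the same chain: 2x polyphase
upsampling (to unify simulator-grid records with 1000 Hz clinical
recordings), a 50 Hz notch against power-line interference, and a
zero-phase fourth-order 0.1-100 Hz Butterworth bandpass. The bandpass
helper is reused at 8-45 Hz for reference fetal-lead filtering and at
10-60 Hz for the pipeline's refinement/output stages.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .records import AnnotatedAECG

__all__ = [
    "resample_2x",
    "map_indices_2x",
    "notch_50",
    "butter_bandpass_zerophase",
    "preprocess_standard",
]


def resample_2x(signal: np.ndarray, fs_in: float) -> tuple[np.ndarray, float]:
    """Double the sampling rate by polyphase filtering (up 2, down 1).

    Returns the resampled signal (length exactly ``2 * len(signal)``)
    and the new rate. Annotation indices map through
    :func:`map_indices_2x`.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot resample an empty signal")
    if fs_in <= 0:
        raise ValueError("fs_in must be positive")
    y = sps.resample_poly(x, up=2, down=1)
    return y, 2.0 * fs_in


def map_indices_2x(indices: np.ndarray) -> np.ndarray:
    """Map annotation sample indices onto the doubled-rate grid."""
    return 2 * np.asarray(indices, dtype=np.int64)


def notch_50(signal: np.ndarray, fs: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase 50 Hz IIR notch (power-line interference removal)."""
    if fs <= 100:
        raise ValueError("fs must exceed 100 Hz for a 50 Hz notch")
    b, a = sps.iirnotch(50.0, Q=q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(signal, dtype=np.float64))


def butter_bandpass_zerophase(
    signal: np.ndarray, fs: float, lo: float, hi: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, SOS form).

    The order refers to the one-way design; forward-backward application
    doubles the magnitude roll-off and cancels the phase.
    """
    if not (0 < lo < hi < fs / 2):
        raise ValueError("band must satisfy 0 < lo < hi < fs/2")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=np.float64))


def preprocess_standard(rec: AnnotatedAECG) -> AnnotatedAECG:
    """Standard chain: 50 Hz notch then 0.1-100 Hz zero-phase bandpass.

    Annotations are carried through unchanged (both filters are
    zero-phase, so fiducials stay aligned).
    """
    if rec.fs < 250:
        raise ValueError("preprocessing expects fs >= 250 Hz")
    y = notch_50(rec.signal, rec.fs)
    hi = min(100.0, 0.49 * rec.fs)
    y = butter_bandpass_zerophase(y, rec.fs, 0.1, hi, order=4)
    return rec.with_signal(y)
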