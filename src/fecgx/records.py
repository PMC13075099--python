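"""Annotated abdominal-ECG record container.

An :class:`AnnotatedAECG` bundles a single abdominal channel with its
sampling rate, maternal/fetal R-peak fiducials, and — for synthetic
records — the clean maternal and fetal components that generated it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["AnnotatedAECG"]


def _as_index_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.int64)
    if a.ndim != 1:
        raise ValueError("R-peak indices must be a 1-D sequence")
    return a


@dataclass
class AnnotatedAECG:
    """A single-channel abdominal ECG trace with ground-truth annotations.

    Parameters
    ----------
    signal
        The abdominal trace, arbitrary units.
    fs
        Sampling rate in Hz.
    fetal_rpeaks, maternal_rpeaks
        Strictly increasing sample indices of the respective R-peaks.
    fetal_clean, maternal_clean
        Noise-free components (synthetic records only); same length as
        ``signal`` when present.
    subject_id
        Identifier used to key leave-one-subject-out folds.
    """

    signal: np.ndarray
    fs: float
    fetal_rpeaks: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    maternal_rpeaks: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    fetal_clean: Optional[np.ndarray] = None
    maternal_clean: Optional[np.ndarray] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1:
            raise ValueError("signal must be 1-D")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.fetal_rpeaks = _as_index_array(self.fetal_rpeaks)
        self.maternal_rpeaks = _as_index_array(self.maternal_rpeaks)
        n = self.signal.size
        for name in ("fetal_rpeaks", "maternal_rpeaks"):
            idx = getattr(self, name)
            if idx.size:
                if idx.min() < 0 or idx.max() >= n:
                    raise ValueError(f"{name} outside [0, len(signal))")
                if np.any(np.diff(idx) <= 0):
                    raise ValueError(f"{name} must be strictly increasing")
        for name in ("fetal_clean", "maternal_clean"):
            comp = getattr(self, name)
            if comp is not None:
                comp = np.asarray(comp, dtype=np.float64)
                if comp.shape != self.signal.shape:
                    raise ValueError(f"{name} length must equal len(signal)")
                setattr(self, name, comp)

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs

    def with_signal(self, signal: np.ndarray) -> "AnnotatedAECG":
        """Copy of the record with ``signal`` replaced, annotations kept."""
        return replace(self, signal=np.asarray(signal, dtype=np.float64))
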