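"""Synthetic annotated abdominal-ECG generation.

Emulates the 15-case maternal/fetal simulator grid used for supervised
training: each case fixes maternal and fetal heart rates and R-wave
amplitudes spanning fetal-to-maternal amplitude ratios from 1:1.17
(fetal upper limit) down to 1:16 (extremely weak fetal component).
Beats are synthesized as sums of five Gaussians (P, Q, R, S, T) placed
at jittered RR intervals; the abdominal mixture is the sum of the
maternal and fetal component tracks, each annotated with exact R-peak
sample indices.

The noise model adds EMG-like 20–150 Hz bandpassed Gaussian noise at
0.1x the signal standard deviation and respiratory baseline wander
(0.2 Hz + 0.33 Hz sinusoids) at 0.18x, then rescales the summed noise
by a single global factor so the realized signal-to-noise ratio hits
the configured target (10 dB by default) exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import signal as sps

from .records import AnnotatedAECG

__all__ = [
    "SimCaseParams",
    "NoiseSpec",
    "table1_cases",
    "synth_clean_aecg",
    "add_noise",
    "make_default_grid",
]


@dataclass(frozen=True)
class SimCaseParams:
    """One simulator case: heart rates (bpm) and R-wave amplitudes (a.u.).

    ``ratio`` is the fetal-to-maternal amplitude ratio expressed as the
    maternal multiple (a "1:R" ratio stores R); it is redundant with
    ``m_amp / f_amp`` and checked to within 5 %.
    """

    case_id: int
    m_hr: float
    m_amp: float
    f_hr: float
    f_amp: float
    ratio: float

    def __post_init__(self) -> None:
        if not (60 <= self.m_hr <= 120):
            raise ValueError("maternal heart rate outside 60-120 bpm")
        if not (110 <= self.f_hr <= 162):
            raise ValueError("fetal heart rate outside 110-162 bpm")
        if self.m_amp <= 0 or self.f_amp <= 0:
            raise ValueError("amplitudes must be positive")
        implied = self.m_amp / self.f_amp
        if abs(implied - self.ratio) > 0.05 * self.ratio:
            raise ValueError(
                f"case {self.case_id}: amplitude ratio {implied:.3f} "
                f"inconsistent with declared 1:{self.ratio}"
            )


# (case_id, m_hr, m_amp, f_hr, f_amp, ratio)
_CASE_GRID = [
    (1, 80, 0.35, 140, 0.30, 1.17),
    (2, 75, 0.60, 152, 0.20, 3.0),
    (3, 90, 0.75, 118, 0.12, 6.3),
    (4, 70, 0.80, 145, 0.07, 11.4),
    (5, 85, 0.80, 162, 0.05, 16.0),
    (6, 72, 0.50, 135, 0.25, 2.0),
    (7, 88, 0.65, 148, 0.15, 4.3),
    (8, 65, 0.70, 160, 0.09, 7.8),
    (9, 78, 0.45, 130, 0.22, 2.0),
    (10, 92, 0.70, 125, 0.08, 8.8),
    (11, 68, 0.55, 150, 0.18, 3.1),
    (12, 84, 0.45, 142, 0.24, 1.9),
    (13, 76, 0.80, 155, 0.06, 13.3),
    (14, 82, 0.40, 138, 0.26, 1.5),
    (15, 77, 0.58, 144, 0.19, 3.1),
]


def table1_cases() -> List[SimCaseParams]:
    """The 15 simulator cases of the training grid, in case order."""
    return [SimCaseParams(*row) for row in _CASE_GRID]


# Gaussian beat morphology: per wave (time offset s, width s, amplitude
# relative to R), calibrated to adult intervals (PR ~0.16 s, QRS
# ~0.10 s, Gaussian R sigma 15 ms). Offsets/widths shrink by
# `time_scale` for the faster, narrower fetal complex (~30 ms QRS at
# the default fetal scale), which keeps maternal QRS energy below
# ~25 Hz and fetal QRS energy near 30-70 Hz.
_WAVES = (
    # (offset, width, rel_amp)
    (-0.180, 0.022, 0.15),   # P
    (-0.032, 0.010, -0.10),  # Q
    (0.000, 0.015, 1.00),    # R
    (0.032, 0.010, -0.25),   # S
    (0.280, 0.060, 0.35),    # T
)

FETAL_TIME_SCALE = 0.3  # fetal wave durations relative to maternal


def _beat_track(
    n: int,
    fs: float,
    hr_bpm: float,
    amp: float,
    rng: np.random.Generator,
    rr_jitter: float,
    amp_jitter: float,
    time_scale: float,
    start_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One ECG component: signal track and its R-peak sample indices."""
    rr_nominal = int(round(fs * 60.0 / hr_bpm))
    peaks = []
    pos = int(round(start_frac * rr_nominal))
    margin = int(round(0.40 * fs * time_scale)) + 1  # room for the T wave
    while pos < n - margin:
        if pos >= margin:
            peaks.append(pos)
        rr = rr_nominal
        if rr_jitter > 0:
            rr = int(round(rr_nominal * max(0.5, 1.0 + rr_jitter * rng.standard_normal())))
        pos += max(1, rr)
    peaks = np.asarray(peaks, dtype=np.int64)
    track = np.zeros(n)
    for p in peaks:
        a = amp
        if amp_jitter > 0:
            a = amp * max(0.1, 1.0 + amp_jitter * rng.standard_normal())
        lo = max(0, p - margin)
        hi = min(n, p + margin + 1)
        t = (np.arange(lo, hi) - p) / fs
        beat = np.zeros(t.size)
        for off, width, rel in _WAVES:
            beat += rel * np.exp(-0.5 * ((t - off * time_scale) / (width * time_scale)) ** 2)
        track[lo:hi] += a * beat
    return track, peaks


def synth_clean_aecg(
    params: SimCaseParams,
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
    rr_jitter: float = 0.03,
    amp_jitter: float = 0.05,
) -> AnnotatedAECG:
    """Generate one clean (noise-free) synthetic abdominal record.

    The abdominal signal is the sum of a maternal and a fetal Gaussian
    PQRST track at the case's heart rates and amplitudes, with
    multiplicative RR jitter (sigma ``rr_jitter``) and beat-amplitude
    jitter (sigma ``amp_jitter``). R-peak annotations are exact sample
    indices of each beat center; determinism is guaranteed per seed.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    m_start = float(rng.uniform(0.3, 0.9))
    f_start = float(rng.uniform(0.3, 0.9))
    m_track, m_peaks = _beat_track(
        n, fs, params.m_hr, params.m_amp, rng, rr_jitter, amp_jitter, 1.0, m_start
    )
    f_track, f_peaks = _beat_track(
        n, fs, params.f_hr, params.f_amp, rng, rr_jitter, amp_jitter, FETAL_TIME_SCALE, f_start
    )
    return AnnotatedAECG(
        signal=m_track + f_track,
        fs=fs,
        fetal_rpeaks=f_peaks,
        maternal_rpeaks=m_peaks,
        fetal_clean=f_track,
        maternal_clean=m_track,
        subject_id=f"sim{params.case_id:02d}",
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise-augmentation recipe with an exact overall-SNR constraint."""

    emg_band_lo: float = 20.0
    emg_band_hi: float = 150.0
    emg_scale: float = 0.1
    bw_freqs: tuple = (0.2, 0.33)
    bw_scale: float = 0.18
    target_snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.emg_scale <= 0 or self.bw_scale <= 0:
            raise ValueError("noise scales must be positive")
        if not self.emg_band_lo < self.emg_band_hi:
            raise ValueError("EMG band must satisfy lo < hi")
        if not np.isfinite(self.target_snr_db):
            raise ValueError("target_snr_db must be finite")


def add_noise(rec: AnnotatedAECG, spec: NoiseSpec) -> AnnotatedAECG:
    """Augment a record with EMG-like noise and baseline wander.

    Both sources are first built at their stated scales relative to
    std(signal) — preserving the EMG:wander power ratio — then the summed
    noise is multiplied by one global scalar so that
    ``10*log10(P_signal / P_noise)`` equals ``spec.target_snr_db``
    exactly (to floating-point precision). Annotations are untouched.
    """
    x = rec.signal
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("cannot augment a constant signal")
    n = x.size
    rng = np.random.default_rng(spec.seed)

    white = rng.standard_normal(n)
    hi = min(spec.emg_band_hi, 0.45 * rec.fs)  # keep the band below Nyquist
    sos = sps.butter(4, [spec.emg_band_lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    emg = sps.sosfiltfilt(sos, white)
    emg *= spec.emg_scale * sd / np.std(emg)

    t = np.arange(n) / rec.fs
    bw = np.zeros(n)
    for f in spec.bw_freqs:
        bw += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    bw *= spec.bw_scale * sd / np.std(bw)

    noise = emg + bw
    p_sig = float(np.mean(x**2))
    p_noise = float(np.mean(noise**2))
    alpha = np.sqrt(p_sig / (p_noise * 10.0 ** (spec.target_snr_db / 10.0)))
    return rec.with_signal(x + alpha * noise)


def make_default_grid(
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
    snr_db: Optional[float] = 10.0,
) -> List[AnnotatedAECG]:
    """All 15 cases, each synthesized and (optionally) noise-augmented.

    Per-case seeds are derived from ``seed`` so records are independent
    but jointly reproducible. ``snr_db=None`` skips augmentation.
    """
    out = []
    for params in table1_cases():
        case_seed = seed * 1000 + params.case_id
        rec = synth_clean_aecg(params, duration_s=duration_s, fs=fs, seed=case_seed)
        if snr_db is not None:
            rec = add_noise(rec, NoiseSpec(target_snr_db=snr_db, seed=case_seed + 500))
        out.append(rec)
    return out
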