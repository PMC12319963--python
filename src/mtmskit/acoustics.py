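"""Acoustic analysis of stimulation pulses: peak SPL and 1/3-octave spectra.

Stimulation pulses in a strong static field produce impulsive acoustic
noise.  Levels are reported Z-weighted (no frequency weighting) as peak
sound pressure levels re 20 uPa, averaged over repeated pulses; spectra are
1/3-octave band levels of a Tukey-tapered window around each pulse
(3 ms before to 40 ms after).  High-intensity measurements taken through a
foam-earplug dampener are corrected by an additive factor estimated from
matched with/without pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

P_REF = 20e-6  # Pa
BAND_RANGE_HZ = (20.0, 20000.0)

__all__ = [
    "AcousticRecording",
    "peak_spl",
    "third_octave_spectrum",
    "third_octave_centers",
    "earplug_correction",
    "apply_correction",
]


@dataclass
class AcousticRecording:
    """Calibrated pressure recording with pulse onset markers."""

    pressure: np.ndarray  # Pa
    sample_rate: float  # Hz
    onsets: np.ndarray | None = None  # sample indices of pulse onsets

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.pressure.ndim != 1 or len(self.pressure) == 0:
            raise ValueError("pressure must be a nonempty 1-D array")
        if self.sample_rate < 2 * BAND_RANGE_HZ[1]:
            raise ValueError(
                "sample rate must be at least 40 kHz to cover the 20 Hz-20 kHz band"
            )
        if self.onsets is not None:
            self.onsets = np.asarray(self.onsets, dtype=int)

    @classmethod
    def from_wav(
        cls, path, calibration_pa_per_fs: float, onsets=None
    ) -> "AcousticRecording":
        """Read a WAV file; ``calibration_pa_per_fs`` converts full scale to Pa."""
        from scipy.io import wavfile

        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return cls(data * calibration_pa_per_fs, float(rate), onsets)

    def to_wav(self, path, calibration_pa_per_fs: float) -> None:
        from scipy.io import wavfile

        wavfile.write(
            path,
            int(self.sample_rate),
            (self.pressure / calibration_pa_per_fs).astype(np.float32),
        )


def peak_spl(rec: AcousticRecording, onsets=None, window_ms: float = 43.0) -> float:
    """Mean of per-pulse peak SPLs, dB(Z) re 20 uPa.

    The peak is the maximum absolute instantaneous pressure within
    ``window_ms`` after each onset (the whole recording if no onsets).
    """
    if onsets is None:
        onsets = rec.onsets
    if onsets is None or len(onsets) == 0:
        raise ValueError("at least one pulse onset is required")
    n_win = int(round(window_ms * 1e-3 * rec.sample_rate))
    spls = []
    for o in onsets:
        seg = rec.pressure[o : o + n_win]
        if len(seg) == 0:
            raise ValueError(f"onset {o} outside the recording")
        spls.append(20.0 * np.log10(np.max(np.abs(seg)) / P_REF))
    return float(np.mean(spls))


def third_octave_centers() -> np.ndarray:
    """Preferred base-10 1/3-octave centre frequencies within 20 Hz-20 kHz."""
    k = np.arange(-17, 14)
    fc = 1000.0 * 10.0 ** (k / 10.0)
    return fc[(fc >= BAND_RANGE_HZ[0] * 0.999) & (fc <= BAND_RANGE_HZ[1] * 1.001)]


def third_octave_spectrum(
    rec: AcousticRecording,
    onset: int,
    pre_ms: float = 3.0,
    post_ms: float = 40.0,
    taper: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """1/3-octave band levels, dB(Z), of one pulse.

    A window from ``pre_ms`` before to ``post_ms`` after the onset is
    Tukey-tapered (ratio ``taper``); band levels are the RMS pressures of
    the spectral energy falling between the band edges ``fc * 10**(+-1/20)``
    (an exact energy partition, so the band energies sum to the windowed
    segment's energy), expressed in dB re 20 uPa.
    Returns (centre frequencies, levels).
    """
    fs = rec.sample_rate
    i0 = onset - int(round(pre_ms * 1e-3 * fs))
    i1 = onset + int(round(post_ms * 1e-3 * fs))
    if i0 < 0 or i1 > len(rec.pressure):
        missing = max(-i0, i1 - len(rec.pressure))
        raise ValueError(f"analysis window truncated by {missing} samples")
    seg = rec.pressure[i0:i1] * tukey(i1 - i0, alpha=taper)

    centers = third_octave_centers()
    levels = np.empty(len(centers))
    half = 10.0 ** (1.0 / 20.0)  # 1/3-octave band edge factor 10^(1/20)
    n = len(seg)
    spec = np.abs(np.fft.fft(seg)) ** 2 / n**2  # mean-square per bin (two-sided)
    freqs = np.abs(np.fft.fftfreq(n, 1.0 / fs))
    for i, fc in enumerate(centers):
        lo, hi = fc / half, min(fc * half, 0.5 * fs)
        ms = spec[(freqs >= lo) & (freqs < hi)].sum()
        levels[i] = 10.0 * np.log10(max(ms, 1e-300) / P_REF**2)
    return centers, levels


def earplug_correction(paired_spls) -> float:
    """Additive dampener correction from matched (without, with) SPL pairs."""
    pairs = np.asarray(paired_spls, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) == 0:
        raise ValueError("need an (n, 2) array of (without, with) SPL pairs")
    return float(np.mean(pairs[:, 0] - pairs[:, 1]))


def apply_correction(spl_db: float, correction_db: float) -> float:
    """Apply an additive dampener correction to a measured SPL."""
    return float(spl_db + correction_db)
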