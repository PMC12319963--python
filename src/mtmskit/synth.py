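"""Seeded synthetic-data generators with known ground truth.

Every analysis module in the package has a matching generator here that
produces the raw inputs it consumes -- FID series, multi-echo/flip-angle
image stacks, EMG recordings with stimulus markers, and calibrated acoustic
pulse trains -- from a known forward model, so analysis results can be
checked against the generating parameters.

One global seed fans out to independent per-scenario substreams (derived by
hashing the scenario name with ``numpy``'s SeedSequence spawn-key
mechanism), so adding a scenario never perturbs the data of existing ones.
Identical configurations produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustics import AcousticRecording
from .emg import EmgRecording
from .mri_qa import DEFAULT_B0_TES_MS, DEFAULT_B1_ANGLES_DEG, FidSignal

DEFAULT_DELAYS_MS = tuple(np.arange(0.0, 10.5, 0.5))
DEFAULT_INTENSITIES = (0, 5, 8, 17, 25)

__all__ = [
    "substream",
    "gen_fid",
    "gen_fid_series",
    "gen_phantom_stacks",
    "gen_emg",
    "gen_acoustic_pulse",
    "mep_template",
]


def substream(seed: int, scenario: str) -> np.random.Generator:
    """Independent random stream for (seed, scenario)."""
    name_key = [ord(c) for c in scenario]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=name_key))


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------


def gen_fid(
    scenario: str = "clean",
    seed: int = 0,
    n_samples: int = 2048,
    dwell: float = 4e-6,
    f0: float = 0.0,
    t2star: float = 5e-3,
    noise_sd: float = 0.002,
    amplitude: float = 1.0,
    phase0: float = 0.7,  # receiver phase offset (rad)
    shift_hz: float = 122.0,
    eddy_tau: float = 3e-4,
    eddy_depth: float = 500.0,
    delay_ms: float | None = None,
    corrupt_cutoff_ms: float = 4.5,
) -> FidSignal:
    """One synthetic FID: decaying complex exponential plus Gaussian noise.

    Scenarios:

    * ``clean`` -- exp(2 pi i f0 t - t/T2*).
    * ``corrupted`` -- amplitude attenuated below the 95% power criterion
      for ``delay_ms <= corrupt_cutoff_ms`` (pulse ring-down emulation).
    * ``shifted`` -- resonance offset by ``shift_hz`` (capacitor-charged
      condition).
    * ``eddy`` -- exponentially decaying frequency modulation whose residual
      at ``delay_ms`` scales with exp(-delay/tau).
    """
    if scenario not in ("clean", "corrupted", "shifted", "eddy"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = substream(seed, f"fid/{scenario}/{delay_ms}")
    t = np.arange(n_samples) * dwell
    freq = f0 + (shift_hz if scenario == "shifted" else 0.0)
    sig = amplitude * np.exp(1j * phase0 + 2j * np.pi * freq * t - t / t2star)
    if scenario == "corrupted" and delay_ms is not None:
        if delay_ms <= corrupt_cutoff_ms:
            sig = sig * 0.9  # power ratio 0.81 < 0.95
    if scenario == "eddy" and delay_ms is not None:
        resid = np.exp(-(delay_ms * 1e-3) / eddy_tau)
        phase = 2 * np.pi * eddy_depth * resid * eddy_tau * (
            1 - np.exp(-t / eddy_tau)
        )
        sig = sig * np.exp(1j * phase) * (1 - 0.5 * resid)
    noise = noise_sd * (rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples))
    return FidSignal(sig + noise, dwell, delay_ms=delay_ms, condition=scenario)


def gen_fid_series(
    scenario: str,
    seed: int = 0,
    delays_ms=DEFAULT_DELAYS_MS,
    **kw,
) -> tuple[list[tuple[float, FidSignal]], FidSignal]:
    """(delay, FID) series over a delay grid plus a no-pulse reference."""
    ref = gen_fid("clean", seed=seed, **kw)
    series = [
        (float(d), gen_fid(scenario, seed=seed, delay_ms=float(d), **kw))
        for d in delays_ms
    ]
    return series, ref


# ---------------------------------------------------------------------------
# Phantom image stacks
# ---------------------------------------------------------------------------


def gen_phantom_stacks(
    shift_field_hz: np.ndarray,
    b1_ratio_field: np.ndarray,
    tes_ms=DEFAULT_B0_TES_MS,
    angles_deg=DEFAULT_B1_ANGLES_DEG,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
):
    """Forward-model image stacks for the B0 and B1+ fitters.

    Returns ``(phase_stack, magnitude_stack)``: wrapped phases
    ``2 pi * shift * TE`` per echo and magnitudes ``A |sin(c * alpha)|`` per
    nominal flip angle, with optional Gaussian noise.
    """
    shift = np.asarray(shift_field_hz, dtype=float)
    ratio = np.asarray(b1_ratio_field, dtype=float)
    if not (np.all(np.isfinite(shift)) and np.all(np.isfinite(ratio))):
        raise ValueError("ground-truth fields must be finite")
    rng = substream(seed, "phantom")
    tes = np.asarray(tes_ms, dtype=float) * 1e-3
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    phase = 2.0 * np.pi * shift[None] * tes.reshape((-1,) + (1,) * shift.ndim)
    phase = np.angle(np.exp(1j * phase))  # wrap to (-pi, pi]
    mag = amplitude * np.abs(
        np.sin(ratio[None] * ang.reshape((-1,) + (1,) * ratio.ndim))
    )
    if noise_sd > 0:
        phase = phase + noise_sd * rng.standard_normal(phase.shape)
        mag = mag + noise_sd * amplitude * rng.standard_normal(mag.shape)
    return phase, mag


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def mep_template(fs: float, duration_ms: float = 8.0, freq_hz: float = 250.0):
    """Biphasic MEP wavelet: Gaussian-windowed sine, unit peak-to-peak."""
    n = int(round(duration_ms * 1e-3 * fs))
    t = np.arange(n) / fs
    w = np.exp(-((t - duration_ms * 5e-4) ** 2) / (2 * (duration_ms * 2e-4) ** 2))
    x = w * np.sin(2 * np.pi * freq_hz * t)
    return x / (x.max() - x.min())


def gen_emg(
    tuning: dict,
    latency_ms: float = 10.0,
    noise_sd_uv: float = 2.0,
    n_trials: int = 5,
    fs: float = 10000.0,
    iti_ms: float = 100.0,
    artifact_uv: float = 2000.0,
    intensity: float = 67.0,
    seed: int = 0,
) -> EmgRecording:
    """Synthetic EMG recording over an orientation-tuned MEP protocol.

    ``tuning`` maps orientation (deg) to the MEP peak-to-peak amplitude
    (uV); each orientation is stimulated ``n_trials`` times.  Every marker
    carries a decaying stimulus artifact; orientations with zero amplitude
    produce artifact and noise only.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = substream(seed, "emg")
    orientations = list(tuning.keys())
    n_ep = int(round(iti_ms * 1e-3 * fs))
    total = n_ep * (len(orientations) * n_trials + 1)
    data = np.zeros(total)
    markers = []
    tmpl = mep_template(fs)
    k = 0
    for o in orientations:
        for _ in range(n_trials):
            onset = n_ep // 2 + k * n_ep
            markers.append({"sample": onset, "orientation": float(o), "intensity": intensity})
            # stimulus artifact: fast decaying transient
            n_art = int(round(1.5e-3 * fs))
            data[onset : onset + n_art] += artifact_uv * np.exp(
                -np.arange(n_art) / (0.2e-3 * fs)
            )
            amp = float(tuning[o])
            if amp > 0:
                i0 = onset + int(round(latency_ms * 1e-3 * fs))
                data[i0 : i0 + len(tmpl)] += amp * tmpl
            k += 1
    data += noise_sd_uv * rng.standard_normal(total)
    return EmgRecording(data, fs, markers)


# ---------------------------------------------------------------------------
# Acoustics
# ---------------------------------------------------------------------------


def gen_acoustic_pulse(
    peak_pa: float = 2.0,
    ring_freqs_hz=(1000.0,),
    decay_ms: float = 5.0,
    n_pulses: int = 3,
    fs: float = 48000.0,
    gap_ms: float = 200.0,
    noise_pa: float = 0.0,
    seed: int = 0,
) -> AcousticRecording:
    """Damped-oscillation pulse train with exactly known peak pressure.

    Each pulse is a sum of exponentially decaying sinusoids normalized so
    the instantaneous peak equals ``peak_pa``.
    """
    if peak_pa <= 0:
        raise ValueError("peak pressure must be positive")
    rng = substream(seed, "acoustic")
    n_gap = int(round(gap_ms * 1e-3 * fs))
    n_ring = int(round(6 * decay_ms * 1e-3 * fs))
    t = np.arange(n_ring) / fs
    ring = sum(np.sin(2 * np.pi * f * t) for f in ring_freqs_hz) * np.exp(
        -t / (decay_ms * 1e-3)
    )
    ring = ring * (peak_pa / np.max(np.abs(ring)))
    total = n_gap * (n_pulses + 1)
    p = np.zeros(total)
    onsets = []
    for k in range(n_pulses):
        onset = n_gap // 2 + k * n_gap
        p[onset : onset + n_ring] += ring
        onsets.append(onset)
    if noise_pa > 0:
        p += noise_pa * rng.standard_normal(total)
    return AcousticRecording(p, fs, np.asarray(onsets))
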