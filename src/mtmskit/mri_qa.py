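"""MRI interference and compatibility analyses.

Quantifies how stimulation pulses and hardware perturb the MR measurement:
FID power-spectrum corruption and the minimum artifact-free delay after a
pulse, B0 maps (Larmor-frequency shift) from multi-echo phase, B1+ maps
(actual/nominal flip-angle ratio) from a flip-angle series, eddy-current
recovery curves after gradient pulses, and a pulse/slice interleaving
planner for concurrent stimulation-fMRI protocols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CORRUPTION_THRESHOLD = 0.95  # power-spectrum ratio below which a FID is corrupted
DEFAULT_B0_TES_MS = (1.6, 2.1, 2.6, 3.6, 4.6, 6.6, 8.6, 10.6)
DEFAULT_B1_ANGLES_DEG = tuple(range(10, 181, 10))
DEFAULT_EDDY_DELAYS_MS = (
    0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0, 20.0, 50.0, 100.0,
    500.0, 1000.0, 2000.0,
)

__all__ = [
    "FidSignal",
    "B0Map",
    "B1Map",
    "corruption_ratio",
    "is_corrupted",
    "min_artifact_free_delay",
    "b0_map",
    "b0_homogeneity",
    "b1_map",
    "eddy_current_curves",
    "plan_interleaving",
    "InfeasibleScheduleError",
    "NO_DELAY_FOUND",
]

NO_DELAY_FOUND = float("nan")


class InfeasibleScheduleError(ValueError):
    """The requested interleaving leaves no room for stimulation pulses."""


@dataclass
class FidSignal:
    """Complex free-induction-decay record."""

    samples: np.ndarray  # complex
    dwell: float  # s
    delay_ms: float | None = None  # delay to the preceding event
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise ValueError("FID needs at least two samples")
        if self.dwell <= 0:
            raise ValueError("dwell time must be positive")

    def power_spectrum(self) -> np.ndarray:
        """|FFT|^2 of the raw (unwindowed) FID."""
        return np.abs(np.fft.fft(self.samples)) ** 2

    def power_integral(self) -> float:
        return float(self.power_spectrum().sum())

    def first_sample_phase(self) -> float:
        return float(np.angle(self.samples[0]))

    def to_csv(self, path) -> None:
        import pandas as pd

        t = np.arange(len(self.samples)) * self.dwell
        pd.DataFrame(
            {"t": t, "re": self.samples.real, "im": self.samples.imag}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "FidSignal":
        import pandas as pd

        df = pd.read_csv(path)
        dwell = float(df["t"].iloc[1] - df["t"].iloc[0])
        return cls(df["re"].to_numpy() + 1j * df["im"].to_numpy(), dwell, **kw)


@dataclass
class B0Map:
    """Per-voxel Larmor-frequency shift (Hz) with a validity mask."""

    shift_hz: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.shift_hz = np.asarray(self.shift_hz, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.shift_hz.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")


@dataclass
class B1Map:
    """Per-voxel actual/nominal flip-angle ratio with a validity mask."""

    ratio: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ratio.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if np.any(self.ratio[self.mask] <= 0):
            raise ValueError("B1 ratio must be positive inside the mask")


# ---------------------------------------------------------------------------
# FID corruption
# ---------------------------------------------------------------------------


def corruption_ratio(fid: FidSignal, ref: FidSignal) -> float:
    """Power-spectrum integral of ``fid`` relative to the no-pulse reference."""
    if len(fid.samples) != len(ref.samples) or fid.dwell != ref.dwell:
        raise ValueError("FID and reference must share length and dwell time")
    ratio = fid.power_integral() / ref.power_integral()
    if ratio > 1.05:
        logger.warning("anomalous FID power ratio %.3f (> 1.05)", ratio)
    return float(ratio)


def is_corrupted(fid: FidSignal, ref: FidSignal) -> bool:
    """A spectrum is corrupted when its power ratio drops below 95%."""
    return corruption_ratio(fid, ref) < CORRUPTION_THRESHOLD


def min_artifact_free_delay(
    series: list[tuple[float, FidSignal]], ref: FidSignal
) -> float:
    """Smallest delay (ms) from which all longer delays are uncorrupted.

    ``series`` pairs each post-pulse delay in ms with its FID, sorted
    ascending.  Returns 0 if nothing is corrupted and NaN (``NO_DELAY_FOUND``)
    if every delay is corrupted.  Non-monotone corruption (clean at a short
    delay, corrupted again later) is logged and handled by the same rule.
    """
    delays = [d for d, _ in series]
    if any(b < a for a, b in zip(delays, delays[1:])):
        raise ValueError("delays must be sorted ascending")
    flags = [is_corrupted(f, ref) for _, f in series]
    if not any(flags):
        return 0.0
    if all(flags):
        return NO_DELAY_FOUND
    last_bad = max(i for i, f in enumerate(flags) if f)
    if any(not f for f in flags[:last_bad]):
        logger.warning("non-monotone FID corruption pattern across delays")
    if last_bad == len(flags) - 1:
        return NO_DELAY_FOUND
    # first delay beyond the last corrupted one; on a uniform grid this is
    # delay[last_bad] + step
    return float(delays[last_bad + 1])


# ---------------------------------------------------------------------------
# Field maps
# ---------------------------------------------------------------------------


def b0_map(
    phase_images: np.ndarray,
    tes_s: np.ndarray,
    mask: np.ndarray | None = None,
    magnitude_weights: np.ndarray | None = None,
) -> B0Map:
    """Frequency-shift map from the phase evolution across echo times.

    ``phase_images`` has shape (n_te, ...) in radians; the phase of each
    voxel is unwrapped along the echo axis and fitted linearly against TE
    (weighted by magnitude if given); the slope over 2 pi is the shift in Hz.
    """
    phase_images = np.asarray(phase_images, dtype=float)
    tes = np.asarray(tes_s, dtype=float)
    if phase_images.shape[0] != len(tes) or len(tes) < 2:
        raise ValueError("need phase images for at least two echo times")
    shape = phase_images.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    flat_w = phase_images.reshape(len(tes), -1)
    # two-stage unwrap for the non-uniform TE grid: a slope estimate from the
    # closest-spaced echo pairs (unambiguous to +-1/(2*min dTE), i.e. +-1 kHz
    # for a 0.5-ms spacing) anchors the wrap integers of every echo
    dtes = np.diff(tes)
    k_min = int(np.argmin(dtes))
    dphi = np.angle(np.exp(1j * (flat_w[k_min + 1] - flat_w[k_min])))
    slope0 = dphi / dtes[k_min]
    model = slope0[None, :] * (tes[:, None] - tes[k_min]) + flat_w[k_min][None, :]
    flat = flat_w + 2.0 * np.pi * np.round((model - flat_w) / (2.0 * np.pi))
    if magnitude_weights is None:
        w = np.ones_like(flat)
    else:
        w = np.asarray(magnitude_weights, dtype=float).reshape(len(tes), -1)
    # weighted least squares slope per voxel
    sw = w.sum(axis=0)
    tbar = (w * tes[:, None]).sum(axis=0) / sw
    ybar = (w * flat).sum(axis=0) / sw
    cov = (w * (tes[:, None] - tbar) * (flat - ybar)).sum(axis=0)
    var = (w * (tes[:, None] - tbar) ** 2).sum(axis=0)
    slope = cov / var
    shift = (slope / (2.0 * np.pi)).reshape(shape)
    shift[~mask] = 0.0
    return B0Map(shift_hz=shift, mask=mask)


def b0_homogeneity(m: B0Map, roi: np.ndarray) -> float:
    """Standard deviation (Hz) of the frequency shift inside an ROI."""
    roi = np.asarray(roi, dtype=bool) & m.mask
    if not np.any(roi):
        raise ValueError("ROI contains no valid voxels")
    return float(np.std(m.shift_hz[roi]))


def ellipsoid_roi(shape, center, semi_axes) -> np.ndarray:
    """Boolean ellipsoid ROI in voxel coordinates (0-based indices)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def b1_map(
    magnitude_images: np.ndarray,
    angles_deg: np.ndarray,
    mask: np.ndarray | None = None,
) -> B1Map:
    """Flip-angle ratio map from the signal across nominal flip angles.

    Fits ``S(alpha) = A * |sin(c * alpha)`` per voxel by nonlinear least
    squares; the returned map is ``c`` (actual/nominal ratio).  Voxels where
    the fit fails (e.g. flat signal) are masked out.
    """
    from scipy.optimize import curve_fit

    mags = np.asarray(magnitude_images, dtype=float)
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    if mags.shape[0] != len(ang) or len(ang) < 3:
        raise ValueError("need magnitudes for at least three flip angles")
    shape = mags.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    flat = mags.reshape(len(ang), -1)
    ratio = np.zeros(flat.shape[1])
    ok = np.zeros(flat.shape[1], dtype=bool)

    def model(a, A, c):
        return A * np.abs(np.sin(c * a))

    mask_flat = mask.ravel()
    for vox in np.flatnonzero(mask_flat):
        y = flat[:, vox]
        if np.ptp(y) <= 0:
            continue
        # initial ratio guess from the argmax of the sine arch
        c0 = (np.pi / 2.0) / ang[int(np.argmax(y))]
        try:
            popt, _ = curve_fit(
                model, ang, y, p0=[y.max(), min(c0, 2.0)], maxfev=2000
            )
        except RuntimeError:
            continue
        if popt[1] > 0:
            ratio[vox] = popt[1]
            ok[vox] = True
    return B1Map(ratio=ratio.reshape(shape), mask=ok.reshape(shape) & mask)


# ---------------------------------------------------------------------------
# Eddy currents
# ---------------------------------------------------------------------------


def eddy_current_curves(
    series_by_axis: dict[str, list[tuple[float, FidSignal]]],
    ref_delay_ms: float = 2000.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Normalized FID power integral and phase vs post-gradient delay.

    Both quantities are normalized to their values at ``ref_delay_ms``
    (2 s by default); the phase is the argument of the first FID sample.
    Returns ``{axis: {"delay_ms", "power", "phase"}}``.
    """
    out = {}
    for axis, series in series_by_axis.items():
        delays = np.array([d for d, _ in series], dtype=float)
        if not np.any(np.isclose(delays, ref_delay_ms)):
            raise ValueError(
                f"axis {axis!r}: reference delay {ref_delay_ms} ms missing"
            )
        powers = np.array([f.power_integral() for _, f in series])
        phases = np.array([f.first_sample_phase() for _, f in series])
        iref = int(np.argmin(np.abs(delays - ref_delay_ms)))
        if abs(phases[iref]) > 1e-12:
            phase_norm = phases / phases[iref]
        else:
            # a zero reference phase makes the ratio ill-defined; report the
            # phase difference offset to 1 so the reference still reads 1
            logger.warning(
                "axis %r: reference FID phase is zero; normalizing by difference",
                axis,
            )
            phase_norm = 1.0 + (phases - phases[iref])
        out[axis] = {
            "delay_ms": delays,
            "power": powers / powers[iref],
            "phase": phase_norm,
        }
    return out


# ---------------------------------------------------------------------------
# Interleaving planner
# ---------------------------------------------------------------------------


@dataclass
class InterleavingPlan:
    """Slice timing and stimulation windows within one repetition."""

    slice_starts_ms: np.ndarray
    slice_interval_ms: float
    windows_ms: list  # (start, end) per inter-slice gap
    window_length_ms: float


def plan_interleaving(
    tr_ms: float,
    n_slices: int,
    required_delay_ms: float,
    slice_acq_ms: float,
) -> InterleavingPlan:
    """Distribute slices evenly over TR and find stimulation windows.

    Slices start every ``TR / n_slices`` ms; within each inter-slice gap a
    stimulation window opens after the acquisition ends and closes
    ``required_delay_ms`` before the next acquisition starts.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if tr_ms <= n_slices * slice_acq_ms:
        raise ValueError("TR too short to fit the slice acquisitions")
    interval = tr_ms / n_slices
    length = interval - slice_acq_ms - required_delay_ms
    if length < 0:
        raise InfeasibleScheduleError(
            f"negative stimulation window ({length:.1f} ms) with "
            f"{interval:.1f}-ms slice interval"
        )
    starts = np.arange(n_slices) * interval
    windows = [
        (float(s + slice_acq_ms), float(s + interval - required_delay_ms))
        for s in starts
    ]
    return InterleavingPlan(
        slice_starts_ms=starts,
        slice_interval_ms=float(interval),
        windows_ms=windows,
        window_length_ms=float(length),
    )
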