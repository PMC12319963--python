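"""Trapezoidal pulse model, orientation calibration and channel commands.

The stimulator drives each coil with a trapezoidal monophasic current pulse;
the induced E-field follows -dI/dt, so the field is constant during the
linear rise, zero during the hold, and of opposite sign (scaled by
rise/fall) during the fall.  Electronic orientation control superposes the
two coils' unit fields with per-channel current slews chosen so the combined
peak field points along the requested in-plane angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .efield import EFieldMap

MAX_VOLTAGE = 1500.0  # V, H-bridge capacitor maximum (100% MSO)

__all__ = [
    "PulseWaveform",
    "OrientationCalibration",
    "ChannelCommand",
    "monophasic_pulse",
    "calibrate_orientation",
    "channel_command",
    "achieved_orientation",
    "orientation_sweep_error",
    "DegenerateCalibrationError",
    "VoltageRangeError",
]


class DegenerateCalibrationError(ValueError):
    """The two coil fields are too close to parallel to steer between."""


class VoltageRangeError(ValueError):
    """A channel would require more than the maximum capacitor voltage."""

    def __init__(self, message: str, channel: str):
        super().__init__(message)
        self.channel = channel


@dataclass
class PulseWaveform:
    """Piecewise-linear coil current (time in microseconds, current in A)."""

    times_us: np.ndarray
    currents: np.ndarray
    phases: list  # label per segment, e.g. ["rise", "hold", "fall"]

    def __post_init__(self) -> None:
        self.times_us = np.asarray(self.times_us, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if np.any(np.diff(self.times_us) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.currents[0] != 0 or self.currents[-1] != 0:
            raise ValueError("current must start and end at zero")
        if len(self.phases) != len(self.times_us) - 1:
            raise ValueError("need one phase label per segment")

    @property
    def duration_us(self) -> float:
        return float(self.times_us[-1] - self.times_us[0])

    def didt_segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment boundaries (us) and per-segment dI/dt (A/us)."""
        return self.times_us, np.diff(self.currents) / np.diff(self.times_us)

    def phase_intervals(self) -> dict:
        out = {}
        for (t0, t1), name in zip(
            zip(self.times_us[:-1], self.times_us[1:]), self.phases
        ):
            out.setdefault(name, (t0, t1))
        return out

    def induced_e(self, e_per_didt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Induced-E step waveform: E = -e_per_didt * dI/dt per segment."""
        t, d = self.didt_segments()
        return t, -e_per_didt * d


def monophasic_pulse(
    rise_us: float, hold_us: float, fall_us: float, peak_current: float
) -> PulseWaveform:
    """Trapezoidal monophasic pulse: linear rise, hold, linear fall to zero."""
    if min(rise_us, hold_us, fall_us) <= 0:
        raise ValueError("all phase durations must be positive")
    times = np.array([0.0, rise_us, rise_us + hold_us, rise_us + hold_us + fall_us])
    currents = np.array([0.0, peak_current, peak_current, 0.0])
    return PulseWaveform(times, currents, ["rise", "hold", "fall"])


# ---------------------------------------------------------------------------
# Orientation control
# ---------------------------------------------------------------------------


@dataclass
class OrientationCalibration:
    """Two-channel orientation calibration from the coils' unit fields.

    ``peak_mags`` are peak |E| per unit dI/dt (V/m per A/us); ``peak_dirs``
    the in-plane unit vectors of the peak fields; ``mixing`` maps a requested
    in-plane field direction to channel weights (relative dI/dt).
    Calibrated 0 deg coincides with the bottom coil's peak direction.
    """

    peak_mags: np.ndarray  # (2,)
    peak_dirs: np.ndarray  # (2, 2) in-plane unit vectors
    mixing: np.ndarray  # (2, 2): weights = mixing @ [cos t, sin t]
    e_bottom: EFieldMap | None = field(default=None, repr=False)
    e_top: EFieldMap | None = field(default=None, repr=False)

    def weights(self, theta_deg: float, normalize: bool = True) -> np.ndarray:
        t = np.radians(theta_deg)
        w = self.mixing @ np.array([np.cos(t), np.sin(t)])
        if normalize:
            n = np.linalg.norm(w)
            if n > 0:
                w = w / n
        return w


def _inplane_peak(m: EFieldMap) -> tuple[float, np.ndarray]:
    from .metrics import peak_field

    _, direction, mag = peak_field(m)
    d2 = direction[:2]
    n = np.linalg.norm(d2)
    if n < 1e-9:
        raise DegenerateCalibrationError("peak field has no in-plane component")
    return mag, d2 / n


def calibrate_orientation(
    e_bottom: EFieldMap, e_top: EFieldMap
) -> OrientationCalibration:
    """Calibrate electronic orientation control from two unit-field maps.

    The two maps must share evaluation points.  The mixing matrix solves for
    channel weights so the superposed field at the calibration (peak) point
    has the requested in-plane direction, with both coils normalized to
    equal peak |E|.
    """
    if e_bottom.points.shape != e_top.points.shape or not np.allclose(
        e_bottom.points, e_top.points
    ):
        raise ValueError("maps must share evaluation points")
    m1, d1 = _inplane_peak(e_bottom)
    m2, d2 = _inplane_peak(e_top)
    cosang = abs(float(np.dot(d1, d2)))
    if cosang > np.cos(np.radians(10.0)):
        raise DegenerateCalibrationError(
            "coil peak-field directions are less than 10 degrees apart"
        )
    # columns: in-plane field per unit weight for each channel
    M = np.column_stack([m1 * d1, m2 * d2])
    mixing = np.linalg.inv(M)
    return OrientationCalibration(
        peak_mags=np.array([m1, m2]),
        peak_dirs=np.vstack([d1, d2]),
        mixing=mixing,
        e_bottom=e_bottom,
        e_top=e_top,
    )


def achieved_orientation(cal: OrientationCalibration, theta_deg: float) -> float:
    """Peak-field orientation (deg) actually achieved for a requested angle.

    Superposes the stored unit-field maps with the calibrated weights, finds
    the peak of the combined |E|, and returns the in-plane angle of the field
    there.
    """
    if cal.e_bottom is None or cal.e_top is None:
        raise ValueError("calibration does not carry the unit-field maps")
    w = cal.weights(theta_deg, normalize=False)
    vec = w[0] * cal.e_bottom.vectors + w[1] * cal.e_top.vectors
    mags = np.linalg.norm(vec, axis=1)
    idx = int(np.argmax(mags))
    return float(np.degrees(np.arctan2(vec[idx, 1], vec[idx, 0])))


def orientation_sweep_error(
    cal: OrientationCalibration, angles_deg=None
) -> tuple[float, np.ndarray]:
    """Max |achieved - requested| (deg) over a grid of requested angles."""
    if angles_deg is None:
        angles_deg = np.arange(0, 360)
    errs = []
    for t in angles_deg:
        a = achieved_orientation(cal, float(t))
        d = (a - t + 180.0) % 360.0 - 180.0
        errs.append(abs(d))
    errs = np.asarray(errs)
    return float(errs.max()), errs


@dataclass
class ChannelCommand:
    """Per-channel drive settings for one pulse."""

    voltage: float  # V
    pct_mso: float  # %
    didt: float  # A/us

    def __post_init__(self) -> None:
        if abs(self.voltage) > MAX_VOLTAGE * (1 + 1e-9):
            raise VoltageRangeError(
                f"|voltage| {abs(self.voltage):.0f} V exceeds {MAX_VOLTAGE:.0f} V",
                channel="unknown",
            )


def channel_command(
    theta_deg: float,
    intensity_pct_mso: float,
    cal: OrientationCalibration,
    coil_inductances: tuple[float, float],
    coil_resistances: tuple[float, float] = (0.0, 0.0),
) -> tuple[ChannelCommand, ChannelCommand]:
    """Channel voltages and slews for a stimulus at angle and intensity.

    Intensity is referenced to the bottom coil: at ``theta = 0`` an intensity
    of x% MSO charges the bottom channel to x% of the 1500-V maximum.  Other
    angles are scaled so the induced field intensity at the calibration point
    is unchanged; an off-angle pulse may therefore need more voltage on a
    channel (raising VoltageRangeError past the capacitor maximum).
    Voltage is the inductive requirement L*dI/dt; the resistive drop R*I at
    peak current is not folded in (reported separately by the caller if
    needed).
    """
    if not 0 <= intensity_pct_mso <= 100:
        raise ValueError("intensity must be within [0, 100] %MSO")
    w = cal.weights(theta_deg, normalize=False)
    # scale so theta=0 at 100% intensity charges the bottom channel to 1500 V
    L = np.asarray(coil_inductances, dtype=float)
    w0 = cal.weights(0.0, normalize=False)
    scale = (intensity_pct_mso / 100.0) * MAX_VOLTAGE / (L[0] * abs(w0[0]))
    didt = w * scale  # A/s
    volts = L * didt  # H * A/s = V
    names = ("bottom", "top")
    cmds = []
    for v, d, name in zip(volts, didt, names):
        if abs(v) > MAX_VOLTAGE * (1 + 1e-9):
            raise VoltageRangeError(
                f"{name} channel needs {abs(v):.0f} V (> {MAX_VOLTAGE:.0f} V)", name
            )
        cmds.append(
            ChannelCommand(
                voltage=float(v),
                pct_mso=float(abs(v) / MAX_VOLTAGE * 100.0),
                didt=float(d) / 1e6,  # report A/us
            )
        )
    return cmds[0], cmds[1]
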