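"""Conversion of raw tri-axial accelerometer streams into postural sway features.

The analysis treats quiet stance as an inverted pendulum pivoting at the
ground: the centre of mass (COM) sits at a fixed distance ``L`` (cm) from the
ground, and the direction of the measured resultant acceleration vector gives
the instantaneous inclination.  Projecting ``L`` along the directional cosines
of the resultant yields the ground displacement of the COM in the mediolateral
(ML) and anterior-posterior (AP) directions:

    R       = sqrt(a_x^2 + a_y^2 + a_z^2)
    cos(a)  = a_x / R,  cos(b) = a_y / R,  cos(g) = a_z / R
    d_x     = -L cos(a),  d_y = -L cos(b),  H = L cos(g)

Raw integer samples (LSB) are converted to g by dividing by the sensitivity
scale factor (16,384 LSB/g at +/-2 g full scale), lowpass-filtered with a
second-order Butterworth at 4 Hz, and projected.  Per direction the offset is
removed with the first sample, velocity and acceleration follow by first
differences, and RMS summaries of displacement, velocity and acceleration are
the features handed to the clustering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateSampleError,
    InsufficientDataError,
    InvalidArgumentError,
)

#: default mapping from sway direction to accelerometer axis for the worn device
DEFAULT_AXIS_MAP = {"ML": "x", "AP": "y"}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: standard anthropometric COM height as a fraction of body height
COM_HEIGHT_FRACTION = 0.53

#: gravitational acceleration in cm/s^2, used only where absolute units are requested
G_CM_S2 = 981.0


@dataclass
class RawAccelRecording:
    """One subject x condition recording of integer tri-axial LSB samples."""

    subject_id: str
    condition_id: int
    fs: float
    samples: np.ndarray  # (N, 3) integers, axes x, y, z

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InvalidArgumentError("samples must be an (N, 3) array")
        if self.samples.shape[0] < 2:
            raise InvalidArgumentError("recording must hold at least 2 samples")
        if not (1 <= int(self.condition_id) <= 4):
            raise InvalidArgumentError("condition_id must be in 1..4")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class SwaySeries:
    """Per-sample pendulum projection of a filtered tri-axial signal."""

    R: np.ndarray            # resultant acceleration (unit of the input)
    cosines: np.ndarray      # (N, 3): cos(alpha), cos(beta), cos(gamma)
    d_x: np.ndarray          # ML ground displacement, cm
    d_y: np.ndarray          # AP ground displacement, cm
    H: np.ndarray            # projected COM height, cm
    L: float                 # COM-to-ground distance, cm
    fs: float
    unit: str = "g"


@dataclass
class SwayKinematics:
    """Offset-removed displacement and its first/second differences.

    D spans samples 1..N, V spans 2..N and A spans 3..N; the undefined leading
    entries are dropped rather than zero-padded so RMS values are not biased.
    """

    direction: str
    D: np.ndarray   # cm
    V: np.ndarray   # cm/s
    A: np.ndarray   # cm/s^2
    T: float        # sampling period, s


FEATURE_COLUMNS = [
    "rms_position_cm",
    "rms_velocity_cms",
    "rms_acceleration_cms2",
]


def lsb_to_g(raw: np.ndarray, sensitivity: float) -> np.ndarray:
    """Convert integer LSB samples to g by dividing by the sensitivity (LSB/g)."""
    if sensitivity <= 0:
        raise InvalidArgumentError("sensitivity must be positive (LSB/g)")
    return np.asarray(raw, dtype=float) / float(sensitivity)


def lowpass_filter(
    x: np.ndarray,
    fs: float,
    cutoff: float = 4.0,
    order: int = 2,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth lowpass with unit DC gain.

    The default is a single causal forward pass of the stated order, with the
    filter state initialised to steady state at the first sample so a constant
    input maps to itself exactly (no startup transient).  ``zero_phase``
    switches to a forward-backward pass, which doubles the effective order.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    if not 0 < cutoff < fs / 2:
        raise InvalidArgumentError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2}); got {cutoff}"
        )
    x = np.asarray(x, dtype=float)
    b, a = signal.butter(order, cutoff / (fs / 2.0), btype="low")
    if zero_phase:
        return signal.filtfilt(b, a, x)
    zi = signal.lfilter_zi(b, a) * x[..., 0]
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def project_sway(accel: np.ndarray, L: float, fs: float, unit: str = "g") -> SwaySeries:
    """Project a tri-axial acceleration series onto the ground plane.

    The projection depends only on the direction of the resultant, so the
    acceleration unit (g or cm/s^2) is irrelevant to ``d_x``/``d_y``/``H``.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise InvalidArgumentError("accel must be an (N, 3) array")
    if L <= 0:
        raise InvalidArgumentError("L must be positive")
    R = np.sqrt(np.sum(accel**2, axis=1))
    zero = np.flatnonzero(R == 0.0)
    if zero.size:
        raise DegenerateSampleError(
            f"zero resultant acceleration at sample index {zero[0]}",
            index=int(zero[0]),
        )
    cosines = accel / R[:, None]
    d_x = -L * cosines[:, 0]
    d_y = -L * cosines[:, 1]
    H = L * cosines[:, 2]
    return SwaySeries(R=R, cosines=cosines, d_x=d_x, d_y=d_y, H=H, L=float(L), fs=fs, unit=unit)


def derive_kinematics(d: np.ndarray, fs: float, direction: str = "") -> SwayKinematics:
    """Offset-removed displacement plus first-difference velocity/acceleration.

    D_n = d_n - d_1 (the first sample removes the inclination offset of the
    worn sensor), V_n = (D_n - D_{n-1}) / T, A_n = (V_n - V_{n-1}) / T.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1:
        raise InvalidArgumentError("displacement series must be 1-D")
    if d.size < 3:
        raise InsufficientDataError("need at least 3 samples for kinematics")
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    T = 1.0 / fs
    D = d - d[0]
    V = np.diff(D) / T
    A = np.diff(V) / T
    return SwayKinematics(direction=direction, D=D, V=V, A=A, T=T)


def rms(values: np.ndarray) -> float:
    """Root mean square over the values' own length."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("RMS of an empty series is undefined")
    return float(np.sqrt(np.mean(values**2)))


def rms_features(kin: SwayKinematics) -> dict[str, float]:
    """RMS of displacement, velocity and acceleration, each over its own N."""
    return {
        "rms_position_cm": rms(kin.D),
        "rms_velocity_cms": rms(kin.V),
        "rms_acceleration_cms2": rms(kin.A),
    }


def extract_features(
    recording: RawAccelRecording,
    L: float,
    sensitivity: float = 16384.0,
    cutoff: float = 4.0,
    order: int = 2,
    zero_phase: bool = False,
    axis_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full raw-to-features chain for one recording.

    LSB -> g -> per-axis Butterworth lowpass -> pendulum projection ->
    per-direction kinematics -> RMS summaries.  Returns one row per sway
    direction (ML, AP) with the subject/condition keys attached.
    """
    axis_map = dict(DEFAULT_AXIS_MAP if axis_map is None else axis_map)
    accel_g = lsb_to_g(recording.samples, sensitivity)
    filtered = np.column_stack(
        [
            lowpass_filter(accel_g[:, i], recording.fs, cutoff, order, zero_phase)
            for i in range(3)
        ]
    )
    series = project_sway(filtered, L=L, fs=recording.fs)
    displacement = {"x": series.d_x, "y": series.d_y}
    rows = []
    for direction, axis in axis_map.items():
        if axis not in displacement:
            raise InvalidArgumentError(
                f"axis_map maps {direction!r} to {axis!r}; expected 'x' or 'y'"
            )
        kin = derive_kinematics(displacement[axis], recording.fs, direction)
        row = {
            "subject_id": recording.subject_id,
            "condition": recording.condition_id,
            "direction": direction,
        }
        row.update(rms_features(kin))
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort_features(
    recordings,
    L_by_subject: dict[str, float],
    sensitivity: float = 16384.0,
    cutoff: float = 4.0,
    order: int = 2,
    zero_phase: bool = False,
    axis_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Feature table (subject x condition x direction) for a set of recordings."""
    frames = [
        extract_features(
            rec,
            L=L_by_subject[rec.subject_id],
            sensitivity=sensitivity,
            cutoff=cutoff,
            order=order,
            zero_phase=zero_phase,
            axis_map=axis_map,
        )
        for rec in recordings
    ]
    if not frames:
        raise InsufficientDataError("no recordings supplied")
    return pd.concat(frames, ignore_index=True)
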