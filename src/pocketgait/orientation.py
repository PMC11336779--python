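"""Device orientation, gravity-aligned vertical extraction, zero-phase filtering.

The pipeline only needs the vertical (gravity-aligned) axis, so orientation is
estimated with a tilt complementary filter: gyroscope integration continuously
corrected toward the accelerometer's low-frequency gravity direction. Heading
about the vertical is unobservable from gravity and irrelevant here; the
magnetometer is not used.

Quaternions are scalar-first unit 4-vectors encoding the device→global
rotation. The small quaternion algebra below is hand-written (and
cross-checked against scipy's Rotation in the test suite) so the per-sample
filter loop stays allocation-light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    CannotInitializeError,
    ContractError,
    ParameterError,
    TooShortError,
)
from .io import STANDARD_GRAVITY, ImuRecording

_UP = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# quaternion algebra (scalar-first, device→global)

def quat_mul(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q, scalar-first."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation vector (axis × angle, radians)."""
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        # second-order small-angle expansion keeps the filter loop smooth
        q = np.array([1.0 - angle * angle / 8.0, v[0] / 2, v[1] / 2, v[2] / 2])
        return q / np.linalg.norm(q)
    axis = v / angle
    half = angle / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector v (device frame) into the global frame by q."""
    w, x, y, z = q
    u = np.array([x, y, z])
    return v + 2.0 * np.cross(u, np.cross(u, v) + w * v)


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest-arc unit quaternion rotating unit vector a onto unit vector b."""
    d = float(np.dot(a, b))
    if d < -1.0 + 1e-12:
        # antiparallel: rotate 180° about any axis orthogonal to a
        axis = np.cross(a, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        return np.concatenate([[0.0], axis])
    c = np.cross(a, b)
    q = np.array([1.0 + d, c[0], c[1], c[2]])
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------

@dataclass
class OrientationSeries:
    """Per-sample device→global rotation, scalar-first unit quaternions (n, 4)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ContractError("orientation series must be of shape (n, 4)")
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ContractError("orientation quaternions must be unit norm")

    def __len__(self) -> int:
        return len(self.q)

    def rotation_matrices(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices equivalent to the quaternion series."""
        w, x, y, z = self.q.T
        return np.stack(
            [
                np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
                np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
                np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
            ],
            axis=1,
        )


@dataclass
class GlobalVertical:
    """Gravity-removed vertical acceleration (m/s², positive up) at fs Hz."""

    az: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.az = np.asarray(self.az, dtype=float)

    def __len__(self) -> int:
        return len(self.az)


def estimate_orientation(
    rec: ImuRecording,
    method: str = "tilt_complementary",
    gain: float = 0.02,
    init_window_s: float = 0.5,
) -> OrientationSeries:
    """Estimate the per-sample device→global orientation.

    Parameters
    ----------
    method : {"tilt_complementary", "gyro_only"}
        ``tilt_complementary`` integrates the gyroscope and leans the estimate
        toward the accelerometer gravity direction by ``gain`` (fraction of the
        residual tilt corrected per sample; default 0.02 at 100 Hz, i.e. a time
        constant of about 0.5 s). ``gyro_only`` integrates the gyroscope from
        the initial pose without correction.
    init_window_s : float
        Quasi-static window at the trial start used to initialise the pose
        from the mean accelerometer vector (trials start from standing).
    """
    if method not in ("tilt_complementary", "gyro_only"):
        raise ParameterError(f"unknown orientation method {method!r}")
    acc = rec.accel
    gyr = rec.gyro
    n = len(rec)
    dt = 1.0 / rec.fs

    n0 = max(1, int(round(init_window_s * rec.fs)))
    a0 = acc[:n0].mean(axis=0)
    a0_norm = np.linalg.norm(a0)
    if a0_norm < 1e-6:
        raise CannotInitializeError("accelerometer reads zero in the initial window")
    q = quat_between(a0 / a0_norm, _UP)

    out = np.empty((n, 4))
    for k in range(n):
        if k > 0:
            dq = quat_from_rotvec(gyr[k - 1] * dt)
            q = quat_mul(q, dq)  # gyro rate is in the device frame
            if method == "tilt_complementary":
                a = acc[k]
                a_norm = np.linalg.norm(a)
                if a_norm > 1e-6:
                    v = quat_rotate(q, a / a_norm)
                    err = np.cross(v, _UP)  # global-frame tilt error axis
                    q = quat_mul(quat_from_rotvec(gain * err), q)
            q = q / np.linalg.norm(q)
        out[k] = q
    return OrientationSeries(out)


def rotate_to_global(
    rec: ImuRecording, q: OrientationSeries, g: float = STANDARD_GRAVITY
) -> GlobalVertical:
    """Rotate device-frame acceleration into the global frame and remove gravity.

    Returns the vertical component only: ``az = (R a_device) · ẑ − g``.
    """
    if len(q) != len(rec):
        raise ContractError(
            f"orientation series length {len(q)} != recording length {len(rec)}"
        )
    R = q.rotation_matrices()
    az = np.einsum("nj,nj->n", R[:, 2, :], rec.accel) - g
    return GlobalVertical(az=az, fs=rec.fs)


def butter_zero_phase(
    x: np.ndarray, fs: float, cutoff: float, order: int = 4, kind: str = "highpass"
) -> np.ndarray:
    """Forward–backward (zero phase) Butterworth filter of the designed order.

    The two passes square the magnitude response: a 4th-order design has an
    8th-order-magnitude rolloff and exactly zero phase lag, which preserves the
    timing of gait events.
    """
    if kind not in ("lowpass", "highpass"):
        raise ParameterError(f"kind must be lowpass or highpass, got {kind!r}")
    if not 0 < cutoff < fs / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie strictly between 0 and Nyquist ({fs / 2} Hz)"
        )
    x = np.asarray(x, dtype=float)
    b, a = signal.butter(order, cutoff, btype="highpass" if kind == "highpass" else "lowpass", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if len(x) <= 3 * padlen:
        raise TooShortError(
            f"series of length {len(x)} too short for an order-{order} zero-phase filter"
        )
    return signal.filtfilt(b, a, x)
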