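"""Inverted-pendulum step length and gait speed from vertical acceleration.

During single support the body vaults over a rigid stance leg of length *l*.
If the centre of mass drops by *h* between its apex and foot contact, the
chord geometry of the pendulum arc gives the step length

    SL = 2·sqrt(2·h·l − h²)

Vertical position is obtained by double trapezoidal integration of the
gravity-removed vertical acceleration followed by a 4th-order zero-phase
high-pass at 0.11 Hz, which removes the (quadratic-in-time) drift that any
accelerometer bias or integration error produces while leaving the gait band
(≈0.5–3 Hz) untouched. *h* for a step is the peak-to-trough excursion of the
vertical position within that step's window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ComputationError, ParameterError, ValidationError
from .events import STRIDE_GATE_S, detect_heel_strikes, segment_strides
from .io import STRIDE_TABLE_COLUMNS, ImuRecording
from .orientation import (
    GlobalVertical,
    butter_zero_phase,
    estimate_orientation,
    rotate_to_global,
)

log = logging.getLogger(__name__)

HP_CUTOFF_HZ = 0.11
HP_ORDER = 4


@dataclass
class VerticalPosition:
    """Drift-free vertical position of the device (m) at fs Hz."""

    z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)

    def __len__(self) -> int:
        return len(self.z)


def vertical_position(
    az: GlobalVertical,
    hp_cutoff: float = HP_CUTOFF_HZ,
    hp_order: int = HP_ORDER,
) -> VerticalPosition:
    """Doubly integrate vertical acceleration and high-pass the result.

    The trial-mean acceleration is removed before integration as a numerical
    guard (it would otherwise grow quadratically and dwarf the signal on long
    trials); the mandated high-pass on the *position* then removes the
    remaining drift. The integration constant of the velocity is likewise
    fixed by removing its mean, which only affects the linear trend that the
    high-pass removes anyway.
    """
    a = az.az - np.mean(az.az)
    dt = 1.0 / az.fs
    v = cumulative_trapezoid(a, dx=dt, initial=0.0)
    v -= np.mean(v)
    z = cumulative_trapezoid(v, dx=dt, initial=0.0)
    z = butter_zero_phase(z, az.fs, hp_cutoff, order=hp_order, kind="highpass")
    return VerticalPosition(z=z, fs=az.fs)


def step_height(z_pos: VerticalPosition, start: int, stop: int) -> float:
    """Peak-to-trough vertical excursion within one step window [start, stop)."""
    if not 0 <= start < stop <= len(z_pos):
        raise ComputationError(f"step window [{start}, {stop}) outside series or empty")
    w = z_pos.z[start:stop]
    return float(np.max(w) - np.min(w))


def step_length_pendulum(h, l):
    """Inverted-pendulum step length 2·sqrt(2·h·l − h²); accepts scalars or arrays.

    Requires 0 ≤ h ≤ 2l (the radicand h·(2l − h) is negative beyond) and l > 0.
    """
    h = np.asarray(h, dtype=float)
    scalar = h.ndim == 0
    if np.any(np.asarray(l) <= 0):
        raise ValidationError(f"leg length must be positive, got {l}")
    if np.any(h < 0) or np.any(h > 2 * np.asarray(l)):
        raise ValidationError("step height h must satisfy 0 <= h <= 2*l")
    sl = 2.0 * np.sqrt(2.0 * h * l - h * h)
    return float(sl) if scalar else sl


def estimate_gait(
    rec: ImuRecording,
    orientation_method: str = "tilt_complementary",
    orientation_gain: float = 0.02,
    gravity: float | None = None,
    lp_cutoff: float = 3.0,
    min_period: float = 0.4,
    prominence_k: float = 1.0,
    stride_gate: tuple[float, float] = STRIDE_GATE_S,
    hp_cutoff: float = HP_CUTOFF_HZ,
    hp_order: int = HP_ORDER,
) -> pd.DataFrame:
    """Run the full raw pipeline on a recording and return a stride table.

    Orientation → vertical acceleration → heel strikes → stride segmentation →
    vertical position → per-step heights → pendulum step lengths → speed.
    Only the raw (unadjusted) columns are filled; the adjusted columns are NaN
    until a coefficient table is applied (see :mod:`pocketgait.adjustment`).

    The returned DataFrame has the canonical stride-table columns; strides
    whose step height reaches or exceeds the leg length (outside pendulum
    geometry) are excluded and logged.
    """
    from .io import STANDARD_GRAVITY

    g = STANDARD_GRAVITY if gravity is None else gravity
    q = estimate_orientation(rec, method=orientation_method, gain=orientation_gain)
    az = rotate_to_global(rec, q, g=g)
    if abs(float(np.mean(az.az))) > 0.5:
        log.warning(
            "mean vertical acceleration %.3f m/s² exceeds 0.5 m/s²; "
            "orientation or gravity removal may be off",
            float(np.mean(az.az)),
        )
    events = detect_heel_strikes(
        az, lp_cutoff=lp_cutoff, min_period=min_period, prominence_k=prominence_k
    )
    seg = segment_strides(events, stride_gate=stride_gate)
    z = vertical_position(az, hp_cutoff=hp_cutoff, hp_order=hp_order)

    rows = []
    n_rejected = 0
    l = rec.leg_length
    for k in range(len(seg)):
        i, m, j = int(seg.hs_i[k]), int(seg.hs_mid[k]), int(seg.hs_next[k])
        h1 = step_height(z, i, m + 1)
        h2 = step_height(z, m, j + 1)
        if not (0 < h1 < l and 0 < h2 < l):
            n_rejected += 1
            continue
        sl1 = step_length_pendulum(h1, l)
        sl2 = step_length_pendulum(h2, l)
        stride_length = sl1 + sl2
        st = float(seg.stride_time[k])
        rows.append(
            {
                "stride_index": len(rows),
                "t_start_s": rec.t[i],
                "stride_time_s": st,
                "h1_m": h1,
                "h2_m": h2,
                "step_length_1_m": sl1,
                "step_length_2_m": sl2,
                "step_length_adj_1_m": np.nan,
                "step_length_adj_2_m": np.nan,
                "zone_1": "",
                "zone_2": "",
                "stride_length_m": stride_length,
                "speed_mps": stride_length / st,
                "speed_adj_mps": np.nan,
            }
        )
    if n_rejected:
        log.info("excluded %d strides with non-physiologic step heights", n_rejected)
    table = pd.DataFrame(rows, columns=list(STRIDE_TABLE_COLUMNS))
    table.attrs["n_excluded_duration"] = seg.n_excluded
    table.attrs["n_excluded_height"] = n_rejected
    table.attrs["subject_id"] = rec.subject_id
    table.attrs["condition"] = rec.condition
    return table
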