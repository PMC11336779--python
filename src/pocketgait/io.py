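"""Reading and writing of IMU trials, reference step tables and stride tables.

File dialect is deliberately plain: comma-separated, dot decimal, mandatory
header row. IMU files carry time in seconds, accelerations in m/s² (or in g
with ``accel_in_g=True``), angular rates in rad/s. All readers validate units
and sampling and drop rows containing non-finite values (the count is kept on
the returned object); runs of more than ``MAX_GAP`` consecutive bad rows abort,
because double integration downstream is sensitive to gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, TooShortError, ValidationError

log = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665
"""Standard gravity in m/s², used for g-unit conversion and gravity removal."""

#: Mandatory IMU channel columns, in file order. Magnetometer columns are optional.
IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
MAG_COLUMNS = ("mx", "my", "mz")

#: Longest run of consecutive non-finite rows that may be dropped silently.
MAX_GAP = 3

#: Column set of the on-disk stride table.
STRIDE_TABLE_COLUMNS = (
    "stride_index",
    "t_start_s",
    "stride_time_s",
    "h1_m",
    "h2_m",
    "step_length_1_m",
    "step_length_2_m",
    "step_length_adj_1_m",
    "step_length_adj_2_m",
    "zone_1",
    "zone_2",
    "stride_length_m",
    "speed_mps",
    "speed_adj_mps",
)

CONDITIONS = ("normal", "dual_task", "unknown")


@dataclass
class ImuRecording:
    """One walking trial of time-stamped tri-axial sensor streams.

    Attributes
    ----------
    t : ndarray
        Seconds since trial start, strictly increasing.
    ax, ay, az : ndarray
        Accelerometer in m/s², device frame.
    gx, gy, gz : ndarray
        Gyroscope in rad/s, device frame.
    mx, my, mz : ndarray or None
        Optional magnetometer channels (arbitrary consistent units).
    fs : float
        Nominal sampling frequency in Hz.
    subject_id : str
    leg_length : float
        Trochanter-to-floor leg length in meters; must lie in (0.5, 1.4).
    condition : str
        One of ``normal``, ``dual_task``, ``unknown``.
    n_dropped : int
        Rows removed during ingest because they contained non-finite values.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    fs: float
    subject_id: str = ""
    leg_length: float = 0.9
    condition: str = "unknown"
    mx: np.ndarray | None = None
    my: np.ndarray | None = None
    mz: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        arrays = [self.t, self.ax, self.ay, self.az, self.gx, self.gy, self.gz]
        for name in ("t", "ax", "ay", "az", "gx", "gy", "gz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        arrays = [self.t, self.ax, self.ay, self.az, self.gx, self.gy, self.gz]
        n = len(self.t)
        if any(len(a) != n for a in arrays):
            raise FormatError("all channel series must have identical length")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if n < 2 * self.fs:
            raise TooShortError(
                f"recording has {n} samples (< 2 s at {self.fs} Hz)"
            )
        if np.any(np.diff(self.t) <= 0):
            raise FormatError("time stamps are not strictly increasing")
        med_dt = float(np.median(np.diff(self.t)))
        if abs(med_dt - 1.0 / self.fs) > 0.05 / self.fs:
            raise ValidationError(
                f"median sampling interval {med_dt:.6g} s deviates more than 5% "
                f"from nominal 1/{self.fs:g} s"
            )
        if not 0.5 < self.leg_length < 1.4:
            raise ValidationError(
                f"leg_length {self.leg_length} m outside the plausible (0.5, 1.4) m range"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        for a in arrays:
            if not np.all(np.isfinite(a)):
                raise ValidationError("non-finite values present after ingest")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def accel(self) -> np.ndarray:
        """(n, 3) accelerometer matrix in the device frame."""
        return np.column_stack([self.ax, self.ay, self.az])

    @property
    def gyro(self) -> np.ndarray:
        """(n, 3) gyroscope matrix in the device frame."""
        return np.column_stack([self.gx, self.gy, self.gz])


@dataclass
class ReferenceSteps:
    """Per-step reference (gold standard) step lengths, ordered by step index."""

    step_index: np.ndarray
    step_length_ref: np.ndarray
    stride_time_ref: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.step_index = np.asarray(self.step_index)
        self.step_length_ref = np.asarray(self.step_length_ref, dtype=float)
        if len(self.step_index) != len(self.step_length_ref):
            raise FormatError("step_index and step_length_ref lengths differ")
        if np.any(self.step_length_ref <= 0):
            raise ValidationError("reference step lengths must be positive")
        order = np.argsort(self.step_index, kind="stable")
        self.step_index = self.step_index[order]
        self.step_length_ref = self.step_length_ref[order]
        if self.stride_time_ref is not None:
            self.stride_time_ref = np.asarray(self.stride_time_ref, dtype=float)[order]

    def __len__(self) -> int:
        return len(self.step_index)


def _drop_bad_rows(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    finite = np.isfinite(df[cols].to_numpy(dtype=float)).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        # refuse long gaps: integration downstream cannot bridge them
        bad = ~finite
        run, longest = 0, 0
        for b in bad:
            run = run + 1 if b else 0
            longest = max(longest, run)
        if longest > MAX_GAP:
            raise FormatError(
                f"{longest} consecutive rows with non-finite values (max allowed {MAX_GAP})"
            )
        log.warning("dropped %d rows with non-finite values", n_bad)
    return df.loc[finite], n_bad


def read_imu_csv(
    path,
    subject_id: str = "",
    leg_length: float = 0.9,
    condition: str = "unknown",
    fs: float = 100.0,
    accel_in_g: bool = False,
) -> ImuRecording:
    """Read an IMU trial from a delimited text file.

    The file must have a header naming at least ``t,ax,ay,az,gx,gy,gz``;
    ``mx,my,mz`` are picked up when present. With ``accel_in_g`` the
    accelerometer columns are converted from g to m/s².
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError as e:
        raise InputError(str(e)) from e
    except Exception as e:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {e}") from e
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    has_mag = all(c in df.columns for c in MAG_COLUMNS)
    cols = list(IMU_COLUMNS) + (list(MAG_COLUMNS) if has_mag else [])
    df, n_dropped = _drop_bad_rows(df, cols)
    scale = STANDARD_GRAVITY if accel_in_g else 1.0
    kwargs = {}
    if has_mag:
        kwargs = {c: df[c].to_numpy(dtype=float) for c in MAG_COLUMNS}
    rec = ImuRecording(
        t=df["t"].to_numpy(dtype=float),
        ax=df["ax"].to_numpy(dtype=float) * scale,
        ay=df["ay"].to_numpy(dtype=float) * scale,
        az=df["az"].to_numpy(dtype=float) * scale,
        gx=df["gx"].to_numpy(dtype=float),
        gy=df["gy"].to_numpy(dtype=float),
        gz=df["gz"].to_numpy(dtype=float),
        fs=fs,
        subject_id=subject_id,
        leg_length=leg_length,
        condition=condition,
        n_dropped=n_dropped,
        **kwargs,
    )
    if n_dropped:
        log.info("read %s: %d samples, %d dropped", path, len(rec), n_dropped)
    return rec


def write_imu_csv(rec: ImuRecording, path) -> None:
    """Write an IMU recording with full float precision (bit-exact round trip)."""
    data = {c: getattr(rec, c) for c in IMU_COLUMNS}
    if rec.mx is not None:
        for c in MAG_COLUMNS:
            data[c] = getattr(rec, c)
    pd.DataFrame(data).to_csv(path, index=False, float_format=lambda v: format(float(v), ".17g"))


def read_reference_csv(path, source: str = "") -> ReferenceSteps:
    """Read a reference step table (``step_index,step_length_ref[,stride_time_ref]``)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError as e:
        raise InputError(str(e)) from e
    if "step_length_ref" not in df.columns:
        raise FormatError("missing mandatory column: step_length_ref")
    if "step_index" not in df.columns:
        df["step_index"] = np.arange(len(df))
    stride = (
        df["stride_time_ref"].to_numpy(dtype=float)
        if "stride_time_ref" in df.columns
        else None
    )
    return ReferenceSteps(
        step_index=df["step_index"].to_numpy(),
        step_length_ref=df["step_length_ref"].to_numpy(dtype=float),
        stride_time_ref=stride,
        source=source or str(path),
    )


def write_reference_csv(ref: ReferenceSteps, path) -> None:
    data = {"step_index": ref.step_index, "step_length_ref": ref.step_length_ref}
    if ref.stride_time_ref is not None:
        data["stride_time_ref"] = ref.stride_time_ref
    pd.DataFrame(data).to_csv(path, index=False, float_format=lambda v: format(float(v), ".17g"))


def write_stride_table(table: pd.DataFrame, path) -> None:
    """Write a stride table with the canonical column set, floats at 6 significant digits."""
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty stride table")
    missing = [c for c in STRIDE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"stride table missing column(s): {', '.join(missing)}")
    out = table.loc[:, list(STRIDE_TABLE_COLUMNS)]
    try:
        out.to_csv(path, index=False, float_format="%.6g")
    except OSError as e:
        raise InputError(f"cannot write {path}: {e}") from e


def read_stride_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as e:
        raise InputError(str(e)) from e
    missing = [c for c in STRIDE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stride table missing column(s): {', '.join(missing)}")
    return df
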