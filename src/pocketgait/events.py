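"""Heel-strike detection and stride segmentation.

Heel strikes appear as the high-amplitude peaks of the vertical acceleration.
Before peak picking the series is smoothed with a zero-phase low-pass (default
3 Hz) so that gait's fundamental and first harmonic survive while impact
ringing collapses into a single peak per contact. The prominence threshold is
expressed in units of the robust dispersion of the filtered signal, making
detection invariant to amplitude scaling.

A single pocket-worn IMU cannot tell left from right, so feet are assigned by
alternation: every other heel strike belongs to the same foot, and a stride
spans heel strike k → k+2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ContractError, InsufficientEventsError
from .orientation import GlobalVertical, butter_zero_phase

log = logging.getLogger(__name__)

#: Physiologic stride-duration gate in seconds; strides outside are excluded.
STRIDE_GATE_S = (0.5, 2.5)


@dataclass
class GaitEventSet:
    """Sample indices of detected heel strikes (and optional toe-offs)."""

    hs_idx: np.ndarray
    fs: float
    to_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hs_idx = np.asarray(self.hs_idx, dtype=int)
        if len(self.hs_idx) and np.any(np.diff(self.hs_idx) <= 0):
            raise ContractError("heel-strike indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.hs_idx)

    @property
    def hs_times(self) -> np.ndarray:
        return self.hs_idx / self.fs


@dataclass
class StrideSegmentation:
    """Same-foot heel-strike triples and stride times after duration gating."""

    hs_i: np.ndarray
    hs_mid: np.ndarray
    hs_next: np.ndarray
    stride_time: np.ndarray
    fs: float
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.hs_i)


def detect_heel_strikes(
    az: GlobalVertical,
    lp_cutoff: float = 3.0,
    min_period: float = 0.4,
    prominence_k: float = 1.0,
    detect_toe_off: bool = False,
) -> GaitEventSet:
    """Detect heel strikes as prominent peaks of the low-passed vertical acceleration.

    ``min_period`` is the shortest admissible interval between successive heel
    strikes (0.4 s ≙ a ceiling cadence of 2.5 steps/s); ``prominence_k`` scales
    the peak-prominence threshold relative to the robust SD (1.4826·MAD) of
    the filtered series. Returns an empty event set when nothing crosses the
    threshold.
    """
    x = butter_zero_phase(az.az, az.fs, lp_cutoff, order=4, kind="lowpass")
    robust_sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    if robust_sd == 0.0:
        return GaitEventSet(hs_idx=np.array([], dtype=int), fs=az.fs)
    distance = max(1, int(round(min_period * az.fs)))
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=prominence_k * robust_sd)
    to_idx = None
    if detect_toe_off and len(peaks) >= 2:
        # toe-off ≙ the low-amplitude extreme between consecutive contacts
        to_idx = np.array(
            [peaks[i] + int(np.argmin(x[peaks[i]:peaks[i + 1]])) for i in range(len(peaks) - 1)]
        )
    return GaitEventSet(hs_idx=peaks, fs=az.fs, to_idx=to_idx)


def segment_strides(
    events: GaitEventSet,
    stride_gate: tuple[float, float] = STRIDE_GATE_S,
) -> StrideSegmentation:
    """Pair alternating heel strikes into strides and gate on duration.

    Stride k spans heel strikes k → k+2 (alternation = same foot) and brackets
    the contralateral contact k+1. Strides outside ``stride_gate`` seconds are
    excluded and counted, not errors: they typically reflect missed events or
    turns.
    """
    if len(events) < 3:
        raise InsufficientEventsError(
            f"need at least 3 heel strikes to form a stride, got {len(events)}"
        )
    hs = events.hs_idx
    i, mid, nxt = hs[:-2], hs[1:-1], hs[2:]
    stride_time = (nxt - i) / events.fs
    keep = (stride_time >= stride_gate[0]) & (stride_time <= stride_gate[1])
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("excluded %d strides outside the %s s duration gate", n_excluded, stride_gate)
    return StrideSegmentation(
        hs_i=i[keep],
        hs_mid=mid[keep],
        hs_next=nxt[keep],
        stride_time=stride_time[keep],
        fs=events.fs,
        n_excluded=n_excluded,
    )
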