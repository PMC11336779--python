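"""Ground-truth-annotated synthetic inputs.

Two generators:

* :func:`simulate_imu_walk` — a pocket-IMU walking trial whose vertical
  kinematics are exactly those of the inverted-pendulum model. Per step the
  pendulum angle sweeps −θ₀ → θ₀ with a raised-cosine time course
  θ(t) = −θ₀·cos(πt/T), so the vertical velocity is zero at each foot contact
  and the acceleration is smooth; the identities h = l·(1−cos θ₀) and
  SL = 2·l·sin θ₀ hold exactly per step, which makes the pendulum step-length
  formula exact on the true (h, l). A damped high-frequency burst is added at
  each heel strike, the signal is rotated into a (tilted) device frame, and
  seeded Gaussian noise plus a constant bias corrupt the channels.
* :func:`simulate_paired_steps` — paired app-vs-reference step lengths with a
  configurable piecewise multiplicative bias (est = ref / c(zone of est)),
  emulating the short-step underestimation / long-step overestimation pattern
  that the zone-coefficient correction targets.

All randomness is fully determined by the profile seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ComputationError, ValidationError
from .io import STANDARD_GRAVITY, ImuRecording
from .orientation import quat_from_rotvec, quat_mul, quat_rotate, quat_conj

_IDENTITY_Q = (1.0, 0.0, 0.0, 0.0)


def tilt_quaternion(angle_deg: float, axis: str = "x") -> np.ndarray:
    """Device→global quaternion for a device tilted by ``angle_deg`` about a horizontal axis."""
    unit = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0])}[axis]
    return quat_from_rotvec(np.deg2rad(angle_deg) * unit)


@dataclass
class WalkProfile:
    """Generator parameters and per-step ground truth commands.

    ``step_lengths`` holds one commanded step length (m) per step;
    ``stride_times`` one duration (s) per stride (two steps). Sensor
    imperfections: per-axis accelerometer noise SD (m/s²), constant per-axis
    accelerometer bias (m/s²), gyroscope noise SD (rad/s). ``impact_amp`` sets
    the heel-strike burst amplitude (an exponentially decaying 15 Hz ring,
    0.1 s long). ``orientation_q`` is the constant device→global attitude;
    ``sway_amp_deg``/``sway_freq_hz`` superimpose a sinusoidal pitch sway to
    exercise the orientation filter. ``lead_s`` seconds of quiet standing pad
    both ends of the walk (orientation initialisation assumes a standing
    start).
    """

    step_lengths: np.ndarray
    stride_times: np.ndarray
    leg_length: float = 0.9
    fs: float = 100.0
    orientation_q: tuple = _IDENTITY_Q
    noise_sd: float = 0.5
    accel_bias: float = 0.0
    gyro_noise_sd: float = 0.02
    impact_amp: float = 3.0
    impact_freq_hz: float = 15.0
    impact_tau_s: float = 0.02
    impact_dur_s: float = 0.1
    sway_amp_deg: float = 0.0
    sway_freq_hz: float = 0.25
    asymmetry: float = 0.0
    lead_s: float = 2.0
    ramp_s: float = 0.5
    seed: int = 0
    subject_id: str = "synthetic"
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.step_lengths = np.atleast_1d(np.asarray(self.step_lengths, dtype=float))
        self.stride_times = np.atleast_1d(np.asarray(self.stride_times, dtype=float))
        if self.step_lengths.size == 0:
            raise ValidationError("profile commands zero steps")
        if np.any(self.step_lengths <= 0) or np.any(
            self.step_lengths >= 2 * self.leg_length
        ):
            raise ValidationError("step lengths must lie in (0, 2·leg_length)")
        if np.any(self.stride_times < 0.5) or np.any(self.stride_times > 2.5):
            raise ValidationError("stride times must lie in [0.5, 2.5] s")
        n_strides_needed = (len(self.step_lengths) + 1) // 2
        if len(self.stride_times) == 1:
            self.stride_times = np.full(n_strides_needed, self.stride_times[0])
        if len(self.stride_times) < n_strides_needed:
            raise ValidationError(
                f"need {n_strides_needed} stride times for {len(self.step_lengths)} steps"
            )
        if not 0 <= abs(self.asymmetry) < 1:
            raise ValidationError("asymmetry factor must lie in (-1, 1)")

    @classmethod
    def constant(
        cls,
        step_length: float = 0.6,
        cadence: float = 1.8,
        duration_s: float = 30.0,
        **kwargs,
    ) -> "WalkProfile":
        """Steady walk: fixed step length (m) and cadence (steps/s) for ``duration_s``."""
        n_steps = max(1, int(np.floor(duration_s * cadence)))
        stride_time = 2.0 / cadence
        return cls(
            step_lengths=np.full(n_steps, step_length),
            stride_times=np.full((n_steps + 1) // 2, stride_time),
            **kwargs,
        )

    @property
    def n_steps(self) -> int:
        return len(self.step_lengths)

    def step_durations(self) -> np.ndarray:
        """Per-step durations: half a stride, modulated by the per-foot asymmetry."""
        d = np.repeat(self.stride_times / 2.0, 2)[: self.n_steps]
        factor = np.where(np.arange(self.n_steps) % 2 == 0, 1 + self.asymmetry, 1 - self.asymmetry)
        return d * factor


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated recording."""

    t_events: np.ndarray  # heel-strike times, s (n_steps + 1)
    h: np.ndarray  # true per-step vertical excursion, m
    step_lengths: np.ndarray  # commanded per-step lengths, m
    stride_times: np.ndarray  # per-stride durations, s
    profile: WalkProfile


def _correct_ramp(z_acc, t, mask, i_ref, v_ref, z_ref) -> None:
    """Nudge ramp samples so the discrete double-trapezoid state at ``i_ref``
    equals (v_ref, z_ref). Uses two half-sine modes that vanish at the ramp
    endpoints, so continuity is preserved; the correction is O(trapezoid
    error), far below the gait signal."""
    from scipy.integrate import cumulative_trapezoid

    dt = t[1] - t[0]
    v = cumulative_trapezoid(z_acc, dx=dt, initial=0.0)
    z = cumulative_trapezoid(v, dx=dt, initial=0.0)
    dv = v_ref - v[i_ref]
    dz = z_ref - z[i_ref]
    idx = np.where(mask)[0]
    if len(idx) < 4:
        return
    u = np.linspace(0.0, 1.0, len(idx) + 2)[1:-1]
    A = np.empty((2, 2))
    modes = [np.sin(np.pi * u), np.sin(2 * np.pi * u)]
    for col, w in enumerate(modes):
        b = np.zeros_like(z_acc)
        b[idx] = w
        vb = cumulative_trapezoid(b, dx=dt, initial=0.0)
        zb = cumulative_trapezoid(vb, dx=dt, initial=0.0)
        A[0, col] = vb[i_ref]
        A[1, col] = zb[i_ref]
    try:
        c = np.linalg.solve(A, np.array([dv, dz]))
    except np.linalg.LinAlgError:
        return
    z_acc[idx] += c[0] * modes[0] + c[1] * modes[1]


def simulate_imu_walk(profile: WalkProfile) -> tuple[ImuRecording, SyntheticTruth]:
    """Generate one synthetic walking trial plus its ground truth.

    Returns the recording in the device frame (accelerometer measures specific
    force: a static level device reads (0, 0, +g)) and the truth object with
    exact event times, per-step heights and commanded step lengths.
    """
    p = profile
    l = p.leg_length
    rng = np.random.default_rng(p.seed)
    theta0 = np.arcsin(p.step_lengths / (2.0 * l))
    h_true = l * (1.0 - np.cos(theta0))
    durations = p.step_durations()
    t_hs = p.lead_s + np.concatenate([[0.0], np.cumsum(durations)])
    total = t_hs[-1] + p.lead_s
    t = np.arange(int(round(total * p.fs))) / p.fs

    z_acc = np.zeros_like(t)
    z_pos = np.zeros_like(t)
    for k in range(p.n_steps):
        sel = (t >= t_hs[k]) & (t < t_hs[k + 1])
        tau = t[sel] - t_hs[k]
        T = durations[k]
        phase = np.pi * tau / T
        th = -theta0[k] * np.cos(phase)
        thd = theta0[k] * (np.pi / T) * np.sin(phase)
        thdd = theta0[k] * (np.pi / T) ** 2 * np.cos(phase)
        z_pos[sel] = l * (np.cos(th) - np.cos(theta0[k]))
        z_acc[sel] = -l * (np.cos(th) * thd**2 + np.sin(th) * thdd)

    # Gait initiation/termination: the pendulum acceleration is nonzero at the
    # first and last contact, so a hard standing→walking transition would be a
    # step discontinuity whose discrete integral leaves a spurious velocity
    # offset. Ramp smoothly inside the quiet pads with a quartic profile
    # p(u) = 6u² − 20u³ + 15u⁴ (p(1)=1, ∫p = ∫∫p = 0): acceleration is
    # continuous and the net velocity/displacement change of the ramp is zero,
    # so the walk still starts and ends at rest at z = 0.
    T_r = min(p.ramp_s, p.lead_s)
    if T_r > 0:
        i_first = int(np.searchsorted(t, t_hs[0]))
        a_start = z_acc[i_first]
        sel = (t >= t_hs[0] - T_r) & (t < t_hs[0])
        u = (t[sel] - (t_hs[0] - T_r)) / T_r
        z_acc[sel] = a_start * (6 * u**2 - 20 * u**3 + 15 * u**4)
        i_last = int(np.searchsorted(t, t_hs[-1]))
        a_end = z_acc[i_last - 1] if i_last > 0 else 0.0
        sel_end = (t >= t_hs[-1]) & (t < t_hs[-1] + T_r)
        u = 1.0 - (t[sel_end] - t_hs[-1]) / T_r
        z_acc[sel_end] = a_end * (6 * u**2 - 20 * u**3 + 15 * u**4)
        # The analytic ramp has zero net ∫ and ∫∫, but its *discrete* trapezoid
        # integral does not quite vanish, which would leave a constant velocity
        # offset (hence a linear position drift) for the rest of the trial.
        # Add a small two-mode correction on the ramp samples so the discrete
        # velocity and position at the junction sample match the model state.
        v_ref = -l * np.sin(-theta0[0] * np.cos(np.pi * (t[i_first] - t_hs[0]) / durations[0])) \
            * theta0[0] * (np.pi / durations[0]) * np.sin(np.pi * (t[i_first] - t_hs[0]) / durations[0])
        z_ref = z_pos[i_first]
        _correct_ramp(z_acc, t, sel, i_first, v_ref, z_ref)
        if sel_end.any():
            _correct_ramp(z_acc, t, sel_end, len(t) - 1, 0.0, 0.0)

    # heel-strike impact transient: damped ring, band-separated from the gait band
    for tk in t_hs:
        sel = (t >= tk) & (t < tk + p.impact_dur_s)
        tau = t[sel] - tk
        z_acc[sel] += (
            p.impact_amp * np.exp(-tau / p.impact_tau_s) * np.sin(2 * np.pi * p.impact_freq_hz * tau)
        )

    f_global = np.zeros((len(t), 3))
    f_global[:, 2] = z_acc + STANDARD_GRAVITY

    q0 = np.asarray(p.orientation_q, dtype=float)
    q0 = q0 / np.linalg.norm(q0)
    gyro = np.zeros((len(t), 3))
    if p.sway_amp_deg != 0.0:
        amp = np.deg2rad(p.sway_amp_deg)
        alpha = amp * np.sin(2 * np.pi * p.sway_freq_hz * t)
        gyro[:, 0] = amp * 2 * np.pi * p.sway_freq_hz * np.cos(2 * np.pi * p.sway_freq_hz * t)
        a_dev = np.empty_like(f_global)
        for k in range(len(t)):
            qk = quat_mul(q0, quat_from_rotvec(np.array([alpha[k], 0.0, 0.0])))
            a_dev[k] = quat_rotate(quat_conj(qk), f_global[k])
    else:
        qc = quat_conj(q0)
        a_dev = np.array([quat_rotate(qc, np.array([0.0, 0.0, 1.0]))]) * f_global[:, 2][:, None]

    if p.noise_sd > 0:
        a_dev = a_dev + rng.normal(0.0, p.noise_sd, a_dev.shape)
    if p.accel_bias != 0.0:
        a_dev = a_dev + p.accel_bias
    if p.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, p.gyro_noise_sd, gyro.shape)

    rec = ImuRecording(
        t=t,
        ax=a_dev[:, 0],
        ay=a_dev[:, 1],
        az=a_dev[:, 2],
        gx=gyro[:, 0],
        gy=gyro[:, 1],
        gz=gyro[:, 2],
        fs=p.fs,
        subject_id=p.subject_id,
        leg_length=l,
        condition=p.condition,
    )
    truth = SyntheticTruth(
        t_events=t_hs,
        h=h_true,
        step_lengths=p.step_lengths.copy(),
        stride_times=p.stride_times.copy(),
        profile=p,
    )
    return rec, truth


def _in_zone(x: float, edges: np.ndarray, k: int) -> bool:
    last = k == len(edges) - 2
    return (edges[k] <= x < edges[k + 1]) or (last and x == edges[k + 1])


def simulate_paired_steps(
    n: int,
    ref_range: tuple[float, float] = (0.28, 0.81),
    zone_edges=(0.2, 0.5, 0.8, 1.1),
    zone_coeffs=(1.37, 1.02, 0.74),
    noise_sd: float = 0.02,
    seed: int = 0,
    max_attempts_per_pair: int = 1000,
):
    """Paired app-vs-reference step lengths with piecewise multiplicative bias.

    For each pair a reference length is drawn uniformly on ``ref_range`` and
    the app estimate is constructed as ref / c(zone) + noise, keeping only
    draws whose observed estimate actually falls in the zone whose coefficient
    was used (so adjusting with the true coefficients inverts the bias
    exactly when ``noise_sd`` is 0). When several zones are consistent with
    one reference value the choice is uniform among them (seeded). Returns
    ``(PairedSteps, truth)`` where truth records the per-pair zone, the
    noiseless estimate and the redraw count.
    """
    from .adjustment import PairedSteps

    edges = np.asarray(zone_edges, dtype=float)
    coeffs = np.asarray(zone_coeffs, dtype=float)
    if n < 2:
        raise ValidationError("need n >= 2 pairs")
    if np.any(coeffs <= 0):
        raise ValidationError("zone coefficients must be positive")
    n_zones = len(edges) - 1
    rng = np.random.default_rng(seed)
    est = np.empty(n)
    ref = np.empty(n)
    zone = np.empty(n, dtype=int)
    est_clean = np.empty(n)
    n_redrawn = 0
    for i in range(n):
        for attempt in range(max_attempts_per_pair):
            r = float(rng.uniform(*ref_range))
            order = rng.permutation(n_zones)
            hit = -1
            for zi in order:
                e = r / coeffs[zi]
                e_obs = e + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                if _in_zone(e_obs, edges, int(zi)):
                    hit = int(zi)
                    break
            if hit >= 0:
                ref[i], est[i], zone[i], est_clean[i] = r, e_obs, hit, e
                break
            n_redrawn += 1
        else:
            raise ComputationError(
                "no zone is consistent with the requested ref_range/coefficients"
            )
    truth = {
        "zone": zone,
        "est_noiseless": est_clean,
        "n_redrawn": n_redrawn,
        "zone_edges": edges,
        "zone_coeffs": coeffs,
        "seed": seed,
    }
    return PairedSteps(est=est, ref=ref), truth
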