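# Methods

This note documents the models, algorithms and numerical conventions behind
pocketgait, the choices made where the design was genuinely open, and what
the synthetic-data validation does and does not demonstrate.

## Inverted-pendulum gait model

A step is modelled as the body vaulting over a rigid stance leg of length
*l*: the leg sweeps from −θ₀ to +θ₀, the centre of mass rises by
h = l·(1 − cos θ₀) between foot contact and apex, and the chord traversed is
the step length SL = 2·l·sin θ₀. Eliminating θ₀ gives

    SL = 2·√(2·h·l − h²),  valid for 0 ≤ h ≤ 2l.

`step_length_pendulum` evaluates this directly; it is strictly increasing in
h on [0, l], homogeneous of degree one in (h, l), and exact whenever h and l
are exact. Assumptions inherited from the model: a rigid stance leg (no knee
flexion), sagittal-plane motion, and a device that shares the trunk's
vertical excursion. The pocket placement approximately satisfies the last
assumption; deviations appear as step-length bias, which is what the zone
correction absorbs.

A stride spans two consecutive same-foot heel strikes (two steps). Stride
length is computed as the **sum of its two step lengths**, not 2× one step:
for symmetric gait the two coincide, for asymmetric gait the sum degrades
gracefully. Speed = stride length / stride time, recomputed (never scaled)
after adjustment.

## Signal pipeline

**Orientation** (`estimate_orientation`). Per-sample device→global
quaternions (scalar-first). The pose is initialised from the mean
accelerometer vector over the first 0.5 s (trials start from standing), then
propagated by gyroscope integration; in the default `tilt_complementary`
method each sample's estimate is additionally rotated toward the
instantaneous accelerometer gravity direction by a fraction `gain` of the
residual tilt (default 0.02 per sample at 100 Hz ≈ 0.5 s time constant).
Heading about gravity is unobservable from the accelerometer and irrelevant
to vertical extraction, so the magnetometer is ignored. `gyro_only` is
available for diagnosing drift. Only the vertical axis of the rotated
acceleration is used downstream: `az = (R·a)·ẑ − g`, with g = 9.80665 m/s².

**Event detection** (`detect_heel_strikes`). Heel strikes are prominent
peaks of the vertical acceleration after a 4th-order zero-phase low-pass at
3 Hz — low enough to collapse impact ringing into one peak per contact,
high enough to keep the gait fundamental and first harmonic. Peak criteria:
minimum separation 0.4 s (cadence ceiling 2.5 steps/s) and prominence ≥
k·(1.4826·MAD) of the filtered series with k = 1 by default; expressing the
threshold in robust-dispersion units makes detection invariant to amplitude
scaling. Feet are assigned by alternation — a single pocket IMU cannot label
left/right, and stride construction only needs same-foot pairing. Strides
outside the physiologic 0.5–2.5 s gate are excluded and counted.

**Vertical position** (`vertical_position`). Cumulative trapezoid twice at
the native grid, then a 4th-order zero-phase Butterworth high-pass at
0.11 Hz on the position to remove integration drift. "Zero-phase"/"zero-lag"
means forward–backward application of the designed filter (`filtfilt`):
the magnitude response is squared and the phase is identically zero, which
preserves event timing. Two numerical guards precede the mandated high-pass:
the trial-mean acceleration is subtracted before the first integration (a
constant bias integrates to a quadratic that can dwarf the signal on long
trials), and the mean of the velocity is subtracted before the second (fixes
the integration constant; only alters the linear trend the high-pass removes
anyway). The filter settles within a few multiples of 1/0.11 Hz ≈ 9 s, so
edge strides of very short recordings are least reliable.

**Step height.** h is the peak-to-trough excursion of the filtered vertical
position within the step window (heel strike to next contralateral heel
strike, inclusive). Peak-to-trough matches the apex-to-contact geometry of
the pendulum and is insensitive to window phase. Strides whose h reaches or
exceeds l are outside pendulum geometry and are excluded with a counter.

## Zone-coefficient adjustment and calibration

Zone membership uses the **original (raw)** step-length estimate; zones are
half-open [low, high) with the last zone closed, so boundary values 0.5 and
0.8 m belong to the upper zone. Out-of-range inputs use the nearest zone's
coefficient and are flagged. The built-in tables (edges 0.2/0.5/0.8/1.1 m;
pooled 1.37/1.02/0.74, normal-only 1.40/1.04/0.74, dual-task-only
1.36/1.01/0.73) are the published defaults for pocket-phone data; users with
access to a reference system should refit.

`fit_zone_coefficients` estimates one multiplier per zone as
mean(ref)/mean(est) over the pairs whose raw estimate falls in the zone.
The ratio of means equals 1 under no bias, is the through-origin
least-squares slope under multiplicative error, and guarantees that after
fit-then-apply the per-zone means of adjusted and reference agree exactly.
Zones with fewer than two pairs inherit the nearest populated zone's
coefficient and are flagged.

`select_interval` scans widths 0.10–0.50 m (0.05 m increments) with all zone
grids anchored at 0.2 m, refits per width, adjusts, and records the
Passing–Bablok slope and intercept of adjusted-vs-reference. Selection is
lexicographic: smallest |slope − 1|, then smallest |intercept|, then the
smaller width. The search is a deterministic function of its inputs.

*Known limitation.* With a shared anchor, widths 0.10 and 0.15 generate zone
grids that exactly refine the 0.30 grid (0.2 + 3·0.1 = 0.2 + 2·0.15 = 0.5;
both also hit 0.8). When the true bias is piecewise-constant on the 0.30
grid — as in the synthetic calibration fixtures — the refining widths
reproduce it equally well, and which of the near-equivalent widths attains
the smallest |slope − 1| is decided by estimation noise. A slope-based
search therefore cannot be expected to single out the generating width with
high probability; on synthetic fixtures it picks 0.30 in roughly a third of
replicates, with the rest going to refining or near-refining widths whose
agreement is statistically indistinguishable. On real data, where the bias
is smooth rather than grid-aligned and measurement noise is larger, coarse
and misaligned widths separate much more clearly (mid-range widths fit,
extreme widths do not), which is the regime the search is intended for.

## Agreement statistics

**Passing–Bablok.** Slope = shifted median of all pairwise slopes
S_ij = (y_j − y_i)/(x_j − x_i): pairs with x_i = x_j are undefined and
dropped, values exactly −1 are dropped, and the median index is offset by
K = #{S_ij < −1}, which makes the estimate invariant under exchanging the
roles of the two methods (slope → 1/slope). Intercept =
median(y − slope·x). Even-count medians average the two central order
statistics. 95% confidence bounds use the large-sample normal approximation
for the rank window, w = z₀.₉₇₅·√(n(n−1)(2n+5)/18), applied to the ordered
slopes with the same K offset; intercept bounds re-use the slope bounds.
Exact small-n tables are out of scope. Note the K-offset references the
fixed cutoff −1, so affine equivariance in y holds only when no pairwise
slope lies below −1 — satisfied by any positively associated
method-comparison data.

**Bland–Altman.** Differences d = y − x; bias = mean(d); limits of agreement
= bias ± 1.96·SD(d) with the sample (n−1) SD; the multiplier is
configurable. Per-pair means are returned for plotting. Per-stride pairs
from the same subject violate independence; the report notes this rather
than modelling it (no mixed-effects limits).

**ICC(1,1).** One-way random-effects, single measures, from the ANOVA mean
squares: ICC = (MSB − MSW)/(MSB + (k−1)·MSW); admissible range
[−1/(k−1), 1]. Confidence bounds via the exact F quantiles
(F_L = F/F₀.₉₇₅(n−1, n(k−1)) etc.). Rows with missing cells are dropped and
counted. Reliability labels: excellent strictly above 0.75; good on
[0.6, 0.75]; fair on [0.4, 0.6); poor below 0.4 — band edges are
lower-inclusive except "excellent".

## Synthetic data

`simulate_imu_walk` builds the vertical centre-of-mass trajectory step by
step: z(t) = l·(cos θ(t) − cos θ₀) with θ sweeping −θ₀ → θ₀ under a
raised-cosine time course θ(t) = −θ₀·cos(πt/T). The raised-cosine sweep was
chosen (over a constant-rate sweep) because it gives zero vertical velocity
at each foot contact: the acceleration is then continuous across steps, its
peaks fall exactly on the heel strikes, and the emitted signal is
numerically re-integrable — trapezoid double integration reproduces the
model position to well under 1 mm RMS at 100 Hz. The geometric identities
h = l(1 − cos θ₀) and SL = 2·l·sin θ₀ hold exactly per step, so the pendulum
formula applied to the true (h, l) returns the commanded step length at
machine precision — this separates formula errors from signal-processing
errors in the tests.

Each trial carries `lead_s` (default 2 s) of quiet standing at both ends.
Because the pendulum acceleration is nonzero at the first/last contact, a
hard standing↔walking transition would be a step discontinuity whose
discrete integral leaves a spurious velocity offset; the generator instead
inserts a smooth gait-initiation ramp (quartic profile with zero net ∫ and
∫∫, plus a tiny two-mode correction that zeroes the *discrete* trapezoid
residual). Heel-strike impacts are exponentially damped 15 Hz bursts
(default amplitude 3 m/s², τ = 20 ms, 0.1 s), separable from the < 3 Hz
gait band yet detectable; their small low-frequency leakage contributes a
≈ +0.01 m step-length bias in the clean round trip, which stays within the
estimator's tolerance. Sensor corruption: constant device tilt (quaternion),
optional sinusoidal pitch sway (exercises the orientation filter), per-axis
Gaussian accelerometer noise (default SD 0.5 m/s², a realistic phone-grade
figure), constant per-axis accelerometer bias, and gyroscope noise (default
SD 0.02 rad/s). All randomness derives from the profile seed.

Defaults describe the steady-walk study condition used throughout the
validation: step length 0.60 m, leg length 0.90 m, cadence 1.8 steps/s,
30 s, 100 Hz.

What the generator does **not** model: double support and weight transfer
dynamics, left/right asymmetry beyond a simple per-foot duration factor,
turns, pocket slip/rattle, knee flexion (which in real gait reduces h below
the rigid-pendulum value), or horizontal accelerations. Passing the
round-trip tests therefore demonstrates that the estimator correctly inverts
the pendulum model under realistic sensor imperfections — not that the
pendulum model is unbiased for real gait; on real data the model's own bias
is the target of the zone correction.

`simulate_paired_steps` draws reference step lengths uniformly (default
0.28–0.81 m — the span that populates all three default calibration zones;
references above ≈ 0.814 m are inconsistent with every zone under the
default coefficients) and constructs the app estimate as ref/c(zone) plus
Gaussian noise (default SD 0.02 m), accepting a draw only if the *observed*
(noisy) estimate lies in the zone whose coefficient was used — so the
generation-time and fitting-time zone assignments coincide, and with zero
noise the published coefficients invert the bias exactly on every pair.
Because the coefficients cross 1, some reference values are consistent with
more than one zone; the generator picks uniformly at random (seeded) among
consistent zones — a deterministic first-match rule would leave the long-step
zone empty. Inconsistent draws are redrawn and counted.

## Numerical conventions and degenerate inputs

- Filters: `scipy.signal.butter` designs, `filtfilt` application; cutoff
  must lie strictly inside (0, Nyquist); series must exceed 3× the padding
  length. Filter symmetry under time reversal holds away from the
  pad-affected edges.
- Ingest drops rows with non-finite values (counted); more than 3
  consecutive bad rows abort — integration cannot bridge gaps. Sampling is
  validated against the nominal rate (median interval within 5%).
- IMU files are written with 17 significant digits (bit-exact round trip)
  and read with round-trip float parsing; stride tables use 6 significant
  digits (1e-6 round-trip tolerance).
- Tie-breaks: adjustment zone boundaries go to the upper zone; interval
  search resolves exact ties toward smaller intercept, then smaller width;
  sparse calibration zones inherit from the nearest populated zone (ties to
  the left).
- Degenerate statistics inputs raise typed errors: all-identical x
  (Passing–Bablok), fewer than 3 pairs, fewer than 2 complete ICC rows;
  MSW = 0 yields ICC = 1 by continuity.
- Problem sizes used in the validation suite (chosen to exercise ≥ 50
  strides and all calibration zones): 30 s walks at 100 Hz (≈ 53 strides),
  paired sets of n = 400, 100-replicate seeded scans for stochastic rates.

## Known limitations

- The 0.11 Hz drift filter cannot remove accelerometer noise between
  ≈ 0.1 Hz and the gait band; that noise floor dominates the step-length
  error under heavy noise (mean absolute error ≈ 0.04–0.05 m at 0.5 m/s²
  noise SD) and is intrinsic to peak-to-trough height estimation.
- Interval-search identifiability under grid-aligned bias (see above).
- No turn detection: hallway walking with 180° turns relies on the stride
  duration gate to shed turning strides.
- The CLI `validate` command treats each (visit, trial) column as one
  repeated measure for ICC; unbalanced designs are reduced to complete rows.
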