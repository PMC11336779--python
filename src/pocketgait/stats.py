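"""Method-agreement and reliability statistics.

Three classical tools for validating one measurement method against another:

* **Passing–Bablok regression** — non-parametric orthogonal regression whose
  slope is the shifted median of all pairwise slopes, robust to measurement
  error in both variables. Slopes equal to −1 and pairs with tied x are
  excluded, and the median index is offset by K = #{slopes < −1}, which makes
  the estimate invariant under swapping the roles of x and y (slope → 1/slope).
* **Bland–Altman limits of agreement** — bias = mean difference, limits at
  bias ± multiplier·SD of the differences (sample SD, n−1; multiplier 1.96
  for 95% limits).
* **ICC(1,1)** — one-way random-effects, single-measure intraclass
  correlation from the ANOVA mean squares, with the conventional
  poor/fair/good/excellent reliability labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

#: Reliability bands: excellent > 0.75, good [0.6, 0.75], fair [0.4, 0.6), poor < 0.4.
RELIABILITY_LABELS = ("excellent", "good", "fair", "poor")


@dataclass
class PBResult:
    """Passing–Bablok slope/intercept with 95% confidence bounds."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int


@dataclass
class BAResult:
    """Bland–Altman bias and limits of agreement for differences y − x."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float
    n: int
    means: np.ndarray  # per-pair (x+y)/2, for plotting
    diffs: np.ndarray


@dataclass
class ICCResult:
    """One-way random single-measure intraclass correlation."""

    icc: float
    n_subjects: int
    k_measures: int
    ci: tuple[float, float]
    label: str
    msb: float
    msw: float
    n_dropped_rows: int = 0
    model: str = "ICC(1,1)"


def _median(sorted_values: np.ndarray, offset: int = 0) -> float:
    """Median of a sorted array, index-shifted by ``offset`` (Passing–Bablok K)."""
    n = len(sorted_values)
    if n == 0:
        raise DegenerateInputError("no valid pairwise slopes")
    if n % 2 == 1:
        idx = (n + 1) // 2 + offset
        return float(sorted_values[np.clip(idx - 1, 0, n - 1)])
    i1 = np.clip(n // 2 + offset - 1, 0, n - 1)
    i2 = np.clip(n // 2 + 1 + offset - 1, 0, n - 1)
    return float(0.5 * (sorted_values[i1] + sorted_values[i2]))


def passing_bablok(x, y, ci_level: float = 0.95) -> PBResult:
    """Passing–Bablok orthogonal regression of y on x.

    Slope = K-shifted median of all pairwise slopes S_ij = (y_j−y_i)/(x_j−x_i),
    excluding undefined (x_i = x_j) and exactly −1 values, where
    K = #{S_ij < −1}. Intercept = median(y − slope·x). Confidence bounds use
    the large-sample binomial (normal-approximation) ranks of the ordered
    slopes; the intercept bounds re-use the slope bounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValidationError("x and y must have equal length")
    if n < 3:
        raise ValidationError(f"need at least 3 pairs, got {n}")
    if np.all(x == x[0]):
        raise DegenerateInputError("all x values identical")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    ok = dx != 0
    S = dy[ok] / dx[ok]
    S = S[S != -1.0]
    S = np.sort(S)
    N = len(S)
    if N == 0:
        raise DegenerateInputError("no valid pairwise slopes")
    K = int(np.sum(S < -1.0))
    slope = _median(S, offset=K)
    intercept = float(np.median(y - slope * x))

    zq = sps.norm.ppf(0.5 + ci_level / 2.0)
    w = zq * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((N - w) / 2.0))
    m2 = N - m1 + 1
    lo = float(S[np.clip(m1 + K - 1, 0, N - 1)])
    hi = float(S[np.clip(m2 + K - 1, 0, N - 1)])
    int_hi = float(np.median(y - lo * x))
    int_lo = float(np.median(y - hi * x))
    return PBResult(
        slope=slope,
        intercept=intercept,
        slope_ci=(lo, hi),
        intercept_ci=(int_lo, int_hi),
        n=n,
    )


def bland_altman(x, y, multiplier: float = 1.96) -> BAResult:
    """Bland–Altman agreement of method y against method x (differences y − x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 2:
        raise ValidationError("need at least 2 pairs")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BAResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        multiplier=multiplier,
        n=len(x),
        means=(x + y) / 2.0,
        diffs=d,
    )


def classify_reliability(icc: float) -> str:
    """Map an ICC value to its reliability label.

    Excellent is strictly above 0.75; the lower band edges are inclusive
    (0.75 → good, 0.6 → good, 0.4 → fair).
    """
    if not np.isfinite(icc):
        raise ValidationError(f"ICC must be finite, got {icc}")
    if icc > 0.75:
        return "excellent"
    if icc >= 0.6:
        return "good"
    if icc >= 0.4:
        return "fair"
    return "poor"


def icc_1_1(data, ci_level: float = 0.95) -> ICCResult:
    """ICC(1,1): one-way random-effects, single-measure intraclass correlation.

    ``data`` is a subjects × repeated-measures matrix (array or DataFrame).
    Rows containing missing values are dropped and counted. From the one-way
    ANOVA mean squares, ICC = (MSB − MSW)/(MSB + (k−1)·MSW); the confidence
    interval uses the exact F-distribution bounds.
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2:
        raise ValidationError("data must be a 2-D subjects × measures matrix")
    complete = np.isfinite(a).all(axis=1)
    n_dropped = int((~complete).sum())
    a = a[complete]
    n, k = a.shape
    if n < 2:
        raise ValidationError(f"need at least 2 complete subject rows, got {n}")
    if k < 2:
        raise ValidationError(f"need at least 2 repeated measures, got {k}")

    row_means = a.mean(axis=1)
    grand = a.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((a - row_means[:, None]) ** 2) / (n * (k - 1))
    if msw == 0.0:
        icc = 1.0
        ci = (1.0, 1.0) if msb > 0 else (np.nan, np.nan)
    else:
        icc = (msb - msw) / (msb + (k - 1) * msw)
        f_obs = msb / msw
        alpha = 1.0 - ci_level
        f_lo = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        f_hi = f_obs * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        ci = ((f_lo - 1) / (f_lo + k - 1), (f_hi - 1) / (f_hi + k - 1))
    return ICCResult(
        icc=float(icc),
        n_subjects=n,
        k_measures=k,
        ci=ci,
        label=classify_reliability(float(icc)),
        msb=float(msb),
        msw=float(msw),
        n_dropped_rows=n_dropped,
    )
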