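"""Agreement statistics: Passing–Bablok (vs brute-force oracle), Bland–Altman,
ICC(1,1) (vs hand-worked ANOVA and pingouin)."""

import statistics

import numpy as np
import pytest

import pocketgait as pg
from pocketgait.errors import DegenerateInputError, ValidationError


def pb_oracle(x, y):
    """Independent brute-force Passing–Bablok: enumerate every pairwise slope
    with plain Python, apply the K-offset median, and return the CI ranks."""
    import scipy.stats

    n = len(x)
    S = []
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    S.append(s)
    S.sort()
    N = len(S)
    K = sum(1 for s in S if s < -1.0)
    if N % 2 == 1:
        slope = S[(N + 1) // 2 + K - 1]
    else:
        slope = 0.5 * (S[N // 2 + K - 1] + S[N // 2 + K])
    intercept = statistics.median(y[i] - slope * x[i] for i in range(n))
    w = scipy.stats.norm.ppf(0.975) * (n * (n - 1) * (2 * n + 5) / 18.0) ** 0.5
    m1 = round((N - w) / 2.0)
    m2 = N - m1 + 1
    lo = S[min(max(m1 + K - 1, 0), N - 1)]
    hi = S[min(max(m2 + K - 1, 0), N - 1)]
    return slope, intercept, lo, hi


class TestPassingBablok:
    def test_identity_line(self):
        x = np.linspace(1, 2, 10)
        r = pg.passing_bablok(x, x)
        assert r.slope == 1.0 and r.intercept == 0.0

    def test_exact_affine_line(self):
        x = np.linspace(0, 5, 12)
        r = pg.passing_bablok(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0, rel=1e-12)
        assert r.intercept == pytest.approx(1.0, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.uniform(0, 2, n)
            y = 1.3 * x - 0.2 + rng.normal(0, 0.3, n)
            r = pg.passing_bablok(x, y)
            slope, intercept, lo, hi = pb_oracle(x, y)
            assert r.slope == slope
            assert r.intercept == intercept
            assert r.slope_ci == (lo, hi)

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(DegenerateInputError):
            pg.passing_bablok(np.ones(5), np.arange(5.0))
        with pytest.raises(ValidationError):
            pg.passing_bablok(np.arange(2.0), np.arange(2.0))

    def test_affine_equivariance(self):
        """Scale/offset equivariance holds when every pairwise slope stays
        above −1 (the K-offset counts slopes < −1 against a fixed cutoff, so
        it is only invariant when that count is zero on both sides)."""
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 1, 25)) + np.arange(25) * 0.1
        y = 0.8 * x + rng.normal(0, 0.02, 25)  # spacing >> noise: slopes > 0
        base = pg.passing_bablok(x, y)
        a, b = 2.5, -0.7
        tr = pg.passing_bablok(x, a * y + b)
        assert tr.slope == pytest.approx(a * base.slope, rel=1e-9)
        assert tr.intercept == pytest.approx(a * base.intercept + b, rel=1e-9, abs=1e-9)

    def test_symmetry_under_axis_swap(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 2, 21)  # odd pair count, no ties
        y = 1.4 * x + rng.normal(0, 0.05, 21)
        fwd = pg.passing_bablok(x, y)
        rev = pg.passing_bablok(y, x)
        assert fwd.slope == pytest.approx(1.0 / rev.slope, rel=1e-6)


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.linspace(0, 1, 10)
        r = pg.bland_altman(x, x)
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset(self):
        x = np.linspace(0, 1, 10)
        r = pg.bland_altman(x, x + 0.5)
        assert r.bias == pytest.approx(0.5)
        assert r.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert r.loa_low == pytest.approx(0.5, abs=1e-12)
        assert r.loa_high == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_computation_exactly(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0.5, 1.5, 200)
        y = x + rng.normal(0.02, 0.1, 200)
        r = pg.bland_altman(x, y)
        d = y - x
        assert r.bias == np.mean(d)
        assert r.loa_high == pytest.approx(np.mean(d) + 1.96 * np.std(d, ddof=1), rel=1e-14)
        assert r.loa_low == pytest.approx(np.mean(d) - 1.96 * np.std(d, ddof=1), rel=1e-14)

    def test_sampling_distribution_at_large_n(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 2, 10_000)
        y = x + rng.normal(0, 0.1, 10_000)
        r = pg.bland_altman(x, y)
        assert abs(r.bias) <= 0.003
        assert r.loa_high == pytest.approx(0.196, abs=0.01)

    def test_invariances(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 1, 50)
        y = x + rng.normal(0, 0.05, 50)
        r = pg.bland_altman(x, y)
        perm = rng.permutation(50)
        rp = pg.bland_altman(x[perm], y[perm])
        assert rp.bias == pytest.approx(r.bias, rel=1e-12)
        assert rp.sd_diff == pytest.approx(r.sd_diff, rel=1e-12)
        rc = pg.bland_altman(x + 3.0, y + 3.0)
        assert rc.bias == pytest.approx(r.bias, rel=1e-9, abs=1e-12)


class TestICC:
    def test_hand_worked_6x3_matrix(self):
        """Rows (x−1, x, x+1) for x = 2..7: MSB = 10.5, MSW = 1,
        ICC = (10.5 − 1)/(10.5 + 2) = 0.76 by the one-way ANOVA closed form."""
        mat = np.array([[x - 1, x, x + 1] for x in range(2, 8)], dtype=float)
        r = pg.icc_1_1(mat)
        assert r.msb == pytest.approx(10.5, rel=1e-12)
        assert r.msw == pytest.approx(1.0, rel=1e-12)
        assert r.icc == pytest.approx(0.76, rel=1e-12)
        assert r.label == "excellent"

    def test_perfect_repeatability(self):
        mat = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        r = pg.icc_1_1(mat)
        assert r.icc == 1.0 and r.label == "excellent"

    def test_equal_subject_means_gives_nonpositive_icc(self):
        mat = np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5], [0.2, 0.8]])
        r = pg.icc_1_1(mat)
        assert r.icc <= 0.0
        assert r.label == "poor"

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        mat = rng.normal(0, 1, (8, 3)) + rng.normal(0, 1, (8, 1))
        mine = pg.icc_1_1(mat)
        df = pd.DataFrame(mat).reset_index().melt("index", var_name="rater", value_name="v")
        ref = pingouin.intraclass_corr(df, targets="index", raters="rater", ratings="v")
        row = ref.loc[ref.Type == "ICC(1,1)"] if (ref.Type == "ICC(1,1)").any() else ref.iloc[[0]]
        assert mine.icc == pytest.approx(float(row.ICC.iloc[0]), rel=1e-9)

    def test_missing_rows_dropped_and_counted(self):
        mat = np.array([[1, 2, 3], [2, 3, 4], [np.nan, 3, 4], [4, 5, 6.0]])
        r = pg.icc_1_1(mat)
        assert r.n_subjects == 3 and r.n_dropped_rows == 1

    def test_bounded_over_random_matrices(self):
        rng = np.random.default_rng(14)
        for _ in range(1000):
            n = int(rng.integers(2, 8))
            k = int(rng.integers(2, 6))
            r = pg.icc_1_1(rng.normal(0, 1, (n, k)))
            assert -1.0 / (k - 1) - 1e-12 <= r.icc <= 1.0 + 1e-12


class TestClassifyReliability:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.86, "excellent"),
            (0.76, "excellent"),
            (0.75, "good"),  # excellent is strictly > 0.75
            (0.64, "good"),
            (0.60, "good"),  # lower-inclusive band
            (0.45, "fair"),
            (0.40, "fair"),
            (0.39, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_band_assignment(self, icc, label):
        assert pg.classify_reliability(icc) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            pg.classify_reliability(float("nan"))
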