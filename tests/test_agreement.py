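"""Agreement statistics against a brute-force oracle and forced arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitalink.agreement import (
    PairedReadings,
    agreement_report,
    bland_altman,
    linear_fit,
    mae,
    mre,
    per_reading_error,
    rmse,
)
from vitalink.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
)

# ---------------------------------------------------------------------------
# brute-force oracle: plain loops, no numpy vectorization, independent code
# ---------------------------------------------------------------------------

def oracle_stats(ms, rs):
    k = len(ms)
    sq = sum((r - m) ** 2 for m, r in zip(ms, rs))
    ab = sum(abs(r - m) for m, r in zip(ms, rs))
    rel = sum(abs(r - m) / r for m, r in zip(ms, rs))
    mx, my = sum(ms) / k, sum(rs) / k
    sxx = sum((m - mx) ** 2 for m in ms)
    syy = sum((r - my) ** 2 for r in rs)
    sxy = sum((m - mx) * (r - my) for m, r in zip(ms, rs))
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = sxy * sxy / (sxx * syy)
    ds = [m - r for m, r in zip(ms, rs)]
    md = sum(ds) / k
    sd = math.sqrt(sum((d - md) ** 2 for d in ds) / (k - 1))
    return {
        "rmse": math.sqrt(sq / k),
        "mae": ab / k,
        "mre": rel / k,
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "mean_diff": md,
        "sd_diff": sd,
        "loa_upper": md + 1.96 * sd,
        "loa_lower": md - 1.96 * sd,
    }


def random_table(rng):
    k = int(rng.integers(3, 30))
    ref = rng.uniform(10, 200, k)
    mes = ref + rng.normal(0, 3, k)
    if np.ptp(mes) == 0:  # pragma: no cover - vanishingly unlikely
        mes[0] += 1.0
    return PairedReadings("x", mes, ref)


def test_matches_brute_force_oracle(rng):
    """Every statistic agrees with an independent loop implementation."""
    for _ in range(300):
        p = random_table(rng)
        exp = oracle_stats(list(p.measured), list(p.reference))
        fit = linear_fit(p)
        ba = bland_altman(p)
        got = {
            "rmse": rmse(p), "mae": mae(p), "mre": mre(p),
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
            "loa_upper": ba.loa_upper, "loa_lower": ba.loa_lower,
        }
        for name, value in exp.items():
            assert got[name] == pytest.approx(value, rel=1e-12, abs=1e-12), name


class TestForcedArithmetic:
    def test_rmse_mae_small_table(self):
        p = PairedReadings.from_pairs("x", [(2, 1), (3, 3)])
        assert rmse(p) == pytest.approx(math.sqrt(0.5))
        assert mae(p) == pytest.approx(0.5)

    def test_identical_pairs_have_zero_error(self):
        p = PairedReadings.from_pairs("x", [(5, 5), (7, 7), (9, 9)])
        assert rmse(p) == mae(p) == mre(p) == 0.0

    def test_bland_altman_sample_sd_convention(self):
        """Differences (-1,+1,-1,+1): limits are +/-1.96*sqrt(4/3)."""
        p = PairedReadings("x", np.array([9, 11, 9, 11.0]), np.full(4, 10.0))
        ba = bland_altman(p)
        assert ba.mean_diff == 0.0
        assert ba.sd_diff == pytest.approx(math.sqrt(4 / 3))
        assert ba.loa_upper == pytest.approx(1.96 * 1.1547, abs=1e-4)
        assert ba.n_outside_loa == 0

    def test_all_zero_differences_collapse_limits(self):
        p = PairedReadings("x", np.array([5, 6, 7.0]), np.array([5, 6, 7.0]))
        ba = bland_altman(p)
        assert ba.loa_lower == ba.loa_upper == 0.0
        assert ba.n_outside_loa == 0

    def test_perfect_match_line(self):
        p = PairedReadings("x", np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 4.0]))
        fit = linear_fit(p)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "measured, reference, expected",
        [(107, 104, 2.88), (88, 88, 0.00), (34.75, 34.6, 0.43)],
    )
    def test_per_reading_error_display_rounding(self, measured, reference, expected):
        assert per_reading_error(measured, reference) == expected


class TestInvariants:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rmse_dominates_mae(self, seed):
        p = random_table(np.random.default_rng(seed))
        assert rmse(p) >= mae(p) >= 0.0

    def test_permutation_invariance(self, rng):
        p = random_table(rng)
        perm = rng.permutation(p.K)
        q = PairedReadings("x", p.measured[perm], p.reference[perm])
        assert rmse(q) == pytest.approx(rmse(p), rel=1e-12)
        assert linear_fit(q).r_squared == pytest.approx(
            linear_fit(p).r_squared, rel=1e-12
        )
        assert bland_altman(q).loa_upper == pytest.approx(
            bland_altman(p).loa_upper, rel=1e-12
        )

    def test_unit_equivariance(self, rng):
        """Scaling both columns by c scales the unit-bearing statistics by c."""
        p = random_table(rng)
        c = 3.25
        q = PairedReadings("x", c * p.measured, c * p.reference)
        assert rmse(q) == pytest.approx(c * rmse(p), rel=1e-12)
        assert mae(q) == pytest.approx(c * mae(p), rel=1e-12)
        ba_p, ba_q = bland_altman(p), bland_altman(q)
        assert ba_q.sd_diff == pytest.approx(c * ba_p.sd_diff, rel=1e-12)
        assert ba_q.loa_upper == pytest.approx(c * ba_p.loa_upper, rel=1e-12)
        assert mre(q) == pytest.approx(mre(p), rel=1e-12)
        assert linear_fit(q).r_squared == pytest.approx(
            linear_fit(p).r_squared, rel=1e-12
        )

    def test_loa_bracket_mean(self, rng):
        p = random_table(rng)
        ba = bland_altman(p)
        assert ba.loa_lower <= ba.mean_diff <= ba.loa_upper

    def test_gaussian_coverage_near_95_percent(self):
        """Fraction of Gaussian differences inside the limits is ~95%."""
        rng = np.random.default_rng(42)
        n = 10_000
        ref = np.full(n, 100.0)
        mes = ref + rng.normal(0, 2.0, n)
        ba = bland_altman(PairedReadings("x", mes, ref))
        inside = 1.0 - ba.n_outside_loa / n
        assert inside == pytest.approx(0.95, abs=0.02)


class TestErrorsAndReport:
    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            PairedReadings("x", np.array([1.0]), np.array([1.0]))
        p = PairedReadings("x", np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(InsufficientDataError):
            linear_fit(p)
        with pytest.raises(InsufficientDataError):
            bland_altman(p)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidParameterError):
            PairedReadings("x", np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        with pytest.raises(InvalidParameterError):
            per_reading_error(5.0, 0.0)

    def test_degenerate_fit(self):
        p = PairedReadings("x", np.full(5, 2.0), np.arange(1.0, 6.0))
        with pytest.raises(DegenerateFitError):
            linear_fit(p)

    def test_report_composes_and_rounds(self, hr_table):
        rep = agreement_report(hr_table.pairs)
        assert rep.n_pairs == 50
        assert rep.rmse >= rep.mae >= 0
        assert 0 <= rep.r_squared <= 1
        assert rep.mre_percent == pytest.approx(100 * rep.mre)
        text = rep.to_text()
        assert "RMSE" in text and "95% LoA" in text
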