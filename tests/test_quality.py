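import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mamsnet import (
    InvalidParameterError,
    ewma_chart,
    ewma_limits,
    ewma_series,
    flag_out_of_control,
    icc_concordance,
)


class TestEwmaSeries:
    def test_two_step_recursion(self):
        m = ewma_series([12.0, 12.0], center=10.0, lam=0.15)
        assert m[0] == pytest.approx(10.3)
        assert m[1] == pytest.approx(10.555)

    def test_center_is_fixed_point(self):
        m = ewma_series([7.5] * 20, center=7.5, lam=0.15)
        assert np.allclose(m, 7.5)

    def test_lambda_one_no_smoothing(self):
        x = [3.0, 1.0, 4.0, 1.5]
        assert np.array_equal(ewma_series(x, center=0.0, lam=1.0), np.array(x))

    @pytest.mark.parametrize("lam", [0.0, -0.1, 1.5])
    def test_invalid_lambda(self, lam):
        with pytest.raises(InvalidParameterError):
            ewma_series([1.0], center=0.0, lam=lam)

    @given(
        x=st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        c=st.floats(-50, 50),
        shift=st.floats(-20, 20),
    )
    def test_shift_equivariance(self, x, c, shift):
        base = ewma_series(x, center=c, lam=0.3)
        shifted = ewma_series([xi + shift for xi in x], center=c + shift, lam=0.3)
        assert np.allclose(shifted, base + shift, atol=1e-9)


class TestEwmaLimits:
    def test_first_step_closed_form(self):
        # 1 - (1-lam)^2 = lam(2-lam), so V_1 = lam * sigma0 exactly
        for lam in (0.05, 0.15, 0.5, 1.0):
            lo, hi = ewma_limits(sigma0=2.0, center=10.0, lam=lam, L=3.0, i=1)
            assert hi - 10.0 == pytest.approx(3.0 * lam * 2.0, rel=1e-12)
            assert 10.0 - lo == pytest.approx(3.0 * lam * 2.0, rel=1e-12)

    def test_asymptotic_half_width(self):
        _, hi = ewma_limits(sigma0=10.0, center=0.0, lam=0.15, L=3.0, i=10_000)
        assert hi == pytest.approx(3 * 10 * np.sqrt(0.15 / 1.85), rel=1e-9)
        assert hi == pytest.approx(8.5424, abs=1e-4)

    def test_zero_sigma_collapses(self):
        lo, hi = ewma_limits(sigma0=0.0, center=5.0, i=7)
        assert lo == hi == 5.0

    def test_variance_monotone_to_asymptote(self):
        steps = np.arange(1, 201)
        _, hi = ewma_limits(sigma0=1.0, center=0.0, lam=0.15, L=1.0, i=steps)
        # strictly increasing until it saturates at the asymptote in float64
        assert np.all(np.diff(hi) >= 0)
        assert np.all(np.diff(hi[:50]) > 0)
        asymptote = np.sqrt(0.15 / 1.85)
        assert hi[-1] == pytest.approx(asymptote, rel=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            ewma_limits(sigma0=-1.0, center=0.0)
        with pytest.raises(InvalidParameterError):
            ewma_limits(sigma0=1.0, center=0.0, i=0)


class TestChartFlags:
    def test_constant_series_in_control(self):
        chart = ewma_chart([10.0] * 15, center=10.0, sigma0=2.0)
        flags, first = flag_out_of_control(chart)
        assert not flags.any() and first is None

    def test_large_shift_flagged_immediately(self):
        # one observation at center + 100 sigma0: EWMA moves 15 sigma0,
        # far beyond the first-step limit of L*lam*sigma0 = 0.45 sigma0
        chart = ewma_chart([10.0 + 100.0 * 2.0], center=10.0, sigma0=2.0)
        flags, first = flag_out_of_control(chart)
        assert flags.tolist() == [True] and first == 0

    def test_excursion_and_recovery(self):
        obs = [10.0] * 10 + [30.0] * 5 + [10.0] * 30
        chart = ewma_chart(obs, center=10.0, sigma0=2.0)
        flags, first = flag_out_of_control(chart)
        assert first is not None and 10 <= first < 15
        assert not flags[-1]  # returns to within limits

    def test_empty_series(self):
        chart = ewma_chart([], center=10.0, sigma0=2.0)
        flags, first = flag_out_of_control(chart)
        assert len(flags) == 0 and first is None

    def test_frame_roundtrip(self):
        chart = ewma_chart([9.0, 11.0, 10.5], center=10.0, sigma0=1.0)
        frame = chart.to_frame()
        assert list(frame.columns) == ["index", "observation", "ewma", "lower", "upper", "flag"]
        assert len(frame) == 3


def simulate_ratings(n, k, subj_sd, rater_sd, err_sd, seed):
    rng = np.random.default_rng(seed)
    return (
        rng.normal(0, subj_sd, n)[:, None]
        + rng.normal(0, rater_sd, k)[None, :]
        + rng.normal(0, err_sd, (n, k))
    )


class TestIcc:
    def test_perfect_agreement(self):
        grid = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = icc_concordance(grid)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        grid = simulate_ratings(200, 3, subj_sd=0.0, rater_sd=0.0, err_sd=1.0, seed=7)
        res = icc_concordance(grid)
        assert res.ci_low < 0.0 < res.ci_high
        assert abs(res.icc) < 0.15

    def test_variance_ratio_recovery(self):
        # subject variance 3, residual variance 1 -> ICC -> 3/(3+1) = 0.75
        grid = simulate_ratings(4000, 3, np.sqrt(3), 0.0, 1.0, seed=11)
        res = icc_concordance(grid)
        assert res.icc == pytest.approx(0.75, abs=0.02)
        assert res.ci_low < 0.75 < res.ci_high

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        grid = simulate_ratings(60, 3, np.sqrt(3), 0.5, 1.0, seed=0)
        n, k = grid.shape
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": grid.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref_row = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(ref["Type"]) \
            else ref[ref["Type"] == "ICC2"].iloc[0]
        res = icc_concordance(grid)
        assert res.icc == pytest.approx(float(ref_row["ICC"]), abs=1e-8)
        lo, hi = ref_row["CI95"] if "CI95" in ref_row else ref_row["CI95%"]
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_long_format_input(self):
        grid = simulate_ratings(30, 3, 1.0, 0.2, 0.5, seed=3)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(30), 3),
                "rater": np.tile(["r1", "r2", "r3"], 30),
                "score": grid.ravel(),
            }
        )
        assert icc_concordance(long).icc == pytest.approx(icc_concordance(grid).icc)

    @given(
        scale=st.floats(0.1, 10),
        shift=st.floats(-100, 100),
    )
    def test_affine_invariance_and_range(self, scale, shift):
        grid = simulate_ratings(40, 3, 1.0, 0.3, 0.7, seed=13)
        base = icc_concordance(grid)
        rescaled = icc_concordance(scale * grid + shift)
        assert rescaled.icc == pytest.approx(base.icc, abs=1e-9)
        assert -1.0 <= base.icc <= 1.0

    def test_covariate_adjustment_runs(self):
        rng = np.random.default_rng(4)
        n, k = 40, 3
        time_effect = np.repeat([0.0, 2.0], n // 2)
        grid = simulate_ratings(n, k, 1.0, 0.2, 0.5, seed=4) + time_effect[:, None]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": grid.ravel(),
                "time": np.repeat(time_effect, k),
            }
        )
        res = icc_concordance(long, adjust_for=["time"])
        assert -1.0 <= res.icc <= 1.0
        # removing a shared time effect reduces apparent subject variance
        assert res.icc <= icc_concordance(long).icc + 1e-9

    def test_rejects_degenerate_grids(self):
        with pytest.raises(InvalidParameterError):
            icc_concordance(np.zeros((10, 1)))
        with pytest.raises(InvalidParameterError):
            icc_concordance(np.zeros((1, 3)))
        bad = np.ones((5, 3))
        bad[2, 1] = np.nan
        with pytest.raises(InvalidParameterError):
            icc_concordance(bad)
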