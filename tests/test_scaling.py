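"""rmsf / MSD / DFA curves, power-law fitting, correlation time, and
regime classification."""

import numpy as np
import pytest

from motilikit import (
    ConfigError,
    DegenerateCurveError,
    ScalingCurve,
    ScalingFit,
    StepSeries,
    Trajectory,
    WalkerConfig,
    classify_dfa_regime,
    correlation_time,
    dfa_curve,
    fit_scaling_exponent,
    gen_ballistic,
    gen_persistent,
    log_spaced_scales,
    msd_curve,
    rmsf_curve,
    to_step_series,
)

SCALES = log_spaced_scales(8, 512)


class TestFitScalingExponent:
    def test_exact_power_law_recovered(self):
        scales = np.array([4, 8, 16, 32, 64])
        curve = ScalingCurve(scales=scales, values=3.0 * scales**0.75, kind="rmsf")
        fit = fit_scaling_exponent(curve)
        assert fit.exponent == pytest.approx(0.75, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log10(3.0), abs=1e-12)

    def test_noisy_power_law_within_ols_se(self, rng):
        """Multiplicative noise: the OLS slope on logs is the oracle."""
        from scipy import stats as sps

        scales = log_spaced_scales(4, 256, 20)
        noise = rng.normal(0, np.log10(1.05), scales.size)
        values = 2.0 * scales**0.75 * 10**noise
        fit = fit_scaling_exponent(
            ScalingCurve(scales=scales, values=values, kind="rmsf")
        )
        res = sps.linregress(np.log10(scales), np.log10(values))
        assert fit.exponent == pytest.approx(res.slope, abs=1e-12)
        assert abs(fit.exponent - 0.75) < 3 * res.stderr

    def test_too_few_points_rejected(self):
        curve = ScalingCurve(
            scales=np.array([4, 8, 16]), values=np.array([1.0, 2, 4]), kind="msd"
        )
        with pytest.raises(ConfigError):
            fit_scaling_exponent(curve)


class TestRmsf:
    def test_iid_alpha_near_half(self, rng):
        alphas = [
            fit_scaling_exponent(rmsf_curve(rng.normal(size=4099), SCALES)).exponent
            for _ in range(20)
        ]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.05)

    def test_fgn_alpha_recovers_hurst(self, rng):
        from motilikit import fgn

        alphas = [
            fit_scaling_exponent(rmsf_curve(fgn(4099, 0.8, rng), SCALES)).exponent
            for _ in range(20)
        ]
        assert np.mean(alphas) == pytest.approx(0.8, abs=0.05)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            rmsf_curve(np.ones(512))

    def test_scale_bounds_enforced(self, rng):
        with pytest.raises(ConfigError):
            rmsf_curve(rng.normal(size=256), scales=[4, 8, 128])


class TestMsd:
    def test_ballistic_beta_two(self):
        traj = gen_ballistic(WalkerConfig(model="ballistic", n_frames=4100))
        fit = fit_scaling_exponent(msd_curve(traj, np.arange(1, 411)))
        assert fit.exponent == pytest.approx(2.0, abs=0.01)

    def test_stationary_degenerate(self):
        traj = Trajectory(track_id="s", positions=np.zeros((100, 2)))
        with pytest.raises(DegenerateCurveError):
            msd_curve(traj)

    def test_unit_change_leaves_exponent(self, rng):
        pos = rng.normal(size=(800, 2)).cumsum(axis=0)
        t1 = Trajectory(track_id="a", positions=pos)
        t2 = Trajectory(track_id="b", positions=2.0 * pos)
        e1 = fit_scaling_exponent(msd_curve(t1)).exponent
        e2 = fit_scaling_exponent(msd_curve(t2)).exponent
        assert e1 == pytest.approx(e2, abs=1e-12)


class TestDfa:
    def test_white_noise_gamma_half(self, rng):
        gammas = [
            fit_scaling_exponent(dfa_curve(rng.normal(size=4096), SCALES)).exponent
            for _ in range(20)
        ]
        assert np.mean(gammas) == pytest.approx(0.5, abs=0.05)

    def test_brownian_path_gamma_three_halves(self, rng):
        gammas = [
            fit_scaling_exponent(
                dfa_curve(np.cumsum(rng.normal(size=4096)), SCALES)
            ).exponent
            for _ in range(20)
        ]
        assert np.mean(gammas) == pytest.approx(1.5, abs=0.1)

    def test_constant_series_exact_zero(self):
        curve = dfa_curve(np.full(512, 3.7), box_sizes=[8, 16, 32, 64])
        assert curve.values == pytest.approx(0.0, abs=1e-10)

    def test_ramp_removed_by_quadratic_detrend(self):
        """A linear ramp integrates to a parabola, which order-2
        detrending removes exactly."""
        x = 0.3 * np.arange(512) + 1.0
        curve = dfa_curve(x, box_sizes=[8, 16, 32, 64], detrend_order=2)
        assert np.all(curve.values < 1e-7 * np.abs(x).max())

    def test_oversized_box_rejected(self, rng):
        with pytest.raises(ConfigError):
            dfa_curve(rng.normal(size=256), box_sizes=[8, 300])


class TestCorrelationTime:
    @staticmethod
    def _curve_and_fit(series):
        n = series.size
        scales = np.unique(
            np.concatenate([log_spaced_scales(8, n // 8), np.arange(50, n // 4 + 1, 50)])
        )
        curve = rmsf_curve(series, scales)
        fit = fit_scaling_exponent(curve, fit_range=(8, n // 8))
        return curve, fit

    def test_iid_has_no_correlated_regime(self, rng):
        curve, fit = self._curve_and_fit(rng.normal(size=4099))
        ct = correlation_time(curve, fit, dt=0.5)
        assert ct.no_correlated_regime
        assert ct.crossover_scale == 50

    def test_minutes_on_25s_grid(self):
        for seed in range(5):
            traj = gen_persistent(
                WalkerConfig(model="persistent", n_frames=4100, seed=seed)
            )
            curve, fit = self._curve_and_fit(to_step_series(traj).values)
            ct = correlation_time(curve, fit, dt=0.5)
            # 50 frames at 2 Hz = 25 s; minutes must sit on that grid
            assert (ct.minutes * 60) % 25 == pytest.approx(0.0, abs=1e-9)

    def test_persistent_walk_correlation_scale(self):
        """A 300 s persistence time shows up as a correlated regime of
        the same order (within a factor of two of 5 min)."""
        minutes = []
        for seed in range(15):
            traj = gen_persistent(
                WalkerConfig(
                    model="persistent", persistence_time=300.0, n_frames=4100,
                    seed=seed,
                )
            )
            curve, fit = self._curve_and_fit(to_step_series(traj).values)
            minutes.append(correlation_time(curve, fit, dt=0.5).minutes)
        assert 2.5 <= np.median(minutes) <= 10.0


class TestClassifyRegime:
    @staticmethod
    def _fit(gamma):
        return ScalingFit(
            exponent=gamma, intercept=0.0, fit_range=(8, 512), r_squared=0.99,
            kind="dfa",
        )

    @pytest.mark.parametrize(
        "gamma,input_class,expected",
        [
            (1.82, "brownian_like", "persistent"),
            (0.48, "noise_like", "uncorrelated"),
            (0.30, "noise_like", "antipersistent"),
            (1.20, "brownian_like", "antipersistent"),
            (1.50, "brownian_like", "uncorrelated"),
        ],
    )
    def test_thresholds(self, gamma, input_class, expected):
        assert classify_dfa_regime(self._fit(gamma), input_class) == expected

    def test_out_of_range_unclassified(self):
        assert classify_dfa_regime(self._fit(2.3), "brownian_like") is None

    def test_wrong_kind_rejected(self):
        fit = ScalingFit(1.0, 0.0, (8, 64), 1.0, kind="msd")
        with pytest.raises(ConfigError):
            classify_dfa_regime(fit, "noise_like")


def test_rmsf_step_series_accepts_domain_type(rng):
    series = StepSeries(values=rng.random(600))
    curve = rmsf_curve(series)
    assert curve.kind == "rmsf"
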