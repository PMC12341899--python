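"""Synthetic walkers: determinism, calibration limits, fGn correctness,
and scenario-level directional structure."""

import numpy as np
import pytest

from motilikit import (
    ConfigError,
    StimulusFrame,
    WalkerConfig,
    directionality_ratio,
    displacement_cosine,
    fgn,
    fit_scaling_exponent,
    gen_ballistic,
    gen_brownian,
    gen_cohort,
    gen_fgn_steps,
    gen_persistent,
    msd_curve,
    scenario_preset,
    sector_histogram,
    to_step_series,
)

FRAME = StimulusFrame()


class TestBallistic:
    CFG = WalkerConfig(model="ballistic", speed_mean=1.5, n_frames=4100, dt=0.5)

    def test_constant_steps_and_path_length(self):
        traj = gen_ballistic(self.CFG)
        steps = to_step_series(traj)
        assert steps.values == pytest.approx(np.full(4099, 0.75))
        assert steps.values.sum() == pytest.approx(3074.25)

    def test_straight_line_limits(self):
        traj = gen_ballistic(self.CFG)
        assert directionality_ratio(traj) == pytest.approx(1.0)
        beta = fit_scaling_exponent(msd_curve(traj)).exponent
        assert beta == pytest.approx(2.0, abs=1e-6)

    def test_zero_speed_warns(self):
        with pytest.warns(UserWarning):
            gen_ballistic(WalkerConfig(model="ballistic", speed_mean=0.0, n_frames=10))


class TestBrownian:
    def test_same_seed_identical(self):
        cfg = WalkerConfig(model="brownian", n_frames=200, seed=42)
        a, b = gen_brownian(cfg), gen_brownian(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_msd_exponent_near_one(self):
        betas = [
            fit_scaling_exponent(
                msd_curve(gen_brownian(WalkerConfig(model="brownian", n_frames=4100, seed=s)))
            ).exponent
            for s in range(10)
        ]
        assert np.mean(betas) == pytest.approx(1.0, abs=0.12)


class TestFgn:
    def test_h_out_of_domain_rejected(self):
        with pytest.raises(ConfigError):
            WalkerConfig(model="fgn_steps", hurst=1.2)
        with pytest.raises(ConfigError):
            fgn(100, 1.2, np.random.default_rng(0))

    def test_white_case_uncorrelated(self, rng):
        x = fgn(4096, 0.5, rng)
        ac = np.correlate(x - x.mean(), x - x.mean(), "full")
        ac = ac[ac.size // 2 :] / ac[ac.size // 2]
        assert np.all(np.abs(ac[1:6]) < 4 / np.sqrt(x.size))

    def test_autocovariance_matches_analytic(self, rng):
        """Sample autocovariance of H=0.8 fGn matches
        rho(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H) within MC error."""
        h, n, reps = 0.8, 2048, 60
        lags = np.arange(0, 6)
        acc = np.zeros(lags.size)
        for _ in range(reps):
            x = fgn(n, h, rng)
            for i, k in enumerate(lags):
                acc[i] += np.mean(x[: n - k] * x[k:])
        acc /= reps
        k = lags.astype(float)
        expected = 0.5 * (
            np.abs(k + 1) ** 1.6 - 2 * k**1.6 + np.abs(k - 1) ** 1.6
        )
        np.testing.assert_allclose(acc, expected, atol=0.03)

    def test_step_series_nonnegative_and_seeded(self):
        cfg = WalkerConfig(model="fgn_steps", hurst=0.75, n_frames=512, seed=9)
        a, b = gen_fgn_steps(cfg), gen_fgn_steps(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.all(a.values >= 0)
        assert len(a) == 511


class TestPersistent:
    def test_seeded_reproducibility(self):
        cfg = WalkerConfig(model="persistent", n_frames=300, seed=5)
        np.testing.assert_array_equal(
            gen_persistent(cfg).positions, gen_persistent(cfg).positions
        )

    def test_nonpositive_persistence_rejected(self):
        with pytest.raises(ConfigError):
            WalkerConfig(model="persistent", persistence_time=0.0)

    def test_unbiased_cosines_center_on_zero(self):
        cohort = gen_cohort(scenario_preset("Sc1", n_frames=1500), 60, seed=7)
        cosines = [displacement_cosine(t, FRAME) for t in cohort]
        assert abs(np.median(cosines)) < 0.3

    def test_unbiased_sectors_uniform(self):
        from scipy import stats as sps

        cohort = gen_cohort(scenario_preset("Sc1", n_frames=1000), 160, seed=8)
        pct = sector_histogram(cohort, FRAME)
        counts = pct / 100 * 160
        assert sps.chisquare(counts).pvalue > 0.001

    def test_strong_bias_gives_cosine_near_one(self):
        cohort = gen_cohort(scenario_preset("Sc2", n_frames=2000), 40, seed=9)
        assert np.median([displacement_cosine(t, FRAME) for t in cohort]) > 0.9

    def test_short_lag_superdiffusion(self):
        """At lags far below the persistence time the walk is nearly
        ballistic (MSD exponent above 1.5)."""
        cfg = WalkerConfig(model="persistent", persistence_time=300.0,
                           n_frames=2000, seed=11)
        traj = gen_persistent(cfg)
        curve = msd_curve(traj, lags=np.arange(1, 60))  # lags << 600 frames
        assert fit_scaling_exponent(curve).exponent > 1.5


class TestCohort:
    def test_single_cell_allowed(self):
        assert len(gen_cohort(scenario_preset("Sc1", n_frames=64), 1, seed=0)) == 1

    def test_sc4_mixture_split(self):
        cohort = gen_cohort(scenario_preset("Sc4", n_frames=1500), 100, seed=13)
        toward_peptide = sum(
            displacement_cosine(t, FRAME) < 0 for t in cohort
        )
        # expected ~58 of 100; allow 3 sigma of binomial sampling error
        assert 43 <= toward_peptide <= 73

    def test_bit_reproducible(self):
        preset = scenario_preset("Sc3", n_frames=200)
        a = gen_cohort(preset, 5, seed=21)
        b = gen_cohort(preset, 5, seed=21)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.positions, y.positions)
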