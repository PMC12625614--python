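"""Generator tests: determinism, noise-free geometry, Monte-Carlo moments,
outcome closed forms, and the true-surface construction."""

import numpy as np
import pandas as pd
import pytest

from sleeproutine import GeneratorConfig, generate_cohort
from sleeproutine.metrics import average_sleep_duration, bracket_fractions
from sleeproutine.simulate import (
    ConfigError,
    GenerationError,
    TrueHazardSurface,
    linear_predictor,
    sample_participant_traits,
    simulate_outcomes,
    simulate_sleep_week,
)
from conftest import noise_free_config


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_participants=0)
        with pytest.raises(ConfigError):
            GeneratorConfig(epoch_minutes=7)
        with pytest.raises(ConfigError):
            GeneratorConfig(weekend_class_probs=(0.5, 0.5, 0.5))
        with pytest.raises(ConfigError):
            GeneratorConfig(chronotype_sd=-1.0)
        with pytest.raises(ConfigError):
            GeneratorConfig(prior_diagnosis_prob=1.5)

    def test_unknown_keys_warn_and_are_ignored(self):
        with pytest.warns(UserWarning, match="unknown generator config key"):
            cfg = GeneratorConfig.from_mapping({"n_participants": 10, "bogus": 1})
        assert cfg.n_participants == 10

    def test_config_hash_stable(self):
        assert (
            GeneratorConfig(seed=1).config_hash()
            == GeneratorConfig(seed=1).config_hash()
        )
        assert (
            GeneratorConfig(seed=1).config_hash()
            != GeneratorConfig(seed=2).config_hash()
        )


class TestSurface:
    def test_minimum_at_optimum_and_nonnegative(self):
        surf = TrueHazardSurface()
        a = np.linspace(2, 14, 121)
        r = np.arange(0, 13, 0.25)
        A, R = np.meshgrid(a, r)
        g = surf(A, R)
        assert g.min() >= 0
        assert surf(8.0, 7.0) == 0.0
        k = np.unravel_index(np.argmin(g), g.shape)
        assert (A[k], R[k]) == (8.0, 7.0)
        assert g.max() <= surf.cap + 1e-12

    def test_invalid_surface(self):
        with pytest.raises(ConfigError):
            TrueHazardSurface(alpha_dur=-0.1)


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        cfg = GeneratorConfig(n_participants=60, seed=9)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(GeneratorConfig(n_participants=60, seed=9))
        pd.testing.assert_frame_equal(c1.frame(), c2.frame())
        for s1, s2 in zip(c1.series, c2.series):
            assert np.array_equal(s1.grid, s2.grid)

    def test_different_seed_differs(self):
        c1 = generate_cohort(GeneratorConfig(n_participants=60, seed=1))
        c2 = generate_cohort(GeneratorConfig(n_participants=60, seed=2))
        assert not c1.outcomes["time_years"].equals(c2.outcomes["time_years"])


class TestTraits:
    def test_weekend_class_fractions_match_probs(self):
        cfg = GeneratorConfig(n_participants=4000, seed=3)
        traits = sample_participant_traits(cfg, np.random.default_rng(3))
        frac = (traits["weekend_class_true"] == "broke").mean()
        # binomial 4 sigma around 0.266
        assert abs(frac - 0.266) < 4 * np.sqrt(0.266 * 0.734 / 4000)

    def test_degenerate_variance_identical_onsets(self):
        cfg = noise_free_config(n_participants=8)
        traits = sample_participant_traits(cfg, np.random.default_rng(0))
        assert traits["chronotype"].nunique() == 1
        assert traits["mean_duration"].nunique() == 1


class TestSleepWeek:
    def test_noise_free_exact_window(self):
        cfg = noise_free_config()
        traits = sample_participant_traits(cfg, np.random.default_rng(0))
        s = simulate_sleep_week(traits.iloc[0].to_dict(), cfg, np.random.default_rng(1))
        fr = bracket_fractions(s)
        on = {23, 0, 1, 2, 3, 4, 5, 6}
        for b in range(24):
            assert fr.aggregated[b] == (1.0 if b in on else 0.0)
        assert average_sleep_duration(s) == pytest.approx(8.0)

    def test_maintainer_weekend_bout_longer_by_extra(self):
        extra = 0.5
        cfg = noise_free_config(weekend_extra_sleep_hours=extra)
        traits = sample_participant_traits(cfg, np.random.default_rng(0))
        s = simulate_sleep_week(traits.iloc[0].to_dict(), cfg, np.random.default_rng(1))
        per_day = s.grid.sum(axis=1) * cfg.epoch_minutes / 60
        # weekend mornings are days 6 and 7; the longer bout splits between
        # an earlier bedtime (evening before) and a later wake time
        week_total = s.grid.sum() * cfg.epoch_minutes / 60
        assert week_total == pytest.approx(7 * 8.0 + 2 * extra, abs=2 * 5 / 60)
        # weekday mornings unchanged
        assert per_day[2] * 60 == pytest.approx(8 * 60, abs=5)

    def test_awakening_rate_monte_carlo(self):
        # noise-free bout of exactly 8 h/night; Poisson(2) one-epoch bouts
        cfg = noise_free_config(
            awakening_rate=2.0, bout_len_probs=(1.0, 0.0, 0.0), n_participants=1
        )
        rng = np.random.default_rng(12)
        traits = sample_participant_traits(cfg, rng).iloc[0].to_dict()
        awake = []
        for _ in range(300):
            s = simulate_sleep_week(traits, cfg, rng)
            awake.append(672 - int(s.grid.sum()))  # 672 = 8 h x 7 days in epochs
        # 8 nightly bouts x rate 2, minus a small collision correction
        expected = 16.0
        assert np.mean(awake) == pytest.approx(expected, rel=0.06)

    def test_duration_above_24_rejected(self):
        cfg = noise_free_config(weekend_extra_sleep_hours=0.5)
        traits = sample_participant_traits(cfg, np.random.default_rng(0))
        row = traits.iloc[0].to_dict()
        row["mean_duration"] = 23.8  # + weekend extra pushes past 24 h
        with pytest.raises(ConfigError, match="exceeds 24"):
            simulate_sleep_week(row, cfg, np.random.default_rng(1))


class TestOutcomes:
    @staticmethod
    def _frame(n, asd, rsh):
        cfg = GeneratorConfig(n_participants=2, seed=0)
        rng = np.random.default_rng(5)
        traits = sample_participant_traits(
            GeneratorConfig(n_participants=n, seed=4), rng
        )
        traits["asd"] = asd
        traits["rsh"] = rsh
        return traits

    def test_exponential_closed_form(self):
        n, r = 20000, 0.01
        df = self._frame(n, 8.0, 7.0)
        cfg = GeneratorConfig(
            n_participants=n, seed=0, baseline_rate=r,
            surface_alpha_dur=0.0, surface_alpha_rsh=0.0,
            beta_linear={}, surface_cap=0.0,
        )
        out = simulate_outcomes(df, cfg.surface, cfg, np.random.default_rng(8))
        expected = 1 - np.exp(-8 * r)
        assert out["event"].mean() == pytest.approx(expected, rel=0.08)
        assert (out["time_years"] <= 8.0).all()

    def test_hazard_ratio_between_sleep_profiles(self):
        n = 30000
        cfg = GeneratorConfig(n_participants=n, seed=0, baseline_rate=0.01,
                              beta_linear={})
        rng = np.random.default_rng(9)
        d_opt = self._frame(n, 8.0, 7.0)
        d_avg = self._frame(n, 8.9, 5.0)
        p_opt = simulate_outcomes(d_opt, cfg.surface, cfg, rng)["event"].mean()
        p_avg = simulate_outcomes(d_avg, cfg.surface, cfg, rng)["event"].mean()
        # hazard ratio from cumulative incidence under exponential times
        hr = np.log(1 - p_opt) / np.log(1 - p_avg)
        assert hr == pytest.approx(float(np.exp(-cfg.surface(8.9, 5.0))), abs=0.04)

    def test_proportionality_in_baseline_rate(self):
        n = 20000
        df = self._frame(n, 8.9, 5.0)
        res = {}
        for r in (0.005, 0.01):
            cfg = GeneratorConfig(n_participants=n, seed=0, baseline_rate=r,
                                  surface_alpha_dur=0.0, surface_alpha_rsh=0.0,
                                  surface_cap=0.0, beta_linear={})
            out = simulate_outcomes(df, cfg.surface, cfg, np.random.default_rng(3))
            res[r] = out["event"].mean()
        assert res[0.01] / res[0.005] == pytest.approx(2.0, abs=0.15)

    def test_nonfinite_predictor_names_row(self):
        df = self._frame(5, 8.0, 7.0)
        df.loc[2, "bmi"] = np.inf
        cfg = GeneratorConfig(n_participants=5, seed=0)
        with pytest.raises(GenerationError, match="participant"):
            simulate_outcomes(df, cfg.surface, cfg, np.random.default_rng(0))


class TestGenerateCohort:
    def test_smoke_bookkeeping_and_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_participants=100, seed=5)
        cohort = generate_cohort(cfg, outdir=tmp_path)
        assert len(cohort.covariates) == len(cohort.metrics) == 100
        assert len(cohort.outcomes) == len(cohort.series) == 100
        assert (tmp_path / "sleep.csv").exists()
        assert (tmp_path / "run_log.json").exists()
        from sleeproutine import io as sio

        series = sio.read_sleep_csv(tmp_path / "sleep.csv")
        assert len(series) == 100
        orig = {s.participant_id: s.grid for s in cohort.series}
        for s in series:
            assert np.array_equal(s.grid, orig[s.participant_id])

    def test_structural_constraint_every_participant(self):
        cohort = generate_cohort(GeneratorConfig(n_participants=300, seed=8))
        m = cohort.metrics
        assert (m["asd"] >= 0.95 * m["rsh"] - 1e-9).all()
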