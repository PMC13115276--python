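"""Schedule module: stage counts, durations, parameter decay, analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdd_dpsgd.schedule import (
    ConfigurationError,
    ScheduleConfig,
    StageTable,
    build_table,
    derive_num_steps,
    epochs_to_iterations,
    expenditure_profile,
    lookup,
    noise_variance_trajectory,
    read_table_csv,
    read_table_json,
    schedule_stats,
    stage_durations,
    stage_durations_real,
    stage_parameters,
    write_table_csv,
    write_table_json,
)


class TestDeriveNumSteps:
    @pytest.mark.parametrize(
        "lambda_, rho, variant, expected",
        [
            (1.1, 0.3, "floor", 3),           # moderate dynamics headline case
            (1.1, 1 / 2.1, "floor", 2),        # argument is exactly lambda**2
            (1 / 0.9, 0.3, "floor", 2),        # lambda=1.111 vs 1.1 inconsistency
            (1.1, 0.3, "floor_minus_1", 2),
            (2.0, 0.9, "floor_minus_1", 1),    # clamped at 1
        ],
    )
    def test_examples(self, lambda_, rho, variant, expected):
        assert derive_num_steps(lambda_, rho, variant) == expected

    @pytest.mark.parametrize("lambda_, rho", [(1.0, 0.3), (0.5, 0.3), (1.1, 0.0), (1.1, 1.5)])
    def test_domain_errors(self, lambda_, rho):
        with pytest.raises(ConfigurationError):
            derive_num_steps(lambda_, rho)

    @given(
        lambda_=st.floats(1.0001, 2.0),
        rho=st.floats(0.05, 0.9),
    )
    @settings(max_examples=200, derandomize=True)
    def test_protection_horizon(self, lambda_, rho):
        """Stage 0 of the real-valued schedule covers at least rho of training."""
        n = derive_num_steps(lambda_, rho, "floor")
        d = stage_durations_real(1.0, lambda_, n)
        assert d[0] >= rho - 1e-9


class TestStageDurations:
    def test_equal_division_at_unit_lambda(self):
        assert stage_durations(4, 1.0, 4) == [1, 1, 1, 1]

    def test_geometric_integerization(self):
        # D0 = 100*0.1/0.331 ~ 30.211; cumulative rounding gives [30, 33, 37]
        assert stage_durations(100, 1.1, 3) == [30, 33, 37]

    def test_matches_cumulative_rounding_oracle(self):
        # independent oracle: accumulate the geometric terms and round half-up
        for T, lam, n in [(100, 1.1, 3), (2000, 1 / 0.9, 3), (57, 1.3, 4), (500, 1.05, 5)]:
            d0 = T * (lam - 1) / (lam**n - 1)
            cum, acc = [], 0.0
            for i in range(n):
                acc += d0 * lam**i
                cum.append(int(math.floor(acc + 0.5)))
            cum[-1] = T
            expected = list(np.diff([0] + cum))
            assert stage_durations(T, lam, n) == expected

    def test_n_plus_1_convention_adds_a_stage(self):
        assert len(stage_durations(100, 1.1, 3, "n_plus_1_stages")) == 4

    def test_durations_nondecreasing_when_expanding(self):
        d = stage_durations(997, 1.4, 5)
        assert all(b >= a for a, b in zip(d, d[1:]))

    def test_too_few_iterations_raises(self):
        with pytest.raises(ConfigurationError):
            stage_durations(2, 1.1, 3)

    @given(
        T=st.integers(10, 5000),
        lambda_=st.floats(1.0, 2.0),
        n=st.integers(1, 6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_conservation(self, T, lambda_, n):
        """Integerized durations always sum exactly to T and are positive."""
        try:
            d = stage_durations(T, lambda_, n)
        except ConfigurationError:
            return
        assert sum(d) == T
        assert all(x >= 1 for x in d)


class TestStageParameters:
    def test_experimental_values(self):
        sigmas, clips = stage_parameters(1.0, 50.0, 0.8, 0.6, 4)
        assert sigmas == pytest.approx([1.0, 1.25, 1.5625, 1.953125], rel=1e-12)
        assert clips == pytest.approx([50.0, 30.0, 18.0, 10.8], rel=1e-12)

    def test_noise_growth_factor(self):
        sigmas, _ = stage_parameters(1.0, 1.0, 0.8, 0.6, 5)
        ratios = [b / a for a, b in zip(sigmas, sigmas[1:])]
        assert ratios == pytest.approx([1.25] * 4, rel=1e-12)

    def test_static_identity(self):
        sigmas, clips = stage_parameters(2.0, 7.0, 1.0, 1.0, 6)
        assert sigmas == [2.0] * 6
        assert clips == [7.0] * 6

    def test_closed_form_matches_recurrence(self):
        """The closed forms agree with the iterative update rules to 1e-12."""
        sigmas, clips = stage_parameters(1.3, 42.0, 0.85, 0.55, 8)
        s, c = 1.3, 42.0
        for i in range(8):
            assert sigmas[i] == pytest.approx(s, rel=1e-12)
            assert clips[i] == pytest.approx(c, rel=1e-12)
            s /= 0.85
            c *= 0.55

    def test_monotonicity(self):
        sigmas, clips = stage_parameters(1.0, 10.0, 0.8, 0.6, 5)
        assert all(b > a for a, b in zip(sigmas, sigmas[1:]))
        assert all(b < a for a, b in zip(clips, clips[1:]))

    @pytest.mark.parametrize("kwargs", [
        dict(sigma0=-1.0, c0=1, beta=0.8, a=0.6, stages=2),
        dict(sigma0=1, c0=0, beta=0.8, a=0.6, stages=2),
        dict(sigma0=1, c0=1, beta=1.2, a=0.6, stages=2),
        dict(sigma0=1, c0=1, beta=0.8, a=0.0, stages=2),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ConfigurationError):
            stage_parameters(**kwargs)


class TestLookup:
    table = StageTable((30, 33, 37), (1.0, 1.25, 1.5625), (50.0, 30.0, 18.0))

    def test_boundaries(self):
        assert lookup(self.table, 0) == (1.0, 50.0)
        assert lookup(self.table, 99) == (1.5625, 18.0)
        # half-open intervals: iteration 30 belongs to stage 1
        assert lookup(self.table, 30) == (1.25, 30.0)

    def test_matches_linear_scan_oracle(self):
        for t in range(100):
            stage = next(
                i for i, (s, e) in enumerate(zip(self.table.starts, self.table.ends))
                if s <= t < e
            )
            assert lookup(self.table, t) == (
                self.table.sigmas[stage], self.table.clips[stage]
            )

    @pytest.mark.parametrize("t", [-1, 100, 1000])
    def test_out_of_range(self, t):
        with pytest.raises(IndexError):
            lookup(self.table, t)


class TestNoiseVariance:
    def test_initial_value(self):
        table = StageTable((10,), (1.0,), (50.0,))
        assert noise_variance_trajectory(table) == [2500.0]

    def test_constant_ratio(self):
        sigmas, clips = stage_parameters(1.0, 50.0, 0.8, 0.6, 6)
        table = StageTable((1,) * 6, sigmas, clips)
        v = noise_variance_trajectory(table)
        for a, b in zip(v, v[1:]):
            assert b / a == pytest.approx((0.6 / 0.8) ** 2, rel=1e-12)
        assert all(b < a for a, b in zip(v, v[1:]))

    def test_constant_when_rates_match(self):
        sigmas, clips = stage_parameters(1.0, 50.0, 0.7, 0.7, 5)
        v = noise_variance_trajectory(StageTable((1,) * 5, sigmas, clips))
        assert v == pytest.approx([v[0]] * 5, rel=1e-12)


class TestExpenditure:
    def test_uniform_when_beta_is_sqrt_gamma(self):
        gamma = 0.81
        cfg = ScheduleConfig(
            total_iterations=1000, sigma0=1.0, c0=1.0, gamma=gamma,
            beta=math.sqrt(gamma), n=4,
        )
        profile = expenditure_profile(build_table(cfg, integerize=False))
        assert max(profile) / min(profile) == pytest.approx(1.0, rel=1e-12)

    def test_decreasing_for_conservative_beta(self):
        """beta below sqrt(gamma) makes later stages cheaper; sign checked
        against brute-force evaluation of the D/sigma^2 recurrence."""
        cfg = ScheduleConfig(
            total_iterations=1000, sigma0=1.0, c0=1.0, gamma=0.9, beta=0.8, n=4,
        )
        profile = expenditure_profile(build_table(cfg, integerize=False))
        assert all(b < a for a, b in zip(profile, profile[1:]))
        # recurrence oracle: x_{i+1} = x_i * lambda * beta^2
        x, oracle = profile[0], [profile[0]]
        for _ in range(3):
            x *= (1 / 0.9) * 0.8**2
            oracle.append(x)
        assert profile == pytest.approx(oracle, rel=1e-9)


class TestScheduleStats:
    def test_two_point_moments(self):
        stats = schedule_stats(StageTable((1, 1), (1.0, 2.0), (1.0, 1.0)))
        assert stats.weighted_mean == pytest.approx(1.5)
        assert stats.weighted_variance == pytest.approx(0.25)

    def test_constant_schedule_zero_variance(self):
        stats = schedule_stats(StageTable((5, 7), (2.0, 2.0), (1.0, 1.0)))
        assert stats.weighted_variance == 0.0

    def test_d0_fraction_meets_protection_constant(self):
        cfg = ScheduleConfig(
            total_iterations=1000, sigma0=1.0, c0=1.0, gamma=1 / 1.1,
            lambda_=1.1, rho=0.3, n=3,
        )
        stats = schedule_stats(build_table(cfg, integerize=False))
        assert stats.d0_fraction == pytest.approx(0.1 / (1.1**3 - 1), rel=1e-9)
        assert stats.d0_fraction >= 0.3


class TestScheduleConfig:
    def test_lambda_gamma_must_agree(self):
        with pytest.raises(ConfigurationError):
            ScheduleConfig(total_iterations=100, sigma0=1, c0=1, gamma=0.9, lambda_=1.2)

    def test_lambda_derived_from_gamma(self):
        cfg = ScheduleConfig(total_iterations=100, sigma0=1, c0=1, gamma=0.8)
        assert cfg.lambda_ == pytest.approx(1.25, rel=1e-12)

    def test_beta_defaults_to_gamma(self):
        cfg = ScheduleConfig(total_iterations=100, sigma0=1, c0=1, gamma=0.9)
        assert cfg.beta == 0.9

    def test_n_derived_when_absent(self):
        cfg = ScheduleConfig(
            total_iterations=100, sigma0=1, c0=1, gamma=1 / 1.1, lambda_=1.1, rho=0.3
        )
        assert cfg.resolved_n() == 3

    def test_unit_lambda_needs_explicit_n(self):
        cfg = ScheduleConfig(total_iterations=100, sigma0=1, c0=1, gamma=1.0)
        with pytest.raises(ConfigurationError):
            cfg.resolved_n()

    def test_epoch_conversion(self):
        assert epochs_to_iterations(50, 10015, 128) == 50 * 79


class TestTableIO:
    def test_csv_round_trip(self, tmp_path, sdd_schedule):
        table = build_table(sdd_schedule)
        path = tmp_path / "table.csv"
        write_table_csv(table, path)
        back = read_table_csv(path)
        assert back.durations == table.durations
        assert back.sigmas == pytest.approx(table.sigmas, rel=1e-12)
        assert back.clips == pytest.approx(table.clips, rel=1e-12)

    def test_json_round_trip_keeps_config(self, tmp_path, sdd_schedule):
        table = build_table(sdd_schedule)
        path = tmp_path / "table.json"
        write_table_json(table, path, config=sdd_schedule)
        back, cfg = read_table_json(path)
        assert back.durations == table.durations
        assert cfg == sdd_schedule

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("stage,duration\n0,10\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_table_csv(path)
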