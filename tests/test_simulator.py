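"""Unit and property tests for the population simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdiv.simulator import (AdderParams, Cdc13Params, CellState, HillCurve,
                            SimulationConfig, SizerParams, TimerParams,
                            cdc13_update, default_config, divide,
                            division_decision, grow_step, hill_eval,
                            init_population, run_simulation,
                            run_simulation_arrays, snapshot_series)


def make_cell(size=10.0, birth_size=None, **kw):
    return CellState(size=size, birth_size=birth_size or size, **kw)


class TestGrowStep:
    def test_one_minute_multiplicative_growth(self):
        cell = grow_step(make_cell(10.0), 0.006)
        assert cell.size == pytest.approx(10.06, abs=1e-12)
        assert cell.age == 1.0

    def test_zero_growth_is_identity_for_size(self):
        assert grow_step(make_cell(10.0), 0.0).size == 10.0

    def test_hundred_steps_match_closed_form_and_loop_oracle(self):
        cell = make_cell(10.0)
        for _ in range(100):
            cell = grow_step(cell, 0.006)
        assert cell.size == pytest.approx(10.0 * 1.006 ** 100, rel=1e-12)
        assert cell.size == pytest.approx(18.189, abs=5e-4)

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            grow_step(make_cell(), -0.01)

    def test_septated_cell_does_not_elongate(self):
        cell = make_cell(phase="septated", septation_entry_time=5.0)
        grown = grow_step(cell, 0.006)
        assert grown.size == cell.size
        assert grown.age == cell.age + 1.0


class TestHillCurve:
    def test_half_maximal_at_ec50(self):
        assert hill_eval(HillCurve(0.1, 14, 14), 14.0) == pytest.approx(0.05)

    def test_zero_size_gives_zero(self):
        assert hill_eval(HillCurve(0.3, 5, 2), 0.0) == 0.0

    def test_direct_evaluation_at_16(self):
        # 0.1 * (16/14)**14 / (1 + (16/14)**14)
        expected = 0.1 * (16 / 14) ** 14 / (1 + (16 / 14) ** 14)
        assert hill_eval(HillCurve(0.1, 14, 14), 16.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.0866, abs=5e-4)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            hill_eval(HillCurve(), -1.0)

    def test_monotone_nondecreasing_and_bounded(self):
        curve = HillCurve(0.25, 12.0, 6.0)
        sizes = np.linspace(0.0, 60.0, 400)
        p = hill_eval(curve, sizes)
        assert np.all(np.diff(p) >= -1e-15)
        assert np.all((p >= 0.0) & (p <= 0.25))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillCurve(1.2, 14, 14)
        with pytest.raises(ValueError):
            HillCurve(0.1, 0.0, 14)
        with pytest.raises(ValueError):
            HillCurve(0.1, 14, -2)


class TestDivisionDecision:
    def test_sizer_boundary(self):
        params = SizerParams(14.5, 0.0)
        below = make_cell(14.4, rule_threshold=14.5)
        at = make_cell(14.5, rule_threshold=14.5)
        assert not division_decision(below, "sizer", params)
        assert division_decision(at, "sizer", params)

    def test_pdiv_with_zero_pmax_never_triggers(self, rng):
        curve = HillCurve(0.0, 14, 14)
        cell = make_cell(100.0)
        assert not any(division_decision(cell, "pdiv", curve, rng)
                       for _ in range(1000))

    def test_pdiv_trigger_rate_approaches_pmax_far_above_ec50(self, rng):
        curve = HillCurve(0.1, 14, 14)
        cell = make_cell(200.0)
        n = 100_000
        hits = sum(division_decision(cell, "pdiv", curve, rng)
                   for _ in range(n))
        assert hits / n == pytest.approx(0.1, abs=0.005)

    def test_unknown_rule_rejected(self, rng):
        with pytest.raises(ValueError):
            division_decision(make_cell(), "osmotic", None, rng)

    def test_minimal_timer_element_suppresses_all_rules(self):
        cell = make_cell(20.0, rule_threshold=14.5, age=3.0)
        assert not division_decision(cell, "sizer", SizerParams(14.5, 0),
                                     min_cycle_duration=10.0)

    def test_cdc13_concentration_statistic(self):
        params = Cdc13Params()
        cell = make_cell(10.0, cyclin_amount=61.0, rule_threshold=6.0)
        assert division_decision(cell, "cdc13", params)
        cell = make_cell(10.0, cyclin_amount=59.0, rule_threshold=6.0)
        assert not division_decision(cell, "cdc13", params)


class TestCdc13Update:
    def test_absolute_mode_arithmetic(self):
        params = Cdc13Params(synthesis_mode="absolute", synthesis_noise_sd=0.0)
        cell = make_cell(10.0, cyclin_amount=5.0)
        assert cdc13_update(cell, params).cyclin_amount == pytest.approx(5.0699)

    def test_all_rates_zero_is_identity(self):
        params = Cdc13Params(synthesis_rate=0.0, synthesis_noise_sd=0.0,
                             degradation_rate=0.0)
        cell = make_cell(8.0, cyclin_amount=2.5)
        assert cdc13_update(cell, params).cyclin_amount == 2.5

    def test_concentration_reaches_threshold_near_110_minutes(self):
        # dC/dt = 0.07 - g*C from C = 0.7 crosses 6 around t = 110 min
        params = Cdc13Params(synthesis_noise_sd=0.0)
        cell = make_cell(7.0, cyclin_amount=4.9)
        t = 0
        while cell.cyclin_amount / cell.size < 6.0:
            cell = grow_step(cell, 0.006)
            cell = cdc13_update(cell, params)
            t += 1
            assert t < 400
        assert 105 <= t <= 115

    def test_basal_component_adds_size_independent_synthesis(self):
        params = Cdc13Params(synthesis_rate=0.0, synthesis_noise_sd=0.0,
                             degradation_rate=0.0, basal_synthesis_rate=0.5)
        cell = make_cell(10.0, cyclin_amount=1.0)
        assert cdc13_update(cell, params).cyclin_amount == pytest.approx(1.5)


class _StubRng:
    """Deterministic stand-in emitting a fixed Gaussian draw."""

    def __init__(self, value):
        self.value = value

    def normal(self, loc, scale, size=None):
        return self.value


class TestDivide:
    def config(self, **kw):
        return default_config("pdiv", **kw)

    def test_symmetric_split_of_published_daughter_rule(self):
        cell = make_cell(14.0, birth_size=7.0, age=100.0)
        d1, d2, rec = divide(cell, self.config(asymmetry_sd=0.0), _StubRng(0.0))
        assert d1.size == pytest.approx(7.35)
        assert d2.size == pytest.approx(7.35)
        assert rec.division_size == 14.0

    def test_asymmetric_split(self):
        cell = make_cell(14.0, birth_size=7.0, age=100.0)
        d1, d2, _ = divide(cell, self.config(), _StubRng(0.5))
        assert d1.size == pytest.approx(7.85)
        assert d2.size == pytest.approx(6.85)

    @settings(max_examples=50, derandomize=True)
    @given(division_size=st.floats(0.5, 80.0),
           seed=st.integers(0, 2 ** 20))
    def test_daughter_size_conservation(self, division_size, seed):
        cell = make_cell(division_size, birth_size=division_size / 2,
                         age=50.0)
        d1, d2, _ = divide(cell, self.config(),
                           np.random.default_rng(seed))
        assert d1.size + d2.size == pytest.approx(1.05 * division_size,
                                                  rel=1e-12)
        assert d1.size > 0 and d2.size > 0

    def test_record_reflects_mother_cycle(self):
        cell = make_cell(15.0, birth_size=7.5, birth_time=40.0, age=110.0)
        _, _, rec = divide(cell, self.config(asymmetry_sd=0.0), _StubRng(0.0))
        assert rec.birth_time == 40.0
        assert rec.division_time == 150.0
        assert rec.extension == pytest.approx(7.5)
        assert rec.duration == pytest.approx(110.0)


class TestInitPopulation:
    def test_degenerate_gaussian(self):
        cfg = default_config("pdiv", init_mean=14.0, init_sd=0.0, n_init=20)
        cells = init_population(cfg)
        assert len(cells) == 20
        assert all(c.size == 14.0 for c in cells)

    def test_seeded_draw_is_reproducible(self):
        cfg = default_config("pdiv", seed=7)
        a = [c.size for c in init_population(cfg)]
        b = [c.size for c in init_population(cfg)]
        assert a == b

    def test_sample_mean_within_three_standard_errors(self):
        cfg = default_config("pdiv", seed=11)
        cells = init_population(cfg)
        assert np.mean([c.size for c in cells]) == pytest.approx(14.0, abs=1.0)

    def test_initial_cells_untracked_by_default(self):
        cells = init_population(default_config("pdiv", seed=0))
        assert not any(c.tracked for c in cells)

    def test_negative_init_sd_rejected(self):
        with pytest.raises(ValueError):
            default_config("pdiv", init_sd=-1.0)


class TestRunSimulation:
    def test_zero_pmax_population_never_divides(self):
        cfg = default_config("pdiv", rule_params=HillCurve(0.0, 14, 14),
                             t_max=200.0)
        records, snap = run_simulation(cfg)
        assert records == []
        assert len(snap) == cfg.n_init

    def test_noiseless_timer_is_exact(self):
        cfg = default_config("timer", rule_params=TimerParams(100.0, 0.0),
                             seed=2, t_max=600.0)
        rec = run_simulation_arrays(cfg)
        assert np.all(rec["duration"] == 100.0)
        ratio = rec["division_size"] / rec["birth_size"]
        assert np.allclose(ratio, 1.006 ** 100, rtol=1e-9)

    def test_default_pdiv_run_exceeds_thousand_cycles(self, pdiv_runs):
        assert pdiv_runs(0)["division_size"].size > 1000

    def test_noiseless_sizer_overshoot_bound(self):
        cfg = default_config("sizer", rule_params=SizerParams(14.5, 0.0),
                             seed=3)
        rec = run_simulation_arrays(cfg)
        d = rec["division_size"]
        assert d.size > 500
        assert np.all(d >= 14.5)
        assert np.all(d <= 14.5 * 1.006 + 1e-12)

    def test_determinism_given_seed(self):
        cfg = default_config("pdiv", seed=77, t_max=300.0)
        a = run_simulation_arrays(cfg)
        b = run_simulation_arrays(cfg)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])

    def test_size_doubles_in_about_116_steps(self):
        cell = make_cell(1.0)
        steps = 0
        while cell.size < 2.0:
            cell = grow_step(cell, 0.006)
            steps += 1
        assert 115 <= steps <= 117

    def test_first_passage_distribution_matches_survival_product(self):
        """Empirical division-size CDF of a cohort against the discrete
        survival product over the growth trajectory (KS distance < 0.02)."""
        b = 10.0
        cfg = default_config("pdiv", n_init=10_000, init_mean=b, init_sd=0.0,
                             asymmetry_sd=0.0, t_max=200.0, seed=4,
                             record_initial=True)
        rec = run_simulation_arrays(cfg)
        first = rec["division_size"][rec["birth_time"] == 0.0]
        assert first.size > 9_900
        steps = np.arange(1, 201)
        sizes = b * 1.006 ** steps
        p = hill_eval(HillCurve(0.1, 14, 14), sizes)
        surv = np.cumprod(1.0 - p)
        pmf = p * np.concatenate([[1.0], surv[:-1]])
        cdf = np.cumsum(pmf) / pmf.sum()  # conditional on division by t_max
        ecdf = np.searchsorted(np.sort(first), sizes, side="right") / first.size
        assert np.max(np.abs(ecdf - cdf)) < 0.02


class TestSnapshotSeries:
    def test_instantaneous_division_never_septates(self):
        cfg = default_config("pdiv", seed=5, t_max=300.0)
        snaps = snapshot_series(cfg, 50.0)
        assert all(not s.septated.any() for s in snaps)

    def test_fixed_seed_series_identical(self):
        cfg = default_config("pdiv", seed=6, t_max=200.0,
                             septation_duration=30.0)
        s1 = snapshot_series(cfg, 25.0)
        s2 = snapshot_series(cfg, 25.0)
        assert [s.time for s in s1] == [s.time for s in s2]
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.sizes, b.sizes)
            np.testing.assert_array_equal(a.septated, b.septated)

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            snapshot_series(default_config("pdiv"), 0.0)

    def test_steady_state_occupancy_matches_renewal_formula(self):
        """Septated fraction in a size bin ~ h*tau/(1 + h*tau) with h the
        local division hazard (Monte-Carlo tolerance)."""
        tau = 30.0
        cfg = default_config("pdiv", septation_duration=tau, seed=3)
        snaps = snapshot_series(cfg, 10.0)
        late = [s for s in snaps if s.time >= 600.0]
        sizes = np.concatenate([s.sizes for s in late])
        sept = np.concatenate([s.septated for s in late])
        curve = cfg.rule_params
        for lo, hi in [(13, 14), (14, 15), (15, 16), (16, 18)]:
            mask = (sizes >= lo) & (sizes < hi)
            assert mask.sum() > 300
            occupancy = sept[mask].mean()
            h = hill_eval(curve, 0.5 * (lo + hi))
            assert occupancy == pytest.approx(h * tau / (1 + h * tau),
                                              abs=0.05)


class TestConfigValidation:
    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(rule="volume")

    def test_mismatched_rule_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(rule="sizer", rule_params=AdderParams())

    def test_default_params_follow_rule(self):
        assert isinstance(default_config("adder").rule_params, AdderParams)
        assert default_config("adder").rule_params.mean == 6.75
        assert default_config("cdc13").n_init == 10
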