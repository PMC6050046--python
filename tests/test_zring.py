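"""Z-ring incorporation model: sampling, statistic, exact oracle, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftszlat import (
    ZRingSimConfig,
    disruptive_fraction_in_ring,
    exact_statistic_small,
    incorporation_states,
    run_simulation,
    sample_compositions,
    sweep,
)


class TestSampling:
    def test_degenerate_fractions(self):
        rng = np.random.default_rng(0)
        zeros = sample_compositions(ZRingSimConfig(f=0.0), rng)
        assert np.all(zeros == 0)
        full = sample_compositions(ZRingSimConfig(f=1.0), rng)
        assert np.all(full == 50)

    def test_binomial_moments(self):
        """Mean of Binomial(50, 0.5) draws within 3 SE of 25."""
        cfg = ZRingSimConfig(n_protofilaments=100_000, f=0.5)
        x = sample_compositions(cfg, np.random.default_rng(7))
        se = np.sqrt(50 * 0.25 / len(x))
        assert abs(x.mean() - 25.0) < 3 * se

    def test_incorporation_rates_at_extremes(self):
        cfg = ZRingSimConfig(T=25)
        rng = np.random.default_rng(11)
        n = 100_000
        all_above = incorporation_states(np.full(n, 50), cfg, rng)
        assert all_above.mean() == pytest.approx(0.01, abs=3 * np.sqrt(0.01 * 0.99 / n))
        all_below = incorporation_states(np.zeros(n, dtype=int), cfg, rng)
        assert all_below.mean() == pytest.approx(0.99, abs=3 * np.sqrt(0.01 * 0.99 / n))

    def test_certain_incorporation(self):
        cfg = ZRingSimConfig(p_incorp_above=1.0, p_incorp_below=1.0)
        v = incorporation_states(np.arange(51), cfg, np.random.default_rng(0))
        assert v.all()

    def test_threshold_tie_is_tolerated_by_default(self):
        """x = T uses the below-threshold probability (f_c = T/L is tolerated)."""
        cfg = ZRingSimConfig(T=10, p_incorp_below=1.0, p_incorp_above=0.0)
        x = np.full(1000, 10)
        assert incorporation_states(x, cfg, np.random.default_rng(0)).all()
        strict = ZRingSimConfig(T=10, p_incorp_below=1.0, p_incorp_above=0.0,
                                tie_is_below=False)
        assert not incorporation_states(x, strict, np.random.default_rng(0)).any()


class TestStatistic:
    def test_direct_arithmetic(self):
        assert disruptive_fraction_in_ring([3, 1], [0, 1]) == pytest.approx(0.25)
        assert disruptive_fraction_in_ring([2, 5], [1, 1]) == 1.0
        assert disruptive_fraction_in_ring([2, 5], [0, 0]) == 0.0
        assert np.isnan(disruptive_fraction_in_ring([0, 0], [1, 1]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_statistic_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 51, size=20)
        v = rng.integers(0, 2, size=20)
        s = disruptive_fraction_in_ring(x, v)
        assert np.isnan(s) or 0.0 <= s <= 1.0


class TestRunSimulation:
    def test_seeded_bit_reproducibility(self):
        cfg = ZRingSimConfig(n_reps=500, seed=123)
        a = run_simulation(cfg).per_rep_statistic
        b = run_simulation(cfg).per_rep_statistic
        assert np.array_equal(a, b, equal_nan=True)
        c = run_simulation(ZRingSimConfig(n_reps=500, seed=124)).per_rep_statistic
        assert not np.array_equal(a, c, equal_nan=True)

    def test_all_above_threshold_limit(self):
        """f = 1, T = 25: every protofilament is above threshold, mean → 0.01."""
        res = run_simulation(ZRingSimConfig(f=1.0, T=25, seed=5))
        assert res.mean == pytest.approx(0.01, abs=3 * res.std_error)

    def test_all_below_threshold_limit(self):
        """f small: essentially no protofilament crosses T, mean → 0.99."""
        res = run_simulation(ZRingSimConfig(f=0.02, T=10, seed=5))
        assert res.mean == pytest.approx(0.99, abs=3 * res.std_error + 1e-4)

    def test_undefined_replicates_counted_not_averaged(self):
        cfg = ZRingSimConfig(n_protofilaments=2, subunits_per_protofilament=3,
                             f=0.05, T=1, n_reps=20_000, seed=9)
        res = run_simulation(cfg)
        assert res.n_undefined > 0
        assert len(res.defined) + res.n_undefined == cfg.n_reps
        expected_p0 = (1 - 0.05) ** 6
        assert res.p_undefined == pytest.approx(expected_p0, abs=0.02)

    def test_degenerate_probability_collapse(self):
        """p_above = p_below = p: incorporation is f-independent, mean = p."""
        cfg = ZRingSimConfig(p_incorp_above=0.6, p_incorp_below=0.6,
                             f=0.3, T=10, n_reps=20_000, seed=2)
        res = run_simulation(cfg)
        assert res.mean == pytest.approx(0.6, abs=4 * res.std_error)
        exact, _ = exact_statistic_small(2, 3, 0.3, 1, p_above=0.6, p_below=0.6)
        assert exact == pytest.approx(0.6, rel=1e-12)


class TestExactOracle:
    def test_trivial_cases(self):
        # single protofilament of one subunit, always disruptive, never incorporated
        e, p0 = exact_statistic_small(1, 1, 1.0, 0, p_above=0.0, p_below=0.99)
        assert e == pytest.approx(0.0)
        assert p0 == pytest.approx(0.0)
        # tie tolerated: x = 1 = T incorporates with certainty
        e, _ = exact_statistic_small(1, 1, 1.0, 1, p_above=0.0, p_below=1.0)
        assert e == pytest.approx(1.0)

    def test_oversized_state_space_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            exact_statistic_small(10, 50, 0.5, 10)

    def test_monte_carlo_agrees_with_enumeration(self):
        """n = 2, L = 3 grid: simulation within 4 SE of the exact expectation."""
        for f in (0.2, 0.5, 0.8):
            for T in (0, 1, 2):
                exact, _ = exact_statistic_small(2, 3, f, T)
                cfg = ZRingSimConfig(n_protofilaments=2, subunits_per_protofilament=3,
                                     f=f, T=T, n_reps=200_000, seed=17)
                res = run_simulation(cfg)
                assert abs(res.mean - exact) < 4 * res.std_error, (f, T)


class TestSweep:
    def test_single_point_equals_run(self):
        cfg = ZRingSimConfig(n_reps=2000, seed=3)
        table = sweep([0.4], [10], cfg)
        assert len(table) == 1
        row = table.iloc[0]
        child = np.random.SeedSequence(3).spawn(1)[0]
        seed = int(child.generate_state(1)[0] % (2**31))
        direct = run_simulation(ZRingSimConfig(n_reps=2000, seed=seed, f=0.4, T=10))
        assert row["mean"] == pytest.approx(direct.mean)
        assert row["f_c"] == pytest.approx(0.2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sweep([], [10])

    def test_mean_decreases_in_f_beyond_threshold(self):
        """More disruptive FtsZ in the cell → a *smaller* disruptive fraction
        in the ring, once f crosses the tolerated fraction (enumeration, small n;
        Monte-Carlo where the gaps are resolvable at the replicate budget)."""
        exacts = [exact_statistic_small(2, 3, f, 1)[0] for f in (0.4, 0.55, 0.7, 0.85)]
        assert all(a > b for a, b in zip(exacts, exacts[1:]))
        cfg = ZRingSimConfig(n_reps=4000, seed=8)
        table = sweep([0.3, 0.4, 0.5], [10], cfg)
        means = table["mean"].to_numpy()
        assert means[0] > means[1] > means[2]


class TestExpectedStatistic:
    def test_agrees_with_enumeration_oracle(self):
        """Two independent exact routes (full enumeration vs the pooled
        Binomial reduction) coincide to machine precision at tiny n, L."""
        from ftszlat import expected_statistic

        for f in (0.2, 0.5, 0.8):
            for T in (0, 1, 2):
                enum, _ = exact_statistic_small(2, 3, f, T)
                reduced = expected_statistic(
                    ZRingSimConfig(n_protofilaments=2, subunits_per_protofilament=3,
                                   f=f, T=T)
                )
                assert reduced == pytest.approx(enum, abs=1e-12)

    def test_monte_carlo_agrees_at_study_scale(self):
        from ftszlat import expected_statistic

        cfg = ZRingSimConfig(f=0.3, T=10, n_reps=20_000, seed=21)
        res = run_simulation(cfg)
        assert res.mean == pytest.approx(expected_statistic(cfg), abs=4 * res.std_error)

    def test_excess_strictly_decreasing_past_threshold(self):
        """The exact sub-threshold excess shrinks monotonically in f, down to
        scales far below Monte-Carlo resolution — the model's central claim."""
        from ftszlat import expected_statistic_excess

        excess = [expected_statistic_excess(ZRingSimConfig(f=f, T=10))
                  for f in np.arange(0.3, 0.95, 0.1)]
        assert all(e > 0 for e in excess)
        assert all(a > b for a, b in zip(excess, excess[1:]))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"f": 1.5},
            {"T": 51},
            {"p_incorp_above": -0.1},
            {"n_reps": 0},
            {"n_protofilaments": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ZRingSimConfig(**kwargs)

    def test_critical_fraction(self):
        assert ZRingSimConfig(T=10).critical_fraction == pytest.approx(0.2)
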