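import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beecolony import (
    ColonyParams,
    ColonyState,
    SimToggles,
    SURVIVAL_PRESETS,
    acceleration,
    aggregate,
    initial_state,
    nurse_factor,
    processing_factor,
    scarcity,
    simulate,
    step,
)


class TestAggregate:
    def test_range_lengths(self):
        c = aggregate(np.full(55, 100.0))
        assert (c.E, c.L, c.P, c.N, c.Q, c.H, c.F) == (300, 500, 1200, 1000, 1100, 2100, 1400)

    def test_zeros(self):
        c = aggregate(np.zeros(55))
        assert c.total == 0.0

    def test_hive_partitions_into_nurses_and_processors(self, rng):
        B = rng.uniform(0, 500, size=55)
        c = aggregate(B)
        assert c.H == pytest.approx(c.N + c.Q, rel=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            aggregate(np.zeros(54))


class TestFeedbackFactors:
    def test_nurse_factor_saturates_at_one(self):
        assert nurse_factor(1200, 1000, 1.0, 0.25) == 1.0

    def test_nurse_factor_quarter_power(self):
        assert nurse_factor(500, 1000, 1.0, 0.25) == pytest.approx(0.5**0.25)

    def test_nurse_factor_no_larvae(self):
        assert nurse_factor(0, 0, 1.0, 0.25) == 1.0

    def test_processing_factor_cases(self):
        assert processing_factor(900, 1000, 0.8) == 1.0
        assert processing_factor(400, 1000, 0.8) == pytest.approx(0.5)
        assert processing_factor(0, 0, 0.8) == 1.0


class TestScarcity:
    def _counts(self, B):
        return aggregate(B)

    def test_ample_food_no_deficit(self, params):
        st_ = initial_state(800, 300, 2000.0, t0=100.0)
        st_.B[3:8] = 90.0  # some larvae
        sc = scarcity(st_, aggregate(st_.B), params)
        assert sc.D == 0.0
        assert (sc.S_L, sc.S_H, sc.S_F) == (1.0, 1.0, 1.0)
        assert sc.gamma_L_active == 0.0
        assert not sc.d.any()

    def test_adults_fed_first(self, params):
        """Accessible food covers adults; larvae share the remainder."""
        B = np.zeros(55)
        B[3:8] = 8.0 / 5 / 0.018     # f_L = 8 g/day
        B[20:41] = 3.0 / 21 / 0.007  # f_H = 3
        B[41:55] = 3.0 / 14 / 0.007  # f_F = 3
        state = ColonyState(100.0, B, 110.0)  # f_a = 10
        sc = scarcity(state, aggregate(B), params)
        assert sc.S_L == pytest.approx((10 - 6) / 8)
        assert (sc.S_H, sc.S_F) == (1.0, 1.0)
        assert sc.gamma_L_active == 0.5

    def test_floors_when_no_food(self, params):
        B = np.zeros(55)
        B[3:8] = 100.0
        B[20:41] = 100.0
        B[41:55] = 100.0
        state = ColonyState(100.0, B, 50.0)  # below the inaccessible reserve
        sc = scarcity(state, aggregate(B), params)
        assert (sc.S_L, sc.S_H, sc.S_F) == (0.2, 0.5, 0.67)
        assert sc.d.sum() > 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        food=st.floats(min_value=0, max_value=5000),
        scale=st.floats(min_value=0, max_value=3000),
    )
    def test_factors_respect_floors_and_saturation(self, food, scale):
        params = ColonyParams()
        B = np.full(55, scale)
        state = ColonyState(100.0, B, food)
        sc = scarcity(state, aggregate(B), params)
        assert 0.2 <= sc.S_L <= 1.0
        assert 0.5 <= sc.S_H <= 1.0
        assert 0.67 <= sc.S_F <= 1.0
        if sc.f_a >= sc.f_d:
            assert (sc.S_L, sc.S_H, sc.S_F) == (1.0, 1.0, 1.0)
            assert sc.D == 0.0 and sc.gamma_L_active == 0.0


class TestAcceleration:
    def _counts(self, H, F, L):
        B = np.zeros(55)
        B[20:41] = H / 21.0
        B[41:55] = F / 14.0
        B[3:8] = L / 5.0
        return aggregate(B)

    def test_balanced_colony_is_neutral(self, params):
        c = self._counts(H=2300, F=1000, L=1150)
        a = acceleration(c, 0.0, 10.0, params)
        np.testing.assert_allclose(a, 1.0)

    def test_surplus_hive_accelerates(self, params):
        c = self._counts(H=4600, F=1000, L=2300)
        a = acceleration(c, 0.0, 10.0, params)
        assert a[34:41] == pytest.approx(2.0)
        assert (a[:34] == 1.0).all() and (a[41:] == 1.0).all()

    def test_clamped_to_bounds(self, params):
        c = self._counts(H=20000, F=1000, L=100)
        a = acceleration(c, 0.0, 10.0, params)
        assert a[34:41] == pytest.approx(3.0)

    def test_winter_disables(self, params):
        c = self._counts(H=20000, F=1000, L=100)
        np.testing.assert_allclose(acceleration(c, 0.0, 10.0, params, winter=True), 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        H=st.floats(min_value=0, max_value=5e4),
        F=st.floats(min_value=0, max_value=5e4),
        L=st.floats(min_value=0, max_value=5e4),
        D=st.floats(min_value=0, max_value=100),
    )
    def test_always_within_bounds(self, H, F, L, D):
        params = ColonyParams()
        c = self._counts(H=H, F=F, L=L)
        a = acceleration(c, D, max(D, 1.0) + 10.0, params)
        assert (a >= 1 / 3 - 1e-12).all() and (a <= 3 + 1e-12).all()


class TestStep:
    def test_lossless_uniform_state_is_fixed_point(self, params_III, toggles_off):
        B = np.full(55, 1500.0)
        state = ColonyState(0.0, B.copy(), 5000.0)
        new, _ = step(state, params_III, 1.0, toggles_off)
        np.testing.assert_allclose(new.B, B, rtol=1e-12)

    def test_single_step_from_empty_colony(self, params, toggles_off):
        state = ColonyState(0.0, np.zeros(55), 2000.0)
        new, _ = step(state, params, 1.0, toggles_off)
        assert new.B[0] == pytest.approx(1500.0)
        assert not new.B[1:].any()

    def test_no_bees_no_food_flux(self, params, toggles_off):
        state = ColonyState(0.0, np.zeros(55), 2000.0)
        new, _ = step(state, params, 1.0, toggles_off)
        assert new.f == 2000.0

    def test_food_balance_identity_without_deficit(self, params):
        """With no deficit the food update is exactly
        dt * (s * f_Q * p * F - f_d)."""
        state = initial_state(8000, 3000, 5000.0, t0=120.0)
        tg = SimToggles()
        new, diag = step(state, params, 0.1, tg)
        c = aggregate(state.B)
        assert diag.scarcity.D == 0.0
        expected = 0.1 * (diag.s_t * diag.f_Q * params.p * c.F - diag.scarcity.f_d)
        assert new.f - state.f == pytest.approx(expected, abs=1e-9)

    def test_rejects_bad_dt(self, params):
        with pytest.raises(ValueError):
            step(initial_state(100), params, 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        t0=st.floats(min_value=0, max_value=365),
        food=st.floats(min_value=0, max_value=4000),
    )
    def test_state_stays_physical_at_stable_dt(self, seed, t0, food):
        """Abundances and the food store stay non-negative for dt <= 1/3 d
        with every feedback active."""
        rng = np.random.default_rng(seed)
        state = ColonyState(t0, rng.uniform(0, 3000, size=55), food)
        params = ColonyParams(E0=1600.0)
        for _ in range(30):
            state, _ = step(state, params, 1.0 / 3.0, SimToggles())
            assert (state.B >= -1e-9).all()
            assert state.f >= 0.0


class TestWinterRules:
    def test_no_eggs_laid_in_winter(self, params):
        state = initial_state(8000, 1000, 2000.0, t0=300.0)
        new, diag = step(state, params, 1.0, SimToggles())
        assert diag.winter
        assert new.B[0] == 0.0

    def test_adult_aging_frozen_with_reduced_mortality(self, params):
        state = initial_state(8400, 1400, 5000.0, t0=300.0)
        new, _ = step(state, params, 1.0, SimToggles())
        # every adult class decays by exactly the winter rate; no transfer
        np.testing.assert_allclose(new.B[20:55], state.B[20:55] * 0.99, rtol=1e-12)

    def test_brood_still_matures_into_hive(self, params):
        state = initial_state(0, 0, 5000.0, t0=300.0)
        state.B[19] = 500.0  # oldest pupae
        new, _ = step(state, params, 1.0, SimToggles())
        assert new.B[20] == pytest.approx(500.0 * 0.999, rel=1e-12)

    def test_wintering_hive_bees_do_not_draw_stores(self, params):
        state = initial_state(8400, 0, 5000.0, t0=300.0)
        new, diag = step(state, params, 1.0, SimToggles())
        assert diag.scarcity.f_H == 0.0
        assert new.f == state.f  # no larvae, no foragers, no income


class TestSimulate:
    def test_records_collapse_day(self, params):
        state = initial_state(1200, 0, 50.0, t0=100.0)
        traj = simulate(state, params.replace(E0=0.0), 200.0, 0.25, SimToggles())
        assert traj.collapse_day is not None
        assert 100.0 < traj.collapse_day < 200.0

    def test_deterministic_rerun_is_identical(self, params):
        def run():
            st_ = initial_state(8000, 0, 2000.0, t0=60.0)
            return simulate(st_, params.replace(E0=1600.0), 120.0, 0.1, SimToggles()).to_frame()

        a, b = run(), run()
        assert a.equals(b)

    def test_initial_state_layout(self):
        st_ = initial_state(10400, 5600, 2000.0, t0=210.0)
        c = aggregate(st_.B)
        assert c.H == pytest.approx(10400)
        assert c.F == pytest.approx(5600)
        assert c.brood == 0.0
        assert st_.f == 2000.0 and st_.t == 210.0

    def test_unstable_step_flagged_not_raised(self, params):
        st_ = initial_state(8000, 0, 2000.0, t0=1.0)
        traj = simulate(st_, params.replace(E0=1600.0), 151.0, 0.7, SimToggles(winter=False))
        assert traj.min_age_class < -1.0  # positivity violated at dt = 16.8 h
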