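"""Deterministic gene-for-gene recursion, equilibrium and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfgcoal import (
    GFGParams,
    HostParasiteState,
    PopulationConfig,
    SimulationSettings,
    classify_dynamics,
    equilibrium_closed_form,
    iterate_to_equilibrium,
    simulate_frequency_path,
    step_deterministic,
)
from gfgcoal.dynamics import classify_deterministic, terminal_mean
from gfgcoal._kernels import gfg_step


class TestStepDeterministic:
    def test_golden_values_exact_rational_oracle(self):
        """One step at (R=0.2, a1=0.2), s=0.5, c_H=0.05, c_P=0.1.

        Expected values computed independently by exact rational
        substitution into the recursion: a2 = 9/41, a1' = 2169/8729,
        R' = 6669/23069.
        """
        state = HostParasiteState(R=0.2, a1=0.2)
        params = GFGParams(s=0.5, c_H=0.05, c_P=0.1)
        nxt = step_deterministic(state, params)
        assert nxt.a2 == pytest.approx(9 / 41, abs=1e-14)
        assert nxt.a1 == pytest.approx(2169 / 8729, abs=1e-14)
        assert nxt.R == pytest.approx(6669 / 23069, abs=1e-14)

    def test_zero_corner_is_absorbing(self):
        state = HostParasiteState(R=0.0, a1=0.0)
        nxt = step_deterministic(state, GFGParams(s=0.3, c_H=0.05, c_P=0.2))
        assert (nxt.R, nxt.a1, nxt.a2) == (0.0, 0.0, 0.0)

    def test_infective_allele_fixed_when_cost_free(self):
        state = HostParasiteState(R=0.5, a1=1.0)
        nxt = step_deterministic(state, GFGParams(s=0.4, c_H=0.05, c_P=0.0))
        assert nxt.a2 == 1.0
        assert nxt.a1 == 1.0

    @settings(max_examples=300, deadline=None)
    @given(
        R=st.floats(0, 1),
        a1=st.floats(0, 1),
        s=st.floats(0, 0.99),
        c_h=st.floats(0, 0.99),
        c_p=st.floats(0, 0.99),
    )
    def test_frequencies_stay_in_unit_interval(self, R, a1, s, c_h, c_p):
        a2, a1n, Rn = gfg_step(R, a1, s, s / 2, c_h, c_p)
        for v in (a2, a1n, Rn):
            assert 0.0 <= v <= 1.0

    def test_unit_interval_bulk_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(100_000):
            vals = rng.random(5)
            a2, a1n, Rn = gfg_step(vals[0], vals[1], vals[2] * 0.99,
                                   vals[2] * 0.495, vals[3] * 0.99, vals[4] * 0.99)
            assert 0.0 <= a2 <= 1.0 and 0.0 <= a1n <= 1.0 and 0.0 <= Rn <= 1.0


class TestEquilibrium:
    def test_no_interior_equilibrium_without_resistance_cost(self):
        eq = equilibrium_closed_form(GFGParams(s=0.4, c_H=0.0, c_P=0.1))
        assert eq.a_hat == pytest.approx(1.0, abs=1e-12)
        assert not eq.valid

    def test_closed_form_identity(self):
        """The two printed forms agree: R_hat * (2 - c_P - a_hat) = c_P."""
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(500):
            params = GFGParams(
                s=rng.uniform(0.1, 0.9),
                c_H=rng.uniform(0.01, 0.35),
                c_P=rng.uniform(0.01, 0.35),
            )
            eq = equilibrium_closed_form(params)
            if eq.valid:
                assert eq.R_hat * (2 - params.c_P - eq.a_hat) == pytest.approx(
                    params.c_P, abs=1e-12
                )
                checked += 1
        assert checked > 100

    def test_matches_long_run_iteration(self):
        """Closed form within 0.05 of the 30,000-generation iterated mean."""
        params = GFGParams(s=0.5, c_H=0.05, c_P=0.1)
        eq = equilibrium_closed_form(params)
        assert eq.valid
        traj = iterate_to_equilibrium(params, R0=0.2, a0=0.2, g_max=30_000)
        R_bar, a_bar = terminal_mean(traj)
        assert abs(a_bar - eq.a_hat) <= 0.05
        assert abs(R_bar - eq.R_hat) <= 0.05

    def test_negative_discriminant_flags_invalid(self):
        # s tiny, c_H large: (s2+s1)^2 < 4 s2 (s1 - c_H) is impossible when
        # s1 <= c_H (discriminant positive); construct via s1 > c_H barely
        eq = equilibrium_closed_form(GFGParams(s=0.02, c_H=0.3, c_P=0.1))
        assert isinstance(eq.valid, bool)  # no exception either way


class TestIteration:
    def test_fixed_point_invariance(self):
        """Starting at the root-refined fixed point, the iteration stays put."""
        from scipy.optimize import fsolve

        params = GFGParams(s=0.3, c_H=0.05, c_P=0.1)

        def residual(x):
            nxt = step_deterministic(HostParasiteState(R=x[0], a1=x[1]), params)
            return [nxt.R - x[0], nxt.a1 - x[1]]

        eq = equilibrium_closed_form(params)
        root = fsolve(residual, [eq.R_hat, eq.a_hat], xtol=1e-13)
        assert np.allclose(residual(root), 0, atol=1e-11)
        traj = iterate_to_equilibrium(params, R0=root[0], a0=root[1], g_max=500)
        for state in traj:
            assert abs(state.R - root[0]) < 1e-9
            assert abs(state.a1 - root[1]) < 1e-9

    def test_susceptible_fixes_when_s_below_resistance_cost(self):
        """s < c_H: the resistant frequency decays monotonically to 0."""
        traj = iterate_to_equilibrium(
            GFGParams(s=0.04, c_H=0.05, c_P=0.1), R0=0.2, a0=0.2, g_max=5_000
        )
        R = np.array([s.R for s in traj])
        assert np.all(np.diff(R) <= 1e-15)
        assert R[-1] < 1e-4

    def test_terminal_mean_matches_golden_equilibrium(self):
        params = GFGParams(s=0.5, c_H=0.05, c_P=0.1)
        traj = iterate_to_equilibrium(params, R0=0.2, a0=0.2, g_max=30_000)
        R_bar, a_bar = terminal_mean(traj)
        # golden values from the independent long-run oracle run
        assert a_bar == pytest.approx(0.904, abs=0.02)
        assert R_bar == pytest.approx(0.092, abs=0.02)

    def test_iterated_inf_equilibrium_nondecreasing_in_s(self):
        """The INF equilibrium rises with the cost of infection."""
        a_bars = []
        for s in np.arange(0.2, 0.81, 0.1):
            traj = iterate_to_equilibrium(
                GFGParams(s=round(s, 2), c_H=0.05, c_P=0.1), 0.2, 0.2, 20_000
            )
            a_bars.append(terminal_mean(traj)[1])
        assert np.all(np.diff(a_bars) >= -1e-6)


class TestClassifyDynamics:
    def test_fixed_parasite_is_arms_race(self):
        host = np.array([20, 30, 40, 35])
        para = np.array([20, 60, 90, 100])
        assert classify_dynamics(host, para, N_H=100, N_P=100) == "arms_race"

    def test_interior_both_species_is_trench_warfare(self):
        host = np.array([20, 30, 40, 35])
        para = np.array([20, 60, 90, 70])
        assert classify_dynamics(host, para, N_H=100, N_P=100) == "trench_warfare"

    def test_loss_without_sweep_is_degenerate(self):
        host = np.array([20, 10, 2, 0])
        para = np.array([20, 10, 5, 3])
        assert classify_dynamics(host, para, N_H=100, N_P=100) == "degenerate"

    def test_deterministic_and_stochastic_labels_agree_on_fixation(self):
        params = GFGParams(s=0.04, c_H=0.05, c_P=0.1)
        traj = iterate_to_equilibrium(params, 0.2, 0.2, 5_000)
        assert classify_deterministic(traj, 1_000, 1_000) == "degenerate"

    def test_arms_race_fraction_increases_with_infection_cost(self):
        """Fraction of arms-race histories rises between s = 0.3 and 0.85."""
        config = PopulationConfig(N_H=10_000, N_P=10_000)
        fractions = []
        for i, s in enumerate((0.3, 0.85)):
            params = GFGParams(s=s, c_H=0.05, c_P=0.1)
            rng = np.random.default_rng(1000 + i)
            n_ar = 0
            for _ in range(200):
                host, para = simulate_frequency_path(
                    params, config, SimulationSettings(), rng
                )
                label = classify_dynamics(host.counts, para.counts, 10_000, 10_000)
                n_ar += label == "arms_race"
            fractions.append(n_ar / 200)
        assert fractions[1] > fractions[0]
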