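import numpy as np
import pytest

import synaptrans as st
from synaptrans.regimes import (
    ClassifierSettings,
    PoincareSection,
    Regime,
    attractor_census,
    classify_regime,
    classify_setting,
    poincare_crossings,
    sensitivity_divergence,
)

from conftest import manufactured_trajectory


class TestPoincareCrossings:
    def test_sine_crossings_at_analytic_instants(self):
        traj = manufactured_trajectory(lambda t: 2 + np.sin(t), np.cos,
                                       t_end=50.0, h=0.01)
        cr = poincare_crossings(traj, PoincareSection("x", 2.0, "increasing"))
        expected = 2 * np.pi * np.arange(1, len(cr) + 1)
        assert len(cr) >= 7
        # refinement on the dense output beats the O(h^2) requirement
        assert np.max(np.abs(cr.times - expected)) < (0.01) ** 2

    def test_direction_filters(self):
        traj = manufactured_trajectory(lambda t: 2 + np.sin(t), np.cos,
                                       t_end=50.0, h=0.01)
        both = poincare_crossings(traj, PoincareSection("x", 2.0, "both"))
        up = poincare_crossings(traj, PoincareSection("x", 2.0, "increasing"))
        dn = poincare_crossings(traj, PoincareSection("x", 2.0, "decreasing"))
        assert len(both) == len(up) + len(dn)

    def test_unreached_plane_gives_empty_set(self):
        traj = manufactured_trajectory(lambda t: 1 + 0.1 * np.sin(t),
                                       lambda t: 0.1 * np.cos(t))
        cr = poincare_crossings(traj, PoincareSection("x", 2.0, "both"))
        assert len(cr) == 0

    def test_transient_cutoff_respected(self):
        traj = manufactured_trajectory(lambda t: 2 + np.sin(t), np.cos,
                                       t_end=50.0, h=0.01)
        cr = poincare_crossings(traj, PoincareSection("x", 2.0, "both"),
                                t_transient=25.0)
        assert np.all(cr.times >= 25.0)

    def test_crossing_error_shrinks_quadratically_without_derivatives(self):
        """With finite-difference Hermite data the refinement error is
        O(h^2), checked by halving h on the manufactured trajectory."""
        errs = []
        for h in (0.04, 0.02):
            t = np.arange(0.0, 30.0 + h / 2, h)
            states = np.zeros((t.size, 3))
            states[:, 0] = 2 + np.sin(t)
            traj = st.Trajectory(t=t, states=states)  # derivs via gradient
            cr = poincare_crossings(traj, PoincareSection("x", 2.0, "increasing"))
            expected = 2 * np.pi * np.arange(1, len(cr) + 1)
            errs.append(np.max(np.abs(cr.times - expected)))
        assert errs[1] < errs[0] / 2.5


class TestClassifyRegime:
    def test_constant_positive_trajectory_is_stationary(self):
        traj = manufactured_trajectory(lambda t: 1.7 + 0 * t, lambda t: 0 * t)
        label = classify_regime(traj, None)
        assert label.category is Regime.STATIONARY

    def test_decayed_trajectory_is_zero(self):
        traj = manufactured_trajectory(lambda t: np.exp(-t), lambda t: -np.exp(-t))
        label = classify_regime(traj, None)
        assert label.category is Regime.ZERO
        assert label.diagnostics["final_norm"] < 1e-6

    def test_clean_oscillation_is_period_one(self):
        traj = manufactured_trajectory(lambda t: 2 + np.sin(t), np.cos,
                                       t_end=800.0, h=0.01)
        cr = poincare_crossings(traj, PoincareSection("x", 2.0, "increasing"),
                                t_transient=100.0)
        label = classify_regime(traj, cr)
        assert label.category is Regime.PERIODIC
        assert label.multiplicity == 1

    def test_two_frequency_oscillation_needs_sensitivity_data(self):
        """An incommensurate two-frequency signal fills its crossing set
        densely; without twin data the verdict must stay UNRESOLVED, with
        twin data reporting insensitivity it becomes QUASIPERIODIC."""
        t = np.arange(0.0, 2000.0 + 0.005, 0.01)
        states = np.zeros((t.size, 3))
        derivs = np.zeros_like(states)
        states[:, 0] = 2 + np.sin(t) + 0.3 * np.sin(np.sqrt(2) * t)
        derivs[:, 0] = np.cos(t) + 0.3 * np.sqrt(2) * np.cos(np.sqrt(2) * t)
        states[:, 1] = 0.5 + 0.3 * np.sin(np.sqrt(2) * t)  # drifting ordinate
        derivs[:, 1] = 0.3 * np.sqrt(2) * np.cos(np.sqrt(2) * t)
        traj = st.Trajectory(t=t, states=states, derivs=derivs, h=0.01)
        cr = poincare_crossings(traj, PoincareSection("x", 2.0, "increasing"),
                                t_transient=200.0)
        label = classify_regime(traj, cr)
        assert label.category is Regime.UNRESOLVED
        div = sensitivity_divergence((traj, traj), t_transient=200.0)
        label2 = classify_regime(traj, cr, div)
        assert label2.category is Regime.QUASIPERIODIC

    def test_zero_resting_state_from_standard_history(self):
        """Maximum set with K_a = 3 and no recycling: all pools vanish."""
        p = st.basic_parameters(h_x=3, h_b=20, k_x=40, k_b=200,
                                K_a=3).with_recycling(0.0)
        d = st.basic_delays(tau_a=1, tau_b=2, tau_r=3, tau_e=3)
        label, traj, _ = classify_setting(
            p, d, int_settings=st.IntegrationSettings(h=0.01, t_end=1000))
        assert label.category is Regime.ZERO
        # agreement with the fixed-point solver: the origin is the resting state
        eqs = st.find_equilibria(p)
        origin = min(eqs, key=lambda e: e.state.x)
        assert np.allclose(origin.state, (0, 0, 0), atol=1e-12)
        assert np.max(np.abs(traj.states[-1])) < 1e-6

    def test_periodic_label_timing_consistency(self, basic_p):
        """Multiplicity x median crossing spacing reproduces the full
        cycle return time within 1%."""
        p = basic_p.with_recycling(1.0)
        d = st.basic_delays(tau_a=1, tau_b=2, tau_r=3, tau_e=5)
        label, traj, cr = classify_setting(p, d)
        assert label.category is Regime.PERIODIC
        m = label.multiplicity
        dt = np.diff(cr.times)
        full_period = m * np.median(dt)
        # time between returns to the same cluster
        returns = cr.times[m:] - cr.times[:-m]
        assert np.median(returns) == pytest.approx(full_period, rel=0.01)


class TestSensitivity:
    def test_identical_twins_not_sensitive(self):
        traj = manufactured_trajectory(lambda t: 2 + np.sin(t), np.cos)
        div = sensitivity_divergence((traj, traj))
        assert not div.sensitive
        assert np.all(div.diff == 0)

    def test_linear_decay_twins_not_sensitive(self, decay_system, basic_d):
        hist = st.make_history(1.0, 0.0, 0.0, basic_d.horizon)
        pair = st.integrate_twin(decay_system, basic_d, hist,
                                 st.IntegrationSettings(h=0.01, t_end=20),
                                 epsilon=1e-6)
        div = sensitivity_divergence(pair)
        assert not div.sensitive

    def test_chaotic_reference_setting_is_sensitive(self, basic_p, short_delays):
        """k_rz = 0.25, tau_e = 5: a 1e-6 history perturbation grows to
        the oscillation amplitude scale."""
        pair = st.integrate_twin(basic_p.with_recycling(0.25), short_delays,
                                 epsilon=1e-6)
        div = sensitivity_divergence(pair)
        assert div.sensitive
        assert div.max_divergence > 0.1 * div.amplitude

    def test_mismatched_grids_rejected(self, decay_system, basic_d):
        t1 = st.integrate_dde(decay_system, basic_d,
                              st.make_history(1, 0, 0, basic_d.horizon),
                              st.IntegrationSettings(h=0.01, t_end=10))
        t2 = st.integrate_dde(decay_system, basic_d,
                              st.make_history(1, 0, 0, basic_d.horizon),
                              st.IntegrationSettings(h=0.02, t_end=10))
        with pytest.raises(ValueError):
            sensitivity_divergence((t1, t2))


class TestCensus:
    def test_global_attractor_gives_single_signature(self, decay_system):
        d = st.basic_delays(tau_a=1, tau_b=1, tau_r=2, tau_e=2)
        entries = attractor_census(
            decay_system, d, n_starts=8, seed=0,
            int_settings=st.IntegrationSettings(h=0.01, t_end=100))
        assert len(entries) == 1
        assert entries[0].signature.category is Regime.ZERO
        assert entries[0].n_members >= 8

    @pytest.mark.parametrize(
        "setting,expected_n",
        [
            ("decay", 1),        # global zero attractor
            ("one-cycle", 1),    # full recycling, tau_e = 5
            ("two-cycles", 2),   # K_a = 3, h_b = 20, full recycling
        ],
    )
    def test_census_seed_invariance(self, setting, expected_n):
        """Counts and fingerprints agree across RNG seeds at 20 starts."""
        if setting == "decay":
            p = st.basic_parameters(k_x=0.0, k_x0=0.0, k_rz=0.0)
            d = st.basic_delays(tau_a=1, tau_b=1, tau_r=2, tau_e=2)
            s = st.IntegrationSettings(h=0.01, t_end=200.0)
        elif setting == "one-cycle":
            p = st.basic_parameters().with_recycling(1.0)
            d = st.basic_delays(tau_a=1, tau_b=2, tau_r=3, tau_e=5)
            s = None
        else:
            p = st.basic_parameters(h_x=3, h_b=20, k_x=40, k_b=200,
                                    K_a=3).with_recycling(1.0)
            d = st.basic_delays(tau_a=1, tau_b=2, tau_r=3, tau_e=3)
            s = None
        results = []
        for seed in (0, 12345):
            entries = attractor_census(p, d, n_starts=20, seed=seed,
                                       int_settings=s)
            results.append([(e.signature.category, e.signature.multiplicity,
                             round(e.signature.mean_level, 2))
                            for e in entries])
        assert results[0] == results[1]
        assert len(results[0]) == expected_n
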