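import numpy as np
import pytest
from scipy.integrate import solve_ivp

import synaptrans as st
from synaptrans.model import model_rhs
from synaptrans.parameters import ParameterDomainError


class TestHistory:
    def test_constant_history_evaluates_exactly(self):
        hist = st.make_history(2.5, 0.5, 5.0, 15.0)
        for t in (-15.0, -7.3, 0.0):
            assert hist(t) == st.State(2.5, 0.5, 5.0)

    def test_history_domain_contract(self):
        hist = st.make_history(0.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            hist(-1.5)
        with pytest.raises(ValueError):
            hist(0.5)

    def test_negative_history_rejected(self):
        with pytest.raises(ParameterDomainError):
            st.make_history(-1.0, 0.0, 0.0, 1.0)

    def test_perturbed_shifts_requested_component_only(self):
        hist = st.STANDARD_HISTORY(5.0).perturbed(1e-6)
        assert hist.x == 2.5 + 1e-6 and hist.y == 0.5 and hist.z == 5.0

    def test_segment_history_matches_source_trajectory(self, decay_system, basic_d):
        traj = st.integrate_dde(decay_system, basic_d,
                                st.make_history(1.0, 0.5, 0.3, basic_d.horizon),
                                st.IntegrationSettings(h=0.01, t_end=40))
        seg = traj.tail_history(basic_d.horizon)
        assert seg.horizon == pytest.approx(basic_d.horizon)
        # t=0 of the segment is the end of the source trajectory
        assert np.allclose(seg(0.0), traj.states[-1])
        assert np.allclose(seg(-basic_d.horizon),
                           traj(traj.t_end - basic_d.horizon), atol=1e-12)


class TestIntegration:
    def test_closed_form_exponential_decay(self, decay_system, basic_d):
        # no synthesis, no recycling: dx/dt = -(k_rx + k_dx) x = -x
        hist = st.make_history(1.0, 0.0, 0.0, basic_d.horizon)
        traj = st.integrate_dde(decay_system, basic_d, hist,
                                st.IntegrationSettings(h=0.01, t_end=5.0))
        assert traj.x[-1] == pytest.approx(np.exp(-5.0), rel=1e-8)

    def test_deterministic_reproducibility(self, basic_p, short_delays, fast_settings):
        t1 = st.integrate_dde(basic_p, short_delays, s=fast_settings)
        t2 = st.integrate_dde(basic_p, short_delays, s=fast_settings)
        assert np.array_equal(t1.states, t2.states)

    def test_step_exceeding_min_delay_rejected(self, basic_p):
        d = st.basic_delays(tau_a=0.005, tau_b=2, tau_r=3, tau_e=5)
        with pytest.raises(ParameterDomainError, match="smallest positive delay"):
            st.integrate_dde(basic_p, d, s=st.IntegrationSettings(h=0.01, t_end=1))

    def test_nonnegativity_and_capacity_bound_along_trajectory(
            self, basic_p, short_delays):
        traj = st.integrate_dde(basic_p.with_recycling(0.25), short_delays,
                                s=st.IntegrationSettings(h=0.01, t_end=200))
        assert np.all(traj.states >= 0)
        assert np.all(traj.y <= basic_p.y0 + 1e-9)

    def test_delay_zero_matches_independent_ode_oracle(self):
        """With all delays zero the system is a plain ODE; compare against
        scipy's adaptive RK45 at tight tolerance, 10 random draws."""
        rng = np.random.default_rng(42)
        d0 = st.DelayParameters(0.0, 0.0, 0.0, 0.0)
        for _ in range(10):
            p = st.basic_parameters(
                k_x=float(rng.uniform(1, 10)),
                k_b=float(rng.uniform(5, 50)),
                h_b=float(rng.integers(1, 6)),
                h_x=float(rng.integers(1, 4)),
                K_a=float(rng.uniform(0.5, 2.0)),
            ).with_recycling(float(rng.uniform(0, 1)))
            hist = st.make_history(*rng.uniform(0.1, 2.0, size=2),
                                   rng.uniform(0.1, 2.0), 0.0)

            def f(t, v):
                return model_rhs(st.State(*np.maximum(v, 0.0)),
                                 max(v[0], 0), max(v[0], 0),
                                 max(v[1], 0), max(v[2], 0), p)

            ref = solve_ivp(f, (0, 100), [hist.x, hist.y, hist.z],
                            rtol=1e-11, atol=1e-12, dense_output=True)
            traj = st.integrate_dde(p, d0, hist,
                                    st.IntegrationSettings(h=0.005, t_end=100))
            ours = traj.states[-1]
            theirs = ref.sol(100.0)
            rel = np.max(np.abs(ours - theirs) / (1.0 + np.abs(theirs)))
            assert rel < 1e-6

    def test_step_halving_fourth_order_convergence(self, basic_p, short_delays):
        """Successive step halvings shrink the solution difference at the
        rate of a fourth-order scheme over a smooth window."""
        # h = 0.02 is outside the linear stability region of the fast
        # FMRP phosphorylation mode (k_b + k_b0 ~ 201/min), so halve from
        # the default step downward
        p = basic_p.with_recycling(0.25)
        sols = {}
        for h in (0.01, 0.005, 0.0025):
            traj = st.integrate_dde(p, short_delays, s=st.IntegrationSettings(
                h=h, t_end=50.0))
            sols[h] = traj.states[-1]
        d1 = np.max(np.abs(sols[0.01] - sols[0.005]))
        d2 = np.max(np.abs(sols[0.005] - sols[0.0025]))
        order = np.log2(d1 / d2)
        assert order > 3.5

    def test_z_record_does_not_feed_back_without_recycling(self, basic_p, short_delays):
        """k_rz = 0 decouples (x, y) from z: changing the z history leaves
        x and y bitwise unchanged."""
        p = basic_p.replace(k_rz=0.0)
        s = st.IntegrationSettings(h=0.01, t_end=100)
        t1 = st.integrate_dde(p, short_delays,
                              st.make_history(2.5, 0.5, 5.0, short_delays.horizon), s)
        t2 = st.integrate_dde(p, short_delays,
                              st.make_history(2.5, 0.5, 0.123, short_delays.horizon), s)
        assert np.array_equal(t1.states[:, :2], t2.states[:, :2])
        assert not np.array_equal(t1.z, t2.z)


class TestDenseEval:
    def test_nodes_reproduced_exactly(self, decay_system, basic_d):
        traj = st.integrate_dde(decay_system, basic_d,
                                st.make_history(1.0, 0.2, 0.1, basic_d.horizon),
                                st.IntegrationSettings(h=0.01, t_end=2.0))
        for i in (0, 57, traj.t.size - 1):
            assert st.dense_eval(traj, traj.t[i]) == st.State(*traj.states[i])

    def test_midpoint_matches_closed_form(self, decay_system, basic_d):
        traj = st.integrate_dde(decay_system, basic_d,
                                st.make_history(1.0, 0.0, 0.0, basic_d.horizon),
                                st.IntegrationSettings(h=0.01, t_end=2.0))
        tq = 1.005  # between nodes
        assert st.dense_eval(traj, tq).x == pytest.approx(np.exp(-tq), rel=1e-9)

    def test_out_of_range_rejected(self, decay_system, basic_d, fast_settings):
        traj = st.integrate_dde(decay_system, basic_d, s=fast_settings)
        with pytest.raises(ValueError):
            st.dense_eval(traj, traj.t_end + 1.0)


class TestTwin:
    def test_zero_epsilon_twins_identical(self, basic_p, short_delays, fast_settings):
        t1, t2 = st.integrate_twin(basic_p, short_delays, s=fast_settings,
                                   epsilon=0.0)
        assert np.array_equal(t1.states, t2.states)

    def test_linear_decay_contracts_difference(self, decay_system, basic_d):
        # dx/dt = -x is linear: the twin gap is epsilon * exp(-t), monotone down
        hist = st.make_history(1.0, 0.0, 0.0, basic_d.horizon)
        t1, t2 = st.integrate_twin(decay_system, basic_d, hist,
                                   st.IntegrationSettings(h=0.01, t_end=10),
                                   epsilon=1e-6)
        gap = np.abs(t1.x - t2.x)
        assert gap[0] == pytest.approx(1e-6)
        assert np.all(np.diff(gap) <= 1e-18)
        assert gap[-1] == pytest.approx(1e-6 * np.exp(-10), rel=1e-6)


class TestTrajectoryIO:
    def test_tsv_roundtrip(self, decay_system, basic_d, fast_settings, tmp_path):
        traj = st.integrate_dde(decay_system, basic_d,
                                st.make_history(1.0, 0.5, 2.0, basic_d.horizon),
                                fast_settings)
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        back = st.Trajectory.from_tsv(path)
        assert np.array_equal(back.t, traj.t)
        assert np.array_equal(back.states, traj.states)
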