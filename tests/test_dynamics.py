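"""Physics invariants of the two-segment body model.

Every test here is parameter-independent: it checks a conservation law,
a closed form, or a limit that must hold for any valid body, so the
stand-in default parameters never enter as expected values.
"""

import numpy as np
import pytest

from mothprune.dynamics import (
    BodyParams,
    Controls,
    SolverOptions,
    State,
    com_state,
    mechanical_energy,
    simulate_segment,
    state_derivative,
)

from conftest import random_body_params, random_controls, random_state


def com_acceleration(state: State, controls: Controls, params: BodyParams):
    """COM acceleration reconstructed from the generalized accelerations."""
    d = state_derivative(state, controls, params)
    xdd, ydd, thdd, phdd = d[4:]
    a1, a2 = params.L1 / 2, params.L2 / 2
    th, ph = state.theta, state.phi
    thd, phd = state.thetadot, state.phidot
    ax1 = xdd - a1 * (np.sin(th) * thdd + np.cos(th) * thd ** 2)
    ay1 = ydd + a1 * (np.cos(th) * thdd - np.sin(th) * thd ** 2)
    ax2 = xdd + a2 * (np.sin(ph) * phdd + np.cos(ph) * phd ** 2)
    ay2 = ydd - a2 * (np.cos(ph) * phdd - np.sin(ph) * phd ** 2)
    mt = params.total_mass
    return np.array([(params.m1 * ax1 + params.m2 * ax2) / mt,
                     (params.m1 * ay1 + params.m2 * ay2) / mt])


def external_force(state: State, controls: Controls, params: BodyParams):
    """Independent total-force oracle: applied force + gravity + drag."""
    from mothprune.dynamics import _drag_force, _segment_velocities

    q = (state.x, state.y, state.theta, state.phi)
    qd = (state.xdot, state.ydot, state.thetadot, state.phidot)
    v1, v2 = _segment_velocities(q, qd, params)
    f = np.array([controls.F * np.cos(state.theta + controls.alpha),
                  controls.F * np.sin(state.theta + controls.alpha)])
    f += np.array([0.0, -params.total_mass * params.g])
    f += _drag_force(np.asarray(v1), params.cd1, params.drag_law)
    f += _drag_force(np.asarray(v2), params.cd2, params.drag_law)
    return f


class TestStateDerivative:
    def test_rest_point_is_equilibrium(self):
        p = BodyParams(g=0.0, cd1=0.0, cd2=0.0, beta0=0.3)
        s = State(theta=0.2, phi=0.5)  # phi - theta == beta0
        assert np.allclose(state_derivative(s, Controls(), p), 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_free_fall_com_acceleration(self, seed):
        """F=0, no drag: the COM accelerates at exactly (0, -g), whatever
        the internal spring/damper/torque state."""
        rng = np.random.default_rng(seed)
        p = random_body_params(rng, cd1=0.0, cd2=0.0)
        s = random_state(rng)
        u = Controls(F=0.0, alpha=0.0, tau=rng.uniform(-1e-3, 1e-3))
        acc = com_acceleration(s, u, p)
        assert np.allclose(acc, [0.0, -p.g], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_com_force_law(self, seed):
        """Newton's second law for the system, against the independent
        total-force oracle (applied + gravity + drag)."""
        rng = np.random.default_rng(100 + seed)
        p = random_body_params(rng)
        s = random_state(rng)
        u = random_controls(rng)
        acc = com_acceleration(s, u, p)
        expect = external_force(s, u, p) / p.total_mass
        assert np.allclose(acc, expect, rtol=1e-9, atol=1e-12)

    def test_rejects_nonfinite_state(self):
        with pytest.raises(ValueError):
            State(x=np.nan)
        with pytest.raises(ValueError):
            Controls(F=-0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BodyParams(m1=0.0)
        with pytest.raises(ValueError):
            BodyParams(rF=1.0)  # > L1
        with pytest.raises(ValueError):
            BodyParams(K=-1.0)


class TestSimulateSegment:
    def test_final_time_is_duration(self, body_params):
        traj = simulate_segment(State(theta=1.0, phi=1.0),
                                Controls(F=0.02), body_params, duration=0.02)
        assert traj.times[-1] == 0.02
        assert traj.times[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 7])
    def test_ballistic_com_closed_form(self, seed):
        """No force, drag, spring or damper: the COM follows projectile
        motion exactly."""
        rng = np.random.default_rng(seed)
        p = random_body_params(rng, K=0.0, C=0.0, cd1=0.0, cd2=0.0)
        s0 = random_state(rng)
        traj = simulate_segment(s0, Controls(), p, duration=0.02)
        r0, v0 = com_state(s0, p)
        for i, t in enumerate(traj.times):
            r, v = com_state(traj.state_at(i), p)
            expect_r = r0 + v0 * t + 0.5 * np.array([0, -p.g]) * t ** 2
            expect_v = v0 + np.array([0, -p.g]) * t
            assert np.allclose(r, expect_r, atol=1e-9)
            assert np.allclose(v, expect_v, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_momentum_theorem_along_trajectory(self, seed):
        """d/dt of total linear momentum equals the external force at every
        sampled time; internal spring/damper/tau torques cancel."""
        rng = np.random.default_rng(200 + seed)
        p = random_body_params(rng)
        s0 = random_state(rng)
        u = random_controls(rng)
        traj = simulate_segment(s0, u, p, duration=0.02)
        for i in range(traj.times.size):
            s = traj.state_at(i)
            acc = com_acceleration(s, u, p)
            f = external_force(s, u, p)
            assert np.allclose(p.total_mass * acc, f, rtol=1e-9, atol=1e-12)

    def test_energy_conserved_in_conservative_limit(self):
        rng = np.random.default_rng(5)
        p = random_body_params(rng, C=0.0, cd1=0.0, cd2=0.0)
        s0 = random_state(rng)
        traj = simulate_segment(s0, Controls(), p, duration=0.02)
        e = [mechanical_energy(traj.state_at(i), p)
             for i in range(traj.times.size)]
        scale = max(abs(np.asarray(e)).max(), 1e-12)
        assert np.max(np.abs(np.diff(e))) < 1e-6 * scale

    def test_energy_dissipates_with_damping_and_drag(self):
        rng = np.random.default_rng(6)
        p = random_body_params(rng, C=2e-5, cd1=5e-3, cd2=5e-3, g=0.0)
        s0 = random_state(rng)
        traj = simulate_segment(s0, Controls(), p, duration=0.02)
        e = np.array([mechanical_energy(traj.state_at(i), p)
                      for i in range(traj.times.size)])
        assert np.all(np.diff(e) <= 1e-12)

    def test_quadratic_drag_also_dissipates(self):
        rng = np.random.default_rng(8)
        p = random_body_params(rng, C=0.0, g=0.0, drag_law="quadratic",
                               cd1=1e-2, cd2=1e-2)
        s0 = random_state(rng)
        traj = simulate_segment(s0, Controls(), p, duration=0.02)
        e = np.array([mechanical_energy(traj.state_at(i), p)
                      for i in range(traj.times.size)])
        assert e[-1] <= e[0] + 1e-12

    def test_tolerance_refinement_converges(self, body_params):
        s0 = State(theta=1.2, phi=1.0, xdot=0.3, thetadot=5.0)
        u = Controls(F=0.03, alpha=0.2, tau=5e-4)
        loose = simulate_segment(s0, u, body_params,
                                 options=SolverOptions(rtol=1e-6, atol=1e-8))
        tight = simulate_segment(s0, u, body_params,
                                 options=SolverOptions(rtol=1e-9, atol=1e-11))
        assert np.max(np.abs(loose.states[-1] - tight.states[-1])) < 1e-5

    def test_report_grid_refinement(self, body_params):
        """Halving the output step leaves the final state unchanged."""
        s0 = State(theta=1.2, phi=1.0, ydot=-0.2)
        u = Controls(F=0.02, alpha=-0.1)
        coarse = simulate_segment(s0, u, body_params,
                                  options=SolverOptions(report_dt=2e-3))
        fine = simulate_segment(s0, u, body_params,
                                options=SolverOptions(report_dt=1e-3))
        assert np.allclose(coarse.states[-1], fine.states[-1], atol=1e-9)

    def test_rejects_nonpositive_duration(self, body_params):
        with pytest.raises(ValueError):
            simulate_segment(State(), Controls(), body_params, duration=0.0)


class TestEnergyAndCom:
    def test_zero_energy_at_rest_reference(self):
        p = BodyParams(beta0=0.0)
        # place both centroids at height 0: theta=phi=0 keeps them at y=0
        s = State(theta=0.0, phi=0.0)
        assert mechanical_energy(s, p) == pytest.approx(0.0, abs=1e-15)

    def test_kinetic_energy_is_quadratic(self):
        rng = np.random.default_rng(9)
        p = random_body_params(rng, g=0.0, K=0.0)
        s = random_state(rng)
        doubled = State(s.x, s.y, s.theta, s.phi, 2 * s.xdot, 2 * s.ydot,
                        2 * s.thetadot, 2 * s.phidot)
        assert mechanical_energy(doubled, p) == pytest.approx(
            4 * mechanical_energy(s, p), rel=1e-12)

    def test_com_at_joint_by_symmetry(self):
        p = BodyParams(m1=1e-3, m2=1e-3, L1=2e-2, L2=2e-2)
        pos, _ = com_state(State(x=0.3, y=-0.2, theta=0.0, phi=0.0), p)
        assert pos == pytest.approx([0.3, -0.2])

    def test_com_tends_to_heavy_segment(self):
        p = BodyParams(m1=1e-3, m2=1e-9)
        s = State(theta=0.5, phi=1.5)
        pos, _ = com_state(s, p)
        head = np.array([s.x + p.L1 / 2 * np.cos(s.theta),
                         s.y + p.L1 / 2 * np.sin(s.theta)])
        assert np.allclose(pos, head, atol=1e-5)

    def test_com_velocity_matches_position_derivative(self, body_params):
        s0 = State(theta=1.0, phi=0.8, xdot=0.2, ydot=-0.1, thetadot=3.0)
        u = Controls(F=0.025, alpha=0.3, tau=3e-4)
        traj = simulate_segment(s0, u, body_params,
                                options=SolverOptions(report_dt=1e-4))
        pos = np.array([com_state(traj.state_at(i), body_params)[0]
                        for i in range(traj.times.size)])
        vel = np.array([com_state(traj.state_at(i), body_params)[1]
                        for i in range(traj.times.size)])
        fd = np.gradient(pos, traj.times, axis=0)
        # central differences on the interior points
        assert np.allclose(fd[1:-1], vel[1:-1], rtol=1e-3, atol=1e-5)


def test_trajectory_validation():
    from mothprune.dynamics import Trajectory

    with pytest.raises(ValueError):
        Trajectory(times=[0.0, 0.0], states=np.zeros((2, 8)))
    with pytest.raises(ValueError):
        Trajectory(times=[0.1, 0.2], states=np.zeros((2, 8)))
    with pytest.raises(ValueError):
        Trajectory(times=[0.0, 0.1], states=np.zeros((3, 8)))
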