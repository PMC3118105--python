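"""Unit and property tests for the Hill-type muscle primitives."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from dystonia_reflex.muscle import (ECCENTRIC_PLATEAU, SE_STRAIN_REF,
                                    JointParams, JointState, MuscleParams,
                                    MuscleState, activation_rate,
                                    force_length, force_velocity,
                                    invert_force_velocity, joint_acceleration,
                                    muscle_force, series_force)


@pytest.fixture(scope="module")
def mp():
    return MuscleParams(f_max=100.0, l_ce_opt=0.05, l_se_slack=0.17,
                        k_se_shape=1.5, w_fl=0.4, v_max=10.0, a_hill=0.25,
                        tau_act=0.04, tau_deact=0.06, r=0.015, sign=+1)


class TestActivation:
    def test_fixed_point(self, mp):
        assert activation_rate(0.5, 0.5, mp) == 0.0

    def test_step_rate(self, mp):
        assert activation_rate(1.0, 0.0, mp) == pytest.approx(25.0)

    def test_excitation_domain(self, mp):
        with pytest.raises(ValueError):
            activation_rate(1.2, 0.5, mp)
        with pytest.raises(ValueError):
            activation_rate(-0.1, 0.5, mp)

    def test_step_response_matches_closed_form(self, mp):
        # first-order step response: a(t) = 1 - exp(-t / tau_act)
        dt = 1e-5
        a = 0.0
        for _ in range(round(mp.tau_act / dt)):
            k1 = activation_rate(1.0, a, mp)
            k2 = activation_rate(1.0, a + 0.5 * dt * k1, mp)
            k3 = activation_rate(1.0, a + 0.5 * dt * k2, mp)
            k4 = activation_rate(1.0, a + dt * k3, mp)
            a += dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        assert a == pytest.approx(1.0 - math.exp(-1.0), abs=1e-6)

    def test_deactivation_slower_than_activation(self, mp):
        assert abs(activation_rate(0.0, 0.5, mp)) < abs(
            activation_rate(1.0, 0.5, mp))


class TestForceLength:
    def test_optimum(self, mp):
        assert force_length(mp.l_ce_opt, mp) == 1.0

    @pytest.mark.parametrize("l_rel", [0.01, 3.0])
    def test_tail_decay(self, mp, l_rel):
        assert force_length(l_rel * mp.l_ce_opt, mp) <= 0.05

    def test_symmetry_at_width(self, mp):
        lo = force_length(mp.l_ce_opt * (1 - mp.w_fl), mp)
        hi = force_length(mp.l_ce_opt * (1 + mp.w_fl), mp)
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(math.exp(-1.0))

    @given(st.floats(0.01, 3.0))
    def test_bounded(self, l_rel):
        p = MuscleParams(f_max=100.0, l_ce_opt=0.05, l_se_slack=0.17,
                         k_se_shape=1.5, w_fl=0.4, v_max=10.0, a_hill=0.25,
                         tau_act=0.04, tau_deact=0.06, r=0.015, sign=+1)
        assert 0.0 <= force_length(l_rel * p.l_ce_opt, p) <= 1.0


class TestForceVelocity:
    def test_isometric(self, mp):
        assert force_velocity(0.0, mp) == 1.0

    def test_max_shortening(self, mp):
        assert force_velocity(-mp.v_max * mp.l_ce_opt, mp) == 0.0

    def test_hyperbola_midpoint_symbolic(self, mp):
        # independent symbolic evaluation of (1 + v)/(1 - v/a) at v = -1/2
        v, a = sympy.symbols("v a")
        expected = sympy.Rational(
            ((1 + v) / (1 - v / a)).subs({v: sympy.Rational(-1, 2),
                                          a: sympy.Rational(1, 4)}))
        got = force_velocity(-0.5 * mp.v_max * mp.l_ce_opt, mp)
        assert got == pytest.approx(float(expected))
        assert expected == sympy.Rational(1, 6)

    def test_monotone_and_plateau(self, mp):
        vs = np.linspace(-1.2, 3.0, 200) * mp.v_max * mp.l_ce_opt
        fv = [force_velocity(v, mp) for v in vs]
        assert all(b >= a for a, b in zip(fv, fv[1:]))
        assert fv[-1] < ECCENTRIC_PLATEAU
        assert force_velocity(1e9, mp) == pytest.approx(ECCENTRIC_PLATEAU,
                                                        rel=1e-6)

    @given(st.floats(0.001, ECCENTRIC_PLATEAU - 0.01))
    def test_inverse_roundtrip(self, fv):
        p = MuscleParams(f_max=100.0, l_ce_opt=0.05, l_se_slack=0.17,
                         k_se_shape=1.5, w_fl=0.4, v_max=10.0, a_hill=0.25,
                         tau_act=0.04, tau_deact=0.06, r=0.015, sign=+1)
        vn = invert_force_velocity(fv, p)
        if abs(vn) < 1.0:  # inside the invertible branch, not at a cap
            assert force_velocity(vn * p.v_max * p.l_ce_opt,
                                  p) == pytest.approx(fv, rel=1e-9)


class TestMuscleForce:
    def test_slack_tendon_zero_force(self, mp):
        state = MuscleState(a=0.0, l_ce=mp.l_ce_opt)
        f, _ = muscle_force(state, mp, mp.l_ce_opt + 0.9 * mp.l_se_slack)
        assert f == 0.0

    def test_isometric_settles_to_f_max(self, mp):
        # hold the musculotendon at the length whose equilibrium is l_ce_opt
        l_mt = mp.l_ce_opt + mp.l_se_slack * (1.0 + SE_STRAIN_REF)
        l_ce, dt = 0.9 * mp.l_ce_opt, 1e-4
        for _ in range(30000):
            _, v = muscle_force(MuscleState(a=1.0, l_ce=l_ce), mp, l_mt)
            l_ce += dt * v
        f, v = muscle_force(MuscleState(a=1.0, l_ce=l_ce), mp, l_mt)
        assert abs(v) < 1e-4
        assert f == pytest.approx(mp.f_max, rel=0.005)
        # static-equilibrium oracle: F_se(l_mt - l) = f_max * f_l(l)
        root = brentq(lambda l: series_force(l_mt - l, mp)
                      - mp.f_max * force_length(l, mp),
                      0.5 * mp.l_ce_opt, l_mt - mp.l_se_slack)
        assert l_ce == pytest.approx(root, rel=1e-3)

    def test_force_nonnegative_random_states(self, mp):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            state = MuscleState(a=float(rng.uniform(0, 1)),
                                l_ce=float(rng.uniform(0.5, 1.5) * mp.l_ce_opt))
            l_mt = float(rng.uniform(0.9, 1.1)) * mp.l_mt_neutral
            f, _ = muscle_force(state, mp, l_mt)
            assert f >= 0.0


class TestJoint:
    jp = JointParams(inertia=0.005, b_passive=0.0)

    def test_rest_equilibrium(self):
        js = JointState(theta=0.0, omega=0.0)
        assert joint_acceleration(js, 0.0, 0.0, 0.0, self.jp, 0.02, 0.02) == 0.0

    def test_cocontraction_balance(self):
        js = JointState(theta=0.1, omega=0.0)
        assert joint_acceleration(js, 80.0, 80.0, 0.0, self.jp, 0.02, 0.02) == 0.0

    def test_flexor_torque_arithmetic(self):
        js = JointState(theta=0.0, omega=0.0)
        alpha = joint_acceleration(js, 100.0, 0.0, 0.0, self.jp, 0.02, 0.02)
        assert alpha == pytest.approx(400.0)

    def test_negative_force_rejected(self):
        js = JointState(theta=0.0, omega=0.0)
        with pytest.raises(ValueError):
            joint_acceleration(js, -1.0, 0.0, 0.0, self.jp, 0.02, 0.02)


def _passive_relax(preset, a, theta0=0.1, duration=5.0, dt=1e-4):
    """Integrate the reflex-free pair at constant activation from theta0."""
    from dystonia_reflex.engine import initial_ce_length
    mp_f, mp_e, jp = preset.flexor, preset.extensor, preset.joint
    l_f = initial_ce_length(mp_f, a)
    l_e = initial_ce_length(mp_e, a)
    theta, omega = theta0, 0.0
    trace = []
    for k in range(round(duration / dt)):
        ff, vf = muscle_force(MuscleState(a=a, l_ce=l_f), mp_f,
                              mp_f.l_mt_neutral - mp_f.r * theta)
        fe, ve = muscle_force(MuscleState(a=a, l_ce=l_e), mp_e,
                              mp_e.l_mt_neutral + mp_e.r * theta)
        alpha = joint_acceleration(JointState(theta, omega), ff, fe, 0.0, jp,
                                   mp_f.r, mp_e.r)
        theta += dt * omega
        omega += dt * alpha
        l_f += dt * vf
        l_e += dt * ve
        if k % 1000 == 0:
            trace.append(theta)
    return theta, trace


def test_passive_return_to_neutral(wrist_preset):
    """With reflexes absent, symmetric muscle tone passively re-centres a
    perturbed joint: firm co-contraction converges to neutral, and even at
    faint tone the deviation decays monotonically (no passive runaway)."""
    final, _ = _passive_relax(wrist_preset, a=0.2)
    assert abs(final) < 0.01
    final, trace = _passive_relax(wrist_preset, a=0.02)
    assert abs(final) < 0.1
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_antagonist_length_changes_mirror(wrist_preset):
    """Flexor musculotendon shortens with flexion exactly as much as the
    extensor lengthens (equal moment arms)."""
    mp_f, mp_e = wrist_preset.flexor, wrist_preset.extensor
    for theta in (-0.4, -0.1, 0.2, 0.5):
        d_f = (mp_f.l_mt_neutral - mp_f.r * theta) - mp_f.l_mt_neutral
        d_e = (mp_e.l_mt_neutral + mp_e.r * theta) - mp_e.l_mt_neutral
        assert d_f == pytest.approx(-d_e)
        if theta < 0:
            assert d_f > 0  # extension lengthens the flexor


def test_param_validation():
    with pytest.raises(ValueError):
        MuscleParams(f_max=-1, l_ce_opt=0.05, l_se_slack=0.17, k_se_shape=1.5,
                     w_fl=0.4, v_max=10, a_hill=0.25, tau_act=0.04,
                     tau_deact=0.06, r=0.015, sign=+1)
    with pytest.raises(ValueError):
        MuscleParams(f_max=100, l_ce_opt=0.05, l_se_slack=0.17, k_se_shape=1.5,
                     w_fl=0.4, v_max=10, a_hill=0.25, tau_act=0.1,
                     tau_deact=0.06, r=0.015, sign=+1)
    with pytest.raises(ValueError):
        MuscleState(a=1.2, l_ce=0.05)
    with pytest.raises(ValueError):
        JointParams(inertia=0.0, b_passive=0.1)
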