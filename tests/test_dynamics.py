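"""Force elements and integration accuracy of the planar engine."""

import math

import numpy as np
import pytest

from jumpsim import (
    BoneSection,
    ContactPoint,
    HillParams,
    Joint,
    Model,
    Segment,
    Shape,
    bone_stress,
    constant_activation,
    contact_force,
    force_length,
    force_velocity,
    hill_force,
    joint_limit_torque,
    simulate,
)


# ---------------------------------------------------------------------------
# Hill-type curves
# ---------------------------------------------------------------------------

class TestHillForce:
    P = HillParams(f_max=0.3 * 1000.0, l_opt_mm=100.0, vmax_ls=8.4)

    def test_maximal_isometric_force(self):
        # sigma 0.3 N/mm^2 x 1000 mm^2 at optimum, isometric, full drive
        assert hill_force(self.P, 1.0, 100.0, 0.0) == pytest.approx(300.0)

    def test_zero_force_at_vmax(self):
        assert hill_force(self.P, 1.0, 100.0, 8.4) == 0.0

    def test_hyperbola_at_third_vmax(self):
        # (1 - 1/3) / (1 + (1/3)/0.25) = 2/7
        p = HillParams(f_max=100.0, l_opt_mm=100.0, vmax_ls=9.0, fv_shape=0.25)
        assert hill_force(p, 1.0, 100.0, 3.0) == pytest.approx(100.0 * 2.0 / 7.0)

    def test_endpoints_of_force_velocity(self):
        assert force_velocity(0.0, 8.4) == 1.0
        assert force_velocity(8.4, 8.4) == 0.0
        assert force_velocity(-1.0, 8.4) == 1.0  # eccentric plateau

    def test_force_length_unity_at_optimum_zero_at_width(self):
        assert force_length(100.0, 100.0, 0.5) == 1.0
        assert force_length(150.0, 100.0, 0.5) == 0.0
        assert force_length(50.0, 100.0, 0.5) == 0.0

    def test_activation_bounds_enforced(self):
        with pytest.raises(ValueError):
            hill_force(self.P, 1.5, 100.0, 0.0)

    def test_peak_power_near_third_vmax(self):
        # d/dv [v * f_v(v)] = 0 near 0.31 vmax for the 0.25 hyperbola
        v = np.linspace(0.0, 8.4, 2001)
        power = v * np.array([force_velocity(x, 8.4, 0.25) for x in v])
        v_opt = v[np.argmax(power)]
        assert 0.25 * 8.4 < v_opt < 0.35 * 8.4


class TestJointLimitTorque:
    J = Joint(
        "j", "a", "b", angle_lo=-30.0, angle_hi=60.0,
        soft_limit_stiffness=100.0, soft_limit_damping=5.0,
    )

    def test_zero_inside_range(self):
        assert joint_limit_torque(10.0, 1.0, self.J) == 0.0

    def test_spring_damper_beyond_upper(self):
        expected = -100.0 * math.radians(2.0) - 5.0 * 0.5
        assert joint_limit_torque(62.0, 0.5, self.J) == pytest.approx(expected)

    def test_opposes_further_violation(self):
        # moving further out at either end, the torque points back inward
        assert joint_limit_torque(65.0, 1.0, self.J) < 0
        assert joint_limit_torque(-35.0, -1.0, self.J) > 0


class TestContactForce:
    CP = ContactPoint("foot", (0, 0), stiffness=1.0e5, damping=1.0e3)

    def test_no_force_above_ground(self):
        assert contact_force(0.01, -1.0, 0.5, self.CP) == (0.0, 0.0)

    def test_spring_force_at_rest(self):
        fz, fx = contact_force(-0.001, 0.0, 0.0, self.CP)
        assert fz == pytest.approx(100.0)
        assert fx == 0.0

    def test_no_adhesion_on_pulloff(self):
        # damping pull-off exceeding the spring force clamps to zero
        fz, _ = contact_force(-0.001, 1.0, 0.0, self.CP)
        assert fz == 0.0

    def test_friction_bounded_by_mu_fz(self):
        fz, fx = contact_force(-0.005, 0.0, 10.0, self.CP)
        assert abs(fx) <= self.CP.friction_mu * fz + 1e-12
        assert fx < 0  # opposes the slip


class TestBoneStress:
    SEC = BoneSection(
        "s", "seg", (0, 0), area=math.pi * 0.01**2,
        second_moment=math.pi * 0.01**4 / 4.0, c=0.01,
    )

    def test_axial_only(self):
        assert bone_stress(1000.0, 0.0, self.SEC) == pytest.approx(3.183e6, rel=1e-3)

    def test_bending_only(self):
        assert bone_stress(0.0, 10.0, self.SEC) == pytest.approx(1.2732e7, rel=1e-3)

    def test_zero_loads(self):
        assert bone_stress(0.0, 0.0, self.SEC) == 0.0

    def test_superposition(self):
        both = bone_stress(1000.0, 10.0, self.SEC)
        assert both == pytest.approx(
            bone_stress(1000.0, 0.0, self.SEC) + bone_stress(0.0, 10.0, self.SEC)
        )


# ---------------------------------------------------------------------------
# integration accuracy
# ---------------------------------------------------------------------------

def _point_mass_model():
    return Model(
        taxon="pm",
        body_mass=3.1416,
        segments=[Segment("ball", Shape("cylinder", 0.4, radius=0.05), 1000.0)],
    )


def _pendulum_model(theta0=3.0):
    base = Segment("base", Shape("cylinder", 0.1, radius=0.05), 1000.0)
    rod = Segment("rod", Shape("cylinder", 0.5, radius=0.01), 1000.0)
    return Model(
        taxon="pend",
        body_mass=base.mass + rod.mass,
        segments=[base, rod],
        joints=[
            Joint(
                "pivot", "base", "rod", angle_lo=-180.0, angle_hi=180.0,
                soft_limit_stiffness=0.0, soft_limit_damping=0.0,
                reference_angle_deg=-90.0,
            )
        ],
        starting_pose={"pivot": theta0},
        base_fixed=True,
    )


def _double_pendulum_model():
    base = Segment("base", Shape("cylinder", 0.1, radius=0.05), 1000.0)
    l1 = Segment("l1", Shape("cylinder", 0.4, radius=0.02), 1000.0)
    l2 = Segment("l2", Shape("cylinder", 0.3, radius=0.015), 1000.0)
    return Model(
        taxon="dpend",
        body_mass=base.mass + l1.mass + l2.mass,
        segments=[base, l1, l2],
        joints=[
            Joint("j1", "base", "l1", angle_lo=-720.0, angle_hi=720.0,
                  soft_limit_stiffness=0.0, soft_limit_damping=0.0,
                  reference_angle_deg=-70.0),
            Joint("j2", "l1", "l2", anchor=(0.4, 0.0), angle_lo=-720.0,
                  angle_hi=720.0, soft_limit_stiffness=0.0,
                  soft_limit_damping=0.0, reference_angle_deg=30.0),
        ],
        starting_pose={"j1": 20.0, "j2": -40.0},
        base_fixed=True,
    )


class TestIntegration:
    def test_equilibrium_without_gravity(self):
        traj = simulate(_point_mass_model(), None, duration=1.0, dt=1e-4, gravity=0.0)
        assert np.allclose(traj.q, traj.q[0], atol=1e-9)

    def test_free_fall_impact_speed(self):
        # released from rest; speed after falling 1 m is sqrt(2 g h)
        traj = simulate(
            _point_mass_model(), None, duration=0.48, dt=1e-4, output_dt=1e-4
        )
        drop = traj.com[0, 1] - traj.com[:, 1]
        i = int(np.argmax(drop >= 1.0))
        v = abs(traj.com_vel[i, 1])
        assert v == pytest.approx(math.sqrt(2 * 9.81), rel=1e-3)

    def test_small_amplitude_pendulum_period(self):
        model = _pendulum_model(theta0=3.0)
        traj = simulate(model, None, duration=4.0, dt=1e-4, output_dt=1e-3)
        ang = traj.q[:, 3]
        a = ang - ang.mean()
        idx = np.where(np.diff(np.sign(a)) > 0)[0]
        period = float(np.mean(np.diff(traj.time[idx])))
        rod = model.segment("rod")
        d = rod.com_offset
        T_exp = 2 * math.pi * math.sqrt((rod.moi / rod.mass + d**2) / (9.81 * d))
        assert period == pytest.approx(T_exp, rel=5e-3)

    def test_conservative_energy_drift(self):
        # double pendulum, no contacts/damping/muscles: drift < 0.1% of the
        # mechanical energy scale over 1 s
        model = _double_pendulum_model()
        traj = simulate(model, None, duration=1.0, dt=1e-4, output_dt=1e-3)
        E = traj.ke + traj.pe
        scale = max(traj.ke.max(), abs(E[0] - traj.pe.min()))
        assert (E.max() - E.min()) / scale < 1e-3

    def test_rk4_conservative_energy_drift_tighter(self):
        model = _double_pendulum_model()
        traj = simulate(
            model, None, duration=1.0, dt=1e-4, output_dt=1e-3, integrator="rk4"
        )
        E = traj.ke + traj.pe
        scale = max(traj.ke.max(), abs(E[0] - traj.pe.min()))
        assert (E.max() - E.min()) / scale < 1e-6


@pytest.fixture(scope="module")
def jump(toy_deep):
    # drive the extensors through the push then relax, so the limbs do
    # not keep whipping (and loading the bones) in flight
    times = np.tile(np.array([0.25, 10.0]), (len(toy_deep.actuators), 1))
    levels = np.array(
        [[0.9, 0.0], [0.9, 0.0], [0.9, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]]
    )
    traj = simulate(
        toy_deep,
        (times, levels),
        duration=0.48,
        dt=2e-5,
        output_dt=2e-5,
        integrator="rk4",
    )
    assert not traj.stress_exceeded and not traj.blown_up
    return traj


class TestJumpInvariants:
    def test_grf_never_negative(self, jump):
        assert (jump.grf >= 0.0).all()

    def test_impulse_momentum_identity(self, jump):
        m = jump_mass = 10.0
        g = 9.81
        net = np.trapezoid(jump.grf - m * g, jump.time) / m
        dv = jump.com_vel[-1, 1] - jump.com_vel[0, 1]
        assert abs(net - dv) < 1e-3

    def test_aerial_apex_matches_ballistic_formula(self, jump):
        grf = jump.grf
        aloft = np.nonzero(grf <= 0.0)[0]
        assert len(aloft) > 10, "the toy should leave the ground"
        i0 = aloft[0]
        z0, v0 = jump.com[i0, 1], jump.com_vel[i0, 1]
        apex_pred = z0 + v0**2 / (2 * 9.81)
        apex_sim = jump.com[i0:, 1].max()
        assert apex_sim == pytest.approx(apex_pred, abs=1e-6)

    def test_work_components_sum_to_actuator_work(self, toy_deep):
        # the work ledger uses the same per-step forces as the default
        # (semi-implicit) stepper, making the identity exact by construction
        times = np.tile(np.array([0.25, 10.0]), (len(toy_deep.actuators), 1))
        levels = np.zeros((len(toy_deep.actuators), 2))
        levels[:3, 0] = 0.9
        traj = simulate(
            toy_deep, (times, levels), duration=0.5, dt=1e-4, output_dt=1e-4
        )
        total = traj.work_ce[-1] + traj.work_se[-1] + traj.work_pe[-1]
        ref = traj.work_mtu[-1]
        scale = max(1.0, np.abs(ref).max())
        assert np.allclose(total, ref, atol=1e-3 * scale)

    def test_takeoff_happens_and_apex_recorded(self, jump):
        assert jump.max_com_height > jump.com[0, 1] + 0.2
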