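"""Force balance, effective range and capture dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.constants import g as G
from scipy.constants import mu_0

import ovomag as om
from ovomag.magnetophoresis import characterize_magnet


class TestParticlesFromCoverage:
    def test_zero_coverage(self):
        assert om.particles_from_coverage(0.0) == 0

    def test_full_coverage_area_ratio_oracle(self):
        """Independent geometry oracle: 4 R_egg^2 / r_particle^2."""
        egg = om.EggBody(150e-6, 1030.0)
        p = om.ESTAPOR_PARTICLE
        oracle = round(4 * (75e-6) ** 2 / (0.1825e-6) ** 2)
        assert om.particles_from_coverage(1.0, egg, p, packing_fraction=1.0) == oracle

    def test_maximum_observed_coverage_scales_oracle(self):
        egg, p = om.EggBody(150e-6, 1030.0), om.ESTAPOR_PARTICLE
        full = 4 * (75e-6) ** 2 / (0.1825e-6) ** 2
        expected = round(0.40 * 0.9069 * full)
        got = om.particles_from_coverage(0.40, egg, p, packing_fraction=0.9069)
        assert got == pytest.approx(expected, abs=1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            om.particles_from_coverage(1.2)
        with pytest.raises(ValueError):
            om.particles_from_coverage(0.5, packing_fraction=0.0)


class TestParticleMoment:
    def test_zero_field(self):
        assert om.particle_moment(om.ESTAPOR_PARTICLE, 0.0) == 0.0

    def test_saturates_exactly(self):
        p = om.ESTAPOR_PARTICLE
        assert om.particle_moment(p, 100.0) == p.saturation_moment

    def test_branch_intersection_oracle(self):
        """B* where linear branch meets saturation: solve the equality
        independently and check continuity there."""
        p = om.ESTAPOR_PARTICLE
        b_star = mu_0 * p.saturation_moment / (p.susceptibility * p.volume)
        assert om.saturation_field(p) == pytest.approx(b_star, rel=1e-12)
        m_lin = p.susceptibility * p.volume * b_star / mu_0
        assert m_lin == pytest.approx(p.saturation_moment, rel=1e-12)
        assert om.particle_moment(p, b_star) == pytest.approx(p.saturation_moment, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(b1=st.floats(0, 0.5), b2=st.floats(0, 0.5))
    def test_non_decreasing(self, b1, b2):
        lo, hi = sorted((b1, b2))
        p = om.ESTAPOR_PARTICLE
        assert om.particle_moment(p, lo) <= om.particle_moment(p, hi)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            om.particle_moment(om.ESTAPOR_PARTICLE, -0.1)


class TestMagneticForce:
    def test_empty_load(self, magnet_small):
        load = om.EggLoad(0, om.ESTAPOR_PARTICLE)
        assert om.magnetic_force(load, magnet_small, 2e-3) == 0.0

    def test_linear_in_particle_number(self, magnet_small):
        p = om.ESTAPOR_PARTICLE
        z = np.linspace(0.1e-3, 20e-3, 50)
        f1 = om.magnetic_force(om.EggLoad(1000, p), magnet_small, z)
        f2 = om.magnetic_force(om.EggLoad(2000, p), magnet_small, z)
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-12)

    def test_linear_branch_compositional_oracle(self, magnet_small):
        """On the linear branch, F = n chi V B |dB/dz| / mu0 composed
        independently from the field module."""
        p = om.ESTAPOR_PARTICLE
        z = 8e-3  # far enough that B << B*
        b = om.axial_field(magnet_small, z)
        assert b < om.saturation_field(p)
        n = 5000
        oracle = n * p.susceptibility * p.volume * b * abs(
            om.axial_gradient(magnet_small, z)
        ) / mu_0
        got = om.magnetic_force(om.EggLoad(n, p), magnet_small, z)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_non_increasing_beyond_contact(self, default_load, magnet_small):
        z = np.linspace(75e-6, 30e-3, 3000)
        f = om.magnetic_force(default_load, magnet_small, z)
        assert np.all(np.diff(f) <= 1e-18)


class TestDragAndWeight:
    def test_stokes_closed_form(self):
        egg = om.EggBody(150e-6, 1030.0)
        med = om.Medium(1e-3, 1005.0)
        assert om.drag_coefficient(egg, med) == pytest.approx(
            3 * math.pi * 1e-3 * 150e-6, rel=1e-12
        )

    def test_viscosity_proportionality(self):
        egg = om.EggBody()
        thin = om.Medium(1e-3, 1005.0)
        thick = om.Medium(1e-2, 1005.0)
        assert om.drag_coefficient(egg, thick) == pytest.approx(
            10 * om.drag_coefficient(egg, thin), rel=1e-12
        )

    def test_terminal_speed_matches_ode_steady_state(self):
        """v = F/gamma under constant force, frictionless, at steady state."""
        egg = om.EggBody()
        med = om.Medium(1e-3, egg.density)  # neutral buoyancy: no friction
        fr = om.FrictionSpec(0.1, 0.1)
        F0 = 2e-9
        res = om.simulate_capture(
            om.EggLoad(1, om.ESTAPOR_PARTICLE), egg, om.MAGNETS["S-02-02"], med, fr,
            z0=1e-3, force_fn=lambda z: F0,
        )
        gamma = om.drag_coefficient(egg, med)
        tau = egg.mass / gamma
        late = res.trajectory.t > 10 * tau
        assert np.abs(res.v[late] / (F0 / gamma) - 1).max() < 1e-3

    def test_net_weight_closed_form_and_signs(self):
        egg = om.EggBody(150e-6, 1030.0)
        med = om.Medium(1e-3, 1005.0)
        expected = 25.0 * math.pi / 6 * (150e-6) ** 3 * G
        assert om.net_weight(egg, med) == pytest.approx(expected, rel=1e-12)
        assert om.net_weight(om.EggBody(150e-6, 1005.0), med) == 0.0
        assert om.net_weight(om.EggBody(150e-6, 990.0), med) < 0.0


class TestEffectiveRange:
    def test_zero_friction_unbounded(self, default_load):
        with pytest.raises(om.UnboundedRangeError):
            om.effective_range(default_load, friction=om.FrictionSpec(0.0, 0.0))

    def test_matches_1um_grid_scan_within_2um(self, default_load, magnet_small):
        z_star = om.effective_range(default_load, magnet=magnet_small)
        egg, med, fr = om.DEFAULT_EGG, om.PBS, om.DEFAULT_FRICTION
        zg = np.arange(egg.radius, 0.05, 1e-6)
        force = om.magnetic_force(default_load, magnet_small, zg)
        grid = zg[np.nonzero(force >= fr.mu_static * om.net_weight(egg, med))[0][-1]]
        assert abs(z_star - grid) < 2e-6

    def test_never_moves_when_threshold_too_high(self, magnet_small):
        tiny = om.EggLoad(1, om.ESTAPOR_PARTICLE)
        heavy = om.FrictionSpec(1e6, 1e6)
        with pytest.raises(om.NeverMovesError):
            om.effective_range(tiny, magnet=magnet_small, friction=heavy)

    def test_increases_with_magnet_size(self, default_load):
        ranges = [
            om.effective_range(default_load, magnet=om.MAGNETS[k])
            for k in ("S-02-02", "S-02-05", "S-03-06")
        ]
        assert ranges[0] < ranges[1] < ranges[2]

    def test_floating_egg_rejected(self, default_load):
        light = om.EggBody(150e-6, 1000.0)
        with pytest.raises(ValueError):
            om.effective_range(default_load, egg=light)


class TestSimulateCapture:
    def test_beyond_range_not_captured(self, default_load, magnet_small):
        z_star = om.effective_range(default_load, magnet=magnet_small)
        res = om.simulate_capture(default_load, magnet=magnet_small, z0=1.05 * z_star)
        assert not res.captured
        assert res.capture_time is None

    def test_constant_force_closed_form(self):
        """Overdamped solution x(t) = x0 - v_inf (t - tau (1 - e^{-t/tau}))
        under uniform force, within 0.5%."""
        egg, med, fr = om.DEFAULT_EGG, om.PBS, om.DEFAULT_FRICTION
        F0 = 5e-9
        res = om.simulate_capture(
            om.EggLoad(1, om.ESTAPOR_PARTICLE), egg, om.MAGNETS["S-02-02"], med, fr,
            z0=2e-3, force_fn=lambda z: F0,
        )
        gamma = om.drag_coefficient(egg, med)
        v_inf = (F0 - fr.mu_kinetic * om.net_weight(egg, med)) / gamma
        tau = egg.mass / gamma
        t = res.trajectory.t
        late = t > 5 * tau
        x_exact = 2e-3 - v_inf * (t[late] - tau * (1 - np.exp(-t[late] / tau)))
        assert np.abs((res.trajectory.x[late] - x_exact) / 2e-3).max() < 5e-3

    def test_overdamped_limit_matches_inertial(self, default_load):
        """Quasi-static capture time within 1% of full inertial dynamics."""
        for k in ("S-02-02", "S-02-05", "S-03-06"):
            _, t_in, _ = characterize_magnet(default_load, magnet=om.MAGNETS[k])
            _, t_qs, _ = characterize_magnet(
                default_load, magnet=om.MAGNETS[k], quasistatic=True
            )
            assert abs(t_in / t_qs - 1) < 0.01

    def test_position_non_increasing_speed_non_negative(self, default_load, magnet_small):
        res = om.simulate_capture(default_load, magnet=magnet_small, z0=3e-3)
        assert res.captured
        assert np.all(np.diff(res.trajectory.x) <= 0)
        assert np.all(res.v >= -1e-15)

    def test_capture_time_and_range_increase_with_magnet_size(self, default_load):
        ranges, times = [], []
        for k in ("S-02-02", "S-02-05", "S-03-06"):
            z_star, t_cap, _ = characterize_magnet(default_load, magnet=om.MAGNETS[k])
            ranges.append(z_star)
            times.append(t_cap)
        assert ranges[0] < ranges[1] < ranges[2]
        assert times[0] < times[1] < times[2]

    def test_capture_time_decreases_with_load(self, magnet_small):
        p = om.ESTAPOR_PARTICLE
        times = []
        for n in (60_000, 120_000, 240_000):
            res = om.simulate_capture(om.EggLoad(n, p), magnet=magnet_small, z0=2e-3)
            assert res.captured
            times.append(res.capture_time)
        assert times[0] > times[1] > times[2]

    def test_energy_accounting(self, default_load, magnet_small):
        """Work done by the magnet covers drag + friction dissipation at
        every output step (the remainder is the kinetic energy)."""
        res = om.simulate_capture(default_load, magnet=magnet_small, z0=3e-3)
        e = res.energy
        scale = e["magnetic"][-1]
        assert np.all(e["magnetic"] - e["drag"] - e["friction"] >= -1e-6 * scale)
        balance = e["magnetic"] - e["drag"] - e["friction"] - e["kinetic"]
        assert np.abs(balance).max() < 1e-6 * scale

    def test_acceleration_signature(self, default_load):
        """Released barely inside the range, the egg creeps with near-null
        acceleration for the first half of the approach and the acceleration
        peaks only in the final 20%."""
        for k in ("S-02-02", "S-02-05", "S-03-06"):
            _, _, res = characterize_magnet(default_load, magnet=om.MAGNETS[k])
            x, a = res.trajectory.x, np.abs(res.a)
            travel = x[0] - x[-1]
            first_half = x >= x[0] - 0.5 * travel
            assert a[first_half].max() < 0.01 * a.max()
            assert x[a.argmax()] <= x[-1] + 0.2 * travel

    def test_invalid_start_rejected(self, default_load, magnet_small):
        with pytest.raises(ValueError):
            om.simulate_capture(default_load, magnet=magnet_small, z0=10e-6)
        with pytest.raises(ValueError):
            om.simulate_capture(default_load, magnet=magnet_small, z0=float("nan"))


class TestScenario:
    def test_default_scenario_start_speed(self):
        sc = om.default_scenario("S-02-02")
        res = om.simulate_scenario(sc, quasistatic=True)
        # quasi-static speed at release equals the 1 mm/s design value
        assert res.v[0] == pytest.approx(1e-3, rel=1e-6)

    def test_type_validation(self):
        with pytest.raises(ValueError):
            om.FrictionSpec(0.1, 0.2)  # kinetic above static
        with pytest.raises(ValueError):
            om.Medium(0.0, 1000.0)
        with pytest.raises(ValueError):
            om.EggLoad(-5, om.ESTAPOR_PARTICLE)
        with pytest.raises(ValueError):
            om.NanoparticleSpec(-1e-6, 1e-15, 1.0)
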