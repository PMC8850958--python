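"""Bioheat solver, Arrhenius damage and necrotic-zone metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mwablate.bioheat import (CoolingBC, arrhenius_step, damage_fraction,
                              ellipsoid_margin, necrotic_metrics, simulate)
from mwablate.constants import CONSTANTS
from mwablate.materials import TissueProperties, properties_for
from mwablate.mesh import structured_mesh

from conftest import make_box_domain

LIVER = properties_for("parenchyma", 0.0)


def uniform_props(**kw):
    base = dict(k=0.521, sigma=0.861, eps_r=46.8, omega_b=0.018,
                cp=3400.0, rho=1050.0, A=7.39e39, dE=2.58e5)
    base.update(kw)
    return TissueProperties(**base)


class TestArrhenius:
    def test_zero_dt_leaves_alpha_unchanged(self):
        a = np.array([0.5])
        out = arrhenius_step(a, np.array([330.0]), np.array([340.0]), 0.0,
                             7.39e39, 2.58e5)
        assert out[0] == 0.5

    def test_constant_temperature_closed_form(self):
        # at constant T the integral is exactly rate * t
        A, dE, T, t = 7.39e39, 2.58e5, 310.15, 900.0
        rate = A * np.exp(-dE / (CONSTANTS.R_gas * T))
        alpha = np.zeros(1)
        for _ in range(10):
            alpha = arrhenius_step(alpha, np.full(1, T), np.full(1, T), t / 10, A, dE)
        assert alpha[0] == pytest.approx(rate * t, rel=1e-12)
        # frozen oracle value: 900 * A * exp(-dE/(R*310.15))
        assert alpha[0] == pytest.approx(0.23553744, rel=1e-6)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_step(np.zeros(1), np.array([-1.0]), np.array([300.0]),
                           1.0, 1.0, 1.0)


class TestDamageFraction:
    def test_zero_alpha_gives_zero(self):
        assert damage_fraction(0.0) == 0.0

    def test_necrosis_threshold_at_ln50(self):
        assert damage_fraction(np.log(50.0)) == pytest.approx(0.98, rel=1e-14)

    @given(st.floats(0, 25), st.floats(1e-4, 25))
    def test_monotone_and_bounded(self, a, da):
        assert 0 <= damage_fraction(a) < 1
        assert damage_fraction(a + da) > damage_fraction(a)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            damage_fraction(-0.1)


class TestSimulateOracles:
    def test_equilibrium_stays_at_body_temperature(self):
        dom = make_box_domain(0.01, 0.03, 0, 0.02, 6, 6, wall=("left", "right"))
        hist = simulate(dom, {0: LIVER}, None, duration=60, dt=5.0, cooling=None,
                        snapshot_interval=30)
        assert np.allclose(hist.final.T, CONSTANTS.T_body, atol=1e-10)

    def test_perfusion_only_relaxation_rate(self):
        """Uniform field relaxes toward blood temperature at the Pennes rate
        rho_b cp_b omega_b / (rho cp)."""
        props = uniform_props(omega_b=0.018)
        lam = (CONSTANTS.rho_blood * CONSTANTS.cp_blood * props.omega_b
               / (props.rho * props.cp))
        dom = make_box_domain(0.01, 0.03, 0, 0.02, 5, 5)   # insulated
        t_end = 60.0
        hist = simulate(dom, {0: props}, None, duration=t_end, dt=0.05, cooling=None,
                        T_wall=None, T_init=CONSTANTS.T_body + 1.0,
                        snapshot_interval=t_end)
        ratio = (hist.final.T - CONSTANTS.T_body) / 1.0
        rate = -np.log(ratio.mean()) / t_end
        assert rate == pytest.approx(lam, rel=5e-3)

    def test_steady_conduction_profile_is_linear(self):
        # fixed 37 C at the bottom, strong convective clamp to 47 C at the top;
        # at steady state the axial profile is linear within discretization error
        dom = make_box_domain(1.0, 1.01, 0, 0.05, 2, 25, wall=("bottom",),
                              cooling=("top",))
        hot = CoolingBC(h=1e8, T_ext=320.15)
        hist = simulate(dom, {0: uniform_props(omega_b=0.0)}, None, duration=4e5,
                        dt=1e4, cooling=hot, snapshot_interval=4e5)
        mesh = dom.mesh
        z = mesh.nodes[:, 1]
        fit = np.polyfit(z, hist.final.T, 1)
        assert np.abs(np.polyval(fit, z) - hist.final.T).max() < 0.05
        assert fit[0] == pytest.approx((320.15 - 310.15) / 0.05, rel=0.01)

    def test_insulated_enthalpy_conserved(self):
        dom = make_box_domain(0.01, 0.03, 0, 0.02, 8, 8)
        rng = np.random.default_rng(0)
        T0 = CONSTANTS.T_body + rng.uniform(0, 5, dom.mesh.n_nodes)
        props = uniform_props(omega_b=0.0)   # also no SAR, no cooling, no wall
        hist = simulate(dom, {0: props}, None, duration=900, dt=5.0, cooling=None,
                        T_wall=None, T_init=T0, snapshot_interval=900)
        from mwablate.mesh import P1Assembler
        asm = P1Assembler(dom.mesh)
        M = asm.mass(np.full(dom.mesh.n_elements, props.rho * props.cp), lumped=True)
        e0 = M.diagonal() @ T0
        e1 = M.diagonal() @ hist.final.T
        assert abs(e1 - e0) / e0 < 1e-3

    def test_discrete_maximum_principle(self):
        dom = make_box_domain(0.01, 0.03, 0, 0.02, 8, 8, wall=("left",))
        rng = np.random.default_rng(1)
        T0 = CONSTANTS.T_body + rng.uniform(0, 10, dom.mesh.n_nodes)
        hist = simulate(dom, {0: uniform_props(omega_b=0.0)}, None, duration=300,
                        dt=1.0, cooling=None, T_init=T0, snapshot_interval=300)
        lo, hi = CONSTANTS.T_body, T0.max()
        for snap in hist.snapshots:
            assert snap.T.min() >= lo - 1e-9
            assert snap.T.max() <= hi + 1e-9

    def test_alpha_nondecreasing_in_time(self):
        dom = make_box_domain(0.01, 0.03, 0, 0.02, 5, 5, wall=("left",))
        sar = np.full(dom.mesh.n_elements, 5e5)
        hist = simulate(dom, {0: LIVER}, sar, duration=60, dt=1.0, cooling=None,
                        snapshot_interval=15)
        for a, b in zip(hist.snapshots, hist.snapshots[1:]):
            assert np.all(b.alpha >= a.alpha - 1e-15)

    def test_duration_must_align_with_snapshots(self):
        dom = make_box_domain(0.01, 0.03, 0, 0.02, 3, 3)
        with pytest.raises(ValueError):
            simulate(dom, {0: LIVER}, None, duration=100, dt=1.0,
                     snapshot_interval=15)


class TestNecroticMetrics:
    def test_axisymmetric_rectangle_revolves_to_cylinder(self):
        # super-threshold block r in [0, a], z in [0, h] -> pi a^2 h
        a, h = 0.01, 0.02
        mesh = structured_mesh(np.linspace(0, 0.03, 31), np.linspace(0, 0.05, 26))
        theta = np.where((mesh.nodes[:, 0] <= a + 1e-12)
                         & (mesh.nodes[:, 1] <= h + 1e-12), 1.0, 0.0)
        m = necrotic_metrics(theta, mesh)
        assert m.necrotic_volume == pytest.approx(np.pi * a**2 * h * 1e6, rel=1e-9)
        assert m.long_axis_diameter == pytest.approx(h * 100)
        assert m.short_axis_diameter == pytest.approx(2 * a * 100)

    def test_voxel_sphere_volume(self):
        # unit-damage sphere of radius 1 cm -> 4 pi / 3 cm^3
        n, sp = 81, 0.5
        ax = (np.arange(n) - n // 2) * sp
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        theta = (X**2 + Y**2 + Z**2 <= 10.0**2).astype(float)
        m = necrotic_metrics(theta, spacing=(sp, sp, sp))
        assert m.necrotic_volume == pytest.approx(4 * np.pi / 3, rel=0.02)

    def test_ellipsoidal_level_set_axes(self):
        # semi-axes (1.0, 1.0, 2.4) cm with the long axis along z
        sp = 0.5
        ax = (np.arange(121) - 60) * sp
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        theta = ((X / 10) ** 2 + (Y / 10) ** 2 + (Z / 24) ** 2 <= 1).astype(float)
        m = necrotic_metrics(theta, spacing=(sp, sp, sp), axis=2)
        assert m.long_axis_diameter == pytest.approx(4.8, abs=0.1)
        assert m.short_axis_diameter == pytest.approx(2.0, abs=0.1)

    def test_empty_field_gives_zero_metrics(self):
        mesh = structured_mesh(np.linspace(0, 0.01, 3), np.linspace(0, 0.01, 3))
        m = necrotic_metrics(np.zeros(mesh.n_nodes), mesh)
        assert (m.necrotic_volume, m.long_axis_diameter, m.short_axis_diameter) == (0, 0, 0)

    def test_centroid_rule_is_more_inclusive(self):
        mesh = structured_mesh(np.linspace(0, 0.02, 21), np.linspace(0, 0.02, 21))
        rng = np.random.default_rng(2)
        theta = rng.uniform(0.9, 1.0, mesh.n_nodes)
        v_strict = necrotic_metrics(theta, mesh, rule="vertices").necrotic_volume
        v_loose = necrotic_metrics(theta, mesh, rule="centroid").necrotic_volume
        assert v_loose >= v_strict

    def test_mode_arguments_are_exclusive(self):
        mesh = structured_mesh(np.linspace(0, 1, 3), np.linspace(0, 1, 3))
        with pytest.raises(ValueError):
            necrotic_metrics(np.zeros(mesh.n_nodes), mesh, spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            necrotic_metrics(np.zeros((3, 3, 3)))


class TestEllipsoidMargin:
    def test_reference_diameters(self):
        assert ellipsoid_margin(4.81, 2.05) == pytest.approx((2.405, 1.025, 1.025))

    def test_sphere_degenerate(self):
        assert ellipsoid_margin(2.0, 2.0) == pytest.approx((1.0, 1.0, 1.0))

    def test_spheroid_volume_differs_from_true_zone_volume(self):
        # pi/6 L S^2 for the zero-fat diameters: the fitted spheroid holds
        # ~10.6 cm^3, deliberately not the ~8.5 cm^3 of the true zone shape
        a, b, c = ellipsoid_margin(4.81, 2.05)
        vol = 4 / 3 * np.pi * a * b * c
        assert vol == pytest.approx(np.pi / 6 * 4.81 * 2.05**2, rel=1e-12)
        assert vol == pytest.approx(10.583, abs=5e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_margin(0.0, 1.0)
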