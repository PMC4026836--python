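import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoflow2d.membrane import (
    CaseFlags,
    MembraneMesh,
    _self_intersects,
    assemble_nodal_forces,
    bending_tension,
    discrete_curvature,
    enclosed_area,
    internal_pressure,
    ld_coefficient,
    segment_tension,
)
from hemoflow2d.units import UM_TO_CM, PhysicalParams

LD_OFF = CaseFlags.case("I")
LD_ALL = CaseFlags.case("III")


class TestHardeningCoefficient:
    def test_unity_at_rest(self):
        assert ld_coefficient(1.0, 0.01, 5.0) == 1.0

    def test_printed_form_value(self):
        """alpha = 1 + D (e^(lam b) - e^b) evaluated by independent arithmetic."""
        expected = 1.0 + 0.01 * (math.exp(6.0) - math.exp(5.0))  # 3.5502
        assert ld_coefficient(1.2, 0.01, 5.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.5502, abs=1e-4)

    def test_approaches_unity_at_low_strain(self):
        assert ld_coefficient(1.0 + 1e-9, 0.01, 5.0) == pytest.approx(1.0, abs=1e-6)

    def test_compression_clamped_to_unity(self):
        assert ld_coefficient(0.7, 0.01, 5.0) == 1.0
        assert ld_coefficient(0.7, 0.01, 5.0, clamp=False) < 1.0

    @given(st.floats(1.0, 2.0), st.floats(1.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing_in_stretch(self, lam1, lam2):
        a1 = ld_coefficient(lam1, 2.34e-4, 8.0)
        a2 = ld_coefficient(lam2, 2.34e-4, 8.0)
        assert (a1 <= a2) == (lam1 <= lam2)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            ld_coefficient(-0.1, 0.01, 5.0)


class TestSegmentTension:
    def test_zero_at_rest(self, params):
        assert segment_tension(1.0, params, LD_OFF) == 0.0

    def test_neo_hookean_value(self, params):
        """tau/E_s at lam = 1.1, plain neo-Hookean (scalar oracle)."""
        tau = segment_tension(1.1, params, LD_OFF)
        assert tau / params.E_s == pytest.approx(
            (1.1**3 - 1.0) / 1.1**1.5, rel=1e-12
        )
        assert tau / params.E_s == pytest.approx(0.28691, abs=1e-5)

    def test_small_strain_series_limit(self, params):
        """tau ~ 3 E_s eps for small strain (series of the neo-Hookean law)."""
        eps = 1e-4
        tau = segment_tension(1.0 + eps, params, LD_OFF)
        assert tau == pytest.approx(3.0 * params.E_s * eps, rel=1e-3)

    def test_sign_follows_strain(self, params):
        assert segment_tension(1.2, params, LD_ALL) > 0
        assert segment_tension(0.8, params, LD_ALL) < 0

    def test_hardening_multiplies(self, params):
        lam = 1.15
        ratio = segment_tension(lam, params, CaseFlags.case("II")) / segment_tension(
            lam, params, LD_OFF
        )
        assert ratio == pytest.approx(
            ld_coefficient(lam, params.D_LD, params.beta_LD), rel=1e-12
        )


class TestCurvature:
    @pytest.mark.parametrize("n", [32, 64, 128])
    def test_circle_recovers_inverse_radius(self, n):
        a = 3.7
        mesh = MembraneMesh.circle((0.0, 0.0), a, n)
        k = discrete_curvature(mesh.X, 5)
        assert k == pytest.approx(1.0 / a, rel=4.0 / n**2 + 1e-9)

    def test_straight_line_zero(self):
        X = np.column_stack([np.linspace(0, 9, 10), np.zeros(10)])
        assert discrete_curvature(X, 5) == 0.0

    def test_reflection_flips_sign(self):
        mesh = MembraneMesh.circle((0.0, 0.0), 2.0, 32)
        X = mesh.X.copy()
        Xr = X.copy()
        Xr[:, 1] *= -1.0
        assert discrete_curvature(Xr, 7) == pytest.approx(
            -discrete_curvature(X, 7), rel=1e-12
        )

    def test_cusp_detected(self):
        """A fold-back reads as near-maximal curvature, not zero."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.05, 1e-3],
                      [0.0, 2.0], [-1.0, 1.0]])
        assert abs(discrete_curvature(X, 1)) > 2.0


class TestEnclosedArea:
    def test_unit_square(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert enclosed_area(X) == 1.0

    def test_regular_polygon_closed_form(self):
        a, n = 2.5, 64
        mesh = MembraneMesh.circle((1.0, -3.0), a, n)
        exact = 0.5 * n * a**2 * math.sin(2 * math.pi / n)
        assert enclosed_area(mesh.X) == pytest.approx(exact, rel=1e-12)
        assert enclosed_area(mesh.X) == pytest.approx(math.pi * a**2, rel=2e-3)

    def test_translation_invariance(self, rng):
        mesh = MembraneMesh.circle((0.0, 0.0), 2.0, 48)
        shift = rng.normal(size=2) * 100
        assert enclosed_area(mesh.X + shift) == pytest.approx(
            enclosed_area(mesh.X), rel=1e-9
        )

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            enclosed_area(bowtie)


class TestInternalPressure:
    def test_zero_at_reference_area(self, params):
        assert internal_pressure(10.0, 10.0, 1.0, params, LD_ALL) == 0.0

    def test_linear_restoring(self, params):
        p = internal_pressure(9.9, 10.0, 1.0, params, LD_OFF)
        assert p == pytest.approx(0.01 * params.k_p, rel=1e-12)
        assert p > 0  # outward when compressed

    def test_hardening_magnifies_by_alpha(self, params):
        lam_C = 1.1
        p_off = internal_pressure(9.0, 10.0, lam_C, params, LD_OFF)
        p_on = internal_pressure(9.0, 10.0, lam_C, params, LD_ALL)
        assert p_on / p_off == pytest.approx(
            ld_coefficient(lam_C, params.D_LD, params.beta_LD), rel=1e-12
        )


class TestBendingTension:
    def test_zero_at_spontaneous_curvature(self, params):
        assert bending_tension(0.25, 0.25, 1.0, params, LD_ALL) == 0.0

    def test_linearity(self, params):
        k0 = 0.2
        assert bending_tension(2 * k0, k0, 1.0, params, LD_OFF) == pytest.approx(
            params.E_b * k0, rel=1e-12
        )

    def test_case_contrast_ratio_is_alpha(self, params):
        """Hardened vs plain bending at identical (kappa, lambda) differ by alpha."""
        lam = 1.12
        t2 = bending_tension(0.5, 0.25, lam, params, CaseFlags.case("II"))
        t3 = bending_tension(0.5, 0.25, lam, params, CaseFlags.case("III"))
        assert t3 / t2 == pytest.approx(
            ld_coefficient(lam, params.D_LD, params.beta_LD), rel=1e-12
        )


class TestMembraneMesh:
    def test_circle_reference_geometry(self):
        a, n = 4.0, 80
        mesh = MembraneMesh.circle((1.0, 2.0), a, n)
        assert mesh.l0.sum() == pytest.approx(mesh.L0, rel=1e-14)
        assert np.allclose(mesh.kappa0, 1.0 / a)
        assert mesh.A_ref == pytest.approx(math.pi * a**2, rel=7.0 / n**2)

    def test_clockwise_ring_rejected(self):
        mesh = MembraneMesh.circle((0.0, 0.0), 1.0, 16)
        with pytest.raises(ValueError, match="counter-clockwise"):
            MembraneMesh(
                X=mesh.X[::-1], l0=mesh.l0, kappa0=mesh.kappa0,
                A_ref=mesh.A_ref, L0=mesh.L0,
            )

    def test_self_intersection_detector(self):
        ring = MembraneMesh.circle((0.0, 0.0), 1.0, 24).X
        assert not _self_intersects(np.ascontiguousarray(ring))
        crossed = ring.copy()
        crossed[[3, 9]] = crossed[[9, 3]]
        assert _self_intersects(np.ascontiguousarray(crossed))


class TestNodalForces:
    def test_rest_circle_in_equilibrium(self, params):
        mesh = MembraneMesh.circle((0.0, 0.0), params.a_cell, 64)
        F = assemble_nodal_forces(mesh, params, LD_ALL)
        assert np.abs(F).max() < 1e-3 * params.E_s

    def test_net_force_and_torque_vanish(self, params, rng):
        mesh = MembraneMesh.circle((0.0, 0.0), 4.0, 48)
        mesh.X += rng.normal(0, 0.15, mesh.X.shape)
        F = assemble_nodal_forces(mesh, params, LD_ALL)
        scale = np.abs(F).sum() + 1e-300
        assert np.abs(F.sum(axis=0)).max() / scale < 1e-10
        torque = np.sum(
            mesh.X[:, 0] * UM_TO_CM * F[:, 1] - mesh.X[:, 1] * UM_TO_CM * F[:, 0]
        )
        assert abs(torque) / (scale * 4.0 * UM_TO_CM) < 1e-10

    def test_inflated_circle_pulls_inward(self, params):
        mesh = MembraneMesh.circle((0.0, 0.0), 4.0, 64)
        mesh.X *= 1.05  # uniform inflation: A > A_ref, lambda > 1
        F = assemble_nodal_forces(mesh, params, LD_OFF)
        rhat = mesh.X / np.linalg.norm(mesh.X, axis=1, keepdims=True)
        radial = (F * rhat).sum(axis=1)
        tangential = F[:, 0] * -rhat[:, 1] + F[:, 1] * rhat[:, 0]
        assert np.all(radial < 0)
        assert np.abs(tangential).max() < 1e-8 * np.abs(radial).max()

    def test_bending_force_is_energy_gradient(self, params, rng):
        """Nodal bending force matches -dE/dX of the discrete bending energy."""
        import dataclasses

        p = dataclasses.replace(params, E_s=1e-30, k_p=1e-30)
        mesh = MembraneMesh.circle((0.0, 0.0), 4.0, 24)
        X0 = mesh.X + rng.normal(0, 0.2, mesh.X.shape)

        def energy(X):
            n = len(X)
            e = 0.0
            for i in range(n):
                k = discrete_curvature_rest(X, i, mesh.l0)
                ds0 = 0.5 * (mesh.l0[i - 1] + mesh.l0[i])
                e += 0.5 * p.E_b * (k - mesh.kappa0[i] / UM_TO_CM) ** 2 * ds0 * UM_TO_CM
            return e

        def discrete_curvature_rest(X, i, l0):
            from hemoflow2d.membrane import _turning_angle_and_grad

            n = len(X)
            im, ip = (i - 1) % n, (i + 1) % n
            th = _turning_angle_and_grad(
                *(X[im] * UM_TO_CM), *(X[i] * UM_TO_CM), *(X[ip] * UM_TO_CM)
            )[0]
            return th / (0.5 * (l0[im] + l0[i]) * UM_TO_CM)

        mesh2 = MembraneMesh(
            X=X0, l0=mesh.l0, kappa0=mesh.kappa0, A_ref=mesh.A_ref, L0=mesh.L0
        )
        F = assemble_nodal_forces(mesh2, p, LD_OFF)
        eps = 1e-6
        for idx in [(0, 0), (5, 1), (11, 0)]:
            Xp = X0.copy()
            Xp[idx] += eps
            Xm = X0.copy()
            Xm[idx] -= eps
            fd = -(energy(Xp) - energy(Xm)) / (2 * eps * UM_TO_CM)
            assert F[idx] == pytest.approx(fd, rel=2e-4, abs=1e-12)

    def test_elastic_work_closed_loop_vanishes(self, params):
        """With hardening off, tension work over a closed strain loop is ~0."""
        import dataclasses

        p = dataclasses.replace(params, E_b=1e-30, k_p=1e-30)
        mesh = MembraneMesh.circle((0.0, 0.0), 4.0, 32)
        X0 = mesh.X.copy()
        t = np.linspace(0, 2 * np.pi, 401)
        work = 0.0
        Xp = X0.copy()
        for ti in t[1:]:
            stretch = 1.0 + 0.05 * np.sin(ti)
            squeeze = 1.0 + 0.03 * (1 - np.cos(ti))
            Xn = np.column_stack([X0[:, 0] * stretch, X0[:, 1] / squeeze])
            mid = MembraneMesh(
                X=0.5 * (Xp + Xn), l0=mesh.l0, kappa0=mesh.kappa0,
                A_ref=mesh.A_ref, L0=mesh.L0,
            )
            F = assemble_nodal_forces(mid, p, LD_OFF)
            work += np.sum(F * (Xn - Xp) * UM_TO_CM)
            Xp = Xn
        scale = params.E_s * 4.0 * UM_TO_CM  # tension x radius
        assert abs(work) < 1e-3 * scale
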