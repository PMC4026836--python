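import numpy as np
import pytest

from hemoflow2d.membrane import MembraneMesh
from hemoflow2d.metrics import (
    apparent_viscosity,
    cfl_width,
    circumferential_strain,
    dimensionless_G,
    fit_strain_curve,
    g3d_to_g2d,
    taylor_index,
)
from hemoflow2d.units import CP_TO_POISE, UM_TO_CM


def ellipse(a, b, n=256, angle=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    X = np.column_stack([a * np.cos(t), b * np.sin(t)])
    c, s = np.cos(angle), np.sin(angle)
    return X @ np.array([[c, s], [-s, c]])


class TestTaylorIndex:
    def test_circle_is_zero(self):
        assert taylor_index(ellipse(2.0, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_two_to_one_ellipse(self):
        assert taylor_index(ellipse(2.0, 1.0)) == pytest.approx(1.0 / 3.0, rel=1e-6)

    @pytest.mark.parametrize("angle", [0.3, 1.0, 2.2])
    def test_rotation_invariance(self, angle):
        """Extents along gyration principal axes match brute-force search."""
        X = ellipse(3.0, 1.5, angle=angle)
        assert taylor_index(X) == pytest.approx(taylor_index(ellipse(3.0, 1.5)),
                                                rel=1e-9)
        # brute-force oracle: maximal/minimal caliper extents over rotations
        t = np.linspace(0, np.pi, 721)
        ext = [
            np.ptp(X @ np.array([np.cos(a), np.sin(a)])) for a in t
        ]
        L, B = max(ext), min(ext)
        assert taylor_index(X) == pytest.approx((L - B) / (L + B), rel=1e-4)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            taylor_index(np.zeros((5, 2)))


class TestDimensionlessG:
    def test_printed_reference_point(self):
        """1.2 cP, 150 1/s, 4.17 um and E_s = 6e-3 dyn/cm give G = 0.125."""
        G = dimensionless_G(1.2 * CP_TO_POISE, 150.0, 4.17 * UM_TO_CM, 6.0e-3)
        assert G == pytest.approx(0.125, abs=5e-4)

    def test_zero_shear(self):
        assert dimensionless_G(1.0, 0.0, 1.0, 1.0) == 0.0

    def test_linearity_in_viscosity(self):
        assert dimensionless_G(2.4e-2, 150.0, 4.17e-4, 6e-3) == pytest.approx(
            2 * dimensionless_G(1.2e-2, 150.0, 4.17e-4, 6e-3)
        )


@pytest.mark.filterwarnings("ignore:2D G conversion")
class TestG3DConversion:
    def test_low_shear_printed_value(self):
        assert g3d_to_g2d(0.01) == pytest.approx(-0.00383, abs=5e-6)

    def test_intercept(self):
        assert g3d_to_g2d(0.0) == pytest.approx(-0.008417, rel=1e-12)

    def test_arithmetic_oracle_at_half(self):
        expected = -0.008417 + 0.45073 * 0.5 + 0.75662 * 0.25
        assert g3d_to_g2d(0.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.406103, abs=1e-6)

    def test_nonpositive_result_warns(self):
        with pytest.warns(UserWarning):
            g3d_to_g2d(0.005)


class TestCircumferentialStrain:
    def test_rest_mesh(self):
        mesh = MembraneMesh.circle((0, 0), 3.0, 48)
        lam, eps = circumferential_strain(mesh)
        assert lam == pytest.approx(1.0, rel=1e-12)
        assert eps == pytest.approx(0.0, abs=1e-12)

    def test_uniform_stretch(self):
        mesh = MembraneMesh.circle((0, 0), 3.0, 48)
        mesh.X *= 1.1
        lam, eps = circumferential_strain(mesh)
        assert lam == pytest.approx(1.1, rel=1e-12)
        assert eps == pytest.approx(0.1, rel=1e-10)

    def test_matches_scalar_loop_oracle(self, rng):
        mesh = MembraneMesh.circle((0, 0), 3.0, 32)
        mesh.X += rng.normal(0, 0.1, mesh.X.shape)
        total = 0.0
        for i in range(32):
            j = (i + 1) % 32
            total += np.hypot(*(mesh.X[j] - mesh.X[i]))
        lam, eps = circumferential_strain(mesh)
        assert lam == pytest.approx(total / mesh.L0, rel=1e-12)
        assert eps == lam - 1.0


class TestCflWidth:
    def test_no_cells_full_channel(self):
        assert cfl_width([np.array([])], H=20.0) == 1.0

    def test_cell_touching_bottom_wall(self):
        y = np.array([0.0, 3.0, 10.0])
        assert cfl_width([y], H=20.0) == pytest.approx(0.5)  # 0 + (20-10) = 10

    def test_cells_confined_to_core(self):
        H = 20.0
        y = np.linspace(H / 4, 3 * H / 4, 33)
        assert cfl_width([y], H=H) == pytest.approx(0.5)

    def test_time_average(self):
        frames = [np.array([5.0, 15.0]), np.array([2.0, 18.0])]
        assert cfl_width(frames, H=20.0) == pytest.approx((0.5 + 0.2) / 2)


class TestApparentViscosity:
    def test_plane_poiseuille_self_consistency(self):
        """A Poiseuille profile of viscosity mu inverts back to mu."""
        mu, H, L, dP = 0.012, 20e-4, 80e-4, 30.0
        g = dP / L
        Q = g * H**3 / (12.0 * mu)
        mu_app, mu_rel = apparent_viscosity(Q, dP, H, L, mu)
        assert mu_app == pytest.approx(mu, rel=1e-12)
        assert mu_rel == pytest.approx(1.0, rel=1e-12)

    def test_linearity_in_pressure(self):
        m1, _ = apparent_viscosity(1.0, 10.0, 1.0, 1.0, 1.0)
        m2, _ = apparent_viscosity(1.0, 20.0, 1.0, 1.0, 1.0)
        assert m2 == pytest.approx(2 * m1)

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            apparent_viscosity(0.0, 1.0, 1.0, 1.0, 1.0)


class TestStrainCurveFit:
    A, B = 0.1771, 0.0611

    def g_grid(self):
        return np.geomspace(0.5, 60.0, 12)

    def test_noiseless_recovery_exact(self):
        g = self.g_grid()
        eps = self.A * (1.0 - np.exp(-self.B * g))
        A, b, r2 = fit_strain_curve(np.column_stack([g, eps]))
        assert A == pytest.approx(self.A, rel=1e-6)
        assert b == pytest.approx(self.B, rel=1e-6)
        assert r2["all"] == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(7)
        g = self.g_grid()
        eps = self.A * (1.0 - np.exp(-self.B * g))
        eps = eps * (1.0 + 0.01 * rng.standard_normal(len(g)))
        A, b, _ = fit_strain_curve(np.column_stack([g, eps]))
        assert A == pytest.approx(self.A, rel=0.05)
        assert b == pytest.approx(self.B, rel=0.05)

    def test_saturation_amplitude(self):
        g = self.g_grid()
        eps = self.A * (1.0 - np.exp(-self.B * g))
        A, b, _ = fit_strain_curve(np.column_stack([g, eps]))
        assert A * (1.0 - np.exp(-b * 1e6)) == pytest.approx(A)

    def test_per_label_r_squared(self):
        g = self.g_grid()
        eps = self.A * (1.0 - np.exp(-self.B * g))
        labels = ["single"] * 6 + ["multi"] * 6
        _, _, r2 = fit_strain_curve(np.column_stack([g, eps]), labels)
        assert set(r2) == {"single", "multi"}
        assert all(v == pytest.approx(1.0, abs=1e-10) for v in r2.values())

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_strain_curve(np.zeros((3, 2)))
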