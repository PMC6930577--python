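"""Dipolar tensors, frame transformations and orientational pseudo-forces."""
import numpy as np
import pytest

from mdoc.engine import ramp_factor
from mdoc.geometry import GeometryError
from mdoc.rdc import (
    ConstraintError,
    RDCConstraint,
    exp_tensor,
    lab_tensor,
    methyl_rdc_observable,
    pas_tensor,
    rdc_pseudo_force,
    tanh_scale,
)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestPasTensor:
    def test_scaled_static_splitting_in_weak_alignment(self):
        t = pas_tensor(47.96e3, 0.004)
        assert t.zz == pytest.approx(191.84, abs=1e-9)

    def test_traceless_and_axial(self):
        t = pas_tensor(2.0, 1.0)
        assert np.allclose(t.tensor, np.diag([-1.0, -1.0, 2.0]))
        assert abs(np.trace(t.tensor)) < 1e-12

    def test_invalid_order_parameter(self):
        with pytest.raises(ValueError):
            pas_tensor(100.0, 0.0)


class TestLabTensor:
    def test_bond_along_z_is_identity(self):
        pas = pas_tensor(10.0, 1.0)
        x = np.array([[0.0, 0, 1.09], [0.0, 0, 0]])
        lab = lab_tensor(x, (0, 1), pas)
        assert np.allclose(lab.tensor, pas.tensor, atol=1e-12)

    def test_bond_along_x_swaps_axes(self):
        pas = pas_tensor(10.0, 1.0)
        x = np.array([[1.09, 0, 0], [0.0, 0, 0]])
        lab = lab_tensor(x, (0, 1), pas)
        assert lab.zz == pytest.approx(-5.0, abs=1e-12)

    @pytest.mark.parametrize("theta_deg", [0.0, 30.0, 54.7356103, 90.0, 120.0])
    def test_zz_follows_second_legendre_polynomial(self, theta_deg):
        d = 8.0
        pas = pas_tensor(d, 1.0)
        th = np.deg2rad(theta_deg)
        x = np.array([[np.sin(th), 0, np.cos(th)], [0.0, 0, 0]])
        lab = lab_tensor(x, (0, 1), pas)
        p2 = 0.5 * (3 * np.cos(th) ** 2 - 1)
        assert lab.zz == pytest.approx(d * p2, abs=1e-9)

    def test_eigenvalues_invariant_under_rotation(self, rng):
        pas = pas_tensor(5.0, 0.5)
        v = rng.normal(size=3)
        for _ in range(100):
            rot = random_rotation(rng)
            x = np.array([rot @ v, [0.0, 0, 0]])
            lab = lab_tensor(x, (0, 1), pas)
            ev = np.sort(np.linalg.eigvalsh(lab.tensor))
            assert np.allclose(ev, np.sort(np.diag(pas.tensor)), atol=1e-9)

    def test_atom_order_swap_leaves_tensor_unchanged(self, rng):
        pas = pas_tensor(3.0, 1.0)
        x = rng.normal(size=(2, 3))
        a = lab_tensor(x, (0, 1), pas).tensor
        b = lab_tensor(x, (1, 0), pas).tensor
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_length_vector_raises(self):
        pas = pas_tensor(3.0, 1.0)
        with pytest.raises(GeometryError):
            lab_tensor(np.zeros((2, 3)), (0, 1), pas)


class TestExpTensor:
    def test_zero_coupling_gives_zero_tensor(self):
        assert np.allclose(exp_tensor(0.0).tensor, 0.0)

    def test_definition(self):
        t = exp_tensor(4.0)
        assert np.allclose(t.tensor, np.diag([-2.0, -2.0, 4.0]))


class TestTanhScale:
    def test_values(self):
        assert tanh_scale(0.0, 0.5) == 0.0
        assert tanh_scale(0.5, 0.5) == pytest.approx(np.tanh(1.0))
        assert tanh_scale(-5.0, 0.5) == pytest.approx(-1.0, abs=1e-8)

    def test_odd_and_bounded(self, rng):
        d = rng.normal(scale=5.0, size=100)
        f = tanh_scale(d, 0.5)
        assert np.allclose(f, -tanh_scale(-d, 0.5))
        assert np.all(np.abs(f) <= 1.0)
        assert np.all(np.abs(tanh_scale(d / 10.0, 0.5)) < 1.0)


def make_rdc(d_exp=3.0, width=0.5):
    return RDCConstraint(
        id="r1", atoms=(0, 1), d_exp=d_exp, error=1.0, d_stat=47.96e3, width=width
    )


class TestRDCPseudoForce:
    S_AM = 0.004

    def test_zero_when_mean_matches_target(self, rng):
        c = make_rdc()
        x = rng.normal(size=(2, 3))
        f_i, f_j = rdc_pseudo_force(
            x, c, exp_tensor(c.d_exp).tensor, k=0.3, t=100.0, rho=5.0, s_am=self.S_AM
        )
        assert np.allclose(f_i, 0.0) and np.allclose(f_j, 0.0)

    def test_equal_opposite_and_perpendicular(self, rng):
        c = make_rdc()
        for _ in range(20):
            x = rng.normal(size=(2, 3)) * 2.0
            mean = rng.normal(scale=3.0, size=(3, 3))
            mean = 0.5 * (mean + mean.T)
            mean -= np.eye(3) * np.trace(mean) / 3
            f_i, f_j = rdc_pseudo_force(x, c, mean, 0.3, 50.0, 5.0, self.S_AM)
            assert np.allclose(f_i, -f_j, atol=1e-12)
            bond = x[0] - x[1]
            assert abs(np.dot(f_i, bond)) < 1e-10 * max(np.linalg.norm(f_i), 1.0)

    def test_matches_finite_difference_of_tanh_energy(self, rng):
        """Force with the memory mean frozen at the instantaneous tensor is
        the exact negative orientational gradient of the tanh-integrated
        pseudo-energy k*dD^2*sum(log cosh((D_ab(x)-D_exp_ab)/dD))."""
        c = make_rdc(d_exp=30.0)
        k, t, rho = 0.3, 80.0, 5.0
        pas = pas_tensor(c.d_stat, self.S_AM)
        target = exp_tensor(c.d_exp).tensor

        def energy(x):
            lab = lab_tensor(x, (0, 1), pas).tensor
            return (
                ramp_factor(t, rho)
                * k
                * c.width**2
                * np.sum(np.log(np.cosh((lab - target) / c.width)))
            )

        h = 1e-6
        for _ in range(10):
            x = rng.normal(size=(2, 3)) * 1.5
            lab_now = lab_tensor(x, (0, 1), pas).tensor
            f_i, f_j = rdc_pseudo_force(x, c, lab_now, k, t, rho, self.S_AM)
            for a, fa in ((0, f_i), (1, f_j)):
                for d in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[a, d] += h
                    xm[a, d] -= h
                    fd = -(energy(xp) - energy(xm)) / (2 * h)
                    assert fd == pytest.approx(fa[d], rel=1e-6, abs=1e-9)

    def test_force_norm_bounded_by_saturation(self, rng):
        c = make_rdc()
        x = np.array([[1.09, 0, 0], [0.0, 0, 0]])
        huge = exp_tensor(1e6).tensor  # drives every tanh to saturation
        f_i, _ = rdc_pseudo_force(x, c, huge, 0.3, 1e9, 5.0, self.S_AM)
        d = self.S_AM * c.d_stat
        bound = 0.3 * c.width * 9 * 3 * d / 1.09  # k*dD * n_components * |dD/dx|
        assert np.linalg.norm(f_i) <= bound


class TestMethylObservable:
    def test_mean_of_parallel_bonds_equals_single_tensor(self):
        pas = pas_tensor(6.0, 1.0)
        # hypothetical: three H all displaced identically from the carbon
        x = np.array([[0.0, 0, 0], [0, 0, 1.09], [0, 0, 1.09], [0, 0, 1.09]])
        t = methyl_rdc_observable(x, [(0, 1), (0, 2), (0, 3)], pas)
        assert np.allclose(t.tensor, pas.tensor, atol=1e-12)

    def test_tetrahedral_methyl_scales_by_p2_of_tilt(self):
        d = 6.0
        pas = pas_tensor(d, 1.0)
        tilt = np.deg2rad(70.529)  # C-H at 180-109.47 deg from the symmetry axis
        x = [np.zeros(3)]
        for az in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            x.append(
                1.09
                * np.array([np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt)])
            )
        t = methyl_rdc_observable(np.array(x), [(0, 1), (0, 2), (0, 3)], pas)
        p2 = 0.5 * (3 * np.cos(tilt) ** 2 - 1)
        assert t.zz == pytest.approx(d * p2, abs=1e-9)
        assert t.zz == pytest.approx(-d / 3.0, abs=1e-3)
        # axially symmetric about z
        assert t.tensor[0, 0] == pytest.approx(t.tensor[1, 1], abs=1e-9)

    def test_mean_tensor_traceless(self, rng):
        pas = pas_tensor(4.0, 0.5)
        x = np.vstack([np.zeros(3), rng.normal(size=(3, 3))])
        t = methyl_rdc_observable(x, [(0, 1), (0, 2), (0, 3)], pas)
        assert abs(np.trace(t.tensor)) < 1e-9

    def test_pairs_not_sharing_carbon_rejected(self):
        pas = pas_tensor(4.0, 0.5)
        with pytest.raises(ConstraintError):
            methyl_rdc_observable(np.zeros((4, 3)), [(0, 1), (2, 3), (0, 2)], pas)
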