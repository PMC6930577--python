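"""NOE r^-6 averaging, Karplus couplings and their pseudo-forces."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdoc.engine import MemoryState, ramp_factor, update_memory
from mdoc.geometry import GeometryError
from mdoc.scalar import (
    HAASNOOT_PARAMS,
    JConstraint,
    NOEConstraint,
    j_instantaneous,
    j_pseudo_force,
    karplus_haasnoot,
    noe_mean_distance,
    noe_pseudo_force,
)


def feed_r6(distances, tau=5.0, dt=0.01):
    mem = MemoryState(tau=tau)
    for i, r in enumerate(distances):
        update_memory(mem, float(r) ** -6.0, i * dt, dt)
    return mem


class TestNOEAveraging:
    def test_constant_distance_recovered_exactly(self):
        assert noe_mean_distance(feed_r6([3.0] * 200)) == pytest.approx(3.0, rel=1e-12)

    def test_equal_time_two_state_average(self):
        # long memory so both states weigh ~equally
        mem = feed_r6([2.0, 4.0] * 2000, tau=1e6)
        expect = (0.5 * (2.0**-6 + 4.0**-6)) ** (-1.0 / 6.0)
        assert expect == pytest.approx(2.24, abs=0.01)
        assert noe_mean_distance(mem) == pytest.approx(expect, rel=1e-4)

    @given(st.lists(st.floats(1.5, 8.0), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_r6_mean_below_arithmetic_mean(self, distances):
        mem = feed_r6(distances, tau=1e9)
        assert noe_mean_distance(mem) <= np.mean(distances) + 1e-9


def make_noe(partners=(1,), target=3.0, width=0.25):
    return NOEConstraint(id="n1", atom_i=0, partners=partners, target=target,
                         error=0.5, width=width)


class TestNOEForce:
    def test_zero_at_target(self, rng):
        x = rng.normal(size=(2, 3)) * 2
        out = noe_pseudo_force(x, make_noe(), r_bar=3.0, k=300.0, t=50.0, rho=5.0)
        for f in out.values():
            assert np.allclose(f, 0.0)

    def test_saturated_magnitude(self):
        c = make_noe()
        x = np.array([[0.0, 0, 0], [3.5, 0, 0]])
        out = noe_pseudo_force(x, c, r_bar=c.target + 10 * c.width, k=300.0, t=1e9, rho=5.0)
        assert np.linalg.norm(out[0]) == pytest.approx(300.0 * c.width, rel=1e-4)
        # attractive: force on atom 0 points toward its partner (+x)
        assert out[0][0] > 0

    def test_central_equal_opposite(self, rng):
        x = rng.normal(size=(2, 3)) * 3
        out = noe_pseudo_force(x, make_noe(), r_bar=2.0, k=300.0, t=50.0, rho=5.0)
        assert np.allclose(out[0], -out[1], atol=1e-12)
        cross = np.cross(out[0], x[0] - x[1])
        assert np.abs(cross).max() < 1e-10

    def test_methyl_partner_full_force_on_each_proton(self):
        c = make_noe(partners=(1, 2, 3), target=2.5)
        x = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0]])
        out = noe_pseudo_force(x, c, r_bar=c.target + 10 * c.width, k=300.0, t=1e9, rho=5.0)
        for h in (1, 2, 3):
            assert np.linalg.norm(out[h]) == pytest.approx(300.0 * c.width, rel=1e-4)

    def test_coincident_protons_raise(self):
        with pytest.raises(GeometryError):
            noe_pseudo_force(np.zeros((2, 3)), make_noe(), 3.0, 300.0, 50.0, 5.0)


class TestKarplus:
    def test_no_substituents_at_ninety_degrees_gives_p3(self):
        params = (7.0, -1.0, 1.4, 0.0, 0.0, 0.0)
        assert karplus_haasnoot(90.0, (), (), params) == pytest.approx(1.4, abs=1e-12)

    def test_even_without_substituent_terms(self, rng):
        params = HAASNOOT_PARAMS["hla-3sub"]
        phi = rng.uniform(-180, 180, size=50)
        assert np.allclose(
            karplus_haasnoot(phi, (), (), params), karplus_haasnoot(-phi, (), (), params)
        )

    def test_anti_larger_than_gauche(self):
        params = HAASNOOT_PARAMS["hla-3sub"]
        assert karplus_haasnoot(180.0, (0.4,) * 3, (1, -1, 1), params) > karplus_haasnoot(
            60.0, (0.4,) * 3, (1, -1, 1), params
        )

    def test_substituent_asymmetry_breaks_phi_parity(self):
        dchi, xi = (0.4, 0.4, 0.4, 1.3), (1, -1, 1, -1)
        params = HAASNOOT_PARAMS["hla-4sub"]
        a = karplus_haasnoot(60.0, dchi, xi, params)
        b = karplus_haasnoot(-60.0, dchi, xi, params)
        assert abs(a - b) > 1.0


def butane_frame(rng):
    x = np.array([[0.0, 1.0, 0.2], [0.0, 0, 0], [1.5, 0, 0], [1.6, 1.0, 0.9]])
    return x + rng.normal(scale=0.05, size=(4, 3))


def make_j(j_exp=6.0):
    return JConstraint(
        id="j1", path=(0, 1, 2, 3), j_exp=j_exp, error=1.0, width=0.5,
        dchi=(0.4, 1.3), xi=(1, -1), params=HAASNOOT_PARAMS["hla-2sub"],
        paramset="hla-2sub",
    )


class TestJForce:
    def test_zero_at_target(self, rng):
        c = make_j()
        out = j_pseudo_force(butane_frame(rng), c, j_mean=c.j_exp, k=30.0, t=50.0, rho=5.0)
        for f in out.values():
            assert np.allclose(f, 0.0)

    def test_net_force_and_torque_vanish(self, rng):
        c = make_j()
        for _ in range(20):
            x = butane_frame(rng)
            out = j_pseudo_force(x, c, j_mean=9.0, k=30.0, t=50.0, rho=5.0)
            total = sum(out.values())
            assert np.abs(total).max() < 1e-10
            torque = sum(np.cross(x[a], f) for a, f in out.items())
            assert np.abs(torque).max() < 1e-10

    def test_matches_finite_difference_of_tanh_energy(self, rng):
        c = make_j(j_exp=4.0)
        k, t, rho = 30.0, 80.0, 5.0

        def energy(x):
            jv = j_instantaneous(x, c)
            return ramp_factor(t, rho) * k * c.width**2 * np.log(np.cosh((jv - c.j_exp) / c.width))

        h = 1e-6
        for _ in range(10):
            x = butane_frame(rng)
            jv = j_instantaneous(x, c)
            out = j_pseudo_force(x, c, j_mean=jv, k=k, t=t, rho=rho)
            for a, fa in out.items():
                for d in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[a, d] += h
                    xm[a, d] -= h
                    fd = -(energy(xp) - energy(xm)) / (2 * h)
                    assert fd == pytest.approx(fa[d], rel=1e-5, abs=1e-9)

    def test_collinear_path_raises(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1, 0]])
        with pytest.raises(GeometryError):
            j_pseudo_force(x, make_j(), 5.0, 30.0, 50.0, 5.0)
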