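"""SVD alignment-tensor fitting, single structure and multi-conformer."""
import numpy as np
import pytest

from mdoc.rdc import RDCConstraint
from mdoc.saupe import (
    UnderdeterminedError,
    direction_cosine_matrix,
    fit_saupe,
    multi_conformer_fit,
    population_grid,
)

from test_rdc import random_rotation


def rigid_structure(rng, n=8):
    return rng.normal(size=(n, 3)) * 2.0


def make_rdcs(structure, saupe, d_stat=20000.0, noise=0.0, rng=None):
    """Forward-model RDCs from a Saupe component vector."""
    cons = []
    n = len(structure)
    pairs = [(i, (i + 1) % n) for i in range(n)]
    for idx, (i, j) in enumerate(pairs):
        c = RDCConstraint(
            id=f"r{idx}", atoms=(i, j), d_exp=1.0, error=1.0, d_stat=d_stat
        )
        cons.append(c)
    a = direction_cosine_matrix(structure, cons)
    vals = a @ np.asarray(saupe)
    if noise and rng is not None:
        vals = vals + rng.normal(scale=noise, size=len(vals))
    for c, v in zip(cons, vals):
        c.d_exp = float(v)
    return cons


SAUPE = np.array([6e-4, 2.5e-4, -1e-4, 1.5e-4, 0.8e-4])


class TestCoefficientMatrix:
    def test_vector_along_z_couples_only_to_szz(self):
        x = np.array([[0.0, 0, 1.0], [0.0, 0, 0]])
        c = RDCConstraint(id="r", atoms=(0, 1), d_exp=0.0, error=1.0, d_stat=10.0)
        row = direction_cosine_matrix(x, [c])[0]
        assert np.allclose(row, [10.0, 0, 0, 0, 0], atol=1e-12)

    def test_duplicated_vector_keeps_rank(self, rng):
        x = rigid_structure(rng)
        cons = make_rdcs(x, SAUPE)
        a1 = direction_cosine_matrix(x, cons)
        a2 = direction_cosine_matrix(x, cons + [cons[0]])
        assert np.linalg.matrix_rank(a1) == np.linalg.matrix_rank(a2)

    def test_rank_at_most_five(self, rng):
        x = rigid_structure(rng, n=12)
        a = direction_cosine_matrix(x, make_rdcs(x, SAUPE))
        assert np.linalg.matrix_rank(a) <= 5


class TestFitSaupe:
    def test_roundtrip_recovery_from_noiseless_data(self, rng):
        x = rigid_structure(rng)
        fit = fit_saupe(x, make_rdcs(x, SAUPE))
        assert np.allclose(fit.components, SAUPE, atol=1e-8 * np.abs(SAUPE).max())
        assert fit.q == pytest.approx(0.0, abs=1e-10)
        assert fit.quality > 1e10  # chi2 at roundoff level

    def test_self_fit_on_back_calculated_values(self, rng):
        x = rigid_structure(rng)
        cons = make_rdcs(x, SAUPE, noise=0.5, rng=rng)
        first = fit_saupe(x, cons)
        for c, v in zip(cons, first.back_calculated):
            c.d_exp = float(v)
        again = fit_saupe(x, cons)
        assert again.q < 1e-10
        assert again.quality > 1e10

    def test_underdetermined_raises(self, rng):
        x = rigid_structure(rng)
        with pytest.raises(UnderdeterminedError):
            fit_saupe(x, make_rdcs(x, SAUPE)[:4])

    def test_coplanar_vectors_ill_conditioned(self, rng):
        flat = rigid_structure(rng)
        flat[:, 2] = 0.0
        fit_flat = fit_saupe(flat, make_rdcs(flat, SAUPE))
        fit_3d = fit_saupe(x3 := rigid_structure(rng), make_rdcs(x3, SAUPE))
        assert fit_flat.condition_number > 10 * fit_3d.condition_number

    def test_saupe_matrix_symmetric_traceless(self, rng):
        x = rigid_structure(rng)
        fit = fit_saupe(x, make_rdcs(x, SAUPE, noise=0.3, rng=rng))
        m = fit.saupe_matrix
        assert np.allclose(m, m.T)
        assert abs(np.trace(m)) < 1e-15

    def test_q_invariant_under_global_rotation(self, rng):
        x = rigid_structure(rng)
        cons = make_rdcs(x, SAUPE, noise=0.5, rng=rng)
        q1 = fit_saupe(x, cons).q
        q2 = fit_saupe(x @ random_rotation(rng).T, cons).q
        assert q1 == pytest.approx(q2, rel=1e-8)


class TestMultiConformer:
    def test_grid_covers_simplex(self):
        grid = population_grid(3, step=0.05)
        arr = np.array(grid)
        assert np.allclose(arr.sum(axis=1), 1.0)
        assert any(np.allclose(g, [1, 0, 0]) for g in grid)

    def test_single_conformer_truth_recovered(self, rng):
        x1 = rigid_structure(rng)
        x2 = rigid_structure(rng)
        cons = make_rdcs(x1, SAUPE)
        fit = multi_conformer_fit([x1, x2], cons)
        assert fit.populations[0] == pytest.approx(1.0)
        assert fit.chi2 == pytest.approx(fit_saupe(x1, cons).chi2, abs=1e-10)

    def test_sixty_forty_population_recovery(self, rng):
        x1 = rigid_structure(rng)
        x2 = rigid_structure(rng)
        cons = make_rdcs(x1, SAUPE)
        a1 = direction_cosine_matrix(x1, cons)
        a2 = direction_cosine_matrix(x2, cons)
        vals = (0.6 * a1 + 0.4 * a2) @ SAUPE
        for c, v in zip(cons, vals):
            c.d_exp = float(v)
        fit = multi_conformer_fit([x1, x2], cons, step=0.05)
        assert fit.populations[0] == pytest.approx(0.6, abs=0.05 + 1e-9)

    def test_identical_conformers_flat_landscape(self, rng):
        x = rigid_structure(rng)
        cons = make_rdcs(x, SAUPE, noise=0.4, rng=rng)
        from mdoc.saupe import _solve

        mats = [direction_cosine_matrix(x, cons)] * 2
        chi2s = []
        for pops in ([1.0, 0.0], [0.5, 0.5], [0.0, 1.0]):
            a = np.tensordot(pops, mats, axes=1)
            chi2s.append(_solve(a, cons, None, False).chi2)
        assert np.ptp(chi2s) < 1e-10

    def test_multi_fit_at_least_as_good_as_best_single(self, rng):
        x1, x2 = rigid_structure(rng), rigid_structure(rng)
        cons = make_rdcs(x1, SAUPE, noise=1.0, rng=rng)
        best_single = min(fit_saupe(x1, cons).chi2, fit_saupe(x2, cons).chi2)
        assert multi_conformer_fit([x1, x2], cons).chi2 <= best_single + 1e-9
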