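"""Classical alignment-tensor (Saupe) fitting by SVD.

The comparison baseline for the restrained-dynamics approach: the measured
RDCs of a rigid structure are linear in the five independent components of
the Saupe order matrix,

    D_i = D_stat,i * (u^T A u)_i,

so a least-squares fit (via singular-value decomposition) determines A and
back-predicts all couplings.  Component ordering throughout is
(S_zz, S_xx - S_yy, S_xy, S_xz, S_yz).  The multi-conformer variant
averages the coefficient rows with population weights under one common
tensor and scans populations on a simplex grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .geometry import GeometryError
from .quality import fidelity, outlier_criterion, chi2_quality, q_factor


class UnderdeterminedError(ValueError):
    """Fewer RDCs than Saupe components."""


@dataclass
class SaupeFit:
    components: np.ndarray  # (Szz, Sxx-Syy, Sxy, Sxz, Syz)
    back_calculated: np.ndarray
    q: float
    chi2: float
    quality: float
    outlier_crit: float
    fidelity: float
    singular_values: np.ndarray
    condition_number: float
    populations: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    @property
    def saupe_matrix(self) -> np.ndarray:
        a, b, c, d, e = self.components
        return np.array(
            [
                [(b - a) / 2.0, c, d],
                [c, -(a + b) / 2.0, e],
                [d, e, a],
            ]
        )


def _unit_vectors(structure, rdc_list):
    x = getattr(structure, "coords", structure)
    out = []
    for c in rdc_list:
        pairs = np.atleast_2d(np.asarray(c.atoms, dtype=int))
        us = []
        for i, j in pairs:
            v = x[i] - x[j]
            r = np.linalg.norm(v)
            if r < 1e-8:
                raise GeometryError(f"{c.id}: zero-length vector")
            us.append(v / r)
        out.append(np.array(us))
    return out


def direction_cosine_matrix(structure, rdc_list) -> np.ndarray:
    """n x 5 coefficient matrix; row i gives D_i as coefficients . components.

    Methyl-averaged constraints contribute the mean row over their three
    C-H vectors.
    """
    if not rdc_list:
        raise ValueError("need at least one RDC")
    rows = []
    for c, us in zip(rdc_list, _unit_vectors(structure, rdc_list)):
        row = np.zeros(5)
        for u in us:
            ux, uy, uz = u
            row += np.array(
                [
                    (3.0 * uz * uz - 1.0) / 2.0,
                    (ux * ux - uy * uy) / 2.0,
                    2.0 * ux * uy,
                    2.0 * ux * uz,
                    2.0 * uy * uz,
                ]
            )
        rows.append(c.d_stat * row / len(us))
    return np.array(rows)


def fit_saupe(structure, rdcs, errors=None, weighted=False) -> SaupeFit:
    """Least-squares Saupe fit of one structure to its RDC list."""
    if len(rdcs) < 5:
        raise UnderdeterminedError(
            f"{len(rdcs)} RDCs cannot determine 5 Saupe components"
        )
    a_mat = direction_cosine_matrix(structure, rdcs)
    return _solve(a_mat, rdcs, errors, weighted)


def _solve(a_mat, rdcs, errors, weighted, populations=None):
    d_exp = np.array([c.d_exp for c in rdcs])
    err = np.array([c.error for c in rdcs]) if errors is None else np.asarray(errors)
    a_w, d_w = (a_mat / err[:, None], d_exp / err) if weighted else (a_mat, d_exp)
    u, s, vt = np.linalg.svd(a_w, full_matrices=False)
    warnings_ = []
    tol = 1e-10 * s.max()
    rank = int(np.sum(s > tol))
    if rank < 5:
        warnings_.append(f"rank-deficient coefficient matrix (rank {rank})")
    s_inv = np.where(s > tol, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    comps = vt.T @ (s_inv * (u.T @ d_w))
    back = a_mat @ comps
    chi2, qual = chi2_quality(back, d_exp, err)
    fid, _ = fidelity(back, d_exp, err, [c.id for c in rdcs])
    cond = s.max() / s.min() if s.min() > 0 else np.inf
    return SaupeFit(
        components=comps,
        back_calculated=back,
        q=q_factor(back, d_exp),
        chi2=chi2,
        quality=qual,
        outlier_crit=outlier_criterion(back, d_exp, err),
        fidelity=fid,
        singular_values=s,
        condition_number=cond,
        populations=populations,
        warnings=warnings_,
    )


def population_grid(n_conformers: int, step: float = 0.05):
    """All population vectors on the simplex with the given grid step."""
    m = int(round(1.0 / step))
    grid = []
    for combo in product(range(m + 1), repeat=n_conformers - 1):
        if sum(combo) <= m:
            rest = m - sum(combo)
            grid.append(np.array([*combo, rest]) / m)
    return grid


def multi_conformer_fit(structures, rdcs, errors=None, step=0.05, weighted=False) -> SaupeFit:
    """Common-tensor fit with population-weighted coefficient rows.

    Scans the population simplex on a grid (default step 0.05) and
    returns the best fit by chi2 together with its populations.
    """
    if len(structures) < 2:
        raise ValueError("need at least two conformers")
    if len(rdcs) < 5:
        raise UnderdeterminedError(
            f"{len(rdcs)} RDCs cannot determine 5 Saupe components"
        )
    mats = [direction_cosine_matrix(s, rdcs) for s in structures]
    best = None
    for pops in population_grid(len(structures), step):
        a_mat = np.tensordot(pops, mats, axes=1)
        fit = _solve(a_mat, rdcs, errors, weighted, populations=pops)
        if best is None or fit.chi2 < best.chi2 - 1e-12:
            best = fit
    return best
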