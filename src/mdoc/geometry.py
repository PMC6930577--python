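"""Vectorized internal-coordinate geometry: distances, angles, dihedrals
and their analytic Cartesian gradients.

All functions accept coordinate arrays of shape (n_atoms, 3) plus integer
index arrays and are fully vectorized over the terms they evaluate.
Dihedral angles follow the right-handed IUPAC convention: cis = 0,
trans = 180 deg, values in (-180, 180].
"""
from __future__ import annotations

import numpy as np


class GeometryError(ValueError):
    """Degenerate geometry (coincident atoms, collinear dihedral axis)."""


def bond_vectors(coords: np.ndarray, i: np.ndarray, j: np.ndarray):
    """Return (r_ij vectors, lengths) for atom index arrays i, j."""
    v = coords[i] - coords[j]
    r = np.linalg.norm(v, axis=-1)
    return v, r


def unit_vectors(coords: np.ndarray, i: np.ndarray, j: np.ndarray, min_r: float = 1e-8):
    v, r = bond_vectors(coords, i, j)
    if np.any(r < min_r):
        raise GeometryError("coincident atoms in vector evaluation")
    return v / r[..., None], r


def angle_values(coords, i, j, k):
    """Bond angles i-j-k in radians, vectorized."""
    u1, _ = unit_vectors(coords, np.asarray(i), np.asarray(j))
    u2, _ = unit_vectors(coords, np.asarray(k), np.asarray(j))
    c = np.clip(np.einsum("...d,...d->...", u1, u2), -1.0, 1.0)
    return np.arccos(c)


def angle_gradients(coords, i, j, k):
    """Angles theta_ijk (rad) and gradients d(theta)/dx on atoms i, j, k.

    Returns (theta, gi, gj, gk) with gradient arrays shaped like coords[i].
    """
    u1, r1 = unit_vectors(coords, np.asarray(i), np.asarray(j))
    u2, r2 = unit_vectors(coords, np.asarray(k), np.asarray(j))
    c = np.clip(np.einsum("...d,...d->...", u1, u2), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
    gi = -(u2 - c[..., None] * u1) / (r1 * s)[..., None]
    gk = -(u1 - c[..., None] * u2) / (r2 * s)[..., None]
    gj = -(gi + gk)
    return theta, gi, gj, gk


def dihedral_values(coords, i, j, k, l):
    """Signed dihedral angles (radians, (-pi, pi]) for paths i-j-k-l."""
    phi, _ = _dihedral_core(coords, i, j, k, l, want_grad=False)
    return phi


def dihedral_gradients(coords, i, j, k, l):
    """Dihedrals and analytic gradients on the four path atoms.

    Returns (phi, g1, g2, g3, g4); the gradients sum to zero and exert
    zero net torque, a consequence of phi being invariant under rigid
    motion.
    """
    return _dihedral_core(coords, i, j, k, l, want_grad=True)


def _dihedral_core(coords, i, j, k, l, want_grad):
    i, j, k, l = (np.asarray(a) for a in (i, j, k, l))
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    n1sq = np.einsum("...d,...d->...", n1, n1)
    n2sq = np.einsum("...d,...d->...", n2, n2)
    if np.any(nb2 < 1e-8) or np.any(n1sq < 1e-16) or np.any(n2sq < 1e-16):
        raise GeometryError("collinear atoms: dihedral undefined")
    x = np.einsum("...d,...d->...", n1, n2)
    y = np.einsum("...d,...d->...", np.cross(n1, n2), b2 / nb2[..., None])
    phi = np.arctan2(y, x)
    if not want_grad:
        return phi, None
    g1 = -(nb2 / n1sq)[..., None] * n1
    g4 = (nb2 / n2sq)[..., None] * n2
    c1 = (np.einsum("...d,...d->...", b1, b2) / nb2**2)[..., None]
    c3 = (np.einsum("...d,...d->...", b3, b2) / nb2**2)[..., None]
    g2 = -(1.0 + c1) * g1 + c3 * g4
    g3 = c1 * g1 - (1.0 + c3) * g4
    return phi, g1, g2, g3, g4
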