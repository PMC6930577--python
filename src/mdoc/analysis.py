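"""Trajectory ensemble analysis: torsion statistics, rotamer populations
and principal component analysis on dihedral angles (dPCA).

Rotamer nomenclature for a three-state rotor: trans for |omega| >= 120
deg, gauche(+) for 0 < omega < 120, gauche(-) for -120 < omega <= 0.

dPCA respects the circular topology of torsion angles by mapping each
angle to the unit complex number exp(i phi) before computing the
(Hermitian) covariance matrix; component contributions are the moduli of
the eigenvector entries, and projecting a snapshot onto eigenvector n
yields a single angular value theta_n = arg(sum_j v*_nj exp(i phi_j)).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import dihedral_values


@dataclass
class RotamerStats:
    angles_deg: np.ndarray
    bin_width: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    fractions: dict  # {"trans", "gauche-", "gauche+"}


@dataclass
class DPCAResult:
    eigenvalues: np.ndarray  # descending, >= 0
    eigenvectors: np.ndarray  # rows = components, complex
    contributions: np.ndarray  # moduli per component (rows), unit norm
    theta_deg: np.ndarray  # (n_components, n_snapshots) projection angles


def torsion_series(trajectory, definition) -> np.ndarray:
    """Signed dihedral series (degrees, (-180, 180]) over a trajectory.

    ``trajectory`` may be a TrajectoryEnsemble or an (n_frames, n_atoms, 3)
    array; ``definition`` the four atom indices.  No unwrapping is applied.
    """
    coords = trajectory if isinstance(trajectory, np.ndarray) else trajectory.coords_array()
    i, j, k, l = (int(a) for a in definition)
    # transpose so integer indexing selects atoms while keeping frames
    phi = dihedral_values(coords.transpose(1, 0, 2), i, j, k, l)
    deg = np.rad2deg(phi)
    # fold -180 into +180 to keep the half-open convention
    deg = np.where(deg <= -180.0 + 1e-12, 180.0, deg)
    return deg


def rotamer_populations(angles_deg, bin_width: float = 5.0) -> RotamerStats:
    """Histogram and three-state fractions of a torsion-angle series."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle series")
    trans = np.abs(a) >= 120.0
    gplus = (a > 0.0) & (a < 120.0)
    gminus = (a > -120.0) & (a <= 0.0)
    n = a.size
    fractions = {
        "trans": float(trans.sum()) / n,
        "gauche-": float(gminus.sum()) / n,
        "gauche+": float(gplus.sum()) / n,
    }
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    hist, edges = np.histogram(a, bins=edges)
    return RotamerStats(a, bin_width, hist, edges, fractions)


def dpca(angle_matrix_deg) -> DPCAResult:
    """Complex-plane principal component analysis of dihedral angles.

    ``angle_matrix_deg`` has shape (n_snapshots, n_dihedrals).  Each angle
    is mapped to exp(i phi); the mean-centered Hermitian covariance is
    diagonalized, eigenvalues are returned in descending order, and their
    sum equals the total variance of the transformed circular variables.
    """
    a = np.asarray(angle_matrix_deg, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 1:
        raise ValueError("need >= 2 snapshots and >= 1 dihedral")
    z = np.exp(1j * np.deg2rad(a))
    dz = z - z.mean(axis=0)
    total_var = float(np.mean(np.abs(dz) ** 2, axis=0).sum())
    if total_var < 1e-14:
        raise ValueError("constant angle matrix: empty spectrum")
    cov = (dz.conj().T @ dz) / a.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order].real, 0.0)
    vecs = vecs[:, order].T  # rows are components
    theta = np.angle(z @ vecs.conj().T).T  # (n_comp, n_snap)
    return DPCAResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        contributions=np.abs(vecs),
        theta_deg=np.rad2deg(theta),
    )
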