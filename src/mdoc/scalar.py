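"""NOE distance and vicinal-coupling restraints.

NOE cross-relaxation distances are averaged as r_bar = <r^-6>^(-1/6) with
the same exponential-memory mean used for the tensors; the r^-6 weighting
makes transient close approaches dominate, as appropriate for a rigid
isotropically reorienting pair.  Vicinal proton-proton couplings are
back-calculated from the intervening H-C-C-H torsion with the
electronegativity-corrected Karplus relation of Haasnoot/Altona,

    J(phi) = P1 cos^2 phi + P2 cos phi + P3
             + sum_i dchi_i * [P4 + P5 cos^2(xi_i phi + P6 |dchi_i|)],

where dchi_i are substituent electronegativity differences relative to
hydrogen and xi_i = +/-1 encodes the substituent orientation.  The
expected accuracy of this relation is about 0.6 Hz RMS, which is why
1.0 Hz is a sensible default experimental error for 3J data.

Both restraint types apply tanh-capped central/chain-rule forces from the
mismatch of the memory mean with the experimental target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import MemoryState, ramp_factor
from .geometry import GeometryError, dihedral_gradients, dihedral_values
from .rdc import ConstraintError, tanh_scale

#: Published Haasnoot-de Leeuw-Altona style parameter sets (P1..P6, P6 in
#: degrees), keyed by substitution class; parameters are data, not code.
HAASNOOT_PARAMS = {
    # plain Karplus limit (no substituent correction)
    "karplus": (9.5, -1.0, 1.4, 0.0, 0.0, 0.0),
    "hla-2sub": (13.89, -0.98, 0.0, 1.02, -3.40, 14.9),
    "hla-3sub": (13.22, -0.99, 0.0, 0.87, -2.46, 19.9),
    "hla-4sub": (13.24, -0.91, 0.0, 0.53, -2.41, 15.5),
}


@dataclass
class NOEConstraint:
    """Interproton distance target (Å).

    ``atom_i`` is a proton index; ``partners`` one proton or the three
    protons of a methyl group.  For a methyl partner the identical
    constraint applies to all three protons with the full force on each;
    the averaged observable pools r^-6 over the listed protons.
    """

    id: str
    atom_i: int
    partners: tuple
    target: float
    error: float
    width: float = 0.25
    names: tuple = field(default=())

    def __post_init__(self):
        if self.target <= 0:
            raise ConstraintError(f"{self.id}: target distance must be positive")
        if self.error <= 0:
            raise ConstraintError(f"{self.id}: error must be positive")
        self.partners = tuple(int(p) for p in np.atleast_1d(self.partners))
        if len(self.partners) not in (1, 3):
            raise ConstraintError(f"{self.id}: partners must be one proton or a methyl triple")
        if self.atom_i in self.partners:
            raise ConstraintError(f"{self.id}: self-distance")


@dataclass
class JConstraint:
    """Vicinal 3J(H,H) coupling constraint over an H-C-C-H path."""

    id: str
    path: tuple
    j_exp: float
    error: float
    width: float = 0.5
    dchi: tuple = ()
    xi: tuple = ()
    params: tuple = HAASNOOT_PARAMS["hla-3sub"]
    paramset: str = "hla-3sub"
    names: tuple = field(default=())

    def __post_init__(self):
        if self.error <= 0:
            raise ConstraintError(f"{self.id}: error must be positive")
        if len(set(self.path)) != 4:
            raise ConstraintError(f"{self.id}: path must name four distinct atoms")
        if len(self.dchi) != len(self.xi):
            raise ConstraintError(f"{self.id}: dchi and xi lists must pair up")
        if any(abs(x) != 1 for x in self.xi):
            raise ConstraintError(f"{self.id}: xi entries must be +1 or -1")
        if len(self.params) != 6:
            raise ConstraintError(f"{self.id}: parameter set needs P1..P6")


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def noe_mean_distance(mem: MemoryState) -> float:
    """r_bar = <r^-6>^(-1/6) from a memory accumulator fed with r^-6."""
    m = float(mem.mean)
    if m <= 0:
        raise GeometryError("non-positive r^-6 mean")
    return m ** (-1.0 / 6.0)


def karplus_haasnoot(phi_deg, dchi=(), xi=(), params=HAASNOOT_PARAMS["hla-3sub"]):
    """3J(H,H) in Hz from the torsion phi (degrees), vectorized in phi."""
    p1, p2, p3, p4, p5, p6 = params
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    c = np.cos(phi)
    j = p1 * c * c + p2 * c + p3
    for dx, sign in zip(dchi, xi):
        arg = sign * phi + np.deg2rad(p6 * abs(dx))
        j = j + dx * (p4 + p5 * np.cos(arg) ** 2)
    return j


def karplus_haasnoot_derivative(phi_deg, dchi=(), xi=(), params=HAASNOOT_PARAMS["hla-3sub"]):
    """dJ/dphi in Hz/radian at phi (degrees), vectorized."""
    p1, p2, p3, p4, p5, p6 = params
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    c, s = np.cos(phi), np.sin(phi)
    dj = -2.0 * p1 * c * s - p2 * s
    for dx, sign in zip(dchi, xi):
        arg = sign * phi + np.deg2rad(p6 * abs(dx))
        dj = dj - dx * p5 * 2.0 * np.cos(arg) * np.sin(arg) * sign
    return dj


# ---------------------------------------------------------------------------
# pseudo-forces
# ---------------------------------------------------------------------------

def noe_pseudo_force(coords, constraint: NOEConstraint, r_bar: float, k: float, t: float, rho: float):
    """Central forces from the mismatch of r_bar with the target distance.

    Returns a dict {atom_index: force vector}.  Attractive when the
    averaged distance exceeds the target, repulsive when it undershoots;
    each listed methyl proton receives the full force along its own
    interproton vector, with the opposite force on the reference proton.
    """
    x = getattr(coords, "coords", coords)
    mag = ramp_factor(t, rho) * k * constraint.width * tanh_scale(
        r_bar - constraint.target, constraint.width
    )
    out = {constraint.atom_i: np.zeros(3)}
    for h in constraint.partners:
        v = x[constraint.atom_i] - x[h]
        r = np.linalg.norm(v)
        if r < 1e-8:
            raise GeometryError(f"{constraint.id}: coincident protons")
        u = v / r
        out[constraint.atom_i] = out[constraint.atom_i] - mag * u
        out[h] = out.get(h, np.zeros(3)) + mag * u
    return out


def j_pseudo_force(coords, constraint: JConstraint, j_mean: float, k: float, t: float, rho: float):
    """Forces on the four path atoms via the chain rule through phi.

    The scalar prefactor couples the tanh-capped mismatch of the
    memory-averaged J with the instantaneous dJ/dphi; the analytic
    dihedral gradient distributes it with zero net force and torque.
    """
    x = getattr(coords, "coords", coords)
    i, j, kk, l = constraint.path
    idx = tuple(np.array([a]) for a in (i, j, kk, l))
    phi, g1, g2, g3, g4 = dihedral_gradients(x, *idx)
    djdphi = karplus_haasnoot_derivative(
        np.rad2deg(phi[0]), constraint.dchi, constraint.xi, constraint.params
    )
    pref = (
        -ramp_factor(t, rho)
        * k
        * constraint.width
        * tanh_scale(j_mean - constraint.j_exp, constraint.width)
        * djdphi
    )
    return {
        i: pref * g1[0],
        j: pref * g2[0],
        kk: pref * g3[0],
        l: pref * g4[0],
    }


def j_instantaneous(coords, constraint: JConstraint) -> float:
    """Instantaneous Haasnoot J (Hz) at the current geometry."""
    x = getattr(coords, "coords", coords)
    idx = tuple(np.array([a]) for a in constraint.path)
    phi = dihedral_values(x, *idx)[0]
    return float(
        karplus_haasnoot(np.rad2deg(phi), constraint.dchi, constraint.xi, constraint.params)
    )
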