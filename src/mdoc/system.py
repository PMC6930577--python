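"""Molecular topology and a lightweight classical force field.

A :class:`MolecularSystem` carries atoms with fixed partial charges,
harmonic bonds and angles, cosine torsions and Lennard-Jones/Coulomb
nonbonded terms.  The restrained-dynamics machinery only requires a force
field good enough to keep covalent geometry and sterics sane in vacuum;
electrostatics uses fixed charges from the topology table.

Energy functional forms (units Å, kJ/mol, degrees in tables, radians
internally):

    E_bond    = 1/2 k_b (r - r0)^2
    E_angle   = 1/2 k_a (theta - theta0)^2
    E_torsion = 1/2 V (1 + cos(n phi - gamma))
    E_LJ      = 4 eps ((sigma/r)^12 - (sigma/r)^6),   r < cutoff
    E_coul    = ke q_i q_j / r

1-2 and 1-3 nonbonded pairs are excluded; 1-4 pairs are scaled.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    GeometryError,
    angle_gradients,
    bond_vectors,
    dihedral_gradients,
)

#: Coulomb constant, kJ mol^-1 Å e^-2
KE_COULOMB = 1389.35458


class TopologyError(ValueError):
    """Invalid or inconsistent topology record."""


@dataclass
class Conformation:
    """Cartesian state of a system at one instant (Å, Å/ps)."""

    time: float
    coords: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.coords)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError("velocities must match coords shape")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.time, self.coords.copy(), self.velocities.copy())


@dataclass
class MolecularSystem:
    """Validated topology plus force-field parameters.

    Index arrays are int arrays; parameter arrays are float.  ``names``
    are free-form atom labels (e.g. ``C1``, ``H12a``) used by constraint
    tables; ``meta`` carries optional annotations (rotor torsions, methyl
    groups) attached by generators.
    """

    elements: list
    names: list
    masses: np.ndarray
    charges: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    bond_idx: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray
    angle_theta0: np.ndarray  # radians
    angle_k: np.ndarray
    torsion_idx: np.ndarray
    torsion_n: np.ndarray
    torsion_gamma: np.ndarray  # radians
    torsion_v: np.ndarray
    scale14: float = 0.5
    cutoff: float = 12.0
    meta: dict = field(default_factory=dict)
    # derived nonbonded pair list
    nb_idx: np.ndarray = None
    nb_scale: np.ndarray = None

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise TopologyError(f"unknown atom name {name!r}") from None

    def bonded_neighbors(self):
        adj = [set() for _ in range(self.n_atoms)]
        for a, b in self.bond_idx:
            adj[a].add(int(b))
            adj[b].add(int(a))
        return adj


def _derive_angles(adj):
    out = []
    for j, nbrs in enumerate(adj):
        nbrs = sorted(nbrs)
        for ai in range(len(nbrs)):
            for bi in range(ai + 1, len(nbrs)):
                out.append((nbrs[ai], j, nbrs[bi]))
    return out


def _derive_torsions(adj, bonds):
    out = []
    for j, k in bonds:
        for i in sorted(adj[j]):
            if i == k:
                continue
            for l in sorted(adj[k]):
                if l == j or l == i:
                    continue
                out.append((i, j, k, l))
    return out


def build_system(topology_table: dict) -> MolecularSystem:
    """Build and validate a :class:`MolecularSystem` from a topology table.

    ``topology_table`` is a mapping with keys ``atoms`` and ``bonds`` and
    optionally ``angles``, ``torsions``, ``scale14``, ``cutoff``, ``meta``.
    Each atom record: name, element, mass, charge, lj_sigma, lj_epsilon.
    Bond record: (i, j, r0, k); angle record: (i, j, k, theta0_deg, k);
    torsion record: (i, j, k, l, n, gamma_deg, barrier).  Angle and
    torsion lists are derived from the bond graph when absent, using
    ``angle_default`` (theta0_deg, k) and ``torsion_default``
    (n, gamma_deg, barrier) entries of the table.
    """
    atoms = topology_table["atoms"]
    n = len(atoms)
    if n == 0:
        raise TopologyError("empty atom list")
    elements = [a["element"] for a in atoms]
    names = [a.get("name", f"{a['element']}{i+1}") for i, a in enumerate(atoms)]
    if len(set(names)) != n:
        raise TopologyError("duplicate atom names in topology")
    masses = np.array([float(a["mass"]) for a in atoms])
    if np.any(masses <= 0):
        bad = names[int(np.argmin(masses))]
        raise TopologyError(f"non-positive mass for atom {bad}")
    charges = np.array([float(a.get("charge", 0.0)) for a in atoms])
    lj_sigma = np.array([float(a.get("lj_sigma", 3.0)) for a in atoms])
    lj_epsilon = np.array([float(a.get("lj_epsilon", 0.1)) for a in atoms])

    def check_idx(rec, k, label):
        idx = tuple(int(x) for x in rec[:k])
        if len(set(idx)) != k:
            raise TopologyError(f"{label} with repeated atom index: {rec}")
        for x in idx:
            if not 0 <= x < n:
                raise TopologyError(f"{label} index {x} out of range: {rec}")
        return idx

    bonds, bond_r0, bond_k = [], [], []
    seen = set()
    for rec in topology_table["bonds"]:
        i, j = check_idx(rec, 2, "bond")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise TopologyError(f"duplicate bond {key}")
        seen.add(key)
        bonds.append((i, j))
        bond_r0.append(float(rec[2]))
        bond_k.append(float(rec[3]))
    if not bonds:
        raise TopologyError("no bonds given")

    adj = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    reach = {0}
    stack = [0]
    while stack:
        for m in adj[stack.pop()]:
            if m not in reach:
                reach.add(m)
                stack.append(m)
    if len(reach) != n:
        missing = [names[i] for i in range(n) if i not in reach][:5]
        raise TopologyError(f"disconnected atoms: {missing}")

    angle_recs = topology_table.get("angles")
    if angle_recs is None:
        t0, ka = topology_table.get("angle_default", (109.47, 400.0))
        angle_recs = [(i, j, k, t0, ka) for i, j, k in _derive_angles(adj)]
    angles, a_t0, a_k = [], [], []
    for rec in angle_recs:
        angles.append(check_idx(rec, 3, "angle"))
        a_t0.append(np.deg2rad(float(rec[3])))
        a_k.append(float(rec[4]))

    torsion_recs = topology_table.get("torsions")
    if torsion_recs is None:
        tn, tg, tv = topology_table.get("torsion_default", (3, 0.0, 4.0))
        torsion_recs = [
            (i, j, k, l, tn, tg, tv) for i, j, k, l in _derive_torsions(adj, bonds)
        ]
    torsions, t_n, t_g, t_v = [], [], [], []
    for rec in torsion_recs:
        torsions.append(check_idx(rec, 4, "torsion"))
        t_n.append(int(rec[4]))
        t_g.append(np.deg2rad(float(rec[5])))
        t_v.append(float(rec[6]))

    sys_ = MolecularSystem(
        elements=elements,
        names=names,
        masses=masses,
        charges=charges,
        lj_sigma=lj_sigma,
        lj_epsilon=lj_epsilon,
        bond_idx=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_r0=np.array(bond_r0),
        bond_k=np.array(bond_k),
        angle_idx=np.array(angles, dtype=int).reshape(-1, 3),
        angle_theta0=np.array(a_t0),
        angle_k=np.array(a_k),
        torsion_idx=np.array(torsions, dtype=int).reshape(-1, 4),
        torsion_n=np.array(t_n, dtype=int),
        torsion_gamma=np.array(t_g),
        torsion_v=np.array(t_v),
        scale14=float(topology_table.get("scale14", 0.5)),
        cutoff=float(topology_table.get("cutoff", 12.0)),
        meta=dict(topology_table.get("meta", {})),
    )
    _build_nonbonded(sys_, adj)
    return sys_


def _build_nonbonded(sys_: MolecularSystem, adj):
    """All-pairs list with 1-2/1-3 exclusion and 1-4 scaling."""
    n = sys_.n_atoms
    # path lengths 1 and 2 excluded, length 3 scaled
    excl = set()
    one4 = set()
    for i in range(n):
        for j in adj[i]:
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
                    for l in adj[k]:
                        if l not in (i, j):
                            one4.add((min(i, l), max(i, l)))
    one4 -= excl
    pairs, scales = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            pairs.append((i, j))
            scales.append(sys_.scale14 if (i, j) in one4 else 1.0)
    sys_.nb_idx = np.array(pairs, dtype=int).reshape(-1, 2)
    sys_.nb_scale = np.array(scales)


def ff_energy_forces(system: MolecularSystem, conformation: Conformation):
    """Total force-field energy (kJ/mol) and forces (kJ/mol/Å).

    Forces are the exact negative gradient of the energy; they sum to
    zero and exert zero net torque for an isolated molecule.
    """
    x = conformation.coords
    forces = np.zeros_like(x)
    energy = 0.0

    if len(system.bond_idx):
        i, j = system.bond_idx[:, 0], system.bond_idx[:, 1]
        v, r = bond_vectors(x, i, j)
        dr = r - system.bond_r0
        energy += 0.5 * np.sum(system.bond_k * dr * dr)
        f = (system.bond_k * dr / r)[:, None] * v  # dE/dx_i direction
        np.add.at(forces, i, -f)
        np.add.at(forces, j, f)

    if len(system.angle_idx):
        i, j, k = (system.angle_idx[:, c] for c in range(3))
        theta, gi, gj, gk = angle_gradients(x, i, j, k)
        dth = theta - system.angle_theta0
        energy += 0.5 * np.sum(system.angle_k * dth * dth)
        pref = (system.angle_k * dth)[:, None]
        np.add.at(forces, i, -pref * gi)
        np.add.at(forces, j, -pref * gj)
        np.add.at(forces, k, -pref * gk)

    if len(system.torsion_idx):
        i, j, k, l = (system.torsion_idx[:, c] for c in range(4))
        phi, g1, g2, g3, g4 = dihedral_gradients(x, i, j, k, l)
        arg = system.torsion_n * phi - system.torsion_gamma
        energy += 0.5 * np.sum(system.torsion_v * (1.0 + np.cos(arg)))
        dEdphi = -0.5 * system.torsion_v * system.torsion_n * np.sin(arg)
        pref = dEdphi[:, None]
        np.add.at(forces, i, -pref * g1)
        np.add.at(forces, j, -pref * g2)
        np.add.at(forces, k, -pref * g3)
        np.add.at(forces, l, -pref * g4)

    if len(system.nb_idx):
        i, j = system.nb_idx[:, 0], system.nb_idx[:, 1]
        v, r = bond_vectors(x, i, j)
        if np.any(r < 0.1):
            worst = int(np.argmin(r))
            raise GeometryError(
                f"nonbonded overlap: atoms {i[worst]}-{j[worst]} at r={r[worst]:.3f} Å"
            )
        mask = r < system.cutoff
        sig = 0.5 * (system.lj_sigma[i] + system.lj_sigma[j])
        eps = np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j]) * system.nb_scale
        sr6 = np.where(mask, (sig / r) ** 6, 0.0)
        e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
        qq = KE_COULOMB * system.charges[i] * system.charges[j] * system.nb_scale
        e_c = np.where(mask, qq / r, 0.0)
        energy += np.sum(e_lj) + np.sum(e_c)
        # dE/dr
        dEdr = np.where(mask, -(24.0 * eps * (2.0 * sr6 * sr6 - sr6) + e_c) / r, 0.0)
        f = (dEdr / r)[:, None] * v
        np.add.at(forces, i, -f)
        np.add.at(forces, j, f)

    return energy, forces
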