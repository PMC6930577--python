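"""Synthetic study systems with known ground truth.

The flagship object is a two-fragment "single-rotor" molecule, a
2,3-dimethylbutane-like frame: two semi-rigid CH(CH3)2-type fragments
joined by one soft central C-C bond whose torsion populates the three
staggered rotamers.  A reference ensemble with prescribed rotamer
populations is drawn from von-Mises mixtures on that torsion; from it,
"experimental" constraint tables are forward-modeled:

* RDCs from an imposed common Saupe tensor (the very simplification that
  breaks down under strong shape-alignment coupling -- recovery failures
  in that regime are expected behavior of the forward model, not bugs),
* NOE targets as ensemble <r^-6>^(-1/6),
* vicinal couplings as ensemble-averaged Karplus values,

each with additive Gaussian noise and error columns floored at the
typical experimental estimates (1.0 Hz RDC, 0.5 Å NOE, 1.0 Hz 3J).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DSTAT_CH_SP3, DSTAT_HH_PREF
from .engine import Snapshot, TrajectoryEnsemble
from .rdc import RDCConstraint
from .restraints import ConstraintSet
from .scalar import HAASNOOT_PARAMS, JConstraint, NOEConstraint, karplus_haasnoot
from .system import Conformation, MolecularSystem, build_system
from .analysis import torsion_series, rotamer_populations

ROTAMER_CENTERS = {"trans": 180.0, "gauche-": -60.0, "gauche+": 60.0}

#: default per-type noise sigmas and error floors
NOISE_DEFAULTS = {"rdc": 0.3, "noe": 0.1, "j": 0.3}
ERROR_FLOORS = {"rdc": 1.0, "noe": 0.5, "j": 1.0}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    kind: str = "single-rotor"
    populations: dict = field(
        default_factory=lambda: {"trans": 0.7, "gauche-": 0.3, "gauche+": 0.0}
    )
    saupe: tuple = (8.0e-4, 3.0e-4, 2.0e-4, -1.5e-4, 1.0e-4)
    noise: dict = field(default_factory=lambda: dict(NOISE_DEFAULTS))
    seed: int = 0
    n_frames: int = 10000

    def __post_init__(self):
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise sigmas must be non-negative")


# ---------------------------------------------------------------------------
# toy molecule construction
# ---------------------------------------------------------------------------

def _subst_dirs(along, angle_deg, azimuths_deg):
    """Unit directions at a given angle from ``along`` at given azimuths."""
    along = along / np.linalg.norm(along)
    ref = np.zeros(3)
    ref[np.argmin(np.abs(along))] = 1.0
    ex = ref - np.dot(ref, along) * along
    ex /= np.linalg.norm(ex)
    ey = np.cross(along, ex)
    a = np.deg2rad(angle_deg)
    out = []
    for az in np.deg2rad(np.asarray(azimuths_deg, dtype=float)):
        out.append(np.cos(a) * along + np.sin(a) * (np.cos(az) * ex + np.sin(az) * ey))
    return out


def _build_single_rotor():
    r_cc, r_ch = 1.53, 1.09
    pos = {}
    pos["C2"] = np.zeros(3)
    pos["C3"] = np.array([r_cc, 0.0, 0.0])
    # substituents on C2 point away from C3 (+x); on C3 away from C2 (-x)
    d2 = _subst_dirs(np.array([-1.0, 0.0, 0.0]), 69.0, [90.0, 210.0, 330.0])
    for name, d, r in zip(["C1", "C5", "H2"], d2, [r_cc, r_cc, r_ch]):
        pos[name] = pos["C2"] + r * d
    d3 = _subst_dirs(np.array([1.0, 0.0, 0.0]), 69.0, [90.0, 210.0, 330.0])
    for name, d, r in zip(["C4", "C6", "H3"], d3, [r_cc, r_cc, r_ch]):
        pos[name] = pos["C3"] + r * d
    # methyl hydrogens
    methyls = {"C1": "C2", "C5": "C2", "C4": "C3", "C6": "C3"}
    for me, parent in methyls.items():
        axis = pos[me] - pos[parent]
        dirs = _subst_dirs(axis, 69.5, [0.0, 120.0, 240.0])
        for tag, d in zip("abc", dirs):
            pos[f"H{me[1]}{tag}"] = pos[me] + r_ch * d
    names = list(pos)
    idx = {n: i for i, n in enumerate(names)}

    bonds = []
    bond_names = [("C2", "C3"), ("C2", "C1"), ("C2", "C5"), ("C2", "H2"),
                  ("C3", "C4"), ("C3", "C6"), ("C3", "H3")]
    for me in methyls:
        for tag in "abc":
            bond_names.append((me, f"H{me[1]}{tag}"))
    for a, b in bond_names:
        heavy = a.startswith("C") and b.startswith("C")
        bonds.append((idx[a], idx[b], r_cc if heavy else r_ch, 2100.0 if heavy else 1500.0))

    # angle terms for every connected triple, parameters by element types
    adj = [set() for _ in names]
    for i, j, *_ in bonds:
        adj[i].add(j)
        adj[j].add(i)
    angles = []
    for j in range(len(names)):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                ei, ek = names[nb[a]][0], names[nb[b]][0]
                if ei == "C" and ek == "C":
                    t0, ka = 111.0, 450.0
                elif ei == "H" and ek == "H":
                    t0, ka = 108.0, 300.0
                else:
                    t0, ka = 110.0, 350.0
                angles.append((nb[a], j, nb[b], t0, ka))

    # one torsion term per rotatable bond: a soft central rotor, stiff methyls
    soft_barrier, methyl_barrier = 8.0, 18.0
    torsions = [(idx["C1"], idx["C2"], idx["C3"], idx["C4"], 3, 0.0, soft_barrier)]
    for me, parent in methyls.items():
        other = "C3" if parent == "C2" else "C2"
        torsions.append(
            (idx[f"H{me[1]}a"], idx[me], idx[parent], idx[other], 3, 0.0, methyl_barrier)
        )

    atoms = []
    for n in names:
        if n.startswith("C"):
            n_h = sum(1 for m in adj[idx[n]] if names[m].startswith("H"))
            atoms.append(
                dict(name=n, element="C", mass=12.011, charge=-0.03 * n_h,
                     lj_sigma=3.40, lj_epsilon=0.30)
            )
        else:
            atoms.append(
                dict(name=n, element="H", mass=1.008, charge=0.03,
                     lj_sigma=2.45, lj_epsilon=0.06)
            )

    # fragment that rotates with C3 when the central bond turns
    frag_b = [n for n in names if n[1] in "346" and n != "C2"]
    frag_b = [n for n in names if (n[0] == "C" and n[1] in "346") or (n[0] == "H" and n[1] in "346")]
    meta = {
        "kind": "single-rotor",
        "rotor": ("H2", "C2", "C3", "H3"),
        "fragment_b": frag_b,
        "methyls": {me: [f"H{me[1]}{t}" for t in "abc"] for me in methyls},
        "methyl_parents": dict(methyls),
        "protons": [n for n in names if n.startswith("H")],
        "soft_torsion_barrier": soft_barrier,
        "stiff_torsion_barrier": methyl_barrier,
    }
    table = dict(atoms=atoms, bonds=bonds, angles=angles, torsions=torsions, meta=meta)
    system = build_system(table)
    coords = np.array([pos[n] for n in names])
    return system, Conformation(0.0, coords)


def _build_chain():
    """Pentane-like chain with uniformly soft backbone torsions."""
    r_cc, r_ch = 1.53, 1.09
    n_c = 5
    pos = {}
    for i in range(n_c):
        pos[f"C{i+1}"] = np.array(
            [i * r_cc * np.cos(np.deg2rad(15.0)), (i % 2) * r_cc * np.sin(np.deg2rad(31.0)), 0.0]
        )
    names = list(pos)
    # hydrogens to fill valence
    for i in range(n_c):
        c = f"C{i+1}"
        nbrs = [pos[f"C{i}"] - pos[c]] if i > 0 else []
        if i < n_c - 1:
            nbrs.append(pos[f"C{i+2}"] - pos[c])
        n_h = 4 - len(nbrs)
        axis = -sum(nbrs, np.zeros(3))
        axis = axis / np.linalg.norm(axis)
        dirs = _subst_dirs(axis, 0.0, [0.0]) if n_h == 1 else _subst_dirs(
            axis, 54.75 if n_h == 2 else 69.5, [90.0, 270.0] if n_h == 2 else [0.0, 120.0, 240.0]
        )
        for tag, d in zip("abc"[:n_h], dirs):
            pos[f"H{i+1}{tag}"] = pos[c] + r_ch * d
    names = list(pos)
    idx = {n: i for i, n in enumerate(names)}
    bonds = []
    for i in range(n_c - 1):
        bonds.append((idx[f"C{i+1}"], idx[f"C{i+2}"], r_cc, 2100.0))
    for n in names:
        if n.startswith("H"):
            bonds.append((idx[f"C{n[1]}"], idx[n], r_ch, 1500.0))
    atoms = []
    adj = [set() for _ in names]
    for i, j, *_ in bonds:
        adj[i].add(j)
        adj[j].add(i)
    for n in names:
        if n.startswith("C"):
            n_h = sum(1 for m in adj[idx[n]] if names[m].startswith("H"))
            atoms.append(dict(name=n, element="C", mass=12.011, charge=-0.03 * n_h,
                              lj_sigma=3.40, lj_epsilon=0.30))
        else:
            atoms.append(dict(name=n, element="H", mass=1.008, charge=0.03,
                              lj_sigma=2.45, lj_epsilon=0.06))
    table = dict(
        atoms=atoms, bonds=bonds,
        angle_default=(111.0, 400.0), torsion_default=(3, 0.0, 6.0),
        meta={"kind": "chain"},
    )
    # derived angles/torsions use the defaults
    table2 = dict(table)
    system = build_system(table2)
    return system, Conformation(0.0, np.array([pos[n] for n in names]))


def make_toy_molecule(kind: str = "single-rotor"):
    """Build a parametrized toy molecule; returns (system, conformation)."""
    if kind == "single-rotor":
        return _build_single_rotor()
    if kind == "chain":
        return _build_chain()
    raise ValueError(f"unknown toy-molecule kind {kind!r}")


# ---------------------------------------------------------------------------
# reference ensembles
# ---------------------------------------------------------------------------

def _rotation_matrix(axis, angle):
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def set_rotor_angle(system, conformation, phi_deg):
    """Return coordinates with the soft torsion set to ``phi_deg``."""
    names = system.names
    rotor = [system.index_of(n) for n in system.meta["rotor"]]
    frag_b = [system.index_of(n) for n in system.meta["fragment_b"]]
    x = conformation.coords.copy()
    phi0 = torsion_series(x[None], rotor)[0]
    delta = np.deg2rad(phi_deg - phi0)
    axis = x[rotor[2]] - x[rotor[1]]
    rot = _rotation_matrix(axis, delta)
    pivot = x[rotor[1]]
    x[frag_b] = (x[frag_b] - pivot) @ rot.T + pivot
    achieved = torsion_series(x[None], rotor)[0]
    if abs(((achieved - phi_deg + 180) % 360) - 180) > 1e-6:
        rot = _rotation_matrix(axis, -delta)
        x = conformation.coords.copy()
        x[frag_b] = (x[frag_b] - pivot) @ rot.T + pivot
    return x


def generate_reference_ensemble(
    system,
    populations,
    n_frames: int,
    seed: int,
    kappa: float = 25.0,
    jitter: float = 0.02,
    start: Conformation | None = None,
) -> TrajectoryEnsemble:
    """Frames with the soft torsion drawn from a von-Mises mixture.

    States are centered at 180/-60/+60 degrees with concentration
    ``kappa``; all coordinates get Gaussian jitter of width ``jitter`` Å.
    """
    if isinstance(populations, (tuple, list)):
        populations = dict(zip(["trans", "gauche-", "gauche+"], populations))
    weights = np.array([populations.get(k, 0.0) for k in ROTAMER_CENTERS])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("populations must sum to 1")
    if start is None:
        _, start = make_toy_molecule(system.meta.get("kind", "single-rotor"))
    rng = np.random.default_rng(seed)
    centers = np.array(list(ROTAMER_CENTERS.values()))
    states = rng.choice(len(centers), size=n_frames, p=weights)
    angles = np.rad2deg(rng.vonmises(np.deg2rad(centers[states]), kappa))
    snaps = []
    for t, phi in enumerate(angles):
        x = set_rotor_angle(system, start, phi)
        x = x + rng.normal(scale=jitter, size=x.shape)
        snaps.append(Snapshot(float(t), x, {}))
    return TrajectoryEnsemble(
        snaps,
        provenance={"populations": dict(populations), "seed": seed, "kappa": kappa},
    )


# ---------------------------------------------------------------------------
# forward-modeled constraint tables
# ---------------------------------------------------------------------------

def _random_rotations(n: int, rng) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=1,
    )


def _saupe_rdc_mean(coords, pairs, d_stat, saupe) -> float:
    """Ensemble mean of D_stat * (u^T A u), averaged over the listed pairs."""
    vals = np.zeros(len(coords))
    for i, j in pairs:
        v = coords[:, i] - coords[:, j]
        u = v / np.linalg.norm(v, axis=-1, keepdims=True)
        ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
        rows = np.stack(
            [
                (3.0 * uz * uz - 1.0) / 2.0,
                (ux * ux - uy * uy) / 2.0,
                2.0 * ux * uy,
                2.0 * ux * uz,
                2.0 * uy * uz,
            ],
            axis=1,
        )
        vals += rows @ saupe
    return float(d_stat * vals.mean() / len(pairs))


def _default_selections(system):
    meta = system.meta
    methyls = meta["methyls"]
    rdc = [("CH", "C2", "H2"), ("CH", "C3", "H3")]
    rdc += [("CH3", me) for me in methyls]
    rdc += [("HH", "H2", "H3")]
    noe = [
        ("H2", ("H3",)),
        ("H2", tuple(methyls["C4"])),
        ("H2", tuple(methyls["C6"])),
        ("H3", tuple(methyls["C1"])),
        ("H3", tuple(methyls["C5"])),
    ]
    j = [("H2", "C2", "C3", "H3")]
    return rdc, noe, j


def synthesize_constraints(
    ensemble: TrajectoryEnsemble,
    system,
    saupe,
    noise: dict | None = None,
    seed: int = 0,
    selections=None,
    isotropic: bool = False,
) -> ConstraintSet:
    """Forward-model noisy "experimental" tables from a reference ensemble.

    RDCs are ensemble averages of D_stat * (u^T A u) under the imposed
    Saupe components ``saupe``; NOE targets are <r^-6>^(-1/6) ensemble
    means; couplings are ensemble-averaged Karplus values.  With
    ``isotropic=True`` every frame gets an independent uniform rigid
    rotation before the RDC average (driving it to zero).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    noise = {**NOISE_DEFAULTS, **(noise or {})}
    rng = np.random.default_rng(seed)
    coords = ensemble.coords_array()
    if isotropic:
        rots = _random_rotations(len(coords), rng)
        coords = np.einsum("fij,faj->fai", rots, coords)
    sel_rdc, sel_noe, sel_j = selections or _default_selections(system)
    saupe = np.asarray(saupe, dtype=float)

    rdc_constraints = []
    for rec in sel_rdc:
        if rec[0] == "CH":
            _, cn, hn = rec
            ci, hi = system.index_of(cn), system.index_of(hn)
            con = RDCConstraint(
                id=f"rdc_{cn}{hn}", atoms=(ci, hi), d_exp=0.0, error=1.0,
                d_stat=DSTAT_CH_SP3, kind="one-bond", names=(cn, hn),
            )
        elif rec[0] == "CH3":
            me = rec[1]
            ci = system.index_of(me)
            hs = [system.index_of(h) for h in system.meta["methyls"][me]]
            con = RDCConstraint(
                id=f"rdc_{me}H3", atoms=tuple((ci, h) for h in hs), d_exp=0.0,
                error=1.0, d_stat=DSTAT_CH_SP3, kind="methyl", names=(me,),
            )
        else:
            _, an, bn = rec
            ai, bi = system.index_of(an), system.index_of(bn)
            r0 = float(np.linalg.norm(coords[0, ai] - coords[0, bi]))
            con = RDCConstraint(
                id=f"rdc_{an}{bn}", atoms=(ai, bi), d_exp=0.0, error=1.0,
                d_stat=DSTAT_HH_PREF / r0**3, kind="long-range", names=(an, bn),
            )
        pairs = np.atleast_2d(np.asarray(con.atoms, dtype=int))
        d_true = _saupe_rdc_mean(coords, pairs, con.d_stat, saupe)
        con.d_exp = d_true + rng.normal(scale=noise["rdc"])
        con.error = max(noise["rdc"], ERROR_FLOORS["rdc"])
        rdc_constraints.append(con)

    noe_constraints = []
    for an, partners in sel_noe:
        ai = system.index_of(an)
        hs = [system.index_of(h) for h in partners]
        r = np.linalg.norm(coords[:, [ai]] - coords[:, hs], axis=-1)
        r_bar = float(np.mean(r**-6.0)) ** (-1.0 / 6.0)
        noe_constraints.append(
            NOEConstraint(
                id=f"noe_{an}_" + "".join(partners), atom_i=ai, partners=tuple(hs),
                target=max(r_bar + rng.normal(scale=noise["noe"]), 1.5),
                error=max(noise["noe"], ERROR_FLOORS["noe"]),
                names=(an, *partners),
            )
        )

    j_constraints = []
    for path in sel_j:
        idx = [system.index_of(n) for n in path]
        phi = torsion_series(coords, idx)
        # three carbon-like substituents plus one oxygen-like (the toy
        # mimics a carbonyl-bearing fragment); the electronegative group
        # breaks the +/-phi symmetry of the coupling curve
        dchi = (0.4, 0.4, 0.4, 1.3)
        xi = (1, -1, 1, -1)
        params = HAASNOOT_PARAMS["hla-4sub"]
        jvals = karplus_haasnoot(phi, dchi, xi, params)
        j_constraints.append(
            JConstraint(
                id="j_" + "".join(path), path=tuple(idx),
                j_exp=float(jvals.mean()) + rng.normal(scale=noise["j"]),
                error=max(noise["j"], ERROR_FLOORS["j"]),
                dchi=dchi, xi=xi, params=params, paramset="hla-4sub",
                names=tuple(path),
            )
        )

    return ConstraintSet(rdc=rdc_constraints, noe=noe_constraints, j=j_constraints)


def make_study(spec: SyntheticSpec):
    """One-call synthetic study: molecule, reference ensemble, tables.

    Returns (system, start conformation, reference ensemble, constraints).
    """
    system, start = make_toy_molecule(spec.kind)
    ens = generate_reference_ensemble(
        system, spec.populations, spec.n_frames, seed=spec.seed, start=start
    )
    cons = synthesize_constraints(ens, system, spec.saupe, spec.noise, seed=spec.seed + 1)
    return system, start, ens, cons


def reference_populations(ensemble, system) -> dict:
    """Empirical rotamer fractions of the soft torsion in an ensemble."""
    rotor = [system.index_of(n) for n in system.meta["rotor"]]
    series = torsion_series(ensemble.coords_array(), rotor)
    return rotamer_populations(series).fractions
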