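"""File formats: constraint tables (TSV), topology tables, XYZ/PDB
coordinates, flat YAML run configuration, snapshot observable tables and
run manifests.

The native constraint dialect is tab-separated text with ``#`` comment
headers; no community standard exists for mixed RDC/NOE/J tables.  Atom
references are by name and resolved against the topology at read time;
parse errors carry file and line number.
"""
from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .engine import MDOCConfig, Snapshot, TrajectoryEnsemble
from .rdc import RDCConstraint
from .restraints import ConstraintSet
from .scalar import HAASNOOT_PARAMS, JConstraint, NOEConstraint
from .system import Conformation, MolecularSystem, TopologyError, build_system


class TableError(ValueError):
    """Malformed table row, reported as file:line."""


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def write_topology(path, system: MolecularSystem):
    lines = [
        "# mdoc topology table",
        "# atom\tname\telement\tmass\tcharge\tlj_sigma\tlj_epsilon",
        "# bond\tname_i\tname_j\tr0_A\tk_kJ_mol_A2",
        "# angle\tname_i\tname_j\tname_k\ttheta0_deg\tk_kJ_mol_rad2",
        "# torsion\tname_i\tname_j\tname_k\tname_l\tn\tgamma_deg\tbarrier_kJ_mol",
        f"# meta\t{json.dumps(system.meta)}",
        f"# scale14\t{system.scale14}",
        f"# cutoff\t{system.cutoff}",
    ]
    for i, n in enumerate(system.names):
        lines.append(
            f"atom\t{n}\t{system.elements[i]}\t{system.masses[i]:.4f}\t"
            f"{system.charges[i]:.5f}\t{system.lj_sigma[i]:.4f}\t{system.lj_epsilon[i]:.4f}"
        )
    nm = system.names
    for (i, j), r0, k in zip(system.bond_idx, system.bond_r0, system.bond_k):
        lines.append(f"bond\t{nm[i]}\t{nm[j]}\t{r0:.5f}\t{k:.3f}")
    for (i, j, k), t0, ka in zip(system.angle_idx, system.angle_theta0, system.angle_k):
        lines.append(f"angle\t{nm[i]}\t{nm[j]}\t{nm[k]}\t{np.rad2deg(t0):.4f}\t{ka:.3f}")
    for (i, j, k, l), n_, g, v in zip(
        system.torsion_idx, system.torsion_n, system.torsion_gamma, system.torsion_v
    ):
        lines.append(
            f"torsion\t{nm[i]}\t{nm[j]}\t{nm[k]}\t{nm[l]}\t{n_}\t{np.rad2deg(g):.4f}\t{v:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> MolecularSystem:
    atoms, bonds, angles, torsions = [], [], [], []
    meta, scale14, cutoff = {}, 0.5, 12.0
    name_to_idx = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("meta\t") or body.startswith("meta "):
                meta = json.loads(body.split(None, 1)[1])
            elif body.startswith("scale14"):
                scale14 = float(body.split()[1])
            elif body.startswith("cutoff"):
                cutoff = float(body.split()[1])
            continue
        f = line.split("\t")
        try:
            kind = f[0]
            if kind == "atom":
                name_to_idx[f[1]] = len(atoms)
                atoms.append(
                    dict(name=f[1], element=f[2], mass=float(f[3]), charge=float(f[4]),
                         lj_sigma=float(f[5]), lj_epsilon=float(f[6]))
                )
            elif kind == "bond":
                bonds.append((name_to_idx[f[1]], name_to_idx[f[2]], float(f[3]), float(f[4])))
            elif kind == "angle":
                angles.append(
                    (name_to_idx[f[1]], name_to_idx[f[2]], name_to_idx[f[3]],
                     float(f[4]), float(f[5]))
                )
            elif kind == "torsion":
                torsions.append(
                    (name_to_idx[f[1]], name_to_idx[f[2]], name_to_idx[f[3]],
                     name_to_idx[f[4]], int(f[5]), float(f[6]), float(f[7]))
                )
            else:
                raise ValueError(f"unknown record kind {kind!r}")
        except (KeyError, IndexError, ValueError) as exc:
            raise TableError(f"{path}:{ln}: {exc}") from None
    table = dict(atoms=atoms, bonds=bonds, meta=meta, scale14=scale14, cutoff=cutoff)
    if angles:
        table["angles"] = angles
    if torsions:
        table["torsions"] = torsions
    return build_system(table)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def write_xyz(path, coords_or_frames, names, comments=None, mode="w"):
    """Write one frame (n, 3) or many frames (f, n, 3) of XYZ."""
    arr = np.asarray(coords_or_frames, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    with open(path, mode) as fh:
        for fi, frame in enumerate(arr):
            comment = comments[fi] if comments is not None else f"frame {fi}"
            fh.write(f"{len(names)}\n{comment}\n")
            for n, (x, y, z) in zip(names, frame):
                fh.write(f"{n} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Read multi-frame XYZ; returns (frames array, names, comments)."""
    lines = Path(path).read_text().splitlines()
    frames, comments, names = [], [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise TableError(f"{path}:{i+1}: expected atom count") from None
        comments.append(lines[i + 1])
        block = lines[i + 2 : i + 2 + nat]
        if len(block) < nat:
            raise TableError(f"{path}:{i+1}: truncated frame")
        fr_names, xyz = [], []
        for raw in block:
            parts = raw.split()
            fr_names.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if names is None:
            names = fr_names
        frames.append(xyz)
        i += 2 + nat
    return np.array(frames), names, comments


def write_pdb(path, coords, names, elements=None):
    """Minimal single-frame PDB (coordinates in Å, atom order preserved)."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for i, (n, (x, y, z)) in enumerate(zip(names, coords), 1):
            el = (elements[i - 1] if elements else n[0]).rjust(2)
            fh.write(
                f"ATOM  {i:5d} {n:<4.4s} MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el}\n"
            )
        fh.write("END\n")


def read_pdb(path):
    """Read ATOM/HETATM records; returns (coords, names)."""
    names, xyz = [], []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if raw.startswith(("ATOM", "HETATM")):
            try:
                names.append(raw[12:16].strip())
                xyz.append([float(raw[30:38]), float(raw[38:46]), float(raw[46:54])])
            except ValueError:
                raise TableError(f"{path}:{ln}: bad coordinate field") from None
    return np.array(xyz), names


# ---------------------------------------------------------------------------
# constraint tables
# ---------------------------------------------------------------------------

_RDC_HEADER = "# id\tclass\tatom_i\tatom_j\td_exp_hz\terror_hz\twidth_hz\td_stat_hz"
_NOE_HEADER = "# id\tatom_i\tpartners\ttarget_A\terror_A\twidth_A"
_J_HEADER = "# id\tatom1\tatom2\tatom3\tatom4\tj_exp_hz\terror_hz\twidth_hz\tdchi\txi\tparamset"


def write_rdc_table(path, constraints, system):
    lines = ["# mdoc RDC constraints", _RDC_HEADER]
    nm = system.names
    for c in constraints:
        if c.kind == "methyl":
            pairs = np.asarray(c.atoms, dtype=int)
            a_i = nm[pairs[0, 0]]
            a_j = ",".join(nm[h] for h in pairs[:, 1])
        else:
            a_i, a_j = nm[c.atoms[0]], nm[c.atoms[1]]
        lines.append(
            f"{c.id}\t{c.kind}\t{a_i}\t{a_j}\t{c.d_exp:.6f}\t{c.error:.6f}\t"
            f"{c.width:.6f}\t{c.d_stat:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_noe_table(path, constraints, system):
    lines = ["# mdoc NOE constraints", _NOE_HEADER]
    nm = system.names
    for c in constraints:
        lines.append(
            f"{c.id}\t{nm[c.atom_i]}\t{','.join(nm[h] for h in c.partners)}\t"
            f"{c.target:.6f}\t{c.error:.6f}\t{c.width:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_j_table(path, constraints, system):
    lines = ["# mdoc 3J constraints", _J_HEADER]
    nm = system.names
    for c in constraints:
        a = "\t".join(nm[i] for i in c.path)
        lines.append(
            f"{c.id}\t{a}\t{c.j_exp:.6f}\t{c.error:.6f}\t{c.width:.6f}\t"
            f"{','.join(str(v) for v in c.dchi)}\t{','.join(str(int(v)) for v in c.xi)}\t"
            f"{c.paramset}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _iter_rows(path):
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield ln, line.split("\t")


def _resolve(system, name, path, ln):
    try:
        return system.index_of(name)
    except TopologyError:
        raise TableError(f"{path}:{ln}: unknown atom name {name!r}") from None


def read_rdc_table(path, system):
    out = []
    for ln, f in _iter_rows(path):
        try:
            cid, kind, a_i, a_j, d_exp, err, width, d_stat = f
        except ValueError:
            raise TableError(f"{path}:{ln}: expected 8 tab-separated fields") from None
        try:
            if kind == "methyl":
                ci = _resolve(system, a_i, path, ln)
                hs = [_resolve(system, h, path, ln) for h in a_j.split(",")]
                atoms = tuple((ci, h) for h in hs)
                names = (a_i, *a_j.split(","))
            else:
                atoms = (_resolve(system, a_i, path, ln), _resolve(system, a_j, path, ln))
                names = (a_i, a_j)
            out.append(
                RDCConstraint(
                    id=cid, atoms=atoms, d_exp=float(d_exp), error=float(err),
                    d_stat=float(d_stat), width=float(width), kind=kind, names=names,
                )
            )
        except (ValueError, TableError) as exc:
            if isinstance(exc, TableError):
                raise
            raise TableError(f"{path}:{ln}: {exc}") from None
    return out


def read_noe_table(path, system):
    out = []
    for ln, f in _iter_rows(path):
        try:
            cid, a_i, partners, target, err, width = f
        except ValueError:
            raise TableError(f"{path}:{ln}: expected 6 tab-separated fields") from None
        try:
            out.append(
                NOEConstraint(
                    id=cid, atom_i=_resolve(system, a_i, path, ln),
                    partners=tuple(_resolve(system, h, path, ln) for h in partners.split(",")),
                    target=float(target), error=float(err), width=float(width),
                    names=(a_i, *partners.split(",")),
                )
            )
        except (ValueError, TableError) as exc:
            if isinstance(exc, TableError):
                raise
            raise TableError(f"{path}:{ln}: {exc}") from None
    return out


def read_j_table(path, system):
    out = []
    for ln, f in _iter_rows(path):
        try:
            cid, a1, a2, a3, a4, j_exp, err, width, dchi, xi, paramset = f
        except ValueError:
            raise TableError(f"{path}:{ln}: expected 11 tab-separated fields") from None
        if paramset not in HAASNOOT_PARAMS:
            raise TableError(f"{path}:{ln}: unknown parameter set {paramset!r}")
        try:
            out.append(
                JConstraint(
                    id=cid,
                    path=tuple(_resolve(system, a, path, ln) for a in (a1, a2, a3, a4)),
                    j_exp=float(j_exp), error=float(err), width=float(width),
                    dchi=tuple(float(v) for v in dchi.split(",")) if dchi else (),
                    xi=tuple(int(v) for v in xi.split(",")) if xi else (),
                    params=HAASNOOT_PARAMS[paramset], paramset=paramset,
                    names=(a1, a2, a3, a4),
                )
            )
        except (ValueError, TableError) as exc:
            if isinstance(exc, TableError):
                raise
            raise TableError(f"{path}:{ln}: {exc}") from None
    return out


def read_constraint_tables(paths, system) -> ConstraintSet:
    """Read any mix of RDC/NOE/3J tables (recognized by their headers)."""
    cs = ConstraintSet()
    for path in paths:
        head = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
        if not Path(path).exists():
            raise FileNotFoundError(path)
        if "RDC" in head:
            cs.rdc.extend(read_rdc_table(path, system))
        elif "NOE" in head:
            cs.noe.extend(read_noe_table(path, system))
        elif "3J" in head:
            cs.j.extend(read_j_table(path, system))
        else:
            raise TableError(f"{path}:1: unrecognized constraint table header")
    import warnings

    if cs.is_empty():
        warnings.warn("constraint tables are empty")
    return cs


def write_constraint_tables(outdir, constraints: ConstraintSet, system) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["rdc"] = outdir / "rdc.tsv"
    write_rdc_table(paths["rdc"], constraints.rdc, system)
    paths["noe"] = outdir / "noe.tsv"
    write_noe_table(paths["noe"], constraints.noe, system)
    paths["j"] = outdir / "jcoup.tsv"
    write_j_table(paths["j"], constraints.j, system)
    return paths


# ---------------------------------------------------------------------------
# configuration, observables, manifest
# ---------------------------------------------------------------------------

def write_config(path, config: MDOCConfig):
    Path(path).write_text(yaml.safe_dump(config.__dict__, sort_keys=False))


def read_config(path) -> MDOCConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(MDOCConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise TableError(f"{path}: unknown config keys {sorted(unknown)}")
    return MDOCConfig(**data)


def write_observables(path, ensemble: TrajectoryEnsemble):
    """Long-format snapshot observable table.

    Scalar observables fill ``value``; dipolar tensors additionally fill
    the component columns with ``value`` carrying the zz component.
    """
    rows = []
    for s in ensemble.snapshots:
        for cid, v in s.observables.items():
            v = np.asarray(v)
            if v.shape == (3, 3):
                rows.append(
                    dict(time_ps=s.time, id=cid, value=v[2, 2], xx=v[0, 0], yy=v[1, 1],
                         zz=v[2, 2], xy=v[0, 1], xz=v[0, 2], yz=v[1, 2])
                )
            else:
                rows.append(
                    dict(time_ps=s.time, id=cid, value=float(v), xx=np.nan, yy=np.nan,
                         zz=np.nan, xy=np.nan, xz=np.nan, yz=np.nan)
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_observables(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def observables_report(df: pd.DataFrame, constraints: ConstraintSet):
    """Quality report from a snapshot observable table."""
    from .quality import build_report

    means = df.groupby("id")["value"].mean()
    groups = {}
    one = [c for c in constraints.rdc if c.kind in ("one-bond", "methyl")]
    far = [c for c in constraints.rdc if c.kind == "long-range"]
    for name, group, exp, err in (
        ("1D", one, [c.d_exp for c in one], [c.error for c in one]),
        ("nD", far, [c.d_exp for c in far], [c.error for c in far]),
        ("NOE", constraints.noe, [c.target for c in constraints.noe],
         [c.error for c in constraints.noe]),
        ("3J", constraints.j, [c.j_exp for c in constraints.j],
         [c.error for c in constraints.j]),
    ):
        if group:
            groups[name] = (
                [means[c.id] for c in group], exp, err, [c.id for c in group]
            )
    return build_report(groups)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config=None, inputs=(), seed=None, extra=None):
    manifest = {
        "version": _pkg_version,
        "started": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": dict(config.__dict__) if config is not None else None,
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def write_trajectory(outdir, ensemble: TrajectoryEnsemble, system):
    """Multi-frame XYZ plus the observable table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coords = ensemble.coords_array()
    comments = [f"t= {s.time:.4f} ps  E= {s.energy:.4f} kJ/mol" for s in ensemble.snapshots]
    write_xyz(outdir / "trajectory.xyz", coords, system.names, comments)
    write_observables(outdir / "observables.tsv", ensemble)
    return outdir / "trajectory.xyz", outdir / "observables.tsv"
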