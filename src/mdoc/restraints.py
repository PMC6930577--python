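"""Batched evaluation of constraint sets during dynamics.

The per-datum operations live in :mod:`mdoc.rdc` and :mod:`mdoc.scalar`;
these evaluator classes hold the same physics in vectorized form (index
arrays + (n, 3, 3) memory accumulators) so the engine pays a handful of
numpy calls per step instead of a Python loop over constraints.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError
from .rdc import ConstraintError, RDCConstraint, bond_lab_tensors
from .scalar import (
    JConstraint,
    NOEConstraint,
    karplus_haasnoot,
    karplus_haasnoot_derivative,
)
from .geometry import dihedral_gradients

_I3 = np.eye(3)


@dataclass
class ConstraintSet:
    """All restraints of one run, grouped by class."""

    rdc: list = field(default_factory=list)
    noe: list = field(default_factory=list)
    j: list = field(default_factory=list)

    def counts(self) -> dict:
        one = sum(1 for c in self.rdc if c.kind in ("one-bond", "methyl"))
        return {
            "rdc_one_bond": one,
            "rdc_long_range": len(self.rdc) - one,
            "noe": len(self.noe),
            "j": len(self.j),
        }

    def is_empty(self) -> bool:
        return not (self.rdc or self.noe or self.j)

    def all_ids(self):
        return [c.id for c in self.rdc + self.noe + self.j]

    def validate(self, n_atoms: int):
        for c in self.rdc:
            idx = np.asarray(c.atoms).ravel()
            if idx.min() < 0 or idx.max() >= n_atoms:
                raise ConstraintError(f"{c.id}: atom index out of range")
        for c in self.noe:
            idx = np.array([c.atom_i, *c.partners])
            if idx.min() < 0 or idx.max() >= n_atoms:
                raise ConstraintError(f"{c.id}: atom index out of range")
        for c in self.j:
            idx = np.asarray(c.path)
            if idx.min() < 0 or idx.max() >= n_atoms:
                raise ConstraintError(f"{c.id}: atom index out of range")


class RDCEvaluator:
    """Memory-averaged dipolar tensors and orientational pseudo-forces."""

    label = "RDC"

    def __init__(self, constraints, s_am: float, k: float):
        self.k = k
        plain = [c for c in constraints if c.kind != "methyl"]
        methyl = [c for c in constraints if c.kind == "methyl"]
        self.constraints = plain + methyl
        self.n_plain = len(plain)
        self.ids = [c.id for c in self.constraints]
        if plain:
            self.pi = np.array([c.atoms[0] for c in plain])
            self.pj = np.array([c.atoms[1] for c in plain])
        if methyl:
            pairs = np.array([c.atoms for c in methyl], dtype=int)  # (m,3,2)
            self.mc = pairs[:, 0, 0]
            self.mh = pairs[:, :, 1]
        self.n_methyl = len(methyl)
        n = len(self.constraints)
        self.d = np.array([s_am * c.d_stat for c in self.constraints])
        self.width = np.array([c.width for c in self.constraints])
        self.d_exp = np.array([c.d_exp for c in self.constraints])
        self.exp_t = np.array(
            [np.diag([-0.5 * e, -0.5 * e, e]) for e in self.d_exp]
        )
        self.err = np.array([c.error for c in self.constraints])
        self.S = np.zeros((n, 3, 3))
        self.N = np.zeros(n)

    # -- observables -------------------------------------------------
    def instantaneous(self, coords) -> np.ndarray:
        out = np.empty((len(self.constraints), 3, 3))
        if self.n_plain:
            out[: self.n_plain] = bond_lab_tensors(
                coords, self.pi, self.pj, self.d[: self.n_plain]
            )
        if self.n_methyl:
            m = self.n_methyl
            ci = np.repeat(self.mc, 3)
            hi = self.mh.ravel()
            t = bond_lab_tensors(coords, ci, hi, np.repeat(self.d[self.n_plain :], 3))
            out[self.n_plain :] = t.reshape(m, 3, 3, 3).mean(axis=1)
        return out

    def update(self, coords, t, dt, prime=False):
        obs = self.instantaneous(coords)
        decay = np.exp(-dt / self._tau)
        self.N = self.N * decay + dt
        self.S = self.S * decay + obs * dt

    def set_tau(self, tau):
        self._tau = tau

    @property
    def means(self) -> np.ndarray:
        return self.S / np.where(self.N > 0, self.N, 1.0)[:, None, None]

    def snapshot_observables(self) -> dict:
        m = self.means
        return {cid: m[i].copy() for i, cid in enumerate(self.ids)}

    # -- forces ------------------------------------------------------
    def add_forces(self, coords, ramp, forces):
        if self.N[0] <= 0:
            return
        f_mat = np.tanh((self.means - self.exp_t) / self.width[:, None, None])
        pref = -ramp * self.k * self.width  # (n,)
        if self.n_plain:
            sl = slice(0, self.n_plain)
            self._add_pair_forces(
                coords, self.pi, self.pj, self.d[sl], f_mat[sl], pref[sl], forces, 1.0
            )
        if self.n_methyl:
            sl = slice(self.n_plain, None)
            ci = np.repeat(self.mc, 3)
            hi = self.mh.ravel()
            self._add_pair_forces(
                coords,
                ci,
                hi,
                np.repeat(self.d[sl], 3),
                np.repeat(f_mat[sl], 3, axis=0),
                np.repeat(pref[sl], 3),
                forces,
                1.0 / 3.0,
            )

    @staticmethod
    def _add_pair_forces(coords, i, j, d, f_mat, pref, forces, weight):
        v = coords[i] - coords[j]
        r = np.linalg.norm(v, axis=-1)
        if np.any(r < 1e-8):
            raise GeometryError("zero-length internuclear vector")
        u = v / r[:, None]
        g = 3.0 * d[:, None] * np.einsum("nab,nb->na", f_mat, u)
        g_perp = (g - np.einsum("na,na->n", g, u)[:, None] * u) / r[:, None]
        f = (weight * pref)[:, None] * g_perp
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)

    # -- diagnostics -------------------------------------------------
    def theo_values(self) -> np.ndarray:
        """Current memory-averaged zz components (Hz)."""
        return self.means[:, 2, 2]

    def current_quality(self):
        if self.N[0] <= 0:
            return None
        dev = (self.theo_values() - self.d_exp) / self.err
        chi2 = float(np.sum(dev * dev))
        return np.inf if chi2 == 0 else len(dev) / chi2


class NOEEvaluator:
    """Memory-averaged r^-6 distances and central pseudo-forces."""

    label = "NOE"

    def __init__(self, constraints, k: float):
        self.k = k
        self.constraints = list(constraints)
        self.ids = [c.id for c in self.constraints]
        n = len(self.constraints)
        self.i = np.array([c.atom_i for c in self.constraints])
        # pad partner lists to width 3; weight rows by 1/len
        self.h = np.array(
            [list(c.partners) * (3 // len(c.partners)) for c in self.constraints]
        )
        self.n_part = np.array([len(c.partners) for c in self.constraints])
        self.target = np.array([c.target for c in self.constraints])
        self.width = np.array([c.width for c in self.constraints])
        self.err = np.array([c.error for c in self.constraints])
        self.S = np.zeros(n)
        self.N = np.zeros(n)

    def set_tau(self, tau):
        self._tau = tau

    def _r6(self, coords):
        v = coords[self.i][:, None, :] - coords[self.h]
        r = np.linalg.norm(v, axis=-1)  # (n,3) with repeats for single pairs
        if np.any(r < 1e-8):
            raise GeometryError("coincident protons in NOE evaluation")
        return (r ** -6.0).mean(axis=1), v, r

    def update(self, coords, t, dt, prime=False):
        r6, _, _ = self._r6(coords)
        decay = np.exp(-dt / self._tau)
        self.N = self.N * decay + dt
        self.S = self.S * decay + r6 * dt

    @property
    def r_bar(self) -> np.ndarray:
        return (self.S / np.where(self.N > 0, self.N, 1.0)) ** (-1.0 / 6.0)

    def snapshot_observables(self) -> dict:
        rb = self.r_bar
        return {cid: float(rb[i]) for i, cid in enumerate(self.ids)}

    def add_forces(self, coords, ramp, forces):
        if self.N[0] <= 0:
            return
        mag = ramp * self.k * self.width * np.tanh((self.r_bar - self.target) / self.width)
        _, v, r = self._r6(coords)
        u = v / r[..., None]
        # single pairs are padded to three identical columns, so each padded
        # column carries n_part/3 of the full per-proton force
        fcol = -(mag * self.n_part / 3.0)[:, None, None] * u
        np.add.at(forces, self.i, fcol.sum(axis=1))
        np.add.at(forces, self.h.ravel(), -fcol.reshape(-1, 3))

    def theo_values(self) -> np.ndarray:
        return self.r_bar

    def current_quality(self):
        if self.N[0] <= 0:
            return None
        dev = (self.r_bar - self.target) / self.err
        chi2 = float(np.sum(dev * dev))
        return np.inf if chi2 == 0 else len(dev) / chi2


class JEvaluator:
    """Memory-averaged vicinal couplings and torsional pseudo-forces."""

    label = "3J"

    def __init__(self, constraints, k: float):
        self.k = k
        self.constraints = list(constraints)
        self.ids = [c.id for c in self.constraints]
        n = len(self.constraints)
        self.paths = np.array([c.path for c in self.constraints], dtype=int)
        self.j_exp = np.array([c.j_exp for c in self.constraints])
        self.width = np.array([c.width for c in self.constraints])
        self.err = np.array([c.error for c in self.constraints])
        self.S = np.zeros(n)
        self.N = np.zeros(n)

    def set_tau(self, tau):
        self._tau = tau

    def _phi_grads(self, coords, want_grad=True):
        i, j, kk, l = (self.paths[:, c] for c in range(4))
        if want_grad:
            return dihedral_gradients(coords, i, j, kk, l)
        from .geometry import dihedral_values

        return dihedral_values(coords, i, j, kk, l)

    def _j_of_phi(self, phi):
        return np.array(
            [
                karplus_haasnoot(np.rad2deg(p), c.dchi, c.xi, c.params)
                for p, c in zip(phi, self.constraints)
            ]
        )

    def update(self, coords, t, dt, prime=False):
        phi = self._phi_grads(coords, want_grad=False)
        jval = self._j_of_phi(phi)
        decay = np.exp(-dt / self._tau)
        self.N = self.N * decay + dt
        self.S = self.S * decay + jval * dt

    @property
    def j_mean(self) -> np.ndarray:
        return self.S / np.where(self.N > 0, self.N, 1.0)

    def snapshot_observables(self) -> dict:
        jm = self.j_mean
        return {cid: float(jm[i]) for i, cid in enumerate(self.ids)}

    def add_forces(self, coords, ramp, forces):
        if self.N[0] <= 0:
            return
        phi, g1, g2, g3, g4 = self._phi_grads(coords)
        djdphi = np.array(
            [
                karplus_haasnoot_derivative(np.rad2deg(p), c.dchi, c.xi, c.params)
                for p, c in zip(phi, self.constraints)
            ]
        )
        pref = (
            -ramp
            * self.k
            * self.width
            * np.tanh((self.j_mean - self.j_exp) / self.width)
            * djdphi
        )[:, None]
        np.add.at(forces, self.paths[:, 0], pref * g1)
        np.add.at(forces, self.paths[:, 1], pref * g2)
        np.add.at(forces, self.paths[:, 2], pref * g3)
        np.add.at(forces, self.paths[:, 3], pref * g4)

    def theo_values(self) -> np.ndarray:
        return self.j_mean

    def current_quality(self):
        if self.N[0] <= 0:
            return None
        dev = (self.j_mean - self.j_exp) / self.err
        chi2 = float(np.sum(dev * dev))
        return np.inf if chi2 == 0 else len(dev) / chi2


def build_evaluators(system, constraints: ConstraintSet, config):
    """Validate a constraint set against the system and build evaluators."""
    constraints.validate(system.n_atoms)
    evs = []
    if constraints.rdc:
        ev = RDCEvaluator(constraints.rdc, config.s_am, config.k_rdc)
        for c in constraints.rdc:
            if not c.check_feasible(config.s_am):
                import warnings

                warnings.warn(
                    f"{c.id}: |D_exp|={abs(c.d_exp):.2f} Hz exceeds the attainable "
                    f"S_am*|D_stat|={config.s_am * abs(c.d_stat):.2f} Hz"
                )
        evs.append(ev)
    if constraints.noe:
        evs.append(NOEEvaluator(constraints.noe, config.k_noe))
    if constraints.j:
        evs.append(JEvaluator(constraints.j, config.k_j))
    for ev in evs:
        ev.set_tau(config.tau_ps)
    return evs
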