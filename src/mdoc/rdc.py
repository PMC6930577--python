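"""Dipolar-coupling tensors and orientational pseudo-forces.

A residual dipolar coupling (RDC) is treated as a full symmetric traceless
3x3 tensor.  In its principal axis system (z along the internuclear unit
vector u) the tensor is diag(-D/2, -D/2, D) with D = S_am * D_stat, the
static splitting scaled by the alignment-medium order parameter.  In the
laboratory frame this is

    D_lab = D * (3 u u^T - I) / 2,

whose zz component is D * P2(cos theta).  The experimental counterpart is
the measured splitting placed on the diagonal, diag(-D_exp/2, -D_exp/2,
D_exp), with off-diagonal targets of zero: rapid reorientation about the
director averages the off-diagonal elements away, and demanding that the
*simulated* time averages do the same is what drives whole-molecule
reorientation without any alignment tensor.

Pseudo-forces act on all nine tensor components.  The magnitude of each
component's contribution comes from the tanh-capped mismatch between the
memory-averaged tensor and the target; the direction is the instantaneous
orientational derivative of the lab-frame tensor -- the internuclear
distance is never strained (unit-vector derivative only), so the force
pair is equal, opposite and perpendicular to the bond.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import ramp_factor
from .geometry import GeometryError

_I3 = np.eye(3)


class ConstraintError(ValueError):
    """Inconsistent constraint definition."""


def tanh_scale(delta, width):
    """Saturating mismatch factor tanh(delta/width), odd, in (-1, 1).

    Equal to (s - 1/s)/(s + 1/s) with s = exp(delta/width); the np.tanh
    form is overflow-safe for large |delta|/width.
    """
    if np.any(np.asarray(width) <= 0):
        raise ValueError("tanh width must be positive")
    return np.tanh(np.asarray(delta, dtype=float) / width)


@dataclass
class DipolarTensor:
    """Symmetric traceless 3x3 dipolar tensor (Hz) in a named frame."""

    tensor: np.ndarray
    frame: str = "lab"

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != (3, 3):
            raise ValueError("dipolar tensor must be 3x3")
        scale = max(np.abs(self.tensor).max(), 1.0)
        if abs(np.trace(self.tensor)) > 1e-9 * scale:
            raise ValueError("dipolar tensor must be traceless")
        if not np.allclose(self.tensor, self.tensor.T, atol=1e-9 * scale):
            raise ValueError("dipolar tensor must be symmetric")

    @property
    def zz(self) -> float:
        return float(self.tensor[2, 2])


@dataclass
class RDCConstraint:
    """One experimental RDC with its error and force-width parameters.

    ``atoms`` is an (i, j) index pair, or for a methyl-averaged coupling a
    tuple of the three (C, H) pairs sharing the carbon.  ``d_stat`` is the
    static (rigid-limit) splitting in Hz; for long-range H-H couplings it
    is computed from the configuration-time distance and then frozen.
    """

    id: str
    atoms: tuple
    d_exp: float
    error: float
    d_stat: float
    width: float = 0.5
    kind: str = "one-bond"  # one-bond | long-range | methyl
    names: tuple = field(default=())

    def __post_init__(self):
        if self.error <= 0:
            raise ConstraintError(f"{self.id}: error must be positive")
        if self.width <= 0:
            raise ConstraintError(f"{self.id}: tanh width must be positive")
        if self.d_stat == 0:
            raise ConstraintError(f"{self.id}: static splitting must be nonzero")
        if self.kind == "methyl":
            pairs = np.asarray(self.atoms, dtype=int)
            if pairs.shape != (3, 2) or len(set(pairs[:, 0])) != 1:
                raise ConstraintError(
                    f"{self.id}: methyl constraint needs three pairs sharing the carbon"
                )
        else:
            i, j = self.atoms
            if i == j:
                raise ConstraintError(f"{self.id}: atom pair must be distinct")

    def check_feasible(self, s_am: float) -> bool:
        """True when |D_exp| <= S_am |D_stat| (attainable splitting)."""
        return abs(self.d_exp) <= s_am * abs(self.d_stat)


def pas_tensor(d_stat: float, s_am: float) -> DipolarTensor:
    """Principal-axis dipolar tensor diag(-D/2, -D/2, D), D = S_am*D_stat."""
    if d_stat == 0:
        raise ValueError("static splitting must be nonzero")
    if not 0.0 < s_am <= 1.0:
        raise ValueError("order parameter must lie in (0, 1]")
    d = s_am * d_stat
    return DipolarTensor(np.diag([-0.5 * d, -0.5 * d, d]), frame="pas")


def _completion_frame(u: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal frame with z = u.

    The x axis is built from the Cartesian axis of smallest |u| component;
    any completion yields the same lab tensor, this one is simply
    reproducible.
    """
    e = np.zeros(3)
    e[np.argmin(np.abs(u))] = 1.0
    x = e - np.dot(e, u) * u
    x /= np.linalg.norm(x)
    y = np.cross(u, x)
    return np.column_stack([x, y, u])


def lab_tensor(coords: np.ndarray, pair, pas: DipolarTensor) -> DipolarTensor:
    """Transform a PAS tensor into the laboratory frame of a bond.

    ``coords`` may be a Conformation or an (n, 3) array; ``pair`` the
    (i, j) atom indices.  D_lab = T D_pas T^T with T built from the unit
    internuclear vector; eigenvalues equal the PAS principal values.
    """
    x = getattr(coords, "coords", coords)
    v = x[pair[0]] - x[pair[1]]
    r = np.linalg.norm(v)
    if r < 1e-8:
        raise GeometryError("zero-length internuclear vector")
    t = _completion_frame(v / r)
    return DipolarTensor(t @ pas.tensor @ t.T, frame="lab")


def exp_tensor(d_exp: float) -> DipolarTensor:
    """Experimental target tensor diag(-D/2, -D/2, D) in the lab frame."""
    return DipolarTensor(np.diag([-0.5 * d_exp, -0.5 * d_exp, d_exp]), frame="lab")


def bond_lab_tensors(coords: np.ndarray, i, j, d: np.ndarray) -> np.ndarray:
    """Vectorized axially symmetric lab tensors D*(3 u u^T - I)/2.

    ``d`` are the scaled splittings S_am*D_stat (Hz); returns (n, 3, 3).
    """
    v = coords[i] - coords[j]
    r = np.linalg.norm(v, axis=-1)
    if np.any(r < 1e-8):
        raise GeometryError("zero-length internuclear vector")
    u = v / r[:, None]
    uu = u[:, :, None] * u[:, None, :]
    return d[:, None, None] * (1.5 * uu - 0.5 * _I3)


def rdc_pseudo_force(
    coords,
    constraint: RDCConstraint,
    mem_mean_tensor: np.ndarray,
    k: float,
    t: float,
    rho: float,
    s_am: float,
):
    """Orientational pseudo-forces on the two coupled atoms.

    Returns (F_i, F_j); F_j = -F_i and F_i is perpendicular to the
    internuclear vector.  The mismatch factor is evaluated per tensor
    component on the memory mean; the derivative is the instantaneous
    unit-vector (orientational) derivative of the lab tensor.
    """
    x = getattr(coords, "coords", coords)
    i, j = constraint.atoms
    v = x[i] - x[j]
    r = np.linalg.norm(v)
    if r < 1e-8:
        raise GeometryError("zero-length internuclear vector")
    u = v / r
    d = s_am * constraint.d_stat
    f_mat = tanh_scale(mem_mean_tensor - exp_tensor(constraint.d_exp).tensor, constraint.width)
    # sum_ab f_ab dD_ab/du = 3 d (f u); orientational projection (I - uu^T)/r
    g = 3.0 * d * (f_mat @ u)
    g_perp = (g - np.dot(g, u) * u) / r
    f_i = -ramp_factor(t, rho) * k * constraint.width * g_perp
    return f_i, -f_i


def methyl_rdc_observable(coords, pairs, pas: DipolarTensor) -> DipolarTensor:
    """Mean lab tensor over the three C-H bonds of a rotating methyl.

    The arithmetic average of the three bond tensors is the observable
    compared against the single experimental methyl RDC.
    """
    pairs = np.asarray(pairs, dtype=int)
    if pairs.shape != (3, 2) or len(set(pairs[:, 0])) != 1:
        raise ConstraintError("methyl observable needs three pairs sharing the carbon")
    x = getattr(coords, "coords", coords)
    acc = np.zeros((3, 3))
    for p in pairs:
        acc += lab_tensor(x, p, pas).tensor
    return DipolarTensor(acc / 3.0, frame="lab")
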