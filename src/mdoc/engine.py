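"""Restrained-dynamics engine: exponential-memory averaging, pseudo-force
ramp-up, velocity-Verlet integration with weak-coupling thermostatting,
and the orchestration loop that turns constraint tables into a trajectory
of snapshots.

The central idea: every constrained observable (dipolar tensor component,
interproton r^-6, vicinal J) is averaged over the running trajectory with
an exponentially decaying memory of time constant tau,

    <D(t)> = (1/N) * int_{t0}^{t} exp(-(t-t')/tau) D(t') dt',

realized by the per-step recursion  N <- N exp(-dt/tau) + dt,
S <- S exp(-dt/tau) + D dt,  <D> = S/N.  Pseudo-force magnitudes are
computed from the mismatch between these memory means and the experimental
targets (capped by a tanh), while force directions come from the
instantaneous geometry, so an orientational mismatch acts immediately.
Forces are switched on smoothly as 1 - exp(-t/rho) to protect the start
of the run when no meaningful averages exist yet.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import ACC_UNIT, KB, KE_UNIT
from .system import Conformation, MolecularSystem, ff_energy_forces

logger = logging.getLogger("mdoc.engine")


class SimulationBlowup(RuntimeError):
    """Non-finite coordinates or runaway forces during integration."""


# ---------------------------------------------------------------------------
# exponential-memory averaging
# ---------------------------------------------------------------------------

@dataclass
class MemoryState:
    """Exponential-memory accumulator for one observable (scalar or tensor).

    ``S`` holds the weighted sum (observable units x ps), ``N`` the weight
    normalizer (ps); the running mean is ``S / N``.  The first update
    initializes the mean to the supplied value.
    """

    tau: float
    t0: float = 0.0
    S: np.ndarray | float = 0.0
    N: float = 0.0

    @property
    def mean(self):
        if self.N <= 0.0:
            raise ValueError("memory empty: no updates yet")
        return self.S / self.N


def update_memory(mem: MemoryState, value, t: float, dt: float) -> MemoryState:
    """Advance the exponential-memory mean by one step of length dt.

    Implements the discretized memory integral as a recursion; applies
    componentwise to array-valued observables.  Returns ``mem`` (updated
    in place) for convenience.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = np.exp(-dt / mem.tau)
    mem.N = mem.N * decay + dt
    mem.S = mem.S * decay + np.asarray(value, dtype=float) * dt
    return mem


def ramp_factor(t: float, rho: float) -> float:
    """Pseudo-force switch-on factor 1 - exp(-t/rho), in [0, 1)."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    return 1.0 - np.exp(-t / rho)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MDOCConfig:
    """Run configuration for restrained dynamics.

    Times in ps unless noted; ``duration_ns`` in ns.  ``tau_ps`` is the
    memory time of the observable averages, ``rho_ps`` the rise time of
    the pseudo-force ramp (defaults to tau), ``s_am`` the alignment-medium
    order parameter scaling static dipolar splittings into the residual
    regime.  Force constants ``k_rdc``/``k_noe``/``k_j`` are in kJ/mol per
    squared observable unit (Hz^2, Å^2, Hz^2).
    """

    dt_ps: float = 0.001
    temperature: float = 313.0
    tau_ps: float = 200.0
    rho_ps: float | None = None
    s_am: float = 0.004
    k_rdc: float = 0.3
    k_noe: float = 300.0
    k_j: float = 30.0
    duration_ns: float = 2.0
    snapshot_interval_ps: float = 5.0
    drop_ps: float = 1000.0
    seed: int = 0
    thermostat_tau_ps: float = 0.5
    remove_com: bool = True

    def __post_init__(self):
        if self.rho_ps is None:
            self.rho_ps = self.tau_ps
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        if self.tau_ps <= 0 or self.rho_ps <= 0:
            raise ValueError("tau and rho must be positive")
        if not 0.0 < self.s_am <= 1.0:
            raise ValueError("s_am must lie in (0, 1]")
        if self.snapshot_interval_ps < self.dt_ps:
            raise ValueError("snapshot interval must be >= dt")
        if self.drop_ps >= self.duration_ns * 1000.0:
            raise ValueError("equilibration drop must be shorter than the run")

    @property
    def duration_ps(self) -> float:
        return self.duration_ns * 1000.0


@dataclass
class Snapshot:
    """Timed frame carrying coordinates and memory-averaged observables."""

    time: float
    coords: np.ndarray
    observables: dict
    energy: float = 0.0


@dataclass
class TrajectoryEnsemble:
    """Ordered snapshots plus the configuration and provenance of a run."""

    snapshots: list
    config: MDOCConfig | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.snapshots)

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def coords_array(self) -> np.ndarray:
        return np.stack([s.coords for s in self.snapshots])

    def observable_series(self, cid: str) -> list:
        return [s.observables[cid] for s in self.snapshots]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def kinetic_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K), COM-reduced DOF count."""
    ke = 0.5 * KE_UNIT * np.sum(masses[:, None] * velocities**2)
    ndf = 3 * len(masses) - 3
    return 2.0 * ke / (ndf * KB)


def integrate_step(
    system: MolecularSystem,
    conformation: Conformation,
    total_forces: np.ndarray,
    dt: float,
    thermostat_params: dict | None = None,
    force_fn=None,
):
    """One velocity-Verlet step; returns (new Conformation, new forces).

    ``total_forces`` are the forces at the current coordinates; the force
    at the advanced coordinates is obtained from ``force_fn`` (default:
    plain force-field forces).  When ``thermostat_params`` (keys ``T``,
    ``tau_t``) is given, velocities are rescaled toward the target
    temperature with a Berendsen-style weak coupling.
    """
    if force_fn is None:
        force_fn = lambda conf: ff_energy_forces(system, conf)[1]
    m = system.masses[:, None]
    a_old = ACC_UNIT * total_forces / m
    x_new = conformation.coords + conformation.velocities * dt + 0.5 * a_old * dt * dt
    if not np.all(np.isfinite(x_new)):
        worst = int(np.argmax(np.abs(total_forces).max(axis=1)))
        raise SimulationBlowup(
            f"non-finite coordinates at t={conformation.time:.4f} ps; "
            f"worst atom {worst}, |F|={np.linalg.norm(total_forces[worst]):.3e}"
        )
    new = Conformation(conformation.time + dt, x_new, conformation.velocities.copy())
    f_new = force_fn(new)
    a_new = ACC_UNIT * f_new / m
    new.velocities = conformation.velocities + 0.5 * (a_old + a_new) * dt
    if thermostat_params is not None:
        t_inst = kinetic_temperature(system.masses, new.velocities)
        if t_inst > 0:
            lam = np.sqrt(
                1.0
                + dt / thermostat_params["tau_t"] * (thermostat_params["T"] / t_inst - 1.0)
            )
            new.velocities *= np.clip(lam, 0.8, 1.25)
    return new, f_new


def maxwell_velocities(masses: np.ndarray, temperature: float, rng) -> np.ndarray:
    """COM-free Maxwell-Boltzmann velocities (Å/ps)."""
    sigma = np.sqrt(KB * temperature / (KE_UNIT * masses))[:, None]
    v = rng.normal(size=(len(masses), 3)) * sigma
    v -= np.average(v, axis=0, weights=masses)
    return v


# ---------------------------------------------------------------------------
# the restrained-dynamics loop
# ---------------------------------------------------------------------------

def run_mdoc(system, start, constraints, config: MDOCConfig, fast: bool | None = None) -> TrajectoryEnsemble:
    """Run restrained dynamics and return the snapshot ensemble.

    ``constraints`` is a :class:`mdoc.restraints.ConstraintSet`; pass an
    empty set for plain thermostatted dynamics.  Reproducible for a given
    ``config.seed``: the only stochastic element is the initial velocity
    draw (stream name ``"velocities"``).  ``fast`` selects the jitted
    inner loop (default when numba is importable); the numpy loop is the
    reference implementation and an equivalence test ties the two paths
    together.
    """
    if fast is None:
        from .engine_fast import HAVE_NUMBA

        fast = HAVE_NUMBA
    if fast:
        return _run_mdoc_fast(system, start, constraints, config)
    return _run_mdoc_numpy(system, start, constraints, config)


def _run_mdoc_numpy(system, start, constraints, config: MDOCConfig) -> TrajectoryEnsemble:
    from .restraints import build_evaluators

    evaluators = build_evaluators(system, constraints, config)
    rng = np.random.default_rng([config.seed, _stream_id("velocities")])
    conf = start.copy()
    conf.time = 0.0
    if not np.any(start.velocities):
        conf.velocities = maxwell_velocities(system.masses, config.temperature, rng)

    dt = config.dt_ps
    n_steps = int(round(config.duration_ps / dt))
    every = max(1, int(round(config.snapshot_interval_ps / dt)))
    thermo = {"T": config.temperature, "tau_t": config.thermostat_tau_ps}
    m = system.masses[:, None]

    def total_force(c):
        _, f = ff_energy_forces(system, c)
        ramp = ramp_factor(c.time, config.rho_ps)
        for ev in evaluators:
            ev.add_forces(c.coords, ramp, f)
        return f

    # prime memories with the starting observables so means exist from step 0
    for ev in evaluators:
        ev.update(conf.coords, conf.time, dt, prime=True)
    f = total_force(conf)

    snapshots = []
    next_log = 1000.0
    for step in range(1, n_steps + 1):
        conf, f = _vv_step(system, conf, f, dt, thermo, total_force, m)
        for ev in evaluators:
            ev.update(conf.coords, conf.time, dt)
        if config.remove_com:
            conf.velocities -= np.average(conf.velocities, axis=0, weights=system.masses)
        if step % every == 0 and conf.time > config.drop_ps + 1e-9:
            obs = {}
            for ev in evaluators:
                obs.update(ev.snapshot_observables())
            e_ff, _ = ff_energy_forces(system, conf)
            snapshots.append(Snapshot(conf.time, conf.coords.copy(), obs, e_ff))
        if conf.time >= next_log - 1e-9:
            _log_progress(conf.time, evaluators)
            next_log += 1000.0

    return TrajectoryEnsemble(
        snapshots,
        config=config,
        provenance={"seed": config.seed, "n_constraints": constraints.counts()},
    )


def _run_mdoc_fast(system, start, constraints, config: MDOCConfig) -> TrajectoryEnsemble:
    """Jitted-loop variant; identical semantics to the numpy path."""
    from . import engine_fast as ef
    from .restraints import JEvaluator, NOEEvaluator, RDCEvaluator, build_evaluators
    from .geometry import GeometryError

    evaluators = build_evaluators(system, constraints, config)
    rdc_ev = next((e for e in evaluators if isinstance(e, RDCEvaluator)), None)
    noe_ev = next((e for e in evaluators if isinstance(e, NOEEvaluator)), None)
    j_ev = next((e for e in evaluators if isinstance(e, JEvaluator)), None)

    rng = np.random.default_rng([config.seed, _stream_id("velocities")])
    x = start.coords.copy()
    if np.any(start.velocities):
        v = start.velocities.copy()
    else:
        v = maxwell_velocities(system.masses, config.temperature, rng)

    dt = config.dt_ps
    n_steps = int(round(config.duration_ps / dt))
    every = max(1, int(round(config.snapshot_interval_ps / dt)))
    drop_steps = int(round(config.drop_ps / dt))

    # --- pack constraint arrays -------------------------------------
    def _rdc_arrays():
        if rdc_ev is None:
            return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, np.int64),
                    np.zeros(0), np.zeros(0), np.zeros(0), np.zeros((0, 3, 3)),
                    np.zeros((0, 3, 3)), np.zeros(0))
        bi, bj, grp, wt = [], [], [], []
        for g in range(rdc_ev.n_plain):
            bi.append(rdc_ev.pi[g])
            bj.append(rdc_ev.pj[g])
            grp.append(g)
            wt.append(1.0)
        for m_ in range(rdc_ev.n_methyl):
            for col in range(3):
                bi.append(rdc_ev.mc[m_])
                bj.append(rdc_ev.mh[m_, col])
                grp.append(rdc_ev.n_plain + m_)
                wt.append(1.0 / 3.0)
        return (np.array(bi, np.int64), np.array(bj, np.int64), np.array(grp, np.int64),
                np.array(wt), rdc_ev.d.copy(), rdc_ev.width.copy(), rdc_ev.exp_t.copy(),
                np.zeros((len(rdc_ev.d), 3, 3)), np.zeros(len(rdc_ev.d)))

    (rdc_bi, rdc_bj, rdc_grp, rdc_wt, rdc_d, rdc_width, rdc_exp,
     rdc_S, rdc_N) = _rdc_arrays()

    if noe_ev is not None:
        noe_i = noe_ev.i.astype(np.int64)
        noe_h = noe_ev.h.astype(np.int64)
        noe_np_ = noe_ev.n_part.astype(np.float64)
        noe_target = noe_ev.target.copy()
        noe_width = noe_ev.width.copy()
    else:
        noe_i = np.zeros(0, np.int64)
        noe_h = np.zeros((0, 3), np.int64)
        noe_np_ = np.zeros(0)
        noe_target = np.zeros(0)
        noe_width = np.zeros(0)
    noe_S = np.zeros(len(noe_i))
    noe_N = np.zeros(len(noe_i))

    if j_ev is not None:
        j_atoms = j_ev.paths.astype(np.int64)
        j_exp = j_ev.j_exp.copy()
        j_width = j_ev.width.copy()
        nsub_max = max((len(c.dchi) for c in j_ev.constraints), default=0)
        nsub_max = max(nsub_max, 1)
        j_dchi = np.zeros((len(j_atoms), nsub_max))
        j_xi = np.zeros((len(j_atoms), nsub_max))
        j_nsub = np.zeros(len(j_atoms), np.int64)
        j_params = np.zeros((len(j_atoms), 6))
        for q, c in enumerate(j_ev.constraints):
            j_nsub[q] = len(c.dchi)
            j_dchi[q, : len(c.dchi)] = c.dchi
            j_xi[q, : len(c.xi)] = c.xi
            j_params[q] = c.params
            j_params[q, 5] = np.deg2rad(c.params[5])  # P6 used in radians here
    else:
        j_atoms = np.zeros((0, 4), np.int64)
        j_exp = np.zeros(0)
        j_width = np.zeros(0)
        j_dchi = np.zeros((0, 1))
        j_xi = np.zeros((0, 1))
        j_nsub = np.zeros(0, np.int64)
        j_params = np.zeros((0, 6))
    j_S = np.zeros(len(j_atoms))
    j_N = np.zeros(len(j_atoms))

    # --- prime memories with the starting observables ---------------
    if len(rdc_d):
        obs0 = np.empty_like(rdc_exp)
        ef._observe_rdc(x, rdc_bi, rdc_bj, rdc_grp, rdc_wt, rdc_d, len(rdc_d), obs0)
        rdc_S[:] = obs0 * dt
        rdc_N[:] = dt
    if len(noe_i) or len(j_atoms):
        no0 = np.empty(len(noe_i))
        jo0 = np.empty(len(j_atoms))
        ef._observe_scalars(x, noe_i, noe_h, j_atoms, j_dchi, j_xi, j_nsub, j_params, no0, jo0)
        noe_S[:] = no0 * dt
        noe_N[:] = dt
        j_S[:] = jo0 * dt
        j_N[:] = dt

    # initial forces (ramp at t=0 nulls the pseudo part)
    f = np.zeros_like(x)
    e0 = ef._ff_forces(
        x, f, system.bond_idx[:, 0].astype(np.int64), system.bond_idx[:, 1].astype(np.int64),
        system.bond_r0, system.bond_k,
        system.angle_idx[:, 0].astype(np.int64), system.angle_idx[:, 1].astype(np.int64),
        system.angle_idx[:, 2].astype(np.int64), system.angle_theta0, system.angle_k,
        system.torsion_idx[:, 0].astype(np.int64), system.torsion_idx[:, 1].astype(np.int64),
        system.torsion_idx[:, 2].astype(np.int64), system.torsion_idx[:, 3].astype(np.int64),
        system.torsion_n.astype(np.float64), system.torsion_gamma, system.torsion_v,
        system.nb_idx[:, 0].astype(np.int64), system.nb_idx[:, 1].astype(np.int64),
        0.5 * (system.lj_sigma[system.nb_idx[:, 0]] + system.lj_sigma[system.nb_idx[:, 1]]),
        np.sqrt(system.lj_epsilon[system.nb_idx[:, 0]] * system.lj_epsilon[system.nb_idx[:, 1]]) * system.nb_scale,
        1389.35458 * system.charges[system.nb_idx[:, 0]] * system.charges[system.nb_idx[:, 1]] * system.nb_scale,
        system.cutoff,
    )
    if np.isnan(e0):
        raise GeometryError("nonbonded overlap in the starting structure")

    nb_i = system.nb_idx[:, 0].astype(np.int64)
    nb_j = system.nb_idx[:, 1].astype(np.int64)
    nb_sig = 0.5 * (system.lj_sigma[nb_i] + system.lj_sigma[nb_j])
    nb_eps = np.sqrt(system.lj_epsilon[nb_i] * system.lj_epsilon[nb_j]) * system.nb_scale
    nb_qq = 1389.35458 * system.charges[nb_i] * system.charges[nb_j] * system.nb_scale

    n_snap_max = n_steps // every + 2
    snap_x = np.zeros((n_snap_max, len(x), 3))
    snap_rdc = np.zeros((n_snap_max, len(rdc_d), 3, 3))
    snap_noe = np.zeros((n_snap_max, len(noe_i)))
    snap_j = np.zeros((n_snap_max, len(j_atoms)))
    snap_t = np.zeros(n_snap_max)
    snap_e = np.zeros(n_snap_max)

    t = 0.0
    count = 0
    step0 = 0
    chunk = max(every, int(round(1000.0 / dt)))
    while step0 < n_steps:
        todo = min(chunk, n_steps - step0)
        t, count, status = ef.run_chunk(
            x, v, f, system.masses, t, todo, dt, config.tau_ps, config.rho_ps,
            config.temperature, config.thermostat_tau_ps, config.remove_com,
            system.bond_idx[:, 0].astype(np.int64), system.bond_idx[:, 1].astype(np.int64),
            system.bond_r0, system.bond_k,
            system.angle_idx[:, 0].astype(np.int64), system.angle_idx[:, 1].astype(np.int64),
            system.angle_idx[:, 2].astype(np.int64), system.angle_theta0, system.angle_k,
            system.torsion_idx[:, 0].astype(np.int64), system.torsion_idx[:, 1].astype(np.int64),
            system.torsion_idx[:, 2].astype(np.int64), system.torsion_idx[:, 3].astype(np.int64),
            system.torsion_n.astype(np.float64), system.torsion_gamma, system.torsion_v,
            nb_i, nb_j, nb_sig, nb_eps, nb_qq, system.cutoff,
            rdc_bi, rdc_bj, rdc_grp, rdc_wt, rdc_d, rdc_width, rdc_exp,
            rdc_S, rdc_N, config.k_rdc,
            noe_i, noe_h, noe_np_, noe_target, noe_width, noe_S, noe_N, config.k_noe,
            j_atoms, j_exp, j_width, j_dchi, j_xi, j_nsub, j_params, j_S, j_N, config.k_j,
            every, drop_steps, step0,
            snap_x, snap_rdc, snap_noe, snap_j, snap_t, snap_e, count,
        )
        if status == 1:
            raise GeometryError(f"nonbonded overlap at t={t:.3f} ps")
        if status == 2:
            raise SimulationBlowup(f"non-finite coordinates at t={t:.3f} ps")
        step0 += todo
        # per-nanosecond progress with the current overall quality
        if logger.isEnabledFor(logging.INFO):
            qparts = []
            if len(rdc_d) and rdc_N[0] > 0:
                dev = (rdc_S[:, 2, 2] / rdc_N - np.array([c.d_exp for c in rdc_ev.constraints])) / rdc_ev.err
                chi2 = float(np.sum(dev**2))
                qparts.append(f"RDC n/chi2={len(dev)/chi2 if chi2 else np.inf:.2f}")
            logger.info("t=%.0f ps  %s", t, "  ".join(qparts))

    snapshots = []
    rdc_ids = rdc_ev.ids if rdc_ev else []
    noe_ids = noe_ev.ids if noe_ev else []
    j_ids = j_ev.ids if j_ev else []
    for s in range(count):
        obs = {}
        for gi, cid in enumerate(rdc_ids):
            obs[cid] = snap_rdc[s, gi].copy()
        for mi, cid in enumerate(noe_ids):
            obs[cid] = float(snap_noe[s, mi]) ** (-1.0 / 6.0)
        for qi, cid in enumerate(j_ids):
            obs[cid] = float(snap_j[s, qi])
        snapshots.append(Snapshot(float(snap_t[s]), snap_x[s].copy(), obs, float(snap_e[s])))
    return TrajectoryEnsemble(
        snapshots,
        config=config,
        provenance={"seed": config.seed, "n_constraints": constraints.counts()},
    )


def _vv_step(system, conf, f, dt, thermo, total_force, m):
    a_old = ACC_UNIT * f / m
    x_new = conf.coords + conf.velocities * dt + 0.5 * a_old * dt * dt
    if not np.all(np.isfinite(x_new)):
        worst = int(np.argmax(np.abs(f).max(axis=1)))
        raise SimulationBlowup(
            f"non-finite coordinates at t={conf.time:.4f} ps; worst atom {worst}, "
            f"|F|={np.linalg.norm(f[worst]):.3e}"
        )
    new = Conformation(conf.time + dt, x_new, conf.velocities)
    f_new = total_force(new)
    new.velocities = conf.velocities + 0.5 * (a_old + ACC_UNIT * f_new / m) * dt
    t_inst = kinetic_temperature(system.masses, new.velocities)
    if t_inst > 0:
        lam = np.sqrt(1.0 + dt / thermo["tau_t"] * (thermo["T"] / t_inst - 1.0))
        new.velocities = new.velocities * np.clip(lam, 0.8, 1.25)
    return new, f_new


def _log_progress(t, evaluators):
    parts = []
    for ev in evaluators:
        q = ev.current_quality()
        if q is not None:
            parts.append(f"{ev.label} n/chi2={q:.2f}")
    if parts:
        logger.info("t=%.0f ps  %s", t, "  ".join(parts))


def _stream_id(name: str) -> int:
    """Stable small integer derived from a stream name (documented seeds)."""
    return sum(ord(c) for c in name) % (2**16)
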