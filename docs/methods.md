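# Methods

## Model

The package integrates Newtonian dynamics for an isolated molecule (no
solvent, no periodicity) under a classical force field plus *pseudo-forces*
derived from NMR observables.  Three constraint classes are supported.

**Tensorial RDC restraints.**  For a coupled pair with unit internuclear
vector u the theoretical dipolar tensor in the laboratory frame is the
axially symmetric, traceless form D_lab = S_am·D_stat·(3uuᵀ − I)/2, i.e. the
principal-axis tensor diag(−D/2, −D/2, D) rotated so its z axis lies along
u.  S_am is the order parameter of the alignment medium; it scales the
rigid-limit splitting D_stat (default 47.96 kHz for one-bond C(sp³)–H in the
doublet-splitting convention; the sp² default 49.5 kHz is a configurable
placeholder, and long-range H–H values are computed from 240.2 kHz·Å³/r³ at
configuration time and frozen).  With the default S_am = 0.004 the largest
attainable C–H splitting is 191.8 Hz, comfortably above any target so the
restraints are always satisfiable.  The experimental tensor is
diag(−D_exp/2, −D_exp/2, D_exp) with zero off-diagonal targets; all nine
components are restrained.  Pseudo-forces use the tanh-capped mismatch of
the *memory-averaged* tensor and the *instantaneous* orientational
derivative ∂D_αβ/∂u·(I − uuᵀ)/r, making the force pair equal, opposite,
and perpendicular to the bond: orientation is steered, the bond length is
never strained, and distance information in long-range couplings is
deliberately ignored.  A methyl group's three C–H tensors are arithmetically
averaged into one observable; forces distribute with weight 1/3 per proton.

**Scalar restraints.**  NOE distances average as r̄ = ⟨r⁻⁶⟩^(−1/6); the
force is central, attractive when r̄ exceeds the target.  A methyl partner
contributes the pooled r⁻⁶ mean of its three protons to the observable and
each proton receives the full force.  ³J(H,H) couplings are back-calculated
from the intervening torsion with the Haasnoot/Altona relation
J = P1 cos²φ + P2 cos φ + P3 + Σᵢ Δχᵢ[P4 + P5 cos²(ξᵢφ + P6|Δχᵢ|)]
(parameter sets for 2/3/4 substituents ship as named data; the relation's
intrinsic accuracy is about 0.6 Hz RMS, which motivates the 1.0 Hz default
experimental error).  The instantaneous J is memory-averaged — not cos φ
moments — and the force follows the chain rule through the analytic
dihedral gradient, exerting zero net force and torque.

**Memory and ramp.**  Every observable is averaged with an exponentially
decaying memory of time constant τ via the recursion
N ← N e^(−dt/τ) + dt, S ← S e^(−dt/τ) + x·dt, mean = S/N, equivalent to a
rectangle-rule discretization of the memory integral (an oracle test checks
the recursion against the explicit weighted sum to 1e−8).  After 5τ less
than 1% of an orientation's weight remains, so τ sets the timescale of
orientational and conformational response.  Pseudo-forces switch on as
1 − e^(−t/ρ) with ρ = τ by default, protecting the start of the run when no
meaningful averages exist; force magnitudes are evaluated with the means of
the previous step (explicit coupling, no implicit solve).

## Force field

A deliberately simple fixed-charge force field stands behind the restrained
dynamics: harmonic bonds and angles, single-cosine torsions
V/2·(1 + cos(nφ − γ)), Lennard-Jones and Coulomb terms with 1-2/1-3
exclusions, 1-4 scaling (default 0.5) and a 12 Å cutoff without switching
(vacuum, small molecules — the cutoff rarely engages).  Partial charges are
fixed inputs of the topology table; no polarization or charge recalculation
is attempted.  Units are Å, ps, u, kJ/mol throughout (k_B =
0.0083144626 kJ/mol/K; acceleration carries the factor 100 (kJ/mol/Å)/u →
Å/ps²).  Forces are the exact negative gradient of the energy; the test
suite verifies this with central finite differences on random
conformations, plus translation/rotation invariance and zero net
force/torque.

## Integration and thermostatting

Velocity Verlet with dt = 1 fs by default (0.5 fs is advisable for
light-atom NVE studies; tests use it for the energy-conservation oracle).
Temperature is held near the 313 K default with Berendsen-style weak
coupling (coupling time 0.5 ps, rescale factor clamped to [0.8, 1.25]),
with per-step removal of center-of-mass drift but *not* of angular
momentum — whole-molecule reorientation is the mechanism by which tensor
averages converge and must remain free.  Canonical-ensemble fidelity is not
a goal; the restraints target averaged observables.  Initial velocities are
Maxwell-Boltzmann draws from a named generator stream derived from the run
seed; given the seed and configuration, trajectories replay exactly.

The per-step loop exists twice: a readable numpy reference implementation
and a numba translation used by default (~10 µs/step for a 20-atom system
against ~600 µs for the reference).  An equivalence test holds the two
paths to agreement at floating-point accumulation level over short runs.

## Quality criteria

χ² = Σ((theo − exp)/err)² over a data type; quality n/χ² exceeds 1 when
data are reproduced within error on average; outlier criterion
1/χ²_min = 1/max((theo−exp)/err)²; fidelity ℱ = fraction of data within
error, with the boundary |dev| = err counted valid (the convention is
documented because it is not universal).  A deviation-free dataset reports
the quality as +inf rather than dividing by zero.  Pooled ("overall")
criteria are recomputed from the concatenated normalized vectors, never by
averaging per-type values.  The Q factor uses the common convention
rms(calc − obs)/rms(obs); published Q values from other fitting programs
may use different normalizations, so cross-program Q comparisons are
convention-sensitive.

## SVD alignment baseline

The classical fit expresses each RDC as D_stat·(uᵀAu) with the Saupe matrix
parametrized as (S_zz, S_xx−S_yy, S_xy, S_xz, S_yz); the n×5 coefficient
matrix is solved by SVD (unweighted by default, error-weighted by flag —
common practice varies), with singular values, condition number and
rank-deficiency warnings reported.  Fewer than five couplings raises an
explicit underdetermination error.  The multi-conformer variant
population-weights the coefficient rows under one common tensor and scans
the population simplex on a 0.05 grid — reproducible and exhaustive for the
two- or three-state problems it targets, in place of a nonlinear joint
optimization.

## Ensemble analysis

Torsions follow the right-handed IUPAC convention (cis = 0°, values in
(−180°, 180°], no unwrapping).  Rotamer fractions use boundaries at 0° and
±120°: trans ⇔ |ω| ≥ 120°, gauche(+) ⇔ 0 < ω < 120°, gauche(−) ⇔
−120° < ω ≤ 0°.  Dihedral PCA maps each angle to e^{iφ}, diagonalizes the
mean-centered Hermitian covariance, and reports eigenvalues (summing to the
total circular variance), per-dihedral contribution moduli, and per-frame
projection angles θ_n = arg Σⱼ v*_{n,j} e^{iφⱼ}.  Using the argument of the
complex projection (rather than a real linear combination of angles) is a
design choice; it respects the circular topology and yields a single
angular coordinate per component.

## Synthetic ground truth

The generator builds a 20-atom, two-fragment rotor (a
2,3-dimethylbutane-like frame: two CH(CH₃)₂ fragments, four methyls,
14 protons) with exactly one soft torsion (8 kJ/mol three-fold barrier;
methyl torsions 18 kJ/mol keep the fragments semi-rigid).  The rotor
coordinate ω is the H2–C2–C3–H3 torsion, so the single vicinal coupling
reports the trans fraction directly.  Reference ensembles draw ω from a
von-Mises mixture at 180°/−60°/+60° with concentration κ = 25 (σ ≈ 11°,
matching the force field's thermal well width at 313 K) plus 0.02 Å
Cartesian jitter.  "Experimental" tables are forward-modeled from the
ensemble: RDCs as averages of D_stat·(uᵀAu) under an imposed Saupe tensor
(magnitude ~8×10⁻⁴, well inside the attainable S_am range), NOE targets as
ensemble ⟨r⁻⁶⟩^(−1/6), couplings as ensemble-averaged Karplus values; all
with additive Gaussian noise (0.3 Hz / 0.1 Å / 0.3 Hz) and error columns
floored at the typical experimental estimates (1.0 Hz / 0.5 Å / 1.0 Hz).
One J-path substituent carries an oxygen-like electronegativity descriptor
(Δχ = 1.3): with four identical carbon-like substituents the Haasnoot curve
is exactly even in φ and the sign of the gauche state would be pinned only
by NOEs, which — being r⁻⁶-weighted — are weakly sensitive to moving
population between *distant* states.  The electronegative substituent (cf.
carbonyl-bearing fragments in real molecules of this class) makes
J(+60°) and J(−60°) differ by ~1.6 Hz.

The forward model deliberately uses a single common Saupe tensor across
conformers — the very simplification whose breakdown under strong
shape–alignment coupling motivates tensor-free restrained dynamics — so
recovery failures in a strongly coupled regime are expected behavior of the
ground truth, not bugs.

**What passing the synthetic study shows, and what it does not.**  The
recovery study demonstrates that the pseudo-force machinery converges the
time-averaged observables to their targets and that the resulting torsion
population matches the generating population within ±0.10.  It does not
probe force-field accuracy, conformer-dependent alignment, spectral overlap
or assignment errors, ring flexibility, or the scale separation of real
experiments (real data involve ~40–200 constraints and 40+ ns trajectories).

## Study conditions and problem sizes

The flagship recovery runs at one-tenth of the memory timescale used for
real molecules: τ = ρ = 20 ps, 2 ns per trajectory (100τ), the first
100 ps (5ρ) dropped, snapshots every 1 ps, three seeds.  The production
defaults remain τ = ρ = 200 ps, 1 ns drop, 5 ps snapshots.  Calibrated
pseudo-force constants (see below) are the package defaults:
k_rdc = 0.3 kJ/mol/Hz², k_noe = 300 kJ/mol/Å², k_j = 30 kJ/mol/Hz².
Under these conditions the recovered fractions across seeds are
trans ≈ 0.69–0.70 (truth 0.70), gauche(−) ≈ 0.20–0.22 (0.30),
gauche(+) ≈ 0.08–0.10 (0.00), with overall n/χ² ≈ 4.4–5.3.  The residual
~0.09 gauche(+) occupancy is the equilibrium of the restrained dynamics
passing through and briefly populating the third well during
trans↔gauche(−) exchange; it is the main known bias of the scaled-down
study.

## Numerical choices and degenerate inputs

* tanh widths: ΔD = 0.5 Hz per RDC tensor component (off-diagonals use the
  same width as zz — nothing suggests per-component widths), Δr = 0.25 Å,
  ΔJ = 0.5 Hz; all overridable per datum.
* k was calibrated by the synthetic recovery study: k_rdc = 1.0 destabilizes
  the toy system (steric collapse through the 0.1 Å singularity guard),
  k_rdc = 0.2 leaves RDC averages under-converged (n/χ² ≈ 1); 0.3 is the
  default.  Scalar constants scale similarly (saturated force =
  k·width).
* Coincident atoms (r < 1e−8 Å) and collinear dihedral axes raise geometry
  errors; nonbonded contacts under 0.1 Å raise a singularity error;
  non-finite coordinates abort with the step, worst atom and force norm.
* The completion of the bond frame (x/y axes perpendicular to u) is built
  deterministically from the smallest-|u| Cartesian axis; any completion
  yields the same lab tensor.
* Memory accumulators are primed with the starting observables so means
  exist from step 0 (the ramp nulls the forces there anyway).
* A χ² of exactly zero reports quality +inf; empty data vectors are
  errors, not silent zeros.

## Known limitations

Vacuum only; no replica exchange or enhanced sampling; no RCSA or
chemical-shift restraints; the force field is not polarizable, so
electrostatically driven conformer preferences are only as good as the
fixed charges supplied; Berendsen weak coupling does not sample a strict
canonical ensemble; the dPCA is the standard complex formulation (adapted
variants are an extension point); no kinetic or Markov-state analysis is
attempted on the ensembles.
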