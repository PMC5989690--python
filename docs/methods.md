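# Methods

## The model

A protein chain A₁A₂…A_N (the ACE and NME blocking groups count as chain
units 1 and N) is cut across every peptide bond.  Each interior residue
becomes a *monomer* fragment Cap*(i−1)·A_i·Cap(i+1): the residue plus the
formyl group (C=O) of its left neighbour and the amide group (N–H) of its
right neighbour, with a capping hydrogen replacing each removed Cα.  The
fused cap pairs (*concaps* — formamide-like peptide units, six atoms each)
are subtracted to cancel the double counting:

    E_QM = Σ_{i=2}^{N−1} E(Cap*_{i−1} A_i Cap_{i+1})
         − Σ_{i=2}^{N−2} E(Cap*_i Cap_{i+1})
         + Σ_{H-bonded (i,j)} [E(A_iᵖ A_jᵖ) − E(A_iᵖ) − E(A_jᵖ)]

The third sum is the two-body hydrogen-bond correction: for every backbone
N–H···O=C contact with d(H,O) < 3.0 Å, ∠N–H···O > 120° and sequence
separation |i−j| ≥ 3 (strict inequalities; boundary ties excluded), the
capped peptide units containing the donor N–H and the acceptor C=O are
evaluated as a dimer and individually.

Everything the fragments do not cover is classical:

    E = E_QM + E_MM,     E_MM = Σ_{(m,n) ∉ same QM zone} [Coulomb + 12-6]

where a pair shares a *QM zone* iff both atoms appear together as real
atoms in at least one monomer fragment.  For solvated systems
E_total = E_protein + E_water + E_protein−water with the solvent handled
entirely classically (mechanical embedding — fragment energy requests
never see water).

## Force balancing

Capping hydrogens are placed at H = B + d·(Cα − B)/|Cα − B| (d = 1.090 Å
from carbon hosts, 1.010 Å from nitrogen hosts), so each cap position is a
smooth function of exactly two real atoms.  Scattering fragment forces
back into system indexing leaves a signed residual ΔF on every geometric
cap site (monomer contributions minus the coinciding concap
contributions).  Three redistribution modes ship:

* **paper** (default): ΔF is added wholly to the anchor Cα.  This
  conserves the net force and is the method's original balancing rule.
* **chain_rule**: ΔF is pushed through the exact Jacobian
  ∂H/∂Cα = (d/r)(I − ûûᵀ), ∂H/∂B = I − ∂H/∂Cα onto both the anchor and
  the host.  Because the Jacobians sum to the identity, the net force is
  conserved *and* the result is the exact negative gradient of the
  assembled energy (verified against central differences to ~3×10⁻⁶
  kcal/mol/Å).
* **none**: residuals dropped — the unbalanced reference variant kept for
  conservation comparisons.

## The analytic test potential

The shipped `MockBackend` is not a toy in the pejorative sense: it is the
instrument that makes the bookkeeping provable.  It evaluates Coulomb +
12-6 over non-excluded pairs plus harmonic bond (k = 300 kcal/mol/Ų) and
angle (k = 50 kcal/mol/rad²) terms with equilibria taken from the
system's reference geometry.  Per-atom charges and 12-6 parameters come
from the shipped residue table (Amber-ff14SB-style values for ACE, NME,
ALA, GLY and TIP3P water).  Two properties matter:

1. With `cap_transparent=True` (all terms involving capping hydrogens
   zeroed) the potential is exactly additive over pairs/bonds/angles of
   real atoms.  The signed fragment combination then reproduces a direct
   full-system evaluation to ~1×10⁻¹⁴ kcal/mol — the pair-bookkeeping
   theorem made executable.  The same holds for bond and angle terms by
   the analogous signed triple-counting argument (the intersection of two
   adjacent monomers is exactly the concap atom set).
2. With caps opaque (the default) the cap error is non-zero and the
   force-balancing machinery does real work, which is what the NVE
   conservation experiments exercise.

Non-bonded exclusions: pairs at covalent-graph distance ≤ 2 (1-2, 1-3)
are excluded everywhere, consistently between fragment evaluations, the
MM layer and the full-system reference (fragment exclusions for real-atom
pairs are computed on the *system* graph, so the three views agree).

### MM valence terms for the blocking-group methyls

The methyl groups of ACE and NME appear in no monomer fragment (their
carbon is what the capping hydrogen replaces), so their bonds, angles and
1-2/1-3 pairs are not covered by any QM zone.  E_MM therefore carries
harmonic bond/angle terms for exactly those uncovered valence elements,
and the standard distance-≤2 exclusion keeps their non-bonded terms out.
Without this the blocking groups would be unbound.  Cα(i)–Cα(i+1) pairs
(graph distance 3) are MM pairs at full strength.

## Hydrogen-bond topology along a trajectory

`FBGMFCCCalculator` freezes the fragment list — including the detected
hydrogen-bond set — at construction.  A hydrogen-bond list that changes
mid-trajectory makes the potential discontinuous and corrupts NVE
diagnostics, so the surface is kept fixed for a run; analysis tools
re-detect per frame.  The two-body correction does not modify MM pair
ownership (the dimer is a correction on top of the MM interaction, and a
switch exists to change that reading).

## Dynamics

Velocity-Verlet NVE and BAOAB-discretized Langevin dynamics share one
integration kernel; at γ = 0 the O-step is skipped and the step is
bitwise velocity Verlet.  Units are Å, fs, amu, kcal/mol
(a = F/m × 4.184×10⁻⁴ Å fs⁻² per (kcal/mol/Å)/amu); kB = 1.9872×10⁻³
kcal/mol/K.  Temperatures are kinetic with 3N degrees of freedom
(production runs are unconstrained).  Initial velocities are
Maxwell–Boltzmann at the requested temperature with centre-of-mass motion
removed for NVE starts.  Restraints are additive: harmonic positional on
a selection (backbone heating restraints, force constants in kcal/mol/Ų
— the conventional reading of force constants quoted in kcal/mol) and a
spherical half-harmonic wall that confines water balls (zero inside the
radius, harmonic outside).  Waters are flexible TIP3P: stiff harmonic
bond (450 kcal/mol/Ų) and angle (55 kcal/mol/rad²) terms hold the rigid
geometry; constraint DOF bookkeeping is therefore unnecessary.

Checkpoints are text dumps with hex-encoded floats and the full RNG
state; a resumed run continues bitwise.

## What the experiments show (and don't)

The gas-phase conservation experiment (bundled recipe
`recipes/nve_gasphase.cfg`: Ace-(ALA)₉-NME, 2 ps NVE at 1 fs, thermal
start at 300 K) measures the least-squares slope of total energy vs time.
Dropping the cap residuals gives a clear secular drift; routing them to
the Cα anchors shrinks the slope several-fold (typical ratios 0.03–0.4
across seeds); the chain_rule mode leaves only integrator-level wander.
On that last point: with exact forces the remaining energy variation is
velocity-Verlet shadow-energy error, and at a 1 fs step the unconstrained
X–H stretches (k = 300 kcal/mol/Ų, ~12.6 fs period, ωΔt ≈ 0.5) bound the
relative drift at roughly 10⁻⁴ over 2 ps, scaling as Δt².  Pushing below
10⁻⁵ requires Δt ≲ 0.25 fs, not a better force.

The solvated recipe (`recipes/solvated_langevin.cfg`) is a deliberately
scaled-down demonstration of the full pipeline — a tri-alanine in a
40-water ball with a Langevin thermostat at 2.0 ps⁻¹, backbone restraint
and a boundary wall — chosen so the recipe runs in seconds while
exercising every term of the solvated energy expression.  Production-
scale counterparts (a 56-residue protein in ~3000 waters, hundreds of
picoseconds) use the same code paths but are outside what an analytic
test potential can say anything physical about.

The synthetic generator (ideal peptide builder + water-ball packer)
emulates connectivity, stoichiometry and secondary-structure geometry; it
does not emulate real electron densities, polarization, or experimental
coordinate noise.  Green tests therefore certify the *bookkeeping,
calculus and statistical mechanics* of the implementation — energy
identities, exact gradients, conservation, thermostat calibration — not
chemical accuracy, which belongs to whatever engine is plugged into the
external-engine adapter (energies in hartree, forces in hartree/bohr,
converted at a single constants table: 627.509474 kcal/mol/hartree,
0.529177210903 Å/bohr).

## Degenerate inputs and numerical choices

* Chains need ≥ 3 units to fragment; chain breaks (C–N > 1.7 Å) act as
  fragmentation barriers — no cap reaches across.
* Proline donors produce no two-body correction (no amide H); proline
  residues are skipped in planarity analysis with a notice.
* Missing backbone amide hydrogens are rebuilt at 1.01 Å along the
  in-plane bisector anti-direction; the repair is flagged because it
  biases planarity toward zero.
* Dihedrals use the IUPAC sign convention, range (−180°, 180°];
  collinear triples raise rather than return garbage.  Peptide-bond
  planarity is reported both as the raw signed O-C-N-H dihedral and as
  the deviation wrap(χ − 180°) from the ideal trans amide, so either
  convention can be compared against external tables.
* Backbone RMSD uses least-squares superposition (SVD); the test suite
  cross-checks it against a direct numerical minimization over rotations.
* Fragment batch evaluation is order- and width-independent (bitwise for
  the analytic backend); a non-converged fragment aborts the step naming
  the fragment.

## Known limitations

* The classical layer is fixed-charge 12-6; polarizable multipoles and
  induced dipoles are not reproduced (an induced-polarization hook
  returns zero).  Salt bridges and side-chain hydrogen bonds get no
  two-body correction — both are outside the current fragment scheme.
* Shipped templates and parameters cover ALA, GLY, ACE, NME and TIP3P
  water; arbitrary PDB inputs can be read and analysed, but energy
  evaluation requires parameters for every atom.
* No periodic boundary conditions, Ewald sums, analytic Hessians or
  virial; water balls are finite and exact-summed.
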