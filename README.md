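# fbgmfcc

Fragment-based total energies and **force-balanced** atomic forces for
proteins, with an ab initio-style molecular dynamics driver.

Quantum-chemical energies scale too steeply with system size to treat a
whole protein, but a protein is chemically local: cut it across its
peptide bonds, cap each residue fragment with the conjugate amine/formyl
groups of its neighbours (dangling valences saturated by hydrogens placed
toward the removed Cα), and the total energy assembles as a signed sum

    E = Σᵢ E(Cap*ᵢ₋₁ Aᵢ Capᵢ₊₁) − Σᵢ E(Cap*ᵢ Capᵢ₊₁)
        + Σ_{H-bond (i,j)} [E(Aᵢᵖ Aⱼᵖ) − E(Aᵢᵖ) − E(Aⱼᵖ)]  +  E_MM

— monomers (+1), fused-cap *concaps* (−1), a two-body correction for each
backbone hydrogen bond (d(H,O) < 3 Å, ∠N–H···O > 120°, |i−j| ≥ 3), and a
classical non-bonded term over atom pairs that never share a fragment.
Each fragment is small, independent, and embarrassingly parallel.

The catch is dynamics: the capping hydrogens are fictitious, and the
forces computed on them do not cancel between monomer and concap.  Run
NVE dynamics on the naive forces and the total energy climbs steadily.
This package's centrepiece is the fix: the signed residual force ΔF on
every cap site is redistributed onto its anchor Cα (the original rule),
or, in `chain_rule` mode, through the exact Jacobian of the cap placement
map — making the forces the exact gradient of the assembled energy.

The per-fragment energy backend is pluggable: an analytic test potential
ships (exact gradients, machine-precision bookkeeping checks), and an
adapter contract drives any external quantum-chemistry engine through
text files (hartree in, kcal/mol out).

## Worked example

Cut the capped nonapeptide into fragments:

```
$ fbgmfcc fragment --sequence AAAAAAAAA --out frags
monomer: 9
concap: 8
hbond_dimer: 0
peptide_unit: 0
wrote 17 fragments to frags/
```

Nine alanines give nine monomer fragments and eight concaps (the ACE/NME
blocking groups enter only through the caps); the extended chain has no
backbone hydrogen bonds, so no two-body fragments appear.  Each fragment
is written as an XYZ block plus a manifest (label, sign, charge,
multiplicity, atom map, cap records) ready for an external engine.

Assemble energy and forces for a tripeptide and compare against a direct
full-system evaluation of the same analytic potential:

```
$ fbgmfcc energy --sequence AGA --oracle full
# mode=paper backend=mock:677e795b93b0
E_total       24.77740678 kcal/mol
E_QM                   8.77598123
E_concap              32.77308409
E_twobody              0.00000000
E_MM                 -16.77165854
...
# force correlation vs full-system reference: slope=0.999870 R2=0.99999313 dE=-4.215e-01
```

The assembled forces track the full-system reference with slope ≈ 1 and
R² ≈ 0.999993; the small energy offset is the cap error that the signed
combination leaves behind when caps interact with their fragments.  (Run
the same command with a cap-transparent backend through the API and the
difference collapses to ~10⁻¹⁴ — the pair-bookkeeping identity.)

Run the bundled gas-phase conservation experiment (2 ps NVE at 1 fs on
Ace-(ALA)₉-NME) and inspect the drift:

```
$ fbgmfcc md --config src/fbgmfcc/recipes/nve_gasphase.cfg
final step=2000 time=2000.0 fs T=314.8 K
$ fbgmfcc analyze drift --energy-log nve_gasphase.log
n=2001 mean=250.730277 slope=2.055153e-01 kcal/mol/ps stderr=5.25e-03 max_excursion=1.279817
```

Editing `balance_mode = paper` to `none` in the config and re-running
raises the drift slope from 0.206 to 0.923 kcal/mol/ps at the same seed:
the energy the fictitious cap hydrogens pump into the system is exactly
what force balancing removes.  `chain_rule` mode drops the slope another
order of magnitude, to the velocity-Verlet discretization floor.

Structure diagnostics work on any PDB.  Here, an (ALA)₄ peptide whose
amide hydrogens at residues 3 and 4 were twisted out of plane by +12.9°
and −9.3° before writing the file (coordinates land on the PDB's 0.001 Å
grid, hence the last-digit wobble):

```
$ fbgmfcc analyze planarity --pdb twisted.pdb
residue  seq  dihedral   deviation  h_rebuilt
ALA      2     180.00      0.00     False
ALA      3    -167.11     12.89     False
ALA      4     170.68     -9.32     False
ALA      5     180.00      0.00     False
NME      6     180.00      0.00     False
```

The table reports the signed O(i−1)-C(i−1)-N(i)-H(i) dihedral and its
deviation from the ideal trans peptide plane (180°); `h_rebuilt` flags
amide hydrogens that had to be reconstructed (a reconstruction biases
the deviation toward zero, so flagged rows are read with care).

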