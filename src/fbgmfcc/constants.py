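"""Physical constants and unit conversions.

Internal units everywhere: length in Å, energy in kcal/mol, time in fs,
mass in amu, charge in elementary charges, temperature in K.  Quantum-
chemistry engines report hartree / hartree-bohr⁻¹; the conversions below
are the single point where those units enter or leave the package.
"""

# energy
HARTREE_TO_KCALMOL = 627.509474
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

# length
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# electrostatics: prefactor of q_i q_j / r_ij with q in e, r in Å,
# energy in kcal/mol (the value used by the Amber family of force fields)
COULOMB_CONSTANT = 332.0637

# Boltzmann constant, kcal/mol/K
KB_KCALMOL = 0.0019872041

# acceleration conversion: a [Å/fs²] = F [kcal/mol/Å] / m [amu] * MD_FORCE_CONV
# (1 kcal/mol = 4184 J/mol; 1 Å/fs = 1e5 m/s)
MD_FORCE_CONV = 4.184e-4

# kinetic energy: KE [kcal/mol] = 0.5 * m [amu] * v² [Å²/fs²] / MD_FORCE_CONV
KE_CONV = 1.0 / MD_FORCE_CONV

# capping-hydrogen bond lengths, Å, by host element
CAP_H_BOND_LENGTH = {"C": 1.090, "N": 1.010}

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}
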