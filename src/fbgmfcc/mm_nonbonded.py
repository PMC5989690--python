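"""Classical non-bonded layer: MM-classified protein pairs, water–water and
protein–water interactions.

A fixed-charge Coulomb + 12-6 model (Lorentz–Berthelot combining) stands in
for the polarizable multipole force field of the original scheme; the
induced-polarization term is exposed as an extension hook returning zero.
Pairs at covalent-graph distance ≤ 2 (1-2 and 1-3) are excluded — almost
all bonded pairs sit inside a QM fragment anyway, but the terminal
blocking-group methyls do not, and those need both the exclusion and the
valence terms supplied by the assembler.  No cutoff by default: systems are
finite (gas phase or a water ball), so exact sums are affordable and
correctness-first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import (
    angle_energy_forces,
    bond_energy_forces,
    pairwise_energy_forces,
)
from .constants import COULOMB_CONSTANT
from .structure import ProteinSystem
from .templates import TIP3P_HOH_ANGLE, TIP3P_OH

#: stiff-harmonic constants holding TIP3P internal geometry
WATER_BOND_K = 450.0  # kcal/mol/Å²
WATER_ANGLE_K = 55.0  # kcal/mol/rad²


@dataclass
class NonbondedParams:
    charges: np.ndarray  # (n,), e
    eps: np.ndarray  # (n,), kcal/mol
    rmin2: np.ndarray  # (n,), Å
    combining_rule: str = "Lorentz-Berthelot"
    coulomb_constant: float = COULOMB_CONSTANT
    cutoff: float | None = None

    @classmethod
    def from_system(cls, system: ProteinSystem) -> "NonbondedParams":
        n = system.n_atoms
        charges = np.zeros(n)
        eps = np.zeros(n)
        rmin2 = np.zeros(n)
        for a in system.atoms:
            if a.vdw_params is None:
                raise ValueError(
                    f"missing non-bonded parameters for atom {a.index} "
                    f"({a.name} of residue {a.residue_index})")
            charges[a.index] = a.partial_charge
            eps[a.index], rmin2[a.index] = a.vdw_params
        return cls(charges=charges, eps=eps, rmin2=rmin2)


def polarization_hook(system, positions, params) -> tuple[float, np.ndarray]:
    """Extension hook for an induced-polarization term; the shipped model
    is fixed-charge, so this contributes nothing."""
    return 0.0, np.zeros((len(positions), 3))


def covalent_adjacency(system: ProteinSystem) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(system.n_atoms)]
    for a, b in system.covalent_bonds:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bonded_exclusion_pairs(system: ProteinSystem) -> set[tuple[int, int]]:
    """All atom pairs at covalent-graph distance 1 or 2 (1-2 and 1-3)."""
    adj = covalent_adjacency(system)
    excl: set[tuple[int, int]] = set()
    for a, nbrs in enumerate(adj):
        for b in nbrs:
            excl.add((min(a, b), max(a, b)))
            for c in adj[b]:
                if c != a:
                    excl.add((min(a, c), max(a, c)))
    return excl


def enumerate_angles(system: ProteinSystem) -> list[tuple[int, int, int]]:
    """All bonded angle triples (i, j, k) with vertex j, i < k."""
    adj = covalent_adjacency(system)
    out = []
    for j, nbrs in enumerate(adj):
        srt = sorted(nbrs)
        for x in range(len(srt)):
            for y in range(x + 1, len(srt)):
                out.append((srt[x], j, srt[y]))
    return out


def mm_energy_forces(positions: np.ndarray, pairs_i: np.ndarray,
                     pairs_j: np.ndarray,
                     params: NonbondedParams) -> tuple[float, np.ndarray]:
    """Coulomb + 12-6 over an explicit (pre-classified, pre-excluded) pair
    list.  Forces are pairwise equal and opposite by construction."""
    forces = np.zeros_like(positions)
    q = params.charges
    eps_ij = np.sqrt(params.eps[pairs_i] * params.eps[pairs_j])
    rmin_ij = params.rmin2[pairs_i] + params.rmin2[pairs_j]
    rmin_ij = np.where(eps_ij > 0, rmin_ij, 1.0)
    energy = pairwise_energy_forces(positions, pairs_i, pairs_j,
                                    q[pairs_i] * q[pairs_j],
                                    eps_ij, rmin_ij, forces)
    return energy, forces


def water_pair_lists(system: ProteinSystem) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray, np.ndarray]:
    """(water-water i, j) and (protein-water i, j) index arrays."""
    waters = system.solvent_waters
    ww_i, ww_j = [], []
    for a in range(len(waters)):
        for b in range(a + 1, len(waters)):
            for x in waters[a]:
                for y in waters[b]:
                    ww_i.append(x)
                    ww_j.append(y)
    protein = system.protein_atom_indices()
    solvent = system.solvent_atom_indices()
    pw_i = np.repeat(np.array(protein, dtype=int), len(solvent)) \
        if protein and solvent else np.array([], dtype=int)
    pw_j = np.tile(np.array(solvent, dtype=int), len(protein)) \
        if protein and solvent else np.array([], dtype=int)
    return (np.array(ww_i, dtype=int), np.array(ww_j, dtype=int), pw_i, pw_j)


def water_terms(system: ProteinSystem, positions: np.ndarray,
                params: NonbondedParams) -> tuple[float, float, np.ndarray]:
    """(E_water, E_protein_water, forces).

    E_water = inter-water non-bonded plus stiff-harmonic TIP3P internal
    geometry restraints; E_protein_water = all protein–water non-bonded.
    """
    for group in system.solvent_waters:
        if len(group) != 3:
            raise ValueError(f"malformed water {group}: expected 3 atoms")
    forces = np.zeros_like(positions)
    ww_i, ww_j, pw_i, pw_j = water_pair_lists(system)
    q = params.charges

    def nb(pi, pj):
        if len(pi) == 0:
            return 0.0
        eps_ij = np.sqrt(params.eps[pi] * params.eps[pj])
        rmin_ij = params.rmin2[pi] + params.rmin2[pj]
        rmin_ij = np.where(eps_ij > 0, rmin_ij, 1.0)
        return pairwise_energy_forces(positions, pi, pj, q[pi] * q[pj],
                                      eps_ij, rmin_ij, forces)

    e_water = nb(ww_i, ww_j)
    # intra-water stiff harmonic (flexible TIP3P)
    if system.solvent_waters:
        groups = np.array(system.solvent_waters, dtype=int)
        bonds = np.concatenate([groups[:, [0, 1]], groups[:, [0, 2]]])
        r0 = np.full(len(bonds), TIP3P_OH)
        kb = np.full(len(bonds), WATER_BOND_K)
        e_water += bond_energy_forces(positions, bonds, r0, kb, forces)
        angles = groups[:, [1, 0, 2]]
        t0 = np.full(len(angles), np.radians(TIP3P_HOH_ANGLE))
        ka = np.full(len(angles), WATER_ANGLE_K)
        e_water += angle_energy_forces(positions, angles, t0, ka, forces)
    e_pw = nb(pw_i, pw_j)
    return e_water, e_pw, forces
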