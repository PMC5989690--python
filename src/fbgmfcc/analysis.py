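"""Structure and trajectory diagnostics.

Covers the peptide-bond planarity measure (the signed O(i−1)-C(i−1)-N(i)-H(i)
dihedral and its deviation from the ideal trans value of 180°), optimal-
superposition backbone RMSD, kinetic-temperature traces, total-energy drift
statistics for conservation checks, and per-residue dihedral histograms
over trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import ProteinSystem


class CollinearError(ValueError):
    pass


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, range (−180, 180].

    Zero for a cis (eclipsed) arrangement of p1 and p4; positive for a
    clockwise rotation of the far bond viewed from p2 towards p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise CollinearError("three consecutive points are collinear; "
                             "dihedral undefined")
    b2h = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2h))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(a: float) -> float:
    """Wrap into (−180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    if a <= -180.0:
        a += 360.0
    # map the -180 representative to +180
    return 180.0 if np.isclose(a, -180.0) else a


@dataclass(frozen=True)
class PlanarityRecord:
    residue_index: int
    residue_name: str
    seq_id: int
    dihedral_OCNH: float  # signed degrees
    deviation: float  # wrap(dihedral − 180°), 0 for an ideal trans peptide
    amide_h_rebuilt: bool


def _resolve_residue_selection(system: ProteinSystem, selection):
    if selection is None:
        return [r.index for r in system.residues if r.is_amino_acid]
    out = []
    for item in selection:
        if isinstance(item, int):
            out.append(item)
            continue
        name = "".join(c for c in item if c.isalpha()).upper()
        num = int("".join(c for c in item if c.isdigit()))
        matches = [r.index for r in system.residues
                   if r.name.upper() == name and r.seq_id == num]
        if not matches:
            raise ValueError(f"no residue matching {item!r}")
        out.append(matches[0])
    return out


def planarity_deviations(system: ProteinSystem,
                         residue_selection=None) -> list[PlanarityRecord]:
    """Peptide-bond planarity per selected residue.

    For residue i, the signed O(i−1)-C(i−1)-N(i)-H(i) dihedral and its
    deviation from the ideal trans amide (180°).  Deposited hydrogens are
    used when present; a rebuilt amide hydrogen is flagged on the record
    (rebuilding biases the deviation toward zero).  Prolines and residues
    without a preceding carbonyl are skipped with a notice.
    """
    positions = system.positions()
    records = []
    for ri in _resolve_residue_selection(system, residue_selection):
        res = system.residues[ri]
        if res.name == "PRO":
            warnings.warn(f"residue {ri} is proline (no amide H): skipped",
                          stacklevel=2)
            continue
        if ri == 0:
            continue
        prev = system.residues[ri - 1]
        roles = res.backbone_roles
        proles = prev.backbone_roles
        if "H_N" not in roles or "O" not in proles or "C" not in proles:
            continue
        chi = dihedral(positions[proles["O"]], positions[proles["C"]],
                       positions[roles["N"]], positions[roles["H_N"]])
        records.append(PlanarityRecord(
            residue_index=ri, residue_name=res.name, seq_id=res.seq_id,
            dihedral_OCNH=chi, deviation=wrap_angle(chi - 180.0),
            amide_h_rebuilt=res.amide_h_rebuilt))
    return records


# -------------------------------------------------------------------- RMSD

BACKBONE_SELECTION = ("N", "CA", "C", "O")


def _backbone_coords(system: ProteinSystem, selection) -> np.ndarray:
    coords = []
    for res in system.residues:
        if not res.is_amino_acid:
            continue
        for role in selection:
            if role in res.backbone_roles:
                coords.append(system.atoms[res.backbone_roles[role]].position)
    return np.array(coords, dtype=float)


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares optimal-superposition RMSD between two coordinate
    sets aligned 1:1 (rigid rotation + translation removed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"mismatched selections: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    diff = ac - rot.apply(bc)
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def backbone_rmsd(frame, reference,
                  selection=BACKBONE_SELECTION) -> float:
    """Backbone (N, CA, C, O) RMSD after optimal superposition.

    Arguments may be :class:`ProteinSystem` objects (backbone atoms taken
    through the role maps) or plain (n, 3) coordinate arrays.
    """
    a = _backbone_coords(frame, selection) \
        if isinstance(frame, ProteinSystem) else np.asarray(frame)
    b = _backbone_coords(reference, selection) \
        if isinstance(reference, ProteinSystem) else np.asarray(reference)
    return superposed_rmsd(a, b)


# ------------------------------------------------------------- drift stats

@dataclass(frozen=True)
class DriftStatistics:
    slope: float  # kcal/mol/ps
    slope_stderr: float  # kcal/mol/ps
    max_excursion: float  # max |E(t) − E(0)|, kcal/mol
    mean: float
    n_samples: int


def drift_statistics(energies, times_fs=None) -> DriftStatistics:
    """Least-squares slope of total energy vs time plus summary stats.

    ``times_fs`` defaults to sample index in fs.  Requires ≥ 100 samples
    (slopes from shorter series are dominated by oscillation phase).
    """
    e = np.asarray(energies, dtype=float)
    if len(e) < 100:
        raise ValueError(f"need >= 100 samples for drift statistics, "
                         f"got {len(e)}")
    t = np.arange(len(e), dtype=float) if times_fs is None \
        else np.asarray(times_fs, dtype=float)
    t_ps = t * 1e-3
    tc = t_ps - t_ps.mean()
    denom = float(np.sum(tc * tc))
    slope = float(np.sum(tc * (e - e.mean())) / denom)
    resid = e - e.mean() - slope * tc
    dof = max(len(e) - 2, 1)
    stderr = float(np.sqrt(np.sum(resid ** 2) / dof / denom))
    return DriftStatistics(
        slope=slope, slope_stderr=stderr,
        max_excursion=float(np.max(np.abs(e - e[0]))),
        mean=float(e.mean()), n_samples=len(e))


# -------------------------------------------------------------- histograms

def dihedral_histogram(system: ProteinSystem, frames, residue_selection,
                       bins: int = 36):
    """Per-residue histograms of the peptide-planarity deviation over a
    trajectory.

    ``frames`` is an iterable of (n_atoms, 3) position arrays on the
    topology of ``system``.  Returns ``{residue_index: (edges, prob)}``
    with probability mass per bin (sums to 1).
    """
    indices = _resolve_residue_selection(system, residue_selection)
    values: dict[int, list[float]] = {i: [] for i in indices}
    n_frames = 0
    original = system.positions()
    try:
        for pos in frames:
            n_frames += 1
            system.set_positions(np.asarray(pos))
            for rec in planarity_deviations(system, indices):
                values[rec.residue_index].append(rec.deviation)
    finally:
        system.set_positions(original)
    if n_frames == 0:
        raise ValueError("empty trajectory")
    out = {}
    edges = np.linspace(-180.0, 180.0, bins + 1)
    for ri, vals in values.items():
        counts, _ = np.histogram(vals, bins=edges)
        total = counts.sum()
        prob = counts / total if total else counts.astype(float)
        out[ri] = (edges, prob)
    return out


def histogram_table(hist: dict) -> str:
    """Plain-text tab-separated table of the histogram dictionary."""
    lines = ["residue\tbin_center\tprobability"]
    for ri, (edges, prob) in sorted(hist.items()):
        centers = 0.5 * (edges[:-1] + edges[1:])
        for c, p in zip(centers, prob):
            lines.append(f"{ri}\t{c:.1f}\t{p:.6f}")
    return "\n".join(lines)
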