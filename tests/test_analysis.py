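"""Dihedrals, planarity, RMSD, drift statistics, histograms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fbgmfcc.analysis import (
    CollinearError,
    backbone_rmsd,
    dihedral,
    dihedral_histogram,
    drift_statistics,
    planarity_deviations,
    superposed_rmsd,
    wrap_angle,
)
from fbgmfcc.structure import build_peptide


def _rotate_about_axis(point, origin, axis, angle_deg):
    rot = Rotation.from_rotvec(np.radians(angle_deg)
                               * axis / np.linalg.norm(axis))
    return origin + rot.apply(point - origin)


def test_dihedral_cis_trans():
    p1 = [1.0, 1.0, 0.0]
    p2 = [0.0, 1.0, 0.0]
    p3 = [0.0, 0.0, 0.0]
    cis = [1.0, 0.0, 0.0]
    trans = [-1.0, 0.0, 0.0]
    assert dihedral(p1, p2, p3, cis) == pytest.approx(0.0, abs=1e-12)
    assert dihedral(p1, p2, p3, trans) == pytest.approx(180.0, abs=1e-12)


@pytest.mark.parametrize("angle", [60.0, -60.0, 10.0, 179.5, -90.0])
def test_dihedral_constructed_rotation(angle):
    """A staggered fixture built by explicitly rotating the fourth point
    about the central bond reads back the applied angle."""
    p1 = np.array([1.0, 1.0, 0.0])
    p2 = np.array([0.0, 1.0, 0.0])
    p3 = np.array([0.0, 0.0, 0.0])
    p4_cis = np.array([1.0, 0.0, 0.0])
    axis = p3 - p2
    p4 = _rotate_about_axis(p4_cis, p3, axis, angle)
    assert dihedral(p1, p2, p3, p4) == pytest.approx(angle, abs=1e-6)


def test_dihedral_collinear_error():
    with pytest.raises(CollinearError):
        dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


@given(st.integers(0, 2 ** 31 - 1))
def test_dihedral_rigid_invariance_and_reflection_flip(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-3, 3, (4, 3))
    try:
        ref = dihedral(*pts)
    except CollinearError:
        return
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-10, 10, 3)
    moved = pts @ rot.T + shift
    assert dihedral(*moved) == pytest.approx(ref, abs=1e-8)
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    if abs(abs(ref) - 180.0) > 1e-6 and abs(ref) > 1e-6:
        assert dihedral(*mirrored) == pytest.approx(-ref, abs=1e-8)


def test_wrap_angle_range():
    assert wrap_angle(190.0) == pytest.approx(-170.0)
    assert wrap_angle(-190.0) == pytest.approx(170.0)
    assert wrap_angle(180.0) == 180.0
    assert wrap_angle(-180.0) == 180.0


def test_ideal_peptide_is_planar(ala9):
    for rec in planarity_deviations(ala9):
        assert rec.deviation == pytest.approx(0.0, abs=1e-6)
        assert rec.dihedral_OCNH == pytest.approx(180.0, abs=1e-6)


def test_planar_trans_regardless_of_bond_metrics():
    """Any exactly planar trans O-C-N-H arrangement has zero deviation,
    whatever the bond lengths and in-plane angles."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        c = np.zeros(3)
        o = c + rng.uniform(0.8, 2.0) * _unit_xy(rng)
        n = c - rng.uniform(0.8, 2.0) * _unit_xy(rng)
        # H on the opposite side of the C-N axis from O, in plane
        h = n + rng.uniform(0.5, 1.5) * _unit_xy(rng)
        ang = dihedral(o, c, n, h)
        if abs(ang) < 1e-9 or abs(abs(ang) - 180.0) < 1e-9:
            assert wrap_angle(ang - 180.0) in (0.0, 180.0)


def _unit_xy(rng):
    a = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(a), np.sin(a), 0.0])


def test_planarity_recovers_constructed_deviation():
    """Twisting the amide hydrogen out of plane by a known angle is read
    back exactly — the synthetic stand-in for a deposited structure with
    non-planar peptide bonds."""
    system = build_peptide(["A", "A", "A"])
    target = {2: 12.88, 3: -9.34}
    pos = system.positions()
    for ri, dev in target.items():
        res = system.residues[ri]
        prev = system.residues[ri - 1]
        n = pos[res.backbone_roles["N"]]
        c = pos[prev.backbone_roles["C"]]
        h_idx = res.backbone_roles["H_N"]
        pos[h_idx] = _rotate_about_axis(pos[h_idx], n, n - c, dev)
    system.set_positions(pos)
    records = {r.residue_index: r for r in planarity_deviations(system)}
    for ri, dev in target.items():
        assert records[ri].deviation == pytest.approx(dev, abs=1e-6)


def test_rmsd_identity_rigid_and_symmetry(ala9):
    pos = ala9.positions()
    assert superposed_rmsd(pos, pos) == pytest.approx(0.0, abs=1e-9)
    rng = np.random.default_rng(6)
    rot = Rotation.random(rng=rng).as_matrix()
    moved = pos @ rot.T + rng.uniform(-9, 9, 3)
    assert superposed_rmsd(pos, moved) == pytest.approx(0.0, abs=1e-9)
    rng2 = np.random.default_rng(7)
    other = pos + 0.3 * rng2.normal(size=pos.shape)
    assert superposed_rmsd(pos, other) \
        == pytest.approx(superposed_rmsd(other, pos), abs=1e-9)


def test_rmsd_against_rotation_search_oracle():
    """Closed-form superposition agrees with an independent numerical
    minimization over rotations on a small asymmetric cloud."""
    from scipy.optimize import minimize
    rng = np.random.default_rng(12)
    a = rng.uniform(-2, 2, (5, 3))
    b = a @ Rotation.from_euler("xyz", [0.4, -0.8, 1.1]).as_matrix().T
    b += 0.2 * rng.normal(size=a.shape) + np.array([1.0, 2.0, 3.0])
    got = superposed_rmsd(a, b)

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec)
        return np.sqrt(np.mean(np.sum((ac - r.apply(bc)) ** 2, axis=1)))

    best = min(
        (minimize(objective, x0, method="Nelder-Mead",
                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
         for x0 in [np.zeros(3), [1, 0, 0], [0, 2, 0], [1, 1, 1],
                    [-1, 1, -2], [2, -2, 1]]),
        key=lambda r: r.fun)
    assert got == pytest.approx(best.fun, abs=1e-8)


def test_rmsd_mismatched_selection_errors():
    with pytest.raises(ValueError):
        superposed_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


def test_backbone_rmsd_on_systems(ala9, helix12):
    assert backbone_rmsd(ala9, ala9) == pytest.approx(0.0, abs=1e-9)


def test_drift_statistics_closed_forms():
    const = np.full(200, 5.0)
    s = drift_statistics(const)
    assert s.slope == pytest.approx(0.0, abs=1e-12)
    assert s.max_excursion == 0.0
    t = np.arange(500, dtype=float)
    lin = 2.0 + 0.003 * t  # slope 3.0 kcal/mol/ps with t in fs
    s = drift_statistics(lin, times_fs=t)
    assert s.slope == pytest.approx(3.0, rel=1e-12)
    with pytest.raises(ValueError):
        drift_statistics(np.zeros(50))


def test_drift_statistics_white_noise_slope_within_3_stderr():
    rng = np.random.default_rng(21)
    e = rng.normal(size=1000)
    s = drift_statistics(e)
    assert abs(s.slope) < 3.0 * s.slope_stderr


def test_histogram_single_frame_delta(ala9):
    h = dihedral_histogram(ala9, [ala9.positions()], [2], bins=36)
    edges, prob = h[2]
    assert prob.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.count_nonzero(prob) == 1


def test_histogram_empty_trajectory(ala9):
    with pytest.raises(ValueError):
        dihedral_histogram(ala9, [], [2])


def test_histogram_mode_tracks_generator():
    """Frames with a von-Mises-perturbed deviation around +15° (the
    middle of a 10°-wide bin): the histogram mode falls in the bin
    containing the generator mean."""
    system = build_peptide(["A", "A", "A"])
    base = system.positions()
    res = system.residues[2]
    prev = system.residues[1]
    n = base[res.backbone_roles["N"]]
    c = base[prev.backbone_roles["C"]]
    h_idx = res.backbone_roles["H_N"]
    rng = np.random.default_rng(17)
    frames = []
    for dev in np.degrees(rng.vonmises(np.radians(15.0), 80.0, size=2000)):
        pos = base.copy()
        pos[h_idx] = _rotate_about_axis(pos[h_idx], n, n - c, dev)
        frames.append(pos)
    h = dihedral_histogram(system, frames, [2], bins=36)
    edges, prob = h[2]
    assert prob.sum() == pytest.approx(1.0, abs=1e-9)
    mode_bin = np.argmax(prob)
    assert edges[mode_bin] <= 15.0 < edges[mode_bin + 1]
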