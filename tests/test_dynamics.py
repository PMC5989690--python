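"""Integrators, thermostat, restraints, checkpointing."""

import numpy as np
import pytest

from fbgmfcc.constants import KB_KCALMOL, MD_FORCE_CONV
from fbgmfcc.dynamics import (
    MDRun,
    MDState,
    RestraintSpec,
    heating_protocol,
    langevin_step,
    load_checkpoint,
    maxwell_boltzmann_velocities,
    nve_step,
    restraint_energy_forces,
    run_trajectory,
    save_checkpoint,
)


def _harmonic_provider(k):
    def provider(x):
        return k * float(np.sum(x * x)), -2.0 * k * x
    return provider


def _harmonic_state(seed=0, n=1, mass=12.0, x0=1.0):
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    pos[:, 0] = x0
    return MDState(positions=pos, velocities=np.zeros((n, 3)),
                   masses=np.full(n, mass), rng=rng)


def test_nve_conserves_energy_on_harmonic_oscillator():
    """10⁴ velocity-Verlet steps at dt = period/100: relative drift of
    the closed-form-conserved energy below 1e-4."""
    k, m = 50.0, 12.0
    omega = np.sqrt(2.0 * k * MD_FORCE_CONV / m)  # rad/fs
    dt = 2 * np.pi / omega / 100.0
    state = _harmonic_state(mass=m)
    provider = _harmonic_provider(k)
    state.energy, state.forces = provider(state.positions)
    e0 = state.energy + state.kinetic_energy()
    for _ in range(10_000):
        nve_step(state, provider, dt)
    e1 = state.energy + state.kinetic_energy()
    assert abs(e1 - e0) / abs(e0) < 1e-4


def test_free_particle_moves_uniformly():
    state = _harmonic_state()
    state.velocities[0] = [0.01, -0.02, 0.005]
    v0 = state.velocities.copy()
    x0 = state.positions.copy()

    def provider(x):
        return 0.0, np.zeros_like(x)
    for _ in range(100):
        nve_step(state, provider, 1.0)
    assert np.allclose(state.positions, x0 + 100.0 * v0, atol=1e-12)
    assert np.array_equal(state.velocities, v0)


def test_zero_dt_only_advances_step_counter():
    state = _harmonic_state()
    x0, v0 = state.positions.copy(), state.velocities.copy()
    nve_step(state, _harmonic_provider(10.0), 0.0)
    assert np.array_equal(state.positions, x0)
    assert np.array_equal(state.velocities, v0)
    assert state.step == 1 and state.time == 0.0


def test_langevin_gamma_zero_is_bitwise_nve():
    provider = _harmonic_provider(30.0)
    a = _harmonic_state(seed=3)
    b = _harmonic_state(seed=3)
    a.velocities[0, 0] = b.velocities[0, 0] = 0.01
    for _ in range(50):
        nve_step(a, provider, 0.7)
        langevin_step(b, provider, 0.7, temperature=300.0, gamma_per_ps=0.0)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.velocities, b.velocities)


def test_langevin_seeded_reproducibility():
    provider = _harmonic_provider(30.0)
    runs = []
    for _ in range(2):
        st = _harmonic_state(seed=11)
        for _ in range(200):
            langevin_step(st, provider, 1.0, 300.0, 2.0)
        runs.append(st.positions.copy())
    assert np.array_equal(runs[0], runs[1])


def test_langevin_gamma_to_zero_approaches_nve():
    provider = _harmonic_provider(30.0)
    ref = _harmonic_state(seed=5)
    ref.velocities[0, 0] = 0.01
    for _ in range(100):
        nve_step(ref, provider, 0.5)
    devs = []
    for gamma in (1.0, 0.1, 0.01):
        st = _harmonic_state(seed=5)
        st.velocities[0, 0] = 0.01
        for _ in range(100):
            langevin_step(st, provider, 0.5, 300.0, gamma)
        devs.append(np.max(np.abs(st.positions - ref.positions)))
    assert devs[0] > devs[1] > devs[2]
    assert devs[2] < 1e-2


def test_langevin_equipartition_short():
    """Kinetic temperature relaxes to the thermostat setpoint (short
    sanity run; the long calibrated check is in the acceptance suite)."""
    provider = _harmonic_provider(100.0)
    st = _harmonic_state(seed=1)
    temps = []
    for i in range(40_000):
        langevin_step(st, provider, 1.0, 300.0, 2.0)
        if i > 5_000:
            temps.append(st.temperature())
    assert np.mean(temps) == pytest.approx(300.0, rel=0.2)


def test_positional_restraint_zero_at_reference():
    ref = np.array([[1.0, 2.0, 3.0]])
    spec = RestraintSpec("backbone_positional", 50.0, ref,
                         atom_indices=np.array([0]))
    e, f = restraint_energy_forces(spec, ref.copy())
    assert e == 0.0
    assert np.all(f == 0.0)
    e, f = restraint_energy_forces(spec, ref + [0.0, 0.1, 0.0])
    assert e == pytest.approx(50.0 * 0.01)
    assert f[0, 1] == pytest.approx(-2.0 * 50.0 * 0.1)


def test_half_harmonic_wall_piecewise():
    spec = RestraintSpec("spherical_half_harmonic", 20.0,
                         (np.zeros(3), 5.0))
    inside = np.array([[3.0, 0.0, 0.0]])
    e, f = restraint_energy_forces(spec, inside)
    assert e == 0.0 and np.all(f == 0.0)
    outside = np.array([[6.0, 0.0, 0.0]])
    e, f = restraint_energy_forces(spec, outside)
    assert e == pytest.approx(20.0)
    assert f[0, 0] == pytest.approx(-2.0 * 20.0 * 1.0)  # inward


def test_heating_ramp_reaches_target():
    """0 → 300 K ramp on a cluster of harmonic wells: the final tenth of
    the run averages within 20% of the target."""
    provider = _harmonic_provider(50.0)
    rng = np.random.default_rng(2)
    st = MDState(positions=rng.normal(size=(10, 3)) * 0.1,
                 velocities=np.zeros((10, 3)),
                 masses=np.full(10, 16.0), rng=rng)
    temps = []
    heating_protocol(st, provider, [(4000.0, 300.0)], dt=1.0,
                     gamma_per_ps=5.0,
                     callback=lambda s, setpoint: temps.append(s.temperature()))
    tail = temps[-len(temps) // 10:]
    assert np.mean(tail) == pytest.approx(300.0, rel=0.2)


def test_checkpoint_resume_is_bitwise():
    provider = _harmonic_provider(30.0)
    a = _harmonic_state(seed=9, n=3)
    a.velocities += 0.01
    for _ in range(20):
        langevin_step(a, provider, 1.0, 300.0, 2.0)

    b = _harmonic_state(seed=9, n=3)
    b.velocities += 0.01
    for _ in range(10):
        langevin_step(b, provider, 1.0, 300.0, 2.0)
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".chk") as fh:
        save_checkpoint(b, fh.name)
        c = load_checkpoint(fh.name)
    for _ in range(10):
        langevin_step(c, provider, 1.0, 300.0, 2.0)
    assert np.array_equal(a.positions, c.positions)
    assert np.array_equal(a.velocities, c.velocities)
    assert a.step == c.step


def test_trajectory_stride_frame_count(tmp_path):
    """100 steps at stride 10 → 11 frames, frame 0 included."""
    from fbgmfcc.assembly import FBGMFCCCalculator
    from fbgmfcc.backends import MockBackend
    from fbgmfcc.structure import build_peptide, read_xyz_trajectory

    system = build_peptide(["A"])
    calc = FBGMFCCCalculator(system, backend=MockBackend())
    rng = np.random.default_rng(1)
    state = MDState(positions=system.positions(),
                    velocities=maxwell_boltzmann_velocities(
                        system.masses(), 100.0, rng),
                    masses=system.masses(), rng=rng)
    run = MDRun(trajectory_path=str(tmp_path / "t.xyz"),
                energy_log_path=str(tmp_path / "e.log"), stride=10)
    run_trajectory(state, calc, 100, 0.5, run=run, system=system)
    assert len(read_xyz_trajectory(tmp_path / "t.xyz")) == 11
    log_lines = (tmp_path / "e.log").read_text().splitlines()
    assert log_lines[0].startswith("# step")
    log_rows = [ln for ln in log_lines if ln.strip() and not ln.startswith("#")]
    assert len(log_rows) == 101


def test_maxwell_boltzmann_statistics():
    rng = np.random.default_rng(0)
    masses = np.full(4000, 18.0)
    v = maxwell_boltzmann_velocities(masses, 250.0, rng, remove_com=True)
    ke = 0.5 * np.sum(masses[:, None] * v ** 2) / MD_FORCE_CONV
    t = 2 * ke / (3 * len(masses) * KB_KCALMOL)
    assert t == pytest.approx(250.0, rel=0.05)
    assert np.allclose((masses[:, None] * v).sum(axis=0), 0.0, atol=1e-9)
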