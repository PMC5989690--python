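"""Molecular dynamics on the fragment-assembled surface.

Velocity-Verlet NVE and BAOAB-discretized Langevin integration (the
γ → 0 limit of the latter reduces bitwise to the former — both run the
same symmetric drift/kick sequence and the noise step is skipped when
γ = 0).  Units: Å, fs, amu, kcal/mol; the single conversion constant
``MD_FORCE_CONV`` turns kcal/mol/Å per amu into Å/fs².

Temperatures are kinetic, with 3N degrees of freedom (production runs are
unconstrained).  Restraints (harmonic positional on a selection; spherical
half-harmonic wall for water balls) are additive force terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import KB_KCALMOL, KE_CONV, MD_FORCE_CONV


@dataclass
class MDState:
    positions: np.ndarray  # (n, 3) Å
    velocities: np.ndarray  # (n, 3) Å/fs
    masses: np.ndarray  # (n,) amu
    time: float = 0.0  # fs
    step: int = 0
    rng: np.random.Generator = None
    #: cached (energy, forces) at ``positions``; invalidated by integration
    energy: float | None = None
    forces: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.rng is None:
            self.rng = np.random.default_rng(0)
        for arr in (self.positions, self.velocities):
            if arr.shape != (len(self.masses), 3):
                raise ValueError("inconsistent MDState array shapes")
        if not (np.all(np.isfinite(self.positions))
                and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite MDState")

    def kinetic_energy(self) -> float:
        return 0.5 * KE_CONV * float(
            np.sum(self.masses[:, None] * self.velocities ** 2))

    def temperature(self) -> float:
        n_dof = 3 * len(self.masses)
        return 2.0 * self.kinetic_energy() / (n_dof * KB_KCALMOL)


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator,
                                 remove_com: bool = True) -> np.ndarray:
    sigma = np.sqrt(KB_KCALMOL * temperature * MD_FORCE_CONV / masses)
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    if remove_com and temperature > 0:
        p = (masses[:, None] * v).sum(axis=0)
        v -= p / masses.sum()
    return v


@dataclass
class RestraintSpec:
    kind: str  # backbone_positional | spherical_half_harmonic
    force_constant: float  # kcal/mol/Å²
    reference: object  # positions array, or (center, radius)
    atom_indices: np.ndarray | None = None  # default: all atoms

    def __post_init__(self):
        if self.kind not in ("backbone_positional", "spherical_half_harmonic"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")


def restraint_energy_forces(spec: RestraintSpec,
                            positions: np.ndarray) -> tuple[float, np.ndarray]:
    forces = np.zeros_like(positions)
    idx = spec.atom_indices if spec.atom_indices is not None \
        else np.arange(len(positions))
    k = spec.force_constant
    if spec.kind == "backbone_positional":
        ref = np.asarray(spec.reference, dtype=float)
        dx = positions[idx] - ref
        forces[idx] = -2.0 * k * dx
        return k * float(np.sum(dx * dx)), forces
    center, radius = spec.reference
    center = np.asarray(center, dtype=float)
    dx = positions[idx] - center
    r = np.linalg.norm(dx, axis=1)
    out = r > radius
    if not np.any(out):
        return 0.0, forces
    dr = r[out] - radius
    u = dx[out] / r[out][:, None]
    forces[idx[out]] = -2.0 * k * dr[:, None] * u
    return k * float(np.sum(dr * dr)), forces


def _combined_provider(force_provider, restraints):
    if not restraints:
        return force_provider

    def provider(x):
        e, f = force_provider(x)
        for spec in restraints:
            er, fr = restraint_energy_forces(spec, x)
            e += er
            f = f + fr
        return e, f
    return provider


def _baoab_step(state: MDState, force_provider, dt: float,
                temperature: float, gamma_per_fs: float) -> MDState:
    """One BAOAB step; with γ = 0 the O-step is the identity and the
    sequence is exactly velocity Verlet (half kick, two half drifts with
    unchanged velocity, half kick)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if state.forces is None:
        state.energy, state.forces = force_provider(state.positions)
    inv_m = MD_FORCE_CONV / state.masses[:, None]
    v = state.velocities + 0.5 * dt * state.forces * inv_m
    x = state.positions + 0.5 * dt * v
    if gamma_per_fs > 0.0:
        c1 = np.exp(-gamma_per_fs * dt)
        sigma = np.sqrt((1.0 - c1 * c1) * KB_KCALMOL * max(temperature, 0.0)
                        * MD_FORCE_CONV / state.masses)
        v = c1 * v + sigma[:, None] * state.rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    energy, forces = force_provider(x)
    v = v + 0.5 * dt * forces * inv_m
    state.positions = x
    state.velocities = v
    state.energy = energy
    state.forces = forces
    state.time += dt
    state.step += 1
    return state


def nve_step(state: MDState, force_provider, dt: float) -> MDState:
    """Standard velocity-Verlet microcanonical step."""
    return _baoab_step(state, force_provider, dt, 0.0, 0.0)


def langevin_step(state: MDState, force_provider, dt: float,
                  temperature: float, gamma_per_ps: float,
                  rng: np.random.Generator | None = None) -> MDState:
    """BAOAB Langevin step; collision frequency in ps⁻¹."""
    if gamma_per_ps < 0 or temperature < 0:
        raise ValueError("gamma and temperature must be >= 0")
    if rng is not None:
        state.rng = rng
    return _baoab_step(state, force_provider, dt, temperature,
                       gamma_per_ps * 1e-3)


def heating_protocol(state: MDState, force_provider,
                     schedule: list[tuple[float, float]],
                     dt: float = 1.0, gamma_per_ps: float = 2.0,
                     restraints: list[RestraintSpec] | None = None,
                     start_temperature: float = 0.0,
                     callback=None) -> MDState:
    """Langevin run with a piecewise-linear thermostat-setpoint ramp.

    ``schedule`` is a list of (duration fs, target T); within each segment
    the setpoint ramps linearly from the previous target (initially
    ``start_temperature``).
    """
    provider = _combined_provider(force_provider, restraints or [])
    t_prev = start_temperature
    for duration, target in schedule:
        n_steps = max(1, int(round(duration / dt)))
        for k in range(n_steps):
            setpoint = t_prev + (target - t_prev) * (k + 1) / n_steps
            _baoab_step(state, provider, dt, setpoint, gamma_per_ps * 1e-3)
            if callback is not None:
                callback(state, setpoint)
        t_prev = target
    return state


# ------------------------------------------------------------- checkpoints

def save_checkpoint(state: MDState, path) -> None:
    """Self-describing text dump of the full MD state (bit-exact floats,
    including the RNG state, so a resumed run continues identically)."""
    doc = {
        "step": state.step,
        "time": state.time,
        "n_atoms": len(state.masses),
        "masses": state.masses.tolist(),
        "positions": [[x.hex() for x in row] for row in state.positions],
        "velocities": [[x.hex() for x in row] for row in state.velocities],
        "rng_state": _jsonable(state.rng.bit_generator.state),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _unjsonable(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.array(obj["__ndarray__"], dtype=obj["dtype"])
        return {k: _unjsonable(v) for k, v in obj.items()}
    return obj


def load_checkpoint(path) -> MDState:
    doc = json.loads(Path(path).read_text())
    rng = np.random.default_rng(0)
    rng.bit_generator.state = _unjsonable(doc["rng_state"])
    return MDState(
        positions=np.array([[float.fromhex(x) for x in row]
                            for row in doc["positions"]]),
        velocities=np.array([[float.fromhex(x) for x in row]
                             for row in doc["velocities"]]),
        masses=np.array(doc["masses"]),
        time=doc["time"], step=doc["step"], rng=rng,
    )


# ---------------------------------------------------------------- MD runs

@dataclass
class MDRun:
    """Trajectory/energy-log bookkeeping for a production run."""
    trajectory_path: str | None = None
    energy_log_path: str | None = None
    checkpoint_path: str | None = None
    stride: int = 10
    energy_rows: list = field(default_factory=list)


def run_trajectory(state: MDState, calculator, n_steps: int, dt: float,
                   ensemble: str = "nve", temperature: float = 300.0,
                   gamma_per_ps: float = 2.0,
                   restraints: list[RestraintSpec] | None = None,
                   run: MDRun | None = None,
                   system=None) -> MDState:
    """Integrate ``n_steps`` on a calculator surface, logging energies per
    step and writing XYZ frames at the configured stride (frame 0
    included)."""
    from .structure import write_xyz_frame

    if run is None:
        run = MDRun()
    ef_holder = {}

    def provider(x):
        ef = calculator.energy_forces(x)
        ef_holder["ef"] = ef
        return ef.total_energy, ef.forces

    provider_r = _combined_provider(provider, restraints or [])

    log_fh = None
    if run.energy_log_path:
        from .assembly import ENERGY_LOG_HEADER
        fresh = True
        try:
            fresh = not open(run.energy_log_path).read().strip()
        except OSError:
            pass
        log_fh = open(run.energy_log_path, "a")
        if fresh:
            log_fh.write(ENERGY_LOG_HEADER + "\n")

    def record(write_frame: bool):
        ef = ef_holder.get("ef")
        ke = state.kinetic_energy()
        total = state.energy + ke  # the conserved quantity (restraints in)
        row = (state.step, state.time, total, state.energy, ke,
               state.temperature())
        run.energy_rows.append(row)
        if log_fh is not None and ef is not None:
            log_fh.write(ef.log_line(state.step)
                         + f" {ke:.10f} {total:.10f} "
                         f"{state.temperature():.3f}\n")
        if write_frame and run.trajectory_path and system is not None:
            system.set_positions(state.positions)
            write_xyz_frame(
                system, run.trajectory_path, append=True,
                comment=f"step={state.step} time={state.time:.1f}fs "
                        f"E={total:.6f}")

    if state.forces is None:
        state.energy, state.forces = provider_r(state.positions)
        record(write_frame=True)
    try:
        for _ in range(n_steps):
            if ensemble == "nve":
                _baoab_step(state, provider_r, dt, 0.0, 0.0)
            elif ensemble == "langevin":
                _baoab_step(state, provider_r, dt, temperature,
                            gamma_per_ps * 1e-3)
            else:
                raise ValueError(f"unknown ensemble {ensemble!r}")
            record(write_frame=state.step % run.stride == 0)
            if run.checkpoint_path and state.step % (run.stride * 10) == 0:
                save_checkpoint(state, run.checkpoint_path)
    finally:
        if run.checkpoint_path:
            save_checkpoint(state, run.checkpoint_path)
        if log_fh is not None:
            log_fh.close()
    return state
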