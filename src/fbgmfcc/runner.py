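"""End-to-end run orchestration from a validated RunConfig."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .assembly import FBGMFCCCalculator
from .backends import MockBackend
from .config import RunConfig
from .dynamics import (
    MDRun,
    MDState,
    RestraintSpec,
    heating_protocol,
    load_checkpoint,
    maxwell_boltzmann_velocities,
    run_trajectory,
)
from .structure import ProteinSystem, build_peptide, build_water_ball, read_pdb


def build_system_from_config(cfg: RunConfig) -> ProteinSystem:
    sys_cfg = cfg["system"]
    if sys_cfg["source"] == "builder":
        system = build_peptide(sys_cfg["sequence"], n_cap=sys_cfg["n_cap"],
                               c_cap=sys_cfg["c_cap"],
                               geometry=sys_cfg["geometry"])
    else:
        system = read_pdb(sys_cfg["pdb_path"])
    if sys_cfg["n_waters"] > 0:
        system = build_water_ball(system, sys_cfg["n_waters"],
                                  seed=sys_cfg["solvent_seed"])
    return system


def build_calculator(cfg: RunConfig, system: ProteinSystem) -> FBGMFCCCalculator:
    backend = MockBackend(cap_transparent=cfg["backend"]["cap_transparent"])
    return FBGMFCCCalculator(
        system, backend=backend, mode=cfg["dynamics"]["balance_mode"],
        include_twobody=cfg["dynamics"]["include_twobody"],
        bond_k=cfg["mm"]["bond_k"], angle_k=cfg["mm"]["angle_k"],
        parallel_width=cfg["backend"]["parallel_width"])


def _restraints(cfg: RunConfig, system: ProteinSystem) -> list[RestraintSpec]:
    out = []
    r_cfg = cfg["restraints"]
    if r_cfg["backbone_k"] > 0:
        idx = []
        for res in system.residues:
            for role in ("N", "CA", "C", "O"):
                if role in res.backbone_roles:
                    idx.append(res.backbone_roles[role])
        idx = np.array(sorted(idx), dtype=int)
        out.append(RestraintSpec(
            kind="backbone_positional", force_constant=r_cfg["backbone_k"],
            reference=system.positions()[idx], atom_indices=idx))
    if r_cfg["boundary_k"] > 0:
        solvent = np.array(system.solvent_atom_indices(), dtype=int)
        heavy = np.array([a.position for a in system.atoms
                          if a.element != "H"])
        center = heavy.mean(axis=0)
        radius = r_cfg["boundary_radius"]
        if radius <= 0:
            sol_pos = system.positions()[solvent] if len(solvent) else heavy
            radius = float(np.max(np.linalg.norm(sol_pos - center, axis=1))) + 1.0
        out.append(RestraintSpec(
            kind="spherical_half_harmonic", force_constant=r_cfg["boundary_k"],
            reference=(center, radius),
            atom_indices=solvent if len(solvent) else None))
    return out


def run_md_config(cfg: RunConfig, restart=None) -> tuple[MDState, MDRun]:
    """Build the system and calculator, then integrate per the [dynamics]
    section.  ``restart`` resumes bitwise from a checkpoint file."""
    system = build_system_from_config(cfg)
    calc = build_calculator(cfg, system)
    dyn = cfg["dynamics"]

    if restart is not None:
        state = load_checkpoint(restart)
    else:
        rng = np.random.default_rng(dyn["seed"])
        velocities = maxwell_boltzmann_velocities(
            system.masses(), dyn["initial_temperature"], rng,
            remove_com=dyn["ensemble"] == "nve")
        state = MDState(positions=system.positions(), velocities=velocities,
                        masses=system.masses(), rng=rng)

    out_cfg = cfg["output"]
    for key in ("trajectory", "energy_log"):
        if out_cfg[key] and restart is None:
            Path(out_cfg[key]).write_text("")
    run = MDRun(trajectory_path=out_cfg["trajectory"] or None,
                energy_log_path=out_cfg["energy_log"] or None,
                checkpoint_path=out_cfg["checkpoint"] or None,
                stride=out_cfg["stride"])
    restraints = _restraints(cfg, system)

    if dyn["ensemble"] == "heating":
        def provider(x):
            ef = calc.energy_forces(x)
            return ef.total_energy, ef.forces
        heating_protocol(state, provider, cfg.heating_schedule(),
                         dt=dyn["dt"], gamma_per_ps=dyn["gamma"],
                         restraints=restraints,
                         start_temperature=dyn["initial_temperature"])
        if run.checkpoint_path:
            from .dynamics import save_checkpoint
            save_checkpoint(state, run.checkpoint_path)
        return state, run

    run_trajectory(state, calc, dyn["steps"], dyn["dt"],
                   ensemble=dyn["ensemble"], temperature=dyn["temperature"],
                   gamma_per_ps=dyn["gamma"], restraints=restraints,
                   run=run, system=system)
    return state, run
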