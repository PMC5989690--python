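"""Energy providers for capped fragments.

Every provider implements ``evaluate(EnergyRequest) -> EnergyResult`` with
energies in kcal/mol and forces in kcal/mol/Å.  Two providers ship:

* :class:`MockBackend` — a smooth analytic potential (Coulomb + 12-6 plus
  harmonic bond/angle terms at a reference geometry) with exact analytic
  gradients.  It makes the whole assembly/dynamics stack testable at desk
  scale, and because the same functional form can serve as the classical
  pair model, the fragment bookkeeping can be validated against a direct
  full-system evaluation to machine precision.
* :class:`ExternalEngineAdapter` — a contract for driving a quantum-
  chemistry engine through text files (XYZ in, a 2-line-header result block
  out, hartree / hartree·bohr⁻¹), with unit conversion and provenance
  recording.  It is engine-agnostic by design.
"""

from __future__ import annotations

import hashlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    BOHR_TO_ANGSTROM,
    COULOMB_CONSTANT,
    HARTREE_TO_KCALMOL,
)


@dataclass
class RequestTopology:
    """Optional per-atom parameters and valence topology carried by a
    request; used by the mock backend, ignored by external engines."""

    charges: np.ndarray | None = None  # (n,), e
    eps: np.ndarray | None = None  # (n,), kcal/mol
    rmin2: np.ndarray | None = None  # (n,), Å (rmin/2)
    bonds: np.ndarray | None = None  # (k, 2) int local indices
    bond_r0: np.ndarray | None = None  # (k,), Å
    bond_k: np.ndarray | None = None  # (k,), kcal/mol/Å²
    angles: np.ndarray | None = None  # (m, 3) int, vertex in the middle
    angle_theta0: np.ndarray | None = None  # (m,), rad
    angle_k: np.ndarray | None = None  # (m,), kcal/mol/rad²
    exclusions: np.ndarray | None = None  # (p, 2) int: pairs with no NB term
    #: pre-filtered non-bonded pair list; takes precedence over exclusions
    pair_i: np.ndarray | None = None
    pair_j: np.ndarray | None = None
    cap_indices: tuple[int, ...] = ()


@dataclass
class EnergyRequest:
    elements: list[str]
    positions: np.ndarray  # (n, 3), Å
    formal_charge: int = 0
    spin_multiplicity: int = 1
    label: str = ""
    topology: RequestTopology | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.elements), 3):
            raise ValueError("positions shape inconsistent with element list")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions in request")


@dataclass
class EnergyResult:
    energy: float  # kcal/mol
    forces: np.ndarray  # (n, 3), kcal/mol/Å
    converged: bool = True
    provenance: str = ""


class BackendError(RuntimeError):
    pass


# --------------------------------------------------------- analytic kernels

def pairwise_energy_forces(positions: np.ndarray, pairs_i: np.ndarray,
                           pairs_j: np.ndarray, qprod: np.ndarray,
                           eps: np.ndarray, rmin: np.ndarray,
                           forces: np.ndarray) -> float:
    """Coulomb + 12-6 over an explicit pair list; accumulates forces."""
    if len(pairs_i) == 0:
        return 0.0
    rvec = positions[pairs_i] - positions[pairs_j]
    r2 = np.einsum("ij,ij->i", rvec, rvec)
    r = np.sqrt(r2)
    inv_r = 1.0 / r
    e_coul = COULOMB_CONSTANT * qprod * inv_r
    s6 = (rmin * inv_r) ** 6
    e_lj = eps * (s6 * s6 - 2.0 * s6)
    # dE/dr
    dedr = -e_coul * inv_r + eps * (-12.0 * s6 * s6 + 12.0 * s6) * inv_r
    fpair = (-dedr * inv_r)[:, None] * rvec  # force on atom i
    np.add.at(forces, pairs_i, fpair)
    np.add.at(forces, pairs_j, -fpair)
    return float(np.sum(e_coul + e_lj))


def bond_energy_forces(positions: np.ndarray, bonds: np.ndarray,
                       r0: np.ndarray, k: np.ndarray,
                       forces: np.ndarray) -> float:
    """Harmonic bonds E = k (r − r0)²; accumulates forces."""
    if bonds is None or len(bonds) == 0:
        return 0.0
    i, j = bonds[:, 0], bonds[:, 1]
    rvec = positions[i] - positions[j]
    r = np.linalg.norm(rvec, axis=1)
    dr = r - r0
    dedr = 2.0 * k * dr
    f = (-dedr / r)[:, None] * rvec
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return float(np.sum(k * dr * dr))


def angle_energy_forces(positions: np.ndarray, angles: np.ndarray,
                        theta0: np.ndarray, k: np.ndarray,
                        forces: np.ndarray) -> float:
    """Harmonic angles E = k (θ − θ0)² with the vertex as middle index."""
    if angles is None or len(angles) == 0:
        return 0.0
    i, j, l = angles[:, 0], angles[:, 1], angles[:, 2]
    u = positions[i] - positions[j]
    v = positions[l] - positions[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 1e-12))
    dtheta = theta - theta0
    dedt = 2.0 * k * dtheta
    dth_di = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
    dth_dl = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
    np.add.at(forces, i, -dedt[:, None] * dth_di)
    np.add.at(forces, l, -dedt[:, None] * dth_dl)
    np.add.at(forces, j, dedt[:, None] * (dth_di + dth_dl))
    return float(np.sum(k * dtheta * dtheta))


#: fallback per-element parameters (charge e, eps kcal/mol, rmin/2 Å) for
#: bare requests that carry no per-atom table
DEFAULT_ELEMENT_PARAMS = {
    "H": (0.10, 0.0157, 0.60),
    "C": (0.05, 0.0860, 1.908),
    "N": (-0.40, 0.1700, 1.824),
    "O": (-0.45, 0.2100, 1.6612),
    "S": (-0.10, 0.2500, 2.000),
}


class MockBackend:
    """Analytic stand-in potential with exact gradients.

    Energy = Coulomb + 12-6 over non-excluded pairs, plus harmonic bond and
    angle terms at reference equilibria; C² in all coordinates.  With
    ``cap_transparent=True`` every term involving a capping hydrogen is
    zeroed, which turns fragment assembly into an exactly additive pair
    bookkeeping (used by the full-system identity tests).
    """

    def __init__(self, element_params: dict | None = None,
                 cap_transparent: bool = False,
                 default_bond_k: float = 300.0,
                 default_angle_k: float = 50.0):
        self.element_params = dict(DEFAULT_ELEMENT_PARAMS)
        if element_params:
            self.element_params.update(element_params)
        self.cap_transparent = cap_transparent
        self.default_bond_k = default_bond_k
        self.default_angle_k = default_angle_k

    @property
    def provenance(self) -> str:
        digest = hashlib.sha256(
            repr(sorted(self.element_params.items())).encode()
            + str(self.cap_transparent).encode()).hexdigest()[:12]
        return f"mock:{digest}"

    def evaluate(self, request: EnergyRequest) -> EnergyResult:
        n = len(request.elements)
        pos = request.positions
        topo = request.topology or RequestTopology()
        if topo.charges is not None:
            q = np.asarray(topo.charges, dtype=float)
            eps = np.asarray(topo.eps, dtype=float)
            rmin2 = np.asarray(topo.rmin2, dtype=float)
        else:
            try:
                rows = [self.element_params[e] for e in request.elements]
            except KeyError as exc:
                raise BackendError(f"no mock parameters for element {exc}") from None
            q = np.array([r[0] for r in rows])
            eps = np.array([r[1] for r in rows])
            rmin2 = np.array([r[2] for r in rows])

        caps = np.array(topo.cap_indices, dtype=int)
        if self.cap_transparent and caps.size:
            q = q.copy()
            eps = eps.copy()
            q[caps] = 0.0
            eps[caps] = 0.0

        forces = np.zeros((n, 3))
        # pair list: pre-filtered if supplied, else all i<j minus exclusions
        # (cap terms zeroed via parameters when transparent)
        if topo.pair_i is not None:
            iu, ju = topo.pair_i, topo.pair_j
        else:
            iu, ju = np.triu_indices(n, k=1)
            if topo.exclusions is not None and len(topo.exclusions):
                excl = {(min(a, b), max(a, b))
                        for a, b in np.asarray(topo.exclusions)}
                keep = np.array([(a, b) not in excl for a, b in zip(iu, ju)])
                iu, ju = iu[keep], ju[keep]
        qprod = q[iu] * q[ju]
        eps_ij = np.sqrt(eps[iu] * eps[ju])
        rmin_ij = rmin2[iu] + rmin2[ju]
        # avoid 0^0 issues for pairs with zero eps and zero rmin
        rmin_ij = np.where(eps_ij > 0, rmin_ij, 1.0)
        energy = pairwise_energy_forces(pos, iu, ju, qprod, eps_ij, rmin_ij,
                                        forces)

        bonds, r0, bk = topo.bonds, topo.bond_r0, topo.bond_k
        angles, t0, ak = topo.angles, topo.angle_theta0, topo.angle_k
        if self.cap_transparent and caps.size:
            capset = set(caps.tolist())
            if bonds is not None and len(bonds):
                keep = np.array([not (a in capset or b in capset)
                                 for a, b in bonds])
                bonds, r0, bk = bonds[keep], r0[keep], bk[keep]
            if angles is not None and len(angles):
                keep = np.array([not (a in capset or b in capset or c in capset)
                                 for a, b, c in angles])
                angles, t0, ak = angles[keep], t0[keep], ak[keep]
        energy += bond_energy_forces(pos, bonds, r0, bk, forces)
        energy += angle_energy_forces(pos, angles, t0, ak, forces)
        return EnergyResult(energy=energy, forces=forces, converged=True,
                            provenance=self.provenance)


# ------------------------------------------------------- external engines

def parse_engine_result(text: str, n_atoms: int) -> tuple[float, np.ndarray]:
    """Parse the exchange result block: line 1 the energy in hartree,
    line 2 a free-form header, then one ``fx fy fz`` line per atom in
    hartree/bohr.  Bit-exact float parsing."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2 + n_atoms:
        raise BackendError(
            f"engine result block has {len(lines)} lines, need {2 + n_atoms}")
    energy_h = float(lines[0].split()[0])
    forces_hb = np.array(
        [[float(x) for x in ln.split()[:3]] for ln in lines[2:2 + n_atoms]])
    return energy_h, forces_hb


@dataclass
class ExternalEngineAdapter:
    """Adapter contract for an external quantum-chemistry engine.

    ``runner`` is any callable mapping an :class:`EnergyRequest` to the
    text result block (or raising on failure).  Energies/forces are
    converted from hartree and hartree/bohr to kcal/mol and kcal/mol/Å.
    """

    runner: object  # callable(EnergyRequest) -> str
    engine_name: str = "external"
    method: str = ""
    basis: str = ""
    settings: dict = field(default_factory=dict)

    @property
    def provenance(self) -> str:
        digest = hashlib.sha256(
            f"{self.engine_name}|{self.method}|{self.basis}|"
            f"{sorted(self.settings.items())}".encode()).hexdigest()[:12]
        return f"{self.engine_name}:{self.method}/{self.basis}:{digest}"

    def evaluate(self, request: EnergyRequest) -> EnergyResult:
        n = len(request.elements)
        try:
            text = self.runner(request)
            energy_h, forces_hb = parse_engine_result(text, n)
        except Exception as exc:
            return EnergyResult(
                energy=float("nan"), forces=np.full((n, 3), np.nan),
                converged=False,
                provenance=f"{self.provenance} FAILED: {str(exc)[:200]}")
        return EnergyResult(
            energy=energy_h * HARTREE_TO_KCALMOL,
            forces=forces_hb * (HARTREE_TO_KCALMOL / BOHR_TO_ANGSTROM),
            converged=True, provenance=self.provenance)


# ----------------------------------------------------------- batch driver

def fragment_batch_evaluate(fragments, system, backend, positions=None,
                            parallel_width: int = 1,
                            request_builder=None) -> dict:
    """Evaluate all fragments; returns ``{fragment: EnergyResult}``.

    Fragment evaluations are independent, so results do not depend on
    evaluation order or on ``parallel_width`` (bitwise for the mock
    backend).  Any non-converged fragment aborts with its label.
    """
    if not fragments:
        return {}
    if positions is None:
        positions = system.positions()
    if request_builder is None:
        def request_builder(frag):
            return EnergyRequest(
                elements=frag.elements(system),
                positions=frag.positions(positions),
                formal_charge=frag.formal_charge,
                spin_multiplicity=frag.spin_multiplicity,
                label=frag.label,
                topology=RequestTopology(
                    cap_indices=tuple(c.cap_hydrogen_local_index
                                      for c in frag.cap_records)),
            )
    requests = [request_builder(f) for f in fragments]
    if parallel_width <= 1 or len(fragments) <= 1:
        results = [backend.evaluate(r) for r in requests]
    else:
        with ThreadPoolExecutor(max_workers=parallel_width) as pool:
            results = list(pool.map(backend.evaluate, requests))
    out = {}
    for frag, res in zip(fragments, results):
        if not res.converged:
            raise BackendError(
                f"fragment {frag.label!r} did not converge: {res.provenance}")
        out[frag] = res
    return out
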