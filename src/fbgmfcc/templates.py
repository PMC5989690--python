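"""Residue templates: atoms, parameters, connectivity and ideal geometry.

Templates cover the blocking groups ACE / NME, the amino acids ALA and GLY,
and TIP3P water.  Non-bonded parameters (charge, 12-6) are read from the
plain-text table shipped in ``fbgmfcc/data/residue_params.txt``; the ideal
internal coordinates used by the peptide builder live here.

Internal-coordinate entries are z-matrix rows
``(name, bond_ref, r, angle_ref, theta, torsion_ref_a, torsion_ref_b, tau)``
where a leading ``-`` on a reference means "atom of the previous residue"
(resolved through its backbone-role map, so e.g. ``-CA`` is ACE's methyl
carbon).  ``tau`` may be a number (degrees) or one of the symbolic torsions
``PHI``, ``PHI+120``, ``PHI-120``, ``PSI+180`` resolved at build time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AtomParams:
    element: str
    mass: float
    charge: float
    eps: float
    rmin2: float


@dataclass
class ResidueTemplate:
    name: str
    atoms: list[str]
    params: dict[str, AtomParams]
    bonds: list[tuple[str, str]]
    #: map backbone role -> template atom name (ACE/NME methyl carbons play Cα)
    roles: dict[str, str] = field(default_factory=dict)
    zmatrix: list[tuple] = field(default_factory=list)
    is_amino_acid: bool = True


def _load_param_table() -> dict[str, dict[str, AtomParams]]:
    text = (
        importlib.resources.files("fbgmfcc").joinpath("data/residue_params.txt")
    ).read_text()
    table: dict[str, dict[str, AtomParams]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, elem, mass, q, eps, rmin2 = line.split()
        table.setdefault(res, {})[atom] = AtomParams(
            elem, float(mass), float(q), float(eps), float(rmin2)
        )
    return table


_PARAMS = _load_param_table()

# ideal bond lengths / angles shared by the builder
PEPTIDE_CN = 1.335  # C(i)-N(i+1), Å

_BACKBONE_N = ("N", "-C", PEPTIDE_CN, "-CA", 116.6, "-O", "-CA", 180.0)
_BACKBONE_H = ("H", "N", 1.010, "-C", 119.0, "-O", "-C", 180.0)
_BACKBONE_CA = ("CA", "N", 1.458, "-C", 121.9, "-CA", "-C", 180.0)
_BACKBONE_C = ("C", "CA", 1.522, "N", 111.1, "-C", "N", "PHI")
_BACKBONE_O = ("O", "C", 1.229, "CA", 120.5, "N", "CA", "PSI+180")


def _aa_zmatrix(side_chain_rows: list[tuple]) -> list[tuple]:
    return [
        _BACKBONE_N,
        _BACKBONE_H,
        _BACKBONE_CA,
        *side_chain_rows,
        _BACKBONE_C,
        _BACKBONE_O,
    ]


RESIDUE_TEMPLATES: dict[str, ResidueTemplate] = {
    "ACE": ResidueTemplate(
        name="ACE",
        atoms=["CH3", "HH31", "HH32", "HH33", "C", "O"],
        params=_PARAMS["ACE"],
        bonds=[("CH3", "HH31"), ("CH3", "HH32"), ("CH3", "HH33"),
               ("CH3", "C"), ("C", "O")],
        roles={"CA": "CH3", "C": "C", "O": "O"},
        zmatrix=[
            # first three atoms bootstrapped explicitly by the builder
            ("CH3", None, None, None, None, None, None, None),
            ("C", "CH3", 1.522, None, None, None, None, None),
            ("O", "C", 1.229, "CH3", 120.5, None, None, None),
            ("HH31", "CH3", 1.090, "C", 109.5, "O", "C", 60.0),
            ("HH32", "CH3", 1.090, "C", 109.5, "O", "C", 180.0),
            ("HH33", "CH3", 1.090, "C", 109.5, "O", "C", 300.0),
        ],
        is_amino_acid=False,
    ),
    "ALA": ResidueTemplate(
        name="ALA",
        atoms=["N", "H", "CA", "HA", "CB", "HB1", "HB2", "HB3", "C", "O"],
        params=_PARAMS["ALA"],
        bonds=[("N", "H"), ("N", "CA"), ("CA", "HA"), ("CA", "CB"),
               ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3"),
               ("CA", "C"), ("C", "O")],
        roles={"N": "N", "H_N": "H", "CA": "CA", "C": "C", "O": "O"},
        zmatrix=_aa_zmatrix([
            ("HA", "CA", 1.090, "N", 109.5, "-C", "N", "PHI-120"),
            ("CB", "CA", 1.526, "N", 110.4, "-C", "N", "PHI+120"),
            ("HB1", "CB", 1.090, "CA", 109.5, "N", "CA", 60.0),
            ("HB2", "CB", 1.090, "CA", 109.5, "N", "CA", 180.0),
            ("HB3", "CB", 1.090, "CA", 109.5, "N", "CA", 300.0),
        ]),
    ),
    "GLY": ResidueTemplate(
        name="GLY",
        atoms=["N", "H", "CA", "HA2", "HA3", "C", "O"],
        params=_PARAMS["GLY"],
        bonds=[("N", "H"), ("N", "CA"), ("CA", "HA2"), ("CA", "HA3"),
               ("CA", "C"), ("C", "O")],
        roles={"N": "N", "H_N": "H", "CA": "CA", "C": "C", "O": "O"},
        zmatrix=_aa_zmatrix([
            ("HA2", "CA", 1.090, "N", 109.5, "-C", "N", "PHI-120"),
            ("HA3", "CA", 1.090, "N", 109.5, "-C", "N", "PHI+120"),
        ]),
    ),
    "NME": ResidueTemplate(
        name="NME",
        atoms=["N", "H", "CH3", "HH31", "HH32", "HH33"],
        params=_PARAMS["NME"],
        bonds=[("N", "H"), ("N", "CH3"), ("CH3", "HH31"),
               ("CH3", "HH32"), ("CH3", "HH33")],
        roles={"N": "N", "H_N": "H", "CA": "CH3"},
        zmatrix=[
            _BACKBONE_N,
            _BACKBONE_H,
            ("CH3", "N", 1.458, "-C", 121.9, "-CA", "-C", 180.0),
            ("HH31", "CH3", 1.090, "N", 109.5, "-C", "N", 60.0),
            ("HH32", "CH3", 1.090, "N", 109.5, "-C", "N", 180.0),
            ("HH33", "CH3", 1.090, "N", 109.5, "-C", "N", 300.0),
        ],
        is_amino_acid=False,
    ),
    "HOH": ResidueTemplate(
        name="HOH",
        atoms=["O", "H1", "H2"],
        params=_PARAMS["HOH"],
        bonds=[("O", "H1"), ("O", "H2")],
        roles={},
        zmatrix=[],
        is_amino_acid=False,
    ),
}

ONE_LETTER = {"A": "ALA", "G": "GLY"}

# TIP3P rigid geometry (used by the water-ball builder and the stiff-water
# restraint terms)
TIP3P_OH = 0.9572
TIP3P_HOH_ANGLE = 104.52

# backbone torsions by named secondary-structure geometry, degrees
GEOMETRY_TORSIONS = {
    "extended": {"PHI": 180.0, "PSI": 180.0},
    "helical": {"PHI": -57.0, "PSI": -47.0},
}


class UnsupportedResidueError(ValueError):
    """Raised when a residue has no shipped template/parameters."""


def get_template(name: str) -> ResidueTemplate:
    try:
        return RESIDUE_TEMPLATES[name]
    except KeyError:
        raise UnsupportedResidueError(
            f"no template for residue {name!r}; shipped templates: "
            f"{sorted(RESIDUE_TEMPLATES)}"
        ) from None
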