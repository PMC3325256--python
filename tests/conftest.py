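"""Shared fixtures: tiny hand-built structures with known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from protonwire.structure import Atom, Residue, Structure, parse_pdb_string
from protonwire.synth import WireSpec, make_wire_structure
from protonwire import protonate, write_pdb

TINY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
HETATM    4  O   HOH W 101      10.000  10.000  10.000  1.00  0.00           O
HETATM    5 NI    NI Z 501      20.000  20.000  20.000  1.00  0.00          NI
END
"""

ALTLOC_PDB = """\
ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BSER A   1       5.000   0.000   0.000  0.40  0.00           C
ATOM      3  CB ATHR A   2       1.000   0.000   0.000  0.50  0.00           C
ATOM      4  CB BTHR A   2       6.000   0.000   0.000  0.50  0.00           C
END
"""


@pytest.fixture
def tiny_structure():
    return parse_pdb_string(TINY_PDB, structure_id="tiny")


@pytest.fixture
def wire_factory():
    def build(protonated: bool = True, **kwargs):
        spec = WireSpec(**kwargs)
        structure, truth = make_wire_structure(spec)
        # round-trip through the PDB text layer like a real input would
        structure = parse_pdb_string(write_pdb(structure), structure_id=structure.id)
        if protonated:
            structure, _ = protonate(structure)
        return structure, truth

    return build


def make_residue(name: str, atoms: list[tuple[str, str, tuple]],
                 chain: str = "A", number: int = 1, hetero: bool = False) -> Residue:
    masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "NI": 58.693, "H": 1.008}
    res = Residue(chain_id=chain, number=number, insertion_code="", name=name)
    for atom_name, element, coords in atoms:
        res.add_atom(
            Atom(serial=0, name=atom_name, element=element.capitalize(),
                 mass=masses.get(element.upper(), 12.0),
                 coords=np.array(coords, dtype=float), is_hetero=hetero)
        )
    return res


def make_histidine(number: int = 1, center=(0.0, 0.0, 0.0)) -> Residue:
    """Idealised imidazole in the xy-plane plus CB stub."""
    c = np.asarray(center, dtype=float)
    ring = {
        "CG": (0.000, 1.160, 0.0),
        "ND1": (-1.103, 0.358, 0.0),
        "CE1": (-0.682, -0.938, 0.0),
        "NE2": (0.682, -0.938, 0.0),
        "CD2": (1.103, 0.358, 0.0),
    }
    atoms = [("CB", "C", tuple(c + np.array([0.0, 2.66, 0.0])))]
    atoms += [(n, n[0], tuple(c + np.array(x))) for n, x in ring.items()]
    return make_residue("HIS", atoms, number=number)


def make_arginine_head(number: int = 1, origin=(0.0, 0.0, 0.0)) -> Residue:
    """Guanidinium group (CD-NE-CZ(NH1)(NH2)) in the xy-plane."""
    o = np.asarray(origin, dtype=float)
    atoms = [
        ("CD", "C", tuple(o + np.array([-0.73, 1.265, 0.0]))),
        ("NE", "N", tuple(o)),
        ("CZ", "C", tuple(o + np.array([1.33, 0.0, 0.0]))),
        ("NH1", "N", tuple(o + np.array([1.995, 1.152, 0.0]))),
        ("NH2", "N", tuple(o + np.array([1.995, -1.152, 0.0]))),
    ]
    return make_residue("ARG", atoms, number=number)


def make_water(number: int, position, chain: str = "W") -> Residue:
    return make_residue("HOH", [("O", "O", tuple(position))],
                        chain=chain, number=number, hetero=True)


def make_nickel(number: int = 501, position=(0.0, 0.0, 0.0)) -> Residue:
    return make_residue("NI", [("NI", "NI", tuple(position))],
                        chain="Z", number=number, hetero=True)


def assemble(chains: dict[str, list[Residue]] | None = None,
             waters: list[Residue] | None = None,
             metals: list[Residue] | None = None) -> Structure:
    s = Structure(id="toy")
    for cid, residues in (chains or {}).items():
        s.chains[cid] = residues
    s.waters.extend(waters or [])
    for m in metals or []:
        s.hetero.append(m)
        s.metal_sites.setdefault("NI", []).append(m)
    return s
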