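"""Typed coordinate model for PDB entries.

The model is deliberately small: atoms grouped into residues, residues
grouped into protein chains, a separate pool for crystallographic waters
and one for hetero groups, with metal/cluster groups classified so the
active site can be addressed by name.  Author residue numbering is kept
verbatim; nothing is renumbered.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "EmptyStructureError",
    "PDBWriteError",
    "parse_pdb",
    "parse_pdb_string",
    "write_pdb",
    "compute_com",
]

WATER_NAMES = {"HOH", "WAT"}

#: hetero residue name -> metal-site category
METAL_SITE_CODES = {
    "NI": "NI",
    "FE": "FE",
    "FE2": "FE",
    "SF4": "4FE4S",
    "F3S": "3FE4S",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class PDBParseError(ValueError):
    """Raised for a malformed fixed-width record; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class EmptyStructureError(ValueError):
    """Raised when a source contains no ATOM/HETATM records."""


class PDBWriteError(ValueError):
    """Raised when a structure cannot be serialized to PDB."""


def _element_mass(symbol: str) -> float:
    el = gemmi.Element(symbol.capitalize() if len(symbol) == 2 else symbol)
    if el.name == "X":
        return 0.0
    return float(el.weight)


def _element_known(symbol: str) -> bool:
    return bool(symbol) and gemmi.Element(symbol).name != "X"


def _guess_element(atom_name: str, is_hetero: bool, res_name: str) -> str:
    """Infer the element from a PDB atom name (columns 13-16)."""
    name = atom_name.strip()
    if not name:
        return ""
    if is_hetero and _element_known(res_name.strip().capitalize()) and len(res_name.strip()) <= 2:
        # monoatomic ions deposited with residue name == element (NI, FE, MG ...)
        if name.strip("0123456789+-").upper() == res_name.strip().upper():
            return res_name.strip().capitalize()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].capitalize()
    if len(stripped) >= 2 and _element_known(two) and two.upper() in {
        "FE", "NI", "MG", "ZN", "CU", "MN", "CO", "NA", "CL", "BR", "SE", "CA", "CD", "HG", "MO", "W",
    }:
        return two
    return stripped[0].upper()


@dataclass
class Atom:
    """A single atom with PDB-convention name and coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    mass: float
    coords: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""
    is_hetero: bool = False
    parent: Optional["Residue"] = None
    #: for constructed hydrogens, the heavy atom they are bonded to
    bonded_heavy: Optional["Atom"] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def distance_to(self, other: Union["Atom", np.ndarray]) -> float:
        other_xyz = other.coords if isinstance(other, Atom) else np.asarray(other, dtype=float)
        return float(np.linalg.norm(self.coords - other_xyz))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        res = f"{self.parent.name}{self.parent.number}" if self.parent else "?"
        return f"<Atom {self.name} of {res} at {np.round(self.coords, 2)}>"


@dataclass
class Residue:
    """A residue (amino acid, water or hetero group) with author numbering."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def add_atom(self, atom: Atom) -> None:
        atom.parent = self
        self.atoms.append(atom)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def hydrogens(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_hydrogen]

    def side_chain_heavy_atoms(self) -> list[Atom]:
        return [
            a for a in self.atoms
            if not a.is_hydrogen and a.name not in BACKBONE_NAMES
        ]

    @property
    def label(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.name}{self.number}{icode}"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Residue {self.label} ({len(self.atoms)} atoms)>"


@dataclass
class Structure:
    """A parsed PDB entry: protein chains, waters and hetero groups."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    waters: list[Residue] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)
    metal_sites: dict[str, list[Residue]] = field(default_factory=dict)

    def protein_residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def all_residues(self) -> Iterator[Residue]:
        yield from self.protein_residues()
        yield from self.waters
        yield from self.hetero

    def all_atoms(self) -> Iterator[Atom]:
        for res in self.all_residues():
            yield from res.atoms

    def heavy_atoms(self) -> Iterator[Atom]:
        for a in self.all_atoms():
            if not a.is_hydrogen:
                yield a

    def find_residue(self, chain_id: str, number: int, insertion_code: str = "") -> Optional[Residue]:
        for res in self.all_residues():
            if res.key == (chain_id, number, insertion_code):
                return res
        return None

    def metal_atoms(self, categories: Optional[Iterable[str]] = None) -> list[Atom]:
        """Metal atoms of classified metal sites (cluster S atoms excluded)."""
        wanted = set(categories) if categories is not None else None
        out: list[Atom] = []
        for cat, residues in self.metal_sites.items():
            if wanted is not None and cat not in wanted:
                continue
            for res in residues:
                for a in res.atoms:
                    if a.element.upper() not in {"S", "O", "C", "N", "H"}:
                        out.append(a)
        return out

    def n_atoms(self) -> int:
        return sum(1 for _ in self.all_atoms())


# ---------------------------------------------------------------------------
# parsing

def _parse_atom_record(line: str, line_number: int) -> dict:
    if len(line) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than the coordinate fields", line_number)
    try:
        serial = int(line[6:11])
    except ValueError:
        # serials beyond 99999 are sometimes hybrid-36 or '*****'; fall back
        serial = -1
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip()
    try:
        res_seq = int(line[22:26])
    except ValueError:
        raise PDBParseError(f"unreadable residue number {line[22:26]!r}", line_number)
    icode = line[26].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        raise PDBParseError(f"unreadable coordinates {line[30:54]!r}", line_number)
    try:
        occupancy = float(line[54:60]) if len(line) >= 60 and line[54:60].strip() else 1.0
    except ValueError:
        raise PDBParseError(f"unreadable occupancy {line[54:60]!r}", line_number)
    element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    return {
        "record": line[:6].strip(),
        "serial": serial,
        "name": name,
        "alt_loc": alt_loc,
        "res_name": res_name,
        "chain_id": chain_id,
        "res_seq": res_seq,
        "icode": icode,
        "coords": np.array([x, y, z]),
        "occupancy": occupancy,
        "element": element,
    }


def parse_pdb(
    source: Union[str, Path, TextIO],
    *,
    model: int = 1,
    structure_id: str = "",
) -> Structure:
    """Parse fixed-width PDB text into a :class:`Structure`.

    Parameters
    ----------
    source:
        Path to a PDB file or an open text handle.
    model:
        1-based index of the MODEL to read from multi-model files.
    structure_id:
        Identifier stored on the returned structure (defaults to the
        HEADER id or the file stem).

    Waters (HOH/WAT) are routed to ``structure.waters``; recognized
    metal/cluster hetero codes (NI, FE, SF4, F3S) are classified into
    ``structure.metal_sites``; any other hetero group lands in
    ``structure.hetero`` (and under the ``"other"`` metal-site key if it
    contains a non-CHNOS atom).  For alternate locations only the
    highest-occupancy conformer is kept; ties go to the alphabetically
    first alt-loc identifier.
    """
    close = False
    if isinstance(source, (str, Path)):
        if not structure_id:
            structure_id = Path(source).stem
        handle: TextIO = open(source, "r")
        close = True
    else:
        handle = source
    try:
        records = []
        current_model = 0
        seen_model_record = False
        for line_number, line in enumerate(handle, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model_record = True
                current_model += 1
            elif rec == "HEADER" and not structure_id:
                structure_id = line[62:66].strip().lower()
            elif rec in ("ATOM", "HETATM"):
                if seen_model_record and current_model != model:
                    continue
                records.append((line_number, _parse_atom_record(line, line_number)))
    finally:
        if close:
            handle.close()

    if not records:
        raise EmptyStructureError("source contains no ATOM/HETATM records")

    # resolve alternate locations: best occupancy, tie -> first alt_loc id
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for line_number, rec in records:
        atom_key = (rec["chain_id"], rec["res_seq"], rec["icode"], rec["res_name"], rec["name"])
        prev = best.get(atom_key)
        if prev is None:
            best[atom_key] = (rec["occupancy"], rec["alt_loc"] or "~", rec)
            order.append(atom_key)
        else:
            cand = (rec["occupancy"], rec["alt_loc"] or "~", rec)
            # higher occupancy wins; on a tie the smaller alt_loc char wins
            if (cand[0], -ord(cand[1][0])) > (prev[0], -ord(prev[1][0])):
                best[atom_key] = cand

    structure = Structure(id=structure_id)
    residues: dict[tuple, Residue] = {}
    res_order: list[tuple] = []
    for atom_key in order:
        _, _, rec = best[atom_key]
        res_key = (rec["chain_id"], rec["res_seq"], rec["icode"], rec["res_name"])
        if res_key not in residues:
            residues[res_key] = Residue(
                chain_id=rec["chain_id"],
                number=rec["res_seq"],
                insertion_code=rec["icode"],
                name=rec["res_name"],
            )
            res_order.append(res_key)
        res = residues[res_key]
        element = rec["element"]
        if not _element_known(element):
            element = _guess_element(rec["name"], rec["record"] == "HETATM", rec["res_name"])
        mass = _element_mass(element) if element else 0.0
        if mass == 0.0:
            warnings.warn(
                f"atom {rec['name']} of {rec['res_name']} {rec['res_seq']}: "
                f"unknown element {element!r}; mass set to 0",
                stacklevel=2,
            )
        res.add_atom(
            Atom(
                serial=rec["serial"],
                name=rec["name"],
                element=element,
                mass=mass,
                coords=rec["coords"],
                occupancy=rec["occupancy"],
                alt_loc="" if best[atom_key][1] == "~" else best[atom_key][1],
                is_hetero=rec["record"] == "HETATM",
            )
        )

    for res_key in res_order:
        res = residues[res_key]
        if res.name in WATER_NAMES:
            structure.waters.append(res)
        elif any(a.is_hetero for a in res.atoms) and res.name in METAL_SITE_CODES:
            structure.metal_sites.setdefault(METAL_SITE_CODES[res.name], []).append(res)
            structure.hetero.append(res)
        elif all(a.is_hetero for a in res.atoms):
            structure.hetero.append(res)
            if any(a.element.upper() not in {"C", "H", "N", "O", "S"} for a in res.atoms):
                structure.metal_sites.setdefault("other", []).append(res)
        else:
            structure.chains.setdefault(res.chain_id, []).append(res)
    return structure


def parse_pdb_string(text: str, **kwargs) -> Structure:
    """Parse PDB-format text held in memory."""
    return parse_pdb(io.StringIO(text), **kwargs)


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(atom: Atom) -> str:
    name = atom.name
    if len(name) > 4:
        raise PDBWriteError(f"atom name {name!r} exceeds 4 characters")
    if len(name) < 4:
        # element symbols of one letter start in column 14
        if len(atom.element) == 1 or (not atom.element and len(name) < 4):
            return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, include_hydrogens: bool = True) -> str:
    """Serialize a structure to fixed-width PDB v3.3 text.

    Serials are renumbered sequentially; past 99999 they wrap back to 1,
    which is stated in a REMARK in the header.
    """
    lines: list[str] = []
    n_atoms = structure.n_atoms()
    if n_atoms > 99999:
        lines.append("REMARK   3 ATOM SERIALS EXCEED 99999 AND WRAP BACK TO 1")
    serial = 0

    def emit(res: Residue, record: str) -> None:
        nonlocal serial
        for atom in res.atoms:
            if atom.is_hydrogen and not include_hydrogens:
                continue
            serial += 1
            if serial > 99999:
                serial = 1
            x, y, z = atom.coords
            lines.append(
                f"{record:<6s}{serial:>5d} {_format_atom_name(atom)}{atom.alt_loc or ' ':1s}"
                f"{res.name:>3s} {res.chain_id or 'A':1s}{res.number:>4d}{res.insertion_code or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2s}"
            )

    for chain_id, chain in structure.chains.items():
        for res in chain:
            emit(res, "ATOM")
        lines.append(f"TER   {serial + 1:>5d}      {chain[-1].name:>3s} "
                     f"{chain_id or 'A':1s}{chain[-1].number:>4d}")
    for res in structure.hetero:
        emit(res, "HETATM")
    for res in structure.waters:
        emit(res, "HETATM")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# geometry

def compute_com(residue: Residue, include_hydrogens: bool = False) -> np.ndarray:
    """Mass-weighted mean position of a residue's atoms, in Angstrom.

    Hydrogens are excluded by default: crystallographic models carry heavy
    atoms only, and constructed hydrogens shift the value by well under
    0.1 A for an amino acid.  Atoms of unknown element (mass 0) are
    skipped with a warning.
    """
    total = 0.0
    acc = np.zeros(3)
    skipped = []
    for atom in residue.atoms:
        if atom.is_hydrogen and not include_hydrogens:
            continue
        if atom.mass <= 0.0:
            skipped.append(atom.name)
            continue
        total += atom.mass
        acc += atom.mass * atom.coords
    if skipped:
        warnings.warn(
            f"{residue.label}: atoms with unknown mass excluded from COM: {skipped}",
            stacklevel=2,
        )
    if total <= 0.0:
        raise ValueError(f"{residue.label}: no atoms with known mass")
    return acc / total
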