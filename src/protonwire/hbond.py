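"""Geometric hydrogen-bond detection and the hydrogen-bond graph.

A hydrogen bond is accepted when the donor and acceptor heavy atoms lie
within ``da_cutoff`` (default 3.5 A) and the angle between the vector
donor->acceptor and the vector hydrogen->acceptor is below
``angle_cutoff`` (default 30 deg).  Note the literal criterion: the
angle is measured between D->A and H->A, not the more common D-H...A
angle.  Bonds with H...A below ``strong_ha_cutoff`` (default 2.2 A) are
classed *strong* — tight contacts of the kind a Grotthuss-style proton
relay needs; ordinary hydrogen bonds sit around 2.4-2.6 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from ._bonds import atoms_within_bonds, covalent_adjacency
from ._geom import angle_deg
from .structure import Atom, Residue, Structure, BACKBONE_NAMES

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondGraph",
    "MissingHydrogensError",
    "detect_hbonds",
    "build_graph",
    "edges_to_tsv",
]

#: amino acids with a polar side-chain group that can join the network
POLAR_SIDECHAINS = {
    "SER", "THR", "TYR", "CYS", "ASN", "GLN", "ASP", "GLU",
    "LYS", "ARG", "HIS", "TRP", "MET",
}


class MissingHydrogensError(ValueError):
    """Raised when hydrogen-bond detection is attempted without hydrogens."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds for a hydrogen bond."""

    da_cutoff: float = 3.5
    angle_cutoff: float = 30.0
    strong_ha_cutoff: float = 2.2

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0 or self.strong_ha_cutoff <= 0:
            raise ValueError("all criteria must be positive")
        if self.angle_cutoff > 90:
            raise ValueError("angle_cutoff must be <= 90 degrees")


@dataclass
class HBond:
    """A donor-H...acceptor contact and its geometry."""

    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    d_da: float
    d_ha: float
    angle: float
    strength: str = "normal"

    @property
    def is_strong(self) -> bool:
        return self.strength == "strong"

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<HBond {self.donor.parent.label}/{self.donor.name} -> "
            f"{self.acceptor.parent.label}/{self.acceptor.name} "
            f"d_HA={self.d_ha:.2f} A>"
        )


def donor_atoms(structure: Structure) -> list[tuple[Atom, list[Atom]]]:
    """(heavy donor, attached hydrogens) pairs: N/O/S carrying >= 1 H."""
    attached: dict[int, list[Atom]] = {}
    hydrogens_present = False
    for atom in structure.all_atoms():
        if atom.is_hydrogen:
            hydrogens_present = True
            heavy = atom.bonded_heavy
            if heavy is None:
                heavy = _nearest_heavy(atom)
            if heavy is not None:
                attached.setdefault(id(heavy), []).append(atom)
    if not hydrogens_present:
        raise MissingHydrogensError(
            "structure carries no hydrogens; run protonation.place_hydrogens first"
        )
    out = []
    for atom in structure.all_atoms():
        if atom.element.upper() in {"N", "O", "S"} and id(atom) in attached:
            out.append((atom, attached[id(atom)]))
    return out


def _nearest_heavy(hydrogen: Atom) -> Optional[Atom]:
    res = hydrogen.parent
    if res is None:
        return None
    best, best_d = None, 1.3
    for a in res.atoms:
        if a.is_hydrogen:
            continue
        d = a.distance_to(hydrogen)
        if d < best_d:
            best, best_d = a, d
    return best


def acceptor_atoms(structure: Structure) -> list[Atom]:
    """Heavy atoms with an available lone pair.

    All oxygens accept (carbonyl, carboxylate, hydroxyl, water); a
    histidine ring nitrogen accepts only while bare (no attached H);
    sulfur accepts as a cysteine thiolate.  Amide and guanidinium
    nitrogens never accept.
    """
    has_h: set[int] = set()
    for atom in structure.all_atoms():
        if atom.is_hydrogen and atom.bonded_heavy is not None:
            has_h.add(id(atom.bonded_heavy))
    out = []
    for atom in structure.all_atoms():
        el = atom.element.upper()
        if el == "O":
            out.append(atom)
        elif el == "N":
            if atom.parent is not None and atom.parent.name in {"HIS", "HID", "HIE", "HIP"} \
                    and atom.name in {"ND1", "NE2"} and id(atom) not in has_h:
                out.append(atom)
        elif el == "S":
            if atom.parent is not None and atom.parent.name in {"CYS", "CYM"} \
                    and id(atom) not in has_h:
                out.append(atom)
    return out


def _res_sort_key(res: Residue) -> tuple:
    return (res.chain_id, res.number, res.insertion_code, res.name)


def detect_hbonds(structure: Structure, criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """All (donor, H, acceptor) triples satisfying the geometric criteria.

    Pairs closer than four covalent bonds (through-bond) are excluded —
    this removes intra-group contacts such as a hydroxyl H against its
    own oxygen's neighbour and amide H against the preceding carbonyl.
    """
    donors = donor_atoms(structure)
    acceptors = acceptor_atoms(structure)
    if not donors or not acceptors:
        return []
    adjacency = covalent_adjacency(structure)
    acc_coords = np.array([a.coords for a in acceptors])
    tree = cKDTree(acc_coords)
    bonds: list[HBond] = []
    for heavy, hydrogens in donors:
        excluded = atoms_within_bonds(heavy, adjacency, max_bonds=3)
        for j in tree.query_ball_point(heavy.coords, criteria.da_cutoff):
            acceptor = acceptors[j]
            if acceptor is heavy or id(acceptor) in excluded:
                continue
            d_da = heavy.distance_to(acceptor)
            if d_da > criteria.da_cutoff:
                continue
            for hyd in hydrogens:
                ang = angle_deg(acceptor.coords - heavy.coords, acceptor.coords - hyd.coords)
                if ang < criteria.angle_cutoff:
                    d_ha = hyd.distance_to(acceptor)
                    bonds.append(
                        HBond(
                            donor=heavy,
                            hydrogen=hyd,
                            acceptor=acceptor,
                            d_da=d_da,
                            d_ha=d_ha,
                            angle=ang,
                            strength="strong" if d_ha <= criteria.strong_ha_cutoff else "normal",
                        )
                    )
    bonds.sort(
        key=lambda b: (
            _res_sort_key(b.donor.parent), b.donor.name, b.hydrogen.name,
            _res_sort_key(b.acceptor.parent), b.acceptor.name,
        )
    )
    return bonds


# ---------------------------------------------------------------------------
# graph construction

def node_id_for_atom(atom: Atom) -> Optional[str]:
    """Graph node the atom belongs to, or None for apolar atoms.

    Granularity: one node per side-chain functional group, one per
    backbone amide, one per backbone carbonyl, one per water, one per
    metal atom.  Distinct groups of one residue must not short-circuit a
    pathway through its covalent skeleton.
    """
    res = atom.parent
    if res is None:
        return None
    if res.is_water:
        return f"W:{res.chain_id}:{res.number}{res.insertion_code}"
    name = atom.bonded_heavy.name if atom.is_hydrogen and atom.bonded_heavy is not None else atom.name
    if atom.is_hetero or any(a.is_hetero for a in res.atoms):
        el = atom.element.upper()
        if el not in {"C", "N", "O", "S", "H"}:
            return f"M:{el}:{res.number}"
        return f"X:{res.chain_id}:{res.name}{res.number}"
    if name in {"N", "H", "H1", "H2", "H3"}:
        return f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:bbN"
    if name in {"O", "OXT"}:
        return f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:bbO"
    return f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:sc"


@dataclass
class HBondGraph:
    """Undirected graph over polar groups; edges carry the best H-bond."""

    graph: nx.Graph
    residues: dict[str, Residue] = field(default_factory=dict)

    def node_for_residue(self, res: Residue, part: str = "sc") -> str:
        if res.is_water:
            return f"W:{res.chain_id}:{res.number}{res.insertion_code}"
        return f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:{part}"

    def metal_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if n.startswith("M:"))

    def residue_of(self, node: str) -> Optional[Residue]:
        return self.residues.get(node)


def build_graph(
    hbonds: Iterable[HBond],
    structure: Structure,
    criteria: HBondCriteria = HBondCriteria(),
    strong_only: bool = False,
    coordination_cutoff: float = 2.6,
) -> HBondGraph:
    """Build the hydrogen-bond graph.

    One undirected edge per connected node pair, carrying the
    geometrically best (smallest H...A) bond between them.  Metal atoms
    enter as nodes with zero-length *coordination* edges to residues
    whose side-chain heavy atoms lie within ``coordination_cutoff``, so
    the active site can serve as a pathway source.
    """
    g = nx.Graph()
    residues: dict[str, Residue] = {}

    def add_node(node: str, res: Residue, kind: str) -> None:
        if node not in g:
            g.add_node(node, kind=kind)
            residues[node] = res

    for res in structure.protein_residues():
        if res.name in POLAR_SIDECHAINS and res.side_chain_heavy_atoms():
            add_node(f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:sc", res, "sidechain")
        if res.atom("N") is not None:
            add_node(f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:bbN", res, "backbone")
        if res.atom("O") is not None or res.atom("OXT") is not None:
            add_node(f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:bbO", res, "backbone")
    for res in structure.waters:
        add_node(f"W:{res.chain_id}:{res.number}{res.insertion_code}", res, "water")
    metal_atoms = []
    for cat, site_residues in sorted(structure.metal_sites.items()):
        if cat == "other":
            continue
        for res in site_residues:
            for atom in res.atoms:
                if atom.element.upper() not in {"C", "N", "O", "S", "H"}:
                    node = f"M:{atom.element.upper()}:{res.number}"
                    add_node(node, res, "metal")
                    metal_atoms.append((node, atom))

    for hb in hbonds:
        if strong_only and not hb.is_strong:
            continue
        u = node_id_for_atom(hb.donor)
        v = node_id_for_atom(hb.acceptor)
        if u is None or v is None or u == v:
            continue
        if u not in g or v not in g:
            continue
        existing = g.get_edge_data(u, v)
        if existing is None or hb.d_ha < existing["d_ha"]:
            g.add_edge(u, v, d_ha=hb.d_ha, d_da=hb.d_da, kind="hbond", hbond=hb)

    for node, atom in metal_atoms:
        for res in structure.protein_residues():
            sc = res.side_chain_heavy_atoms()
            if not sc:
                continue
            dmin = min(atom.distance_to(a) for a in sc)
            if dmin <= coordination_cutoff:
                target = f"{res.chain_id}:{res.name}{res.number}{res.insertion_code}:sc"
                if target in g:
                    g.add_edge(node, target, d_ha=0.0, d_da=dmin, kind="coordination", hbond=None)

    return HBondGraph(graph=g, residues=residues)


def edges_to_tsv(hbonds: Iterable[HBond]) -> str:
    """Edge list export: one hydrogen bond per line."""
    lines = ["donor_res\tdonor_atom\tacceptor_res\tacceptor_atom\td_DA\td_HA\tangle\tstrength"]
    for hb in hbonds:
        lines.append(
            f"{hb.donor.parent.label}\t{hb.donor.name}\t"
            f"{hb.acceptor.parent.label}\t{hb.acceptor.name}\t"
            f"{hb.d_da:.3f}\t{hb.d_ha:.3f}\t{hb.angle:.2f}\t{hb.strength}"
        )
    return "\n".join(lines) + "\n"
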