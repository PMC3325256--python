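"""Protonation microstates and explicit hydrogen construction.

The assignment is a documented rule set, not a free-energy minimisation:

* metal-site groups keep fixed formal charges (cluster irons, ligating
  cysteine thiolates, sulfides, the Ni/Fe pair) and are never titrated;
* at physiological pH the defaults are Asp/Glu anionic, Lys/Arg
  cationic, Cys neutral;
* a cationic side chain whose charged group sits within
  ``metal_neutralization_cutoff`` of a fixed metal cation is assigned
  its neutral form — a buried positive charge next to Ni(2+) is
  electrostatically untenable;
* histidine tautomers are chosen to maximise the number of satisfiable
  ring-nitrogen hydrogen bonds, and a histidine becomes doubly
  protonated (HIP, +1) only when both ring nitrogens see an acceptor in
  range and at least one partner is an anionic oxygen.

Hydrogens are then built at ideal geometry (N-H 1.01 A, O-H 0.96 A,
S-H 1.34 A); heavy-atom coordinates are never touched.  Rotatable
donors (hydroxyls, ammonium groups, water) are oriented toward the
best available acceptors on a deterministic grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._bonds import atoms_within_bonds, covalent_adjacency
from ._geom import angle_deg, any_perpendicular, rotate_about, unit
from .hbond import HBondCriteria
from .structure import Atom, Residue, Structure

__all__ = [
    "ProtonationConfig",
    "MetalSiteConstraints",
    "ProtonationVariant",
    "assign_microstates",
    "place_hydrogens",
    "orient_waters",
    "protonate",
    "rename_to_variants",
]

N_H = 1.01
O_H = 0.96
S_H = 1.34
WATER_ANGLE = 104.52
SP3_ANGLE = 109.47
ROTOR_STEPS = 72  # 5-degree grid

TITRATABLE = {"ASP", "GLU", "LYS", "ARG", "CYS", "HIS"}

ANIONIC_OXYGENS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}


@dataclass(frozen=True)
class ProtonationConfig:
    """Parameters of the microstate assignment."""

    pH: float = 7.4
    metal_neutralization_cutoff: float = 5.0
    water_orientation_passes: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pH <= 14.0):
            raise ValueError("pH must lie in [0, 14]")
        if self.metal_neutralization_cutoff <= 0:
            raise ValueError("metal_neutralization_cutoff must be positive")


@dataclass(frozen=True)
class MetalSiteConstraints:
    """Fixed formal charges of the metal sites; never re-titrated."""

    fe4s4_iron_charges: tuple[int, ...] = (2, 2, 3, 3)
    fe3s4_iron_charges: tuple[int, ...] = (3, 3, 2)
    cysteine_charge: int = -1
    sulfide_charge: int = -2
    ni_charge: int = 2
    fe_charge: int = 2
    coordination_cutoff: float = 2.6


@dataclass
class ProtonationVariant:
    """Assigned protonation state of one residue."""

    residue: Residue
    code: str  # HID/HIE/HIP, ASP-/ASH, GLU-/GLH, LYS+/LYN, ARG+/ARN, CYS-/CYSH, default
    formal_charge: int = 0
    constrained: bool = False

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{self.residue.label} -> {self.code} ({self.formal_charge:+d})>"


VARIANT_RESNAME = {
    "HID": "HID", "HIE": "HIE", "HIP": "HIP",
    "ASP-": "ASP", "ASH": "ASH", "GLU-": "GLU", "GLH": "GLH",
    "LYS+": "LYS", "LYN": "LYN", "ARG+": "ARG", "ARN": "ARN",
    "CYS-": "CYM", "CYSH": "CYS",
}


def _fixed_metal_cations(structure: Structure) -> list[Atom]:
    return structure.metal_atoms(categories={"NI", "FE", "4FE4S", "3FE4S"})


def _candidate_acceptors(structure: Structure, constraints: MetalSiteConstraints) -> list[Atom]:
    """Heavy atoms usable as acceptors before hydrogens exist: all oxygens
    plus thiolate sulfurs of metal-ligating cysteines."""
    metals = _fixed_metal_cations(structure)
    out = []
    for atom in structure.all_atoms():
        el = atom.element.upper()
        if el == "O":
            out.append(atom)
        elif el == "S" and atom.parent is not None and atom.parent.name == "CYS":
            if metals and min(atom.distance_to(m) for m in metals) <= constraints.coordination_cutoff:
                out.append(atom)
    return out


def _candidate_donor_heavies(structure: Structure) -> list[Atom]:
    """Heavy atoms that will carry at least one hydrogen under default rules."""
    donor_names = {
        "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
        "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",),
        "GLN": ("NE2",), "TRP": ("NE1",),
    }
    out = []
    for res in structure.protein_residues():
        n = res.atom("N")
        if n is not None and res.name != "PRO":
            out.append(n)
        for name in donor_names.get(res.name, ()):
            a = res.atom(name)
            if a is not None:
                out.append(a)
    for res in structure.waters:
        for a in res.atoms:
            if a.element.upper() == "O":
                out.append(a)
    return out


def _is_anionic_oxygen(atom: Atom) -> bool:
    if atom.name == "OXT":
        return True
    return (atom.parent.name if atom.parent else "", atom.name) in ANIONIC_OXYGENS


def assign_microstates(
    structure: Structure,
    config: ProtonationConfig = ProtonationConfig(),
    constraints: MetalSiteConstraints = MetalSiteConstraints(),
) -> list[ProtonationVariant]:
    """Assign a protonation variant to every titratable residue."""
    metals = _fixed_metal_cations(structure)
    unclassified = structure.metal_sites.get("other", [])
    acceptors = _candidate_acceptors(structure, constraints)
    donors = _candidate_donor_heavies(structure)
    acc_tree = cKDTree(np.array([a.coords for a in acceptors])) if acceptors else None
    don_tree = cKDTree(np.array([a.coords for a in donors])) if donors else None

    def near_metal(atoms: Sequence[Atom], cutoff: float) -> bool:
        return bool(metals) and any(
            a.distance_to(m) <= cutoff for a in atoms for m in metals
        )

    def warn_unclassified(res: Residue) -> None:
        for other in unclassified:
            for oa in other.atoms:
                if any(a.distance_to(oa) <= config.metal_neutralization_cutoff for a in res.atoms):
                    warnings.warn(
                        f"{res.label} is adjacent to unclassified hetero group "
                        f"{other.label}; default protonation rules applied",
                        stacklevel=3,
                    )
                    return

    variants: list[ProtonationVariant] = []
    for res in structure.protein_residues():
        if res.name not in TITRATABLE:
            continue
        warn_unclassified(res)
        if res.name == "CYS":
            sg = res.atom("SG")
            if sg is not None and near_metal([sg], constraints.coordination_cutoff):
                variants.append(ProtonationVariant(res, "CYS-", constraints.cysteine_charge, constrained=True))
            else:
                variants.append(ProtonationVariant(res, "CYSH", 0))
        elif res.name == "ASP":
            variants.append(ProtonationVariant(res, "ASP-", -1))
        elif res.name == "GLU":
            variants.append(ProtonationVariant(res, "GLU-", -1))
        elif res.name == "LYS":
            nz = res.atom("NZ")
            if nz is not None and near_metal([nz], config.metal_neutralization_cutoff):
                variants.append(ProtonationVariant(res, "LYN", 0))
            else:
                variants.append(ProtonationVariant(res, "LYS+", +1))
        elif res.name == "ARG":
            group = [res.atom(n) for n in ("NE", "NH1", "NH2", "CZ")]
            group = [a for a in group if a is not None]
            if group and near_metal(group, config.metal_neutralization_cutoff):
                variants.append(ProtonationVariant(res, "ARN", 0))
            else:
                variants.append(ProtonationVariant(res, "ARG+", +1))
        elif res.name == "HIS":
            variants.append(
                _assign_histidine(
                    res, acceptors, acc_tree, donors, don_tree, metals, config, constraints
                )
            )
    return variants


def _neighbors(
    atom: Atom,
    pool: list[Atom],
    tree: Optional[cKDTree],
    cutoff: float,
) -> list[Atom]:
    if tree is None:
        return []
    out = []
    for j in tree.query_ball_point(atom.coords, cutoff):
        cand = pool[j]
        if cand.parent is not atom.parent:
            out.append(cand)
    return out


def _assign_histidine(
    res: Residue,
    acceptors: list[Atom],
    acc_tree: Optional[cKDTree],
    donors: list[Atom],
    don_tree: Optional[cKDTree],
    metals: list[Atom],
    config: ProtonationConfig,
    constraints: MetalSiteConstraints,
) -> ProtonationVariant:
    nd1, ne2 = res.atom("ND1"), res.atom("NE2")
    if nd1 is None or ne2 is None:
        warnings.warn(f"{res.label}: incomplete imidazole; defaulting to HIE", stacklevel=3)
        return ProtonationVariant(res, "HIE", 0)
    cutoff = HBondCriteria().da_cutoff
    acc_nd1 = _neighbors(nd1, acceptors, acc_tree, cutoff)
    acc_ne2 = _neighbors(ne2, acceptors, acc_tree, cutoff)
    don_nd1 = _neighbors(nd1, donors, don_tree, cutoff)
    don_ne2 = _neighbors(ne2, donors, don_tree, cutoff)
    bound_nd1 = bool(metals) and any(nd1.distance_to(m) <= constraints.coordination_cutoff for m in metals)
    bound_ne2 = bool(metals) and any(ne2.distance_to(m) <= constraints.coordination_cutoff for m in metals)

    if bound_nd1:
        return ProtonationVariant(res, "HIE", 0, constrained=True)
    if bound_ne2:
        return ProtonationVariant(res, "HID", 0, constrained=True)

    if acc_nd1 and acc_ne2 and any(_is_anionic_oxygen(a) for a in acc_nd1 + acc_ne2):
        ring = [nd1, ne2]
        if bool(metals) and any(
            n.distance_to(m) <= config.metal_neutralization_cutoff for n in ring for m in metals
        ):
            pass  # cationic form suppressed next to a fixed metal cation
        else:
            return ProtonationVariant(res, "HIP", +1)

    score_hid = int(bool(acc_nd1)) + int(bool(don_ne2))
    score_hie = int(bool(acc_ne2)) + int(bool(don_nd1))
    return ProtonationVariant(res, "HID" if score_hid > score_hie else "HIE", 0)


# ---------------------------------------------------------------------------
# hydrogen construction


def _add_h(res: Residue, name: str, heavy: Atom, position: np.ndarray) -> Atom:
    h = Atom(
        serial=0,
        name=name,
        element="H",
        mass=1.008,
        coords=np.asarray(position, dtype=float),
        is_hetero=heavy.is_hetero,
    )
    h.bonded_heavy = heavy
    res.add_atom(h)
    return h


def _bisector_h(res: Residue, name: str, n: Atom, a: Atom, b: Atom, length: float) -> Atom:
    direction = -(unit(a.coords - n.coords) + unit(b.coords - n.coords))
    return _add_h(res, name, n, n.coords + length * unit(direction))


def _sp2_terminal_pair(
    res: Residue, names: tuple[str, str], n: Atom, stem: Atom, plane_ref: Atom, length: float
) -> list[Atom]:
    """Two in-plane hydrogens on an sp2 terminal nitrogen (amide, guanidinium)."""
    u = unit(n.coords - stem.coords)
    normal = np.cross(plane_ref.coords - stem.coords, u)
    if np.linalg.norm(normal) < 1e-8:
        normal = any_perpendicular(u)
    p = unit(np.cross(unit(normal), u))
    out = []
    for name, sign in zip(names, (+1.0, -1.0)):
        direction = 0.5 * u + sign * (np.sqrt(3.0) / 2.0) * p
        out.append(_add_h(res, name, n, n.coords + length * unit(direction)))
    return out


class _RotorPlacer:
    """Places rotatable hydrogens oriented toward the best acceptors."""

    def __init__(self, structure: Structure, criteria: HBondCriteria):
        self.criteria = criteria
        self.acceptors = [a for a in structure.all_atoms() if a.element.upper() == "O"]
        for atom in structure.all_atoms():
            el = atom.element.upper()
            if el == "S" and atom.parent is not None and atom.parent.name in {"CYS", "CYM"}:
                self.acceptors.append(atom)
        self.tree = (
            cKDTree(np.array([a.coords for a in self.acceptors])) if self.acceptors else None
        )
        self.adjacency = covalent_adjacency(structure)

    def targets_for(self, donor: Atom) -> list[Atom]:
        if self.tree is None:
            return []
        excluded = atoms_within_bonds(donor, self.adjacency, max_bonds=3)
        return [
            self.acceptors[j]
            for j in self.tree.query_ball_point(donor.coords, self.criteria.da_cutoff)
            if id(self.acceptors[j]) not in excluded and self.acceptors[j] is not donor
        ]

    def place(
        self,
        res: Residue,
        donor: Atom,
        root: Atom,
        h_names: Sequence[str],
        length: float,
        cone_angle: float = SP3_ANGLE,
    ) -> list[Atom]:
        axis = unit(donor.coords - root.coords)
        p = any_perpendicular(axis)
        half = np.radians(180.0 - cone_angle)
        targets = self.targets_for(donor)
        n_h = len(h_names)
        spread = 2.0 * np.pi / n_h if n_h > 1 else 0.0

        def positions(phase: float) -> list[np.ndarray]:
            out = []
            for k in range(n_h):
                phi = phase + k * spread
                direction = (
                    np.cos(half) * axis
                    + np.sin(half) * (np.cos(phi) * p + np.sin(phi) * np.cross(axis, p))
                )
                out.append(donor.coords + length * unit(direction))
            return out

        best_phase, best_key = 0.0, None
        for step in range(ROTOR_STEPS):
            phase = 2.0 * np.pi * step / ROTOR_STEPS
            score, dist_sum = _score_donation(
                donor, positions(phase), targets, self.criteria
            )
            key = (-score, dist_sum, step)
            if best_key is None or key < best_key:
                best_key, best_phase = key, phase
        return [
            _add_h(res, name, donor, pos)
            for name, pos in zip(h_names, positions(best_phase))
        ]


def _score_donation(
    donor: Atom,
    h_positions: Sequence[np.ndarray],
    targets: Sequence[Atom],
    criteria: HBondCriteria,
) -> tuple[int, float]:
    """(number of satisfied acceptors, summed best H...A distance)."""
    score, total = 0, 0.0
    for acc in targets:
        d_da = donor.distance_to(acc)
        if d_da > criteria.da_cutoff:
            continue
        best = None
        for hp in h_positions:
            ang = angle_deg(acc.coords - donor.coords, acc.coords - hp)
            if ang < criteria.angle_cutoff:
                d_ha = float(np.linalg.norm(acc.coords - hp))
                if best is None or d_ha < best:
                    best = d_ha
        if best is not None:
            score += 1
            total += best
    return score, total


def _variant_lookup(variants: Iterable[ProtonationVariant]) -> dict[tuple, ProtonationVariant]:
    return {v.residue.key: v for v in variants}


def place_hydrogens(
    structure: Structure,
    variants: Iterable[ProtonationVariant],
    criteria: HBondCriteria = HBondCriteria(),
    config: ProtonationConfig = ProtonationConfig(),
) -> Structure:
    """Construct explicit hydrogens for the assigned microstates.

    Only polar hydrogens are built (N-H, O-H, S-H): carbon-bound
    hydrogens play no part in hydrogen-bond donation.  The structure is
    modified in place and returned.
    """
    lookup = _variant_lookup(variants)
    placer = _RotorPlacer(structure, criteria)

    for chain in structure.chains.values():
        prev: Optional[Residue] = None
        for res in chain:
            _place_residue(res, prev, lookup.get(res.key), placer)
            prev = res

    rng_seed = config.random_seed
    for res in sorted(structure.waters, key=lambda r: (r.chain_id, r.number, r.insertion_code)):
        _place_water(res, rng_seed)
    return structure


def _require(res: Residue, names: Sequence[str]) -> Optional[list[Atom]]:
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        missing = [n for n, a in zip(names, atoms) if a is None]
        warnings.warn(
            f"{res.label}: missing heavy atoms {missing}; hydrogens skipped", stacklevel=3
        )
        return None
    return atoms  # type: ignore[return-value]


def _place_residue(
    res: Residue,
    prev: Optional[Residue],
    variant: Optional[ProtonationVariant],
    placer: _RotorPlacer,
) -> None:
    name = res.name
    # backbone amide
    n = res.atom("N")
    ca = res.atom("CA")
    if n is not None and ca is not None and name != "PRO":
        prev_c = prev.atom("C") if prev is not None else None
        if prev_c is not None and prev_c.distance_to(n) <= 1.8:
            direction = -(unit(ca.coords - n.coords) + unit(prev_c.coords - n.coords))
            _add_h(res, "H", n, n.coords + N_H * unit(direction))
        else:
            # chain start (or an isolated residue): ammonium rotor
            placer.place(res, n, ca, ("H1", "H2", "H3"), N_H)

    code = variant.code if variant is not None else None
    if name == "SER":
        atoms = _require(res, ["OG", "CB"])
        if atoms:
            placer.place(res, atoms[0], atoms[1], ("HG",), O_H)
    elif name == "THR":
        atoms = _require(res, ["OG1", "CB"])
        if atoms:
            placer.place(res, atoms[0], atoms[1], ("HG1",), O_H)
    elif name == "TYR":
        atoms = _require(res, ["OH", "CZ"])
        if atoms:
            placer.place(res, atoms[0], atoms[1], ("HH",), O_H, cone_angle=120.0)
    elif name == "CYS":
        if code != "CYS-":
            atoms = _require(res, ["SG", "CB"])
            if atoms:
                placer.place(res, atoms[0], atoms[1], ("HG",), S_H)
    elif name == "LYS":
        atoms = _require(res, ["NZ", "CE"])
        if atoms:
            h_names = ("HZ1", "HZ2", "HZ3") if code != "LYN" else ("HZ1", "HZ2")
            placer.place(res, atoms[0], atoms[1], h_names, N_H)
    elif name == "ARG":
        _place_arginine(res, code, placer)
    elif name == "HIS":
        _place_histidine(res, code or "HIE")
    elif name == "TRP":
        atoms = _require(res, ["NE1", "CD1", "CE2"])
        if atoms:
            _bisector_h(res, "HE1", atoms[0], atoms[1], atoms[2], N_H)
    elif name == "ASN":
        atoms = _require(res, ["ND2", "CG", "OD1"])
        if atoms:
            _sp2_terminal_pair(res, ("HD21", "HD22"), atoms[0], atoms[1], atoms[2], N_H)
    elif name == "GLN":
        atoms = _require(res, ["NE2", "CD", "OE1"])
        if atoms:
            _sp2_terminal_pair(res, ("HE21", "HE22"), atoms[0], atoms[1], atoms[2], N_H)
    elif name == "ASP" and code == "ASH":
        atoms = _require(res, ["OD2", "CG", "OD1"])
        if atoms:
            _sp2_terminal_pair(res, ("HD2", "_drop"), atoms[0], atoms[1], atoms[2], O_H)
            _drop_h(res, "_drop")
    elif name == "GLU" and code == "GLH":
        atoms = _require(res, ["OE2", "CD", "OE1"])
        if atoms:
            _sp2_terminal_pair(res, ("HE2", "_drop"), atoms[0], atoms[1], atoms[2], O_H)
            _drop_h(res, "_drop")


def _drop_h(res: Residue, name: str) -> None:
    res.atoms = [a for a in res.atoms if a.name != name]


def _place_arginine(res: Residue, code: Optional[str], placer: _RotorPlacer) -> None:
    atoms = _require(res, ["NE", "CD", "CZ", "NH1", "NH2"])
    if not atoms:
        return
    ne, cd, cz, nh1, nh2 = atoms
    _bisector_h(res, "HE", ne, cd, cz, N_H)
    eta_hs = _sp2_terminal_pair(res, ("HH11", "HH12"), nh1, cz, nh2, N_H)
    eta_hs += _sp2_terminal_pair(res, ("HH21", "HH22"), nh2, cz, nh1, N_H)
    if code == "ARN":
        # neutral guanidine: remove the least hydrogen-bond-capable eta H
        criteria = placer.criteria
        targets = placer.targets_for(nh1) + placer.targets_for(nh2)

        def engagement(h: Atom) -> float:
            best = np.inf
            donor = h.bonded_heavy
            for acc in targets:
                if donor.distance_to(acc) > criteria.da_cutoff:
                    continue
                ang = angle_deg(acc.coords - donor.coords, acc.coords - h.coords)
                if ang < criteria.angle_cutoff:
                    best = min(best, h.distance_to(acc))
            return best

        worst = max(eta_hs, key=lambda h: (engagement(h), h.name))
        res.atoms = [a for a in res.atoms if a is not worst]


def _place_histidine(res: Residue, code: str) -> None:
    nd1 = _require(res, ["ND1", "CG", "CE1"])
    ne2 = _require(res, ["NE2", "CD2", "CE1"])
    if code in ("HID", "HIP") and nd1:
        _bisector_h(res, "HD1", nd1[0], nd1[1], nd1[2], N_H)
    if code in ("HIE", "HIP") and ne2:
        _bisector_h(res, "HE2", ne2[0], ne2[1], ne2[2], N_H)


def _place_water(res: Residue, seed: int) -> None:
    oxy = next((a for a in res.atoms if a.element.upper() == "O"), None)
    if oxy is None:
        warnings.warn(f"{res.label}: water without oxygen; skipped", stacklevel=3)
        return
    rng = np.random.default_rng([abs(seed), abs(res.number)])
    d1 = unit(rng.normal(size=3))
    axis = any_perpendicular(d1)
    d2 = rotate_about(d1, axis, np.radians(WATER_ANGLE))
    _add_h(res, "H1", oxy, oxy.coords + O_H * d1)
    _add_h(res, "H2", oxy, oxy.coords + O_H * d2)


# ---------------------------------------------------------------------------
# water orientation


def _water_oxygen(res: Residue) -> Optional[Atom]:
    return next((a for a in res.atoms if a.element.upper() == "O"), None)


def _set_water_orientation(res: Residue, oxy: Atom, d1: np.ndarray, d2: np.ndarray) -> None:
    hs = [a for a in res.atoms if a.is_hydrogen]
    hs[0].coords = oxy.coords + O_H * d1
    hs[1].coords = oxy.coords + O_H * d2


def _pair_orientation(u_a: np.ndarray, u_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """H1 along u_a; H2 at the water angle, tilted toward u_b."""
    ortho = u_b - np.dot(u_b, u_a) * u_a
    v = unit(ortho) if np.linalg.norm(ortho) > 1e-8 else any_perpendicular(u_a)
    ang = np.radians(WATER_ANGLE)
    return u_a, np.cos(ang) * u_a + np.sin(ang) * v


def orient_waters(
    structure: Structure,
    config: ProtonationConfig = ProtonationConfig(),
    criteria: HBondCriteria = HBondCriteria(),
) -> Structure:
    """Greedy iterative optimisation of water hydrogen orientations.

    Waters are swept in residue order; each is re-oriented to maximise
    the number of geometric hydrogen bonds it donates, ties broken by
    the smallest summed H...A distance.  Converges when a full sweep
    changes nothing, or after ``water_orientation_passes`` sweeps.
    Isolated waters keep their seed-deterministic orientation.
    """
    from .hbond import acceptor_atoms

    waters = sorted(structure.waters, key=lambda r: (r.chain_id, r.number, r.insertion_code))
    for _ in range(max(1, config.water_orientation_passes)):
        changed = False
        acceptors = acceptor_atoms(structure)
        pool = [a for a in acceptors]
        tree = cKDTree(np.array([a.coords for a in pool])) if pool else None
        for res in waters:
            oxy = _water_oxygen(res)
            if oxy is None or len(res.hydrogens()) != 2:
                continue
            targets = [
                pool[j]
                for j in (tree.query_ball_point(oxy.coords, criteria.da_cutoff) if tree else [])
                if pool[j].parent is not res
            ]
            if not targets:
                continue
            hs = res.hydrogens()
            current = (unit(hs[0].coords - oxy.coords), unit(hs[1].coords - oxy.coords))
            candidates = [current]
            units = [unit(t.coords - oxy.coords) for t in targets]
            for i, u_a in enumerate(units):
                axis = any_perpendicular(u_a)
                candidates.append((u_a, rotate_about(u_a, axis, np.radians(WATER_ANGLE))))
                for j, u_b in enumerate(units):
                    if i != j:
                        candidates.append(_pair_orientation(u_a, u_b))
            best, best_key = None, None
            for d1, d2 in candidates:
                positions = [oxy.coords + O_H * d1, oxy.coords + O_H * d2]
                score, dist_sum = _score_donation(oxy, positions, targets, criteria)
                key = (-score, round(dist_sum, 9))
                if best_key is None or key < best_key:
                    best, best_key = (d1, d2), key
            score_now = _score_donation(oxy, [h.coords for h in hs], targets, criteria)
            current_key = (-score_now[0], round(score_now[1], 9))
            if best is not None and best_key < current_key:
                _set_water_orientation(res, oxy, *best)
                changed = True
        if not changed:
            break
    return structure


# ---------------------------------------------------------------------------
# convenience


def protonate(
    structure: Structure,
    config: ProtonationConfig = ProtonationConfig(),
    constraints: MetalSiteConstraints = MetalSiteConstraints(),
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[Structure, list[ProtonationVariant]]:
    """assign_microstates + place_hydrogens + orient_waters in one call."""
    variants = assign_microstates(structure, config, constraints)
    place_hydrogens(structure, variants, criteria, config)
    orient_waters(structure, config, criteria)
    return structure, variants


def rename_to_variants(structure: Structure, variants: Iterable[ProtonationVariant]) -> None:
    """Rewrite residue names to variant codes (HID/HIE/HIP...) for export."""
    for v in variants:
        new = VARIANT_RESNAME.get(v.code)
        if new:
            v.residue.name = new
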