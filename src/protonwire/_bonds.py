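"""Covalent bond inference (internal).

Bonds are inferred from heavy-atom distances (standard covalent ranges)
plus the explicit hydrogen attachments recorded at construction time.
Used to exclude trivially close covalent neighbours from hydrogen-bond
detection and rotor scoring.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure, Atom

#: heavy atoms closer than this are considered covalently bonded
HEAVY_BOND_CUTOFF = 1.95
#: disulfide S-S
SS_BOND_CUTOFF = 2.20


def covalent_adjacency(structure: Structure) -> dict[int, list[Atom]]:
    """Map ``id(atom) -> covalently bonded atoms`` over the whole structure."""
    heavy = [a for a in structure.all_atoms() if not a.is_hydrogen]
    adj: dict[int, list[Atom]] = {id(a): [] for a in structure.all_atoms()}
    if heavy:
        coords = np.array([a.coords for a in heavy])
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(SS_BOND_CUTOFF):
            a, b = heavy[i], heavy[j]
            d = a.distance_to(b)
            limit = SS_BOND_CUTOFF if {a.element, b.element} == {"S"} else HEAVY_BOND_CUTOFF
            if d <= limit:
                adj[id(a)].append(b)
                adj[id(b)].append(a)
    for atom in structure.all_atoms():
        if atom.is_hydrogen and atom.bonded_heavy is not None:
            adj[id(atom)].append(atom.bonded_heavy)
            adj[id(atom.bonded_heavy)].append(atom)
    return adj


def atoms_within_bonds(atom: Atom, adjacency: dict[int, list[Atom]], max_bonds: int) -> set[int]:
    """ids of atoms within ``max_bonds`` covalent bonds of ``atom``."""
    seen = {id(atom)}
    frontier = deque([(atom, 0)])
    while frontier:
        current, depth = frontier.popleft()
        if depth == max_bonds:
            continue
        for nbr in adjacency.get(id(current), ()):
            if id(nbr) not in seen:
                seen.add(id(nbr))
                frontier.append((nbr, depth + 1))
    return seen
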