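"""Seed-deterministic synthetic structures and alignments with ground truth.

The wire generator emits a toy structure containing a buried pseudo-metal
connected to an exposed terminus by a planted chain of alternating
serine hydroxyls and waters.  The chain zig-zags with a turn angle equal
to the water H-O-H angle, so that an optimally oriented water can donate
one hydrogen to each of its two neighbours — the geometry of an ideal
Grotthuss relay.  Wire chemistry is deliberately ordinary (serine OH,
water): the protonation module treats it with its default rules and no
production code special-cases synthetic input.

Ground truth (the planted node sequence) is returned as an object and
serialized to a JSON sidecar, never embedded in the PDB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._geom import fibonacci_sphere, rotate_about, unit
from .conservation import AlignmentSet, MotifPattern
from .structure import Atom, Residue, Structure

__all__ = [
    "WireSpec",
    "GroundTruth",
    "MotifAlignmentSpec",
    "make_wire_structure",
    "make_motif_alignment",
]

#: zig-zag half-angle: consecutive steps subtend 180 - 2*37.75 = 104.5 deg,
#: matching the water angle so one water can donate to both neighbours
_ZIGZAG_HALF_ANGLE = 37.75


@dataclass(frozen=True)
class WireSpec:
    """Parameters of a planted proton wire."""

    n_nodes: int = 6
    step_distance: float = 2.8
    angular_noise: float = 0.0
    n_decoys: int = 0
    decoy_min_separation: float = 4.0
    occluder_shell: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (2.4 < self.step_distance < 3.5):
            raise ValueError("step_distance must lie in (2.4, 3.5) A")
        if self.angular_noise < 0 or self.n_decoys < 0:
            raise ValueError("angular_noise and n_decoys must be non-negative")


@dataclass
class GroundTruth:
    """The planted wire as hydrogen-bond-graph node ids."""

    source_node: str
    wire_nodes: list[str]
    sink_spec: str  # "chain:number" of the terminal residue/water
    step_distance: float
    node_positions: list[list[float]] = field(default_factory=list)

    @property
    def all_nodes(self) -> list[str]:
        return [self.source_node] + self.wire_nodes

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_node": self.source_node,
                "wire_nodes": self.wire_nodes,
                "sink_spec": self.sink_spec,
                "step_distance": self.step_distance,
                "node_positions": self.node_positions,
            },
            indent=2,
        )


def _wire_points(spec: WireSpec, rng: np.random.Generator) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Node positions and local tangents of the zig-zag wire."""
    half = np.radians(_ZIGZAG_HALF_ANGLE)
    points = [np.array([3.0, 0.0, 0.0])]  # first node, near the metal at origin
    tangents = []
    for k in range(spec.n_nodes - 1):
        d = np.array([np.cos(half), np.sin(half) * (1.0 if k % 2 == 0 else -1.0), 0.0])
        if spec.angular_noise > 0:
            axis = unit(rng.normal(size=3))
            angle = np.radians(rng.uniform(0.0, spec.angular_noise))
            d = rotate_about(d, axis, angle)
        tangents.append(d)
        points.append(points[-1] + spec.step_distance * d)
    tangents.append(tangents[-1] if tangents else np.array([1.0, 0.0, 0.0]))
    return points, tangents


def _make_serine(number: int, og_pos: np.ndarray, tangent: np.ndarray) -> Residue:
    """Minimal serine whose OG sits on the wire; backbone offset out of plane."""
    s = np.array([0.0, 0.0, 1.0])
    s = s - np.dot(s, tangent) * tangent
    s = unit(s) if np.linalg.norm(s) > 1e-6 else np.array([0.0, 0.0, 1.0])
    t = unit(np.cross(tangent, s))
    res = Residue(chain_id="A", number=number, insertion_code="", name="SER")
    og = og_pos
    cb = og + 1.43 * s
    ca = cb + 1.53 * unit(0.77 * s + 0.64 * t)
    n = ca + 1.47 * unit(0.77 * s - 0.64 * t)
    c = ca + 1.53 * unit(0.50 * s + 0.866 * t)
    o = c + 1.23 * s
    for name, element, pos in [
        ("N", "N", n), ("CA", "C", ca), ("C", "C", c),
        ("O", "O", o), ("CB", "C", cb), ("OG", "O", og),
    ]:
        res.add_atom(Atom(serial=0, name=name, element=element,
                          mass=14.007 if element == "N" else (15.999 if element == "O" else 12.011),
                          coords=pos))
    return res


def _make_water(number: int, pos: np.ndarray) -> Residue:
    res = Residue(chain_id="W", number=number, insertion_code="", name="HOH")
    res.add_atom(Atom(serial=0, name="O", element="O", mass=15.999,
                      coords=pos, is_hetero=True))
    return res


def make_wire_structure(spec: WireSpec) -> tuple[Structure, GroundTruth]:
    """Generate the planted-wire structure and its ground truth.

    Odd wire nodes are serine hydroxyls, even nodes are waters; O...O
    spacing equals ``step_distance`` (plus angular jitter).  Decoy polar
    sites (extra waters) are kept at least ``decoy_min_separation`` from
    every wire node.  With ``occluder_shell`` an apolar carbon shell is
    placed around the metal end, burying the source; the terminus stays
    exposed.
    """
    rng = np.random.default_rng(spec.seed)
    points, tangents = _wire_points(spec, rng)

    structure = Structure(id=f"wire{spec.n_nodes}")
    metal = Residue(chain_id="Z", number=9001, insertion_code="", name="NI")
    metal.add_atom(Atom(serial=0, name="NI", element="Ni", mass=58.693,
                        coords=np.zeros(3), is_hetero=True))
    structure.hetero.append(metal)
    structure.metal_sites["NI"] = [metal]

    wire_nodes: list[str] = []
    sers: list[Residue] = []
    waters: list[Residue] = []
    ser_number = 0
    wat_number = 1000
    sink_spec = ""
    for k, (pos, tan) in enumerate(zip(points, tangents)):
        if k % 2 == 0:
            ser_number += 1
            res = _make_serine(ser_number, pos, tan)
            sers.append(res)
            wire_nodes.append(f"A:SER{ser_number}:sc")
            sink_spec = f"A:{ser_number}"
        else:
            wat_number += 1
            res = _make_water(wat_number, pos)
            waters.append(res)
            wire_nodes.append(f"W:W:{wat_number}")
            sink_spec = f"W:{wat_number}"
    structure.chains["A"] = sers
    structure.waters.extend(waters)

    # decoy polar sites: lone waters away from the wire
    wire_atoms = [a for r in sers + waters for a in r.atoms] + metal.atoms
    lo = np.min([p for p in points], axis=0) - 10.0
    hi = np.max([p for p in points], axis=0) + 10.0
    placed: list[np.ndarray] = []
    for _ in range(spec.n_decoys):
        ok = False
        for _attempt in range(1000):
            cand = rng.uniform(lo, hi)
            if min(np.linalg.norm(cand - p) for p in points) < spec.decoy_min_separation:
                continue
            if any(np.linalg.norm(cand - a.coords) < 3.0 for a in wire_atoms):
                continue
            if placed and min(np.linalg.norm(cand - p) for p in placed) < 2.8:
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                "infeasible decoy packing: could not satisfy decoy_min_separation"
            )
        placed.append(cand)
        wat_number += 1
        structure.waters.append(_make_water(wat_number, cand))

    if spec.occluder_shell:
        shell = Residue(chain_id="X", number=9100, insertion_code="", name="DUM")
        protected = [a.coords for r in sers + waters for a in r.atoms]
        for i, point in enumerate(fibonacci_sphere(128)):
            pos = 7.0 * point
            if min(np.linalg.norm(pos - p) for p in protected) < 3.0:
                continue  # leave the wire channel open
            shell.add_atom(Atom(serial=0, name=f"C{i}", element="C", mass=12.011,
                                coords=pos, is_hetero=True))
        if shell.atoms:
            structure.hetero.append(shell)

    truth = GroundTruth(
        source_node="M:NI:9001",
        wire_nodes=wire_nodes,
        sink_spec=sink_spec,
        step_distance=spec.step_distance,
        node_positions=[list(map(float, p)) for p in points],
    )
    return structure, truth


# ---------------------------------------------------------------------------
# alignments


@dataclass(frozen=True)
class MotifAlignmentSpec:
    """Parameters of a planted-motif alignment."""

    n_sequences: int = 10
    length: int = 120
    motif: str = "H-x-H-x(2)-H-x(2)-H-x-H"
    planted_start: int = 40  # 1-based column of the motif
    mutation_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be positive")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        motif_len = len(MotifPattern(self.motif))
        if self.planted_start < 1 or self.planted_start + motif_len - 1 > self.length:
            raise ValueError("planted motif does not fit in the sequence length")


_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_motif_alignment(spec: MotifAlignmentSpec) -> tuple[AlignmentSet, list[int]]:
    """Generate an ungapped alignment sharing a motif at a known column.

    Motif columns are mutation-free; every other column mutates per row
    at ``mutation_rate`` from a common ancestral sequence.  Returns the
    alignment and the planted 1-based start per sequence (identical for
    all rows, as the rows carry no gaps).
    """
    rng = np.random.default_rng(spec.seed)
    pattern = MotifPattern(spec.motif)
    elements = pattern.elements()
    motif_instance = "".join(
        e.upper() if e != "x" and not e.startswith("[") and not e.startswith("{")
        else _AA[rng.integers(len(_AA))]
        for e in elements
    )
    ancestral = "".join(_AA[rng.integers(len(_AA))] for _ in range(spec.length))
    start0 = spec.planted_start - 1
    ancestral = (
        ancestral[:start0] + motif_instance + ancestral[start0 + len(motif_instance):]
    )
    motif_cols = set(range(start0, start0 + len(motif_instance)))
    ids, rows = [], []
    for i in range(spec.n_sequences):
        row = list(ancestral)
        for col in range(spec.length):
            if col in motif_cols:
                continue
            if rng.random() < spec.mutation_rate:
                row[col] = _AA[rng.integers(len(_AA))]
        ids.append(f"seq{i + 1}")
        rows.append("".join(row))
    alignment = AlignmentSet(ids=ids, sequences=rows, reference_id=ids[0])
    return alignment, [spec.planted_start] * spec.n_sequences
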