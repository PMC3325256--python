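"""Pathway enumeration through the hydrogen-bond graph.

Candidate proton-transfer routes are simple paths from an active-site
source (typically the Ni atom) to solvent-exposed polar residues.  A
proton wire is limited by its weakest hop, so paths are ranked by their
bottleneck — the longest single H...A step — with total length and node
count as tie-breakers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .hbond import HBondGraph, POLAR_SIDECHAINS
from .structure import Residue, Structure

__all__ = [
    "PathQuery",
    "Pathway",
    "ExposureResult",
    "SourceNotFoundError",
    "surface_exposure",
    "find_pathways",
    "compare_pathways",
]

#: outermost side-chain heavy atom used by the neighbour-count heuristic
TIP_ATOMS = {
    "GLY": "CA", "ALA": "CB", "SER": "OG", "CYS": "SG", "THR": "OG1",
    "VAL": "CB", "LEU": "CG", "ILE": "CD1", "MET": "SD", "PRO": "CG",
    "PHE": "CZ", "TYR": "OH", "TRP": "CH2", "ASN": "ND2", "GLN": "NE2",
    "ASP": "OD2", "GLU": "OE2", "LYS": "NZ", "ARG": "CZ", "HIS": "NE2",
}

#: theoretical maximum accessible surface areas (A^2), Tien et al. 2013
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

NEIGHBOUR_RADIUS = 8.0
NEIGHBOUR_BURIED_THRESHOLD = 18
SASA_EXPOSED_THRESHOLD = 0.2


class SourceNotFoundError(KeyError):
    """Raised when the requested pathway source is not in the graph."""


@dataclass(frozen=True)
class PathQuery:
    """What to search: source, sinks and limits.

    ``source`` is either a metal element symbol (``"NI"``) or a
    ``"chain:number"`` residue spec.  ``sinks=None`` selects all
    surface-exposed polar residues automatically.
    """

    source: str = "NI"
    sinks: Optional[Sequence[Union[str, Residue]]] = None
    max_path_length: int = 12
    strong_only: bool = True
    exposure_method: str = "sasa"
    source_attachment_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.max_path_length < 2:
            raise ValueError("max_path_length must be >= 2 nodes")


@dataclass
class ExposureResult:
    """Solvent exposure of one residue."""

    residue: Residue
    neighbour_count: int
    relative_accessibility: float  # NaN when only the counting heuristic ran
    exposed: bool
    method: str
    fallback: bool = False  # tip atom missing; backbone atom used


@dataclass
class Pathway:
    """An ordered chain of graph nodes with per-step H...A distances."""

    nodes: list[str]
    steps: list[float]
    bottleneck: float
    total_length: float
    sink_exposure: float = float("nan")
    annotations: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def residue_names(self) -> list[str]:
        """Human-readable residue descriptors, e.g. ``ARG479`` or ``W:2001``."""
        out = []
        for node in self.nodes:
            if node.startswith("W:"):
                out.append(node)
            elif node.startswith("M:"):
                out.append(node)
            else:
                out.append(node.split(":")[1])
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Pathway {' -> '.join(self.nodes)} "
            f"bottleneck={self.bottleneck:.2f} A>"
        )


# ---------------------------------------------------------------------------
# surface exposure


def _occluding_atoms(structure: Structure):
    """Heavy atoms that occlude solvent: protein plus non-water hetero."""
    atoms = []
    for res in structure.protein_residues():
        atoms.extend(a for a in res.atoms if not a.is_hydrogen)
    for res in structure.hetero:
        atoms.extend(a for a in res.atoms if not a.is_hydrogen)
    return atoms


def _neighbour_counts(structure: Structure) -> dict[tuple, tuple[int, bool]]:
    atoms = _occluding_atoms(structure)
    tree = cKDTree(np.array([a.coords for a in atoms]))
    out = {}
    for res in structure.protein_residues():
        tip = res.atom(TIP_ATOMS.get(res.name, "CB"))
        fallback = False
        if tip is None:
            tip = res.atom("CB") or res.atom("CA")
            fallback = True
        if tip is None:
            continue
        idx = tree.query_ball_point(tip.coords, NEIGHBOUR_RADIUS)
        count = sum(1 for j in idx if atoms[j].parent is not res)
        out[res.key] = (count, fallback)
    return out


def _shrake_rupley(structure: Structure, point_number: int) -> dict[tuple, float]:
    """Per-residue SASA via biotite's rolling-probe implementation."""
    import biotite.structure as bst

    atoms = _occluding_atoms(structure)
    arr = bst.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    arr.element = np.array([a.element.upper() or "C" for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.res_name = np.array([a.parent.name for a in atoms])
    arr.res_id = np.array([a.parent.number for a in atoms])
    arr.chain_id = np.array([a.parent.chain_id or "A" for a in atoms])
    arr.hetero = np.array([a.is_hetero for a in atoms])
    per_atom = bst.sasa(
        arr, probe_radius=1.4, point_number=point_number, vdw_radii="Single"
    )
    per_atom = np.nan_to_num(per_atom)
    out: dict[tuple, float] = {}
    for atom, area in zip(atoms, per_atom):
        key = atom.parent.key
        out[key] = out.get(key, 0.0) + float(area)
    return out


def surface_exposure(
    structure: Structure,
    method: str = "sasa",
    point_number: int = 256,
) -> list[ExposureResult]:
    """Classify every protein residue as surface-exposed or buried.

    ``sasa``: Shrake-Rupley accessible surface (probe 1.4 A, fixed
    deterministic sphere-point count) relative to per-residue reference
    maxima; exposed when relative accessibility >= 0.2.

    ``neighbour_count``: exposed when fewer than 18 heavy atoms of other
    residues lie within 8 A of the side-chain tip atom.
    """
    if method not in ("sasa", "neighbour_count"):
        raise ValueError(f"unknown exposure method {method!r}")
    counts = _neighbour_counts(structure)
    areas = _shrake_rupley(structure, point_number) if method == "sasa" else {}
    results = []
    for res in structure.protein_residues():
        if res.key not in counts:
            warnings.warn(f"{res.label}: no usable atoms for exposure", stacklevel=2)
            continue
        count, fallback = counts[res.key]
        if method == "sasa":
            rel = areas.get(res.key, 0.0) / MAX_ASA.get(res.name, 200.0)
            exposed = rel >= SASA_EXPOSED_THRESHOLD
        else:
            rel = float("nan")
            exposed = count < NEIGHBOUR_BURIED_THRESHOLD
        results.append(
            ExposureResult(
                residue=res,
                neighbour_count=count,
                relative_accessibility=rel,
                exposed=exposed,
                method=method,
                fallback=fallback,
            )
        )
    return results


# ---------------------------------------------------------------------------
# path search


def _ranking_key(p: Pathway) -> tuple:
    return (round(p.bottleneck, 9), round(p.total_length, 9), p.n_nodes, tuple(p.nodes))


def compare_pathways(a: Pathway, b: Pathway) -> int:
    """Total order: bottleneck, then total length, then node count, then ids."""
    ka, kb = _ranking_key(a), _ranking_key(b)
    return -1 if ka < kb else (1 if ka > kb else 0)


def _strong_view(hb_graph: HBondGraph, strong_only: bool) -> nx.Graph:
    g = hb_graph.graph
    if not strong_only:
        return g.copy()
    keep = [
        (u, v)
        for u, v, data in g.edges(data=True)
        if data.get("kind") != "hbond" or (data.get("hbond") is not None and data["hbond"].is_strong)
    ]
    sub = nx.Graph()
    sub.add_nodes_from(g.nodes(data=True))
    for u, v in keep:
        sub.add_edge(u, v, **g.get_edge_data(u, v))
    return sub


def _resolve_source_nodes(hb_graph: HBondGraph, g: nx.Graph, spec: str) -> list[str]:
    spec = spec.strip()
    metal_prefix = f"M:{spec.upper()}:"
    metal_nodes = [n for n in g.nodes if n.startswith(metal_prefix)]
    if metal_nodes:
        return sorted(metal_nodes)
    if ":" in spec:
        chain, _, num = spec.partition(":")
        for node, res in hb_graph.residues.items():
            if node.endswith(":sc") and res.chain_id == chain and str(res.number) == num:
                return [node]
    available = hb_graph.metal_nodes()
    raise SourceNotFoundError(
        f"source {spec!r} not found in graph; available metal nodes: {available}"
    )


def _sink_nodes(
    hb_graph: HBondGraph,
    g: nx.Graph,
    structure: Structure,
    query: PathQuery,
    exposure: Optional[list[ExposureResult]],
) -> tuple[list[str], dict[tuple, ExposureResult]]:
    if query.sinks is not None:
        nodes = []
        for item in query.sinks:
            if isinstance(item, Residue):
                node = hb_graph.node_for_residue(item)
            else:
                chain, _, num = str(item).partition(":")
                res = structure.find_residue(chain, int(num))
                if res is None:
                    raise KeyError(f"sink residue {item!r} not found")
                node = hb_graph.node_for_residue(res)
            if node in g:
                nodes.append(node)
        return sorted(set(nodes)), {}
    if exposure is None:
        exposure = surface_exposure(structure, method=query.exposure_method)
    by_key = {e.residue.key: e for e in exposure}
    nodes = []
    for e in exposure:
        if not e.exposed or e.residue.name not in POLAR_SIDECHAINS:
            continue
        node = hb_graph.node_for_residue(e.residue)
        if node in g:
            nodes.append(node)
    return sorted(set(nodes)), by_key


def _attach_source(
    g: nx.Graph,
    hb_graph: HBondGraph,
    structure: Structure,
    source_nodes: list[str],
    cutoff: float,
) -> None:
    """Zero-length attachment edges from a metal source to nearby side chains."""
    for node in source_nodes:
        if not node.startswith("M:"):
            continue
        res = hb_graph.residues.get(node)
        metal_atoms = [a for a in res.atoms if a.element.upper() not in {"C", "N", "O", "S", "H"}]
        for pres in structure.protein_residues():
            sc = pres.side_chain_heavy_atoms()
            if not sc:
                continue
            dmin = min(m.distance_to(a) for m in metal_atoms for a in sc)
            if dmin <= cutoff:
                target = hb_graph.node_for_residue(pres)
                if target in g and not g.has_edge(node, target):
                    g.add_edge(node, target, d_ha=0.0, d_da=dmin, kind="source", hbond=None)


def find_pathways(
    hb_graph: HBondGraph,
    structure: Structure,
    query: PathQuery = PathQuery(),
    exposure: Optional[list[ExposureResult]] = None,
) -> list[Pathway]:
    """Enumerate and rank simple paths from the source to the sinks.

    Returns every simple path up to ``max_path_length`` nodes, ranked by
    (bottleneck, total length, node count); the list is deterministic
    for a given graph regardless of node insertion order.  An empty list
    means no connection — not an error.
    """
    g = _strong_view(hb_graph, query.strong_only)
    source_nodes = _resolve_source_nodes(hb_graph, g, query.source)
    _attach_source(g, hb_graph, structure, source_nodes, query.source_attachment_cutoff)
    sinks, exposure_by_key = _sink_nodes(hb_graph, g, structure, query, exposure)

    pathways: list[Pathway] = []
    for src in source_nodes:
        for sink in sinks:
            if sink == src:
                pathways.append(Pathway([src], [], 0.0, 0.0))
                continue
            for node_list in nx.all_simple_paths(g, src, sink, cutoff=query.max_path_length - 1):
                steps = [
                    float(g.get_edge_data(u, v)["d_ha"])
                    for u, v in zip(node_list[:-1], node_list[1:])
                ]
                term = hb_graph.residues.get(sink)
                exp = exposure_by_key.get(term.key) if term is not None else None
                pathways.append(
                    Pathway(
                        nodes=list(node_list),
                        steps=steps,
                        bottleneck=max(steps) if steps else 0.0,
                        total_length=float(sum(steps)),
                        sink_exposure=(
                            exp.relative_accessibility if exp is not None else float("nan")
                        ),
                    )
                )
    pathways.sort(key=_ranking_key)
    return pathways
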