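"""Active-site distance tables, pipeline orchestration and reports.

The distance table mirrors the classic way metalloenzyme papers report
residue placement: the Euclidean distance from the catalytic metal to
the centre of mass (COM) of each residue of interest, with the COM
taken as the mass-weighted mean of the residue's atoms.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .conservation import (
    AlignmentSet,
    ConservationProfile,
    annotate_pathway,
    column_to_residue_map,
)
from .hbond import HBondCriteria, build_graph, detect_hbonds, edges_to_tsv
from .pathway import PathQuery, Pathway, find_pathways, surface_exposure
from .protonation import (
    MetalSiteConstraints,
    ProtonationConfig,
    assign_microstates,
    orient_waters,
    place_hydrogens,
)
from .structure import Residue, Structure, compute_com, parse_pdb, write_pdb

__all__ = [
    "DistanceRecord",
    "PipelineConfig",
    "PipelineError",
    "locate_metal",
    "ni_com_distances",
    "ni_residue_min_distance",
    "run_pipeline",
]

logger = logging.getLogger("protonwire")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class DistanceRecord:
    """One metal-to-residue distance."""

    residue: str
    metric: str  # "Ni-COM" | "Ni-min-side-chain-heavy" | "Ni-atom"
    value: float


def locate_metal(structure: Structure, element: str = "NI",
                 residue_number: Optional[int] = None):
    """Locate exactly one metal atom of the given element.

    Raises ``ValueError`` when none or several are present and no
    residue-number selector disambiguates.
    """
    atoms = [
        a for a in structure.metal_atoms()
        if a.element.upper() == element.upper()
        and (residue_number is None or (a.parent and a.parent.number == residue_number))
    ]
    if not atoms:
        raise ValueError(f"no {element} atom found among classified metal sites")
    if len(atoms) > 1:
        labels = [a.parent.label for a in atoms if a.parent]
        raise ValueError(
            f"multiple {element} atoms found ({labels}); pass residue_number to select one"
        )
    return atoms[0]


def _resolve_residue(structure: Structure, item: Union[Residue, str]) -> Residue:
    if isinstance(item, Residue):
        return item
    chain, _, num = str(item).partition(":")
    res = structure.find_residue(chain, int(num))
    if res is None:
        raise KeyError(f"residue {item!r} not found")
    return res


def ni_com_distances(
    structure: Structure,
    residues: Sequence[Union[Residue, str]],
    include_hydrogens: bool = False,
    metal_element: str = "NI",
) -> list[DistanceRecord]:
    """Distance from the metal to the centre of mass of each residue."""
    metal = locate_metal(structure, metal_element)
    records = []
    for item in residues:
        res = _resolve_residue(structure, item)
        com = compute_com(res, include_hydrogens=include_hydrogens)
        records.append(
            DistanceRecord(
                residue=res.label,
                metric=f"{metal_element.capitalize()}-COM",
                value=float(np.linalg.norm(metal.coords - com)),
            )
        )
    return records


ATOM_SUBSETS = ("side-chain-heavy", "guanidinium-N", "all")


def ni_residue_min_distance(
    structure: Structure,
    residue: Union[Residue, str],
    atom_subset: str = "side-chain-heavy",
    metal_element: str = "NI",
) -> float:
    """Minimum metal-to-atom distance over a named atom subset."""
    metal = locate_metal(structure, metal_element)
    res = _resolve_residue(structure, residue)
    if atom_subset == "side-chain-heavy":
        atoms = res.side_chain_heavy_atoms()
    elif atom_subset == "guanidinium-N":
        atoms = [a for a in res.atoms if a.name in ("NE", "NH1", "NH2")]
    elif atom_subset == "all":
        atoms = list(res.atoms)
    else:
        raise ValueError(f"unknown atom subset {atom_subset!r}; use one of {ATOM_SUBSETS}")
    if not atoms:
        raise ValueError(f"{res.label}: no atoms in subset {atom_subset!r}")
    return float(min(metal.distance_to(a) for a in atoms))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs."""

    structure_path: str = ""
    chain: Optional[str] = None
    protonation: ProtonationConfig = field(default_factory=ProtonationConfig)
    constraints: MetalSiteConstraints = field(default_factory=MetalSiteConstraints)
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    query: PathQuery = field(default_factory=PathQuery)
    alignment_path: Optional[str] = None
    reference_id: Optional[str] = None
    distance_residues: list[str] = field(default_factory=list)
    output_dir: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "protonation" in kwargs:
            kwargs["protonation"] = ProtonationConfig(**kwargs["protonation"])
        if "constraints" in kwargs:
            kwargs["constraints"] = MetalSiteConstraints(**kwargs["constraints"])
        if "criteria" in kwargs:
            kwargs["criteria"] = HBondCriteria(**kwargs["criteria"])
        if "query" in kwargs:
            kwargs["query"] = PathQuery(**kwargs["query"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pathway_dict(p: Pathway) -> dict:
    return {
        "nodes": p.nodes,
        "steps": [round(s, 4) for s in p.steps],
        "bottleneck": round(p.bottleneck, 4),
        "total_length": round(p.total_length, 4),
        "sink_exposure": None if np.isnan(p.sink_exposure) else round(p.sink_exposure, 4),
        "annotations": p.annotations,
    }


def run_pipeline(
    config: PipelineConfig,
    structure: Optional[Structure] = None,
) -> dict:
    """Parse -> protonate -> H-bond graph -> exposure -> pathways -> distances.

    Returns the report as a JSON-serializable dict; when
    ``config.output_dir`` is set, also writes report.json, edges.tsv,
    pathways.json, the protonated PDB and a parameter log.  A stage
    failure raises :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {
        "version": _pkg_version,
        "parameters": {
            "protonation": asdict(config.protonation),
            "criteria": asdict(config.criteria),
            "query": {
                "source": config.query.source,
                "sinks": None if config.query.sinks is None else [str(s) for s in config.query.sinks],
                "max_path_length": config.query.max_path_length,
                "strong_only": config.query.strong_only,
                "exposure_method": config.query.exposure_method,
                "source_attachment_cutoff": config.query.source_attachment_cutoff,
            },
        },
        "inputs": {},
    }

    stage = "parse"
    try:
        if structure is None:
            path = Path(config.structure_path)
            report["inputs"]["structure"] = {
                "path": str(path), "sha256": _sha256(path),
            }
            structure = parse_pdb(path)
        report["structure"] = {
            "id": structure.id,
            "n_protein_residues": sum(1 for _ in structure.protein_residues()),
            "n_waters": len(structure.waters),
            "metal_sites": {k: len(v) for k, v in structure.metal_sites.items()},
        }

        stage = "protonation"
        variants = assign_microstates(structure, config.protonation, config.constraints)
        place_hydrogens(structure, variants, config.criteria, config.protonation)
        orient_waters(structure, config.protonation, config.criteria)
        report["protonation"] = {
            "n_variants": len(variants),
            "states": {
                v.residue.label: {"code": v.code, "charge": v.formal_charge}
                for v in variants
            },
        }

        stage = "hbond_detection"
        hbonds = detect_hbonds(structure, config.criteria)
        report["hbonds"] = {
            "n_total": len(hbonds),
            "n_strong": sum(1 for b in hbonds if b.is_strong),
        }

        stage = "graph"
        graph = build_graph(hbonds, structure, config.criteria,
                            coordination_cutoff=config.constraints.coordination_cutoff)
        report["graph"] = {
            "n_nodes": graph.graph.number_of_nodes(),
            "n_edges": graph.graph.number_of_edges(),
        }

        stage = "exposure"
        exposure = surface_exposure(structure, method=config.query.exposure_method)
        report["exposure"] = {
            "n_exposed": sum(1 for e in exposure if e.exposed),
            "n_residues": len(exposure),
        }

        stage = "pathways"
        pathways = find_pathways(graph, structure, config.query, exposure=exposure)
        report["pathways"] = {
            "n_found": len(pathways),
            "top": [_pathway_dict(p) for p in pathways[:10]],
        }

        stage = "conservation"
        if config.alignment_path and config.reference_id and pathways:
            alignment = AlignmentSet.from_file(config.alignment_path)
            profile = ConservationProfile.from_alignment(alignment)
            chain_id = config.chain or next(iter(structure.chains))
            mapping = column_to_residue_map(
                alignment, config.reference_id, structure, chain_id
            )
            annotate_pathway(pathways[0], profile, mapping)
            report["pathways"]["top"][0] = _pathway_dict(pathways[0])

        stage = "distances"
        if config.distance_residues:
            records = ni_com_distances(structure, config.distance_residues)
            records_h = ni_com_distances(structure, config.distance_residues,
                                         include_hydrogens=True)
            report["distances"] = {
                "heavy_atom_com": {r.residue: round(r.value, 3) for r in records},
                "with_hydrogens_com": {r.residue: round(r.value, 3) for r in records_h},
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    if config.output_dir:
        stage = "write"
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "edges.tsv").write_text(edges_to_tsv(hbonds))
        (out / "pathways.json").write_text(
            json.dumps([_pathway_dict(p) for p in pathways], indent=2)
        )
        (out / "protonated.pdb").write_text(write_pdb(structure, include_hydrogens=True))
        (out / "run.log").write_text(
            json.dumps(
                {
                    "version": _pkg_version,
                    "parameters": report["parameters"],
                    "inputs": report["inputs"],
                },
                indent=2,
                sort_keys=True,
            )
        )
    return report
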