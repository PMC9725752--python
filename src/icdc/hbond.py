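"""Hydrogen-bond networks over structure ensembles and residue-to-residue pathways.

Each model of a multi-model structure (e.g. snapshots sampled from an MD
trajectory and converted to PDB MODEL records) yields one set of
residue-residue hydrogen-bond edges from a geometric criterion: a donor
heavy atom (N/O/S per residue-template chemistry) within ``d_max`` of an
acceptor heavy atom of another residue, plus a donor-H...acceptor angle
gate when explicit hydrogens are available.  Edges aggregate across models
into occupancies; simple paths between a source and target residue are
enumerated over sufficiently occupied edges, and each path's *support* —
the fraction of models in which all of its edges co-occur — is recomputed
against the per-model edge sets, since co-occurrence can only be rarer than
the weakest single edge (support <= bottleneck).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enm import ResidueKey, Structure

__all__ = [
    "HbondCriteria",
    "HbondGraph",
    "Pathway",
    "detect_hbonds",
    "aggregate",
    "find_pathways",
]

# Donor and acceptor heavy atoms per residue template (standard amino acid
# chemistry); backbone N donates and backbone O accepts for every residue.
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "CYS": ("SG",),
}


@dataclass(frozen=True)
class HbondCriteria:
    d_max: float = 3.5          # donor...acceptor heavy-atom distance cap (Angstrom)
    angle_min: float = 120.0    # donor-H...acceptor angle floor (degrees), if H present
    exclude_adjacent: bool = True  # skip |resnum difference| <= 1 within a chain


@dataclass
class HbondGraph:
    """Aggregated hydrogen-bond network with per-model edge sets retained."""

    graph: nx.Graph                              # nodes: ResidueKey; edge attrs: occupancy, witnesses
    model_edges: list[set[frozenset[ResidueKey]]]

    @property
    def n_models(self) -> int:
        return len(self.model_edges)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            rows.append(
                {
                    "res_a": str(u),
                    "res_b": str(v),
                    "occupancy": data["occupancy"],
                    "witnesses": ";".join(sorted(set(data["witnesses"]))),
                }
            )
        return pd.DataFrame(rows, columns=["res_a", "res_b", "occupancy", "witnesses"])


@dataclass
class Pathway:
    residues: list[ResidueKey]
    support: float     # fraction of models containing every edge simultaneously
    bottleneck: float  # minimum single-edge occupancy along the path


def _donors(resname: str, atoms: dict[str, np.ndarray]) -> list[str]:
    out = []
    if "N" in atoms and resname != "PRO":
        out.append("N")
    out.extend(a for a in SIDECHAIN_DONORS.get(resname, ()) if a in atoms)
    return out


def _acceptors(resname: str, atoms: dict[str, np.ndarray]) -> list[str]:
    out = [a for a in ("O", "OXT") if a in atoms]
    out.extend(a for a in SIDECHAIN_ACCEPTORS.get(resname, ()) if a in atoms)
    return out


def _is_hydrogen(atom_name: str) -> bool:
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1] == "H"


def _attached_hydrogens(donor_xyz: np.ndarray, atoms: dict[str, np.ndarray]) -> list[np.ndarray]:
    return [
        xyz
        for name, xyz in atoms.items()
        if _is_hydrogen(name) and np.linalg.norm(xyz - donor_xyz) <= 1.3
    ]


def detect_hbonds(
    structure: Structure,
    model_index: int = 0,
    criteria: HbondCriteria = HbondCriteria(),
) -> dict[frozenset[ResidueKey], list[str]]:
    """Residue pairs sharing >= 1 hydrogen bond in one model, with atom witnesses.

    Distance-only when the donor carries no explicit hydrogen; with
    hydrogens, the donor-H...acceptor angle must reach ``angle_min``.
    """
    model = structure.models[model_index]
    if model.atoms is None:
        raise ValueError("hydrogen-bond detection needs heavy-atom records (Calpha-only model)")
    if not any("N" in a or "O" in a for a in model.atoms):
        raise ValueError("model has no N/O atoms; cannot assign donors/acceptors")
    n = structure.n_residues
    edges: dict[frozenset[ResidueKey], list[str]] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ki, kj = structure.residues[i].key, structure.residues[j].key
            if (
                criteria.exclude_adjacent
                and ki.chain == kj.chain
                and abs(ki.number - kj.number) <= 1
            ):
                continue
            ri, rj = structure.residues[i].name, structure.residues[j].name
            ai, aj = model.atoms[i], model.atoms[j]
            for d_name in _donors(ri, ai):
                d_xyz = ai[d_name]
                hydrogens = _attached_hydrogens(d_xyz, ai)
                for a_name in _acceptors(rj, aj):
                    a_xyz = aj[a_name]
                    dist = float(np.linalg.norm(a_xyz - d_xyz))
                    if dist > criteria.d_max or dist == 0.0:
                        continue
                    if hydrogens:
                        best = max(_dha_angle(d_xyz, h, a_xyz) for h in hydrogens)
                        if best < criteria.angle_min:
                            continue
                    pair = frozenset((ki, kj))
                    witness = f"{ki}.{d_name}->{kj}.{a_name}"
                    edges.setdefault(pair, []).append(witness)
    return edges


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosine = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def aggregate(structure: Structure, criteria: HbondCriteria = HbondCriteria()) -> HbondGraph:
    """Detect hydrogen bonds in every model and aggregate edge occupancies."""
    n_models = structure.n_models
    model_edges: list[set[frozenset[ResidueKey]]] = []
    witnesses: dict[frozenset[ResidueKey], list[str]] = {}
    counts: dict[frozenset[ResidueKey], int] = {}
    for m in range(n_models):
        edges = detect_hbonds(structure, model_index=m, criteria=criteria)
        model_edges.append(set(edges))
        for pair, wit in edges.items():
            counts[pair] = counts.get(pair, 0) + 1
            witnesses.setdefault(pair, []).extend(wit)
    graph = nx.Graph()
    graph.add_nodes_from(r.key for r in structure.residues)
    for pair, count in counts.items():
        u, v = sorted(pair)
        graph.add_edge(u, v, occupancy=count / n_models, witnesses=witnesses[pair])
    return HbondGraph(graph=graph, model_edges=model_edges)


def find_pathways(
    hbonds: HbondGraph,
    source: ResidueKey,
    target: ResidueKey,
    min_occupancy: float = 0.1,
    max_length: int = 6,
) -> list[Pathway]:
    """All simple hydrogen-bond pathways from source to target.

    Only edges with occupancy >= ``min_occupancy`` are walked, paths are
    capped at ``max_length`` edges, and results sort by descending support,
    then ascending length, then lexicographic residue order.
    """
    for key in (source, target):
        if key not in hbonds.graph:
            raise KeyError(f"residue {key} not present in the hydrogen-bond graph")
    sub = nx.Graph(
        (u, v, d)
        for u, v, d in hbonds.graph.edges(data=True)
        if d["occupancy"] >= min_occupancy
    )
    if source not in sub or target not in sub:
        return []
    n_models = hbonds.n_models
    pathways = []
    for nodes in nx.all_simple_paths(sub, source, target, cutoff=max_length):
        pairs = [frozenset((a, b)) for a, b in zip(nodes, nodes[1:])]
        co_occurring = sum(
            1 for edges in hbonds.model_edges if all(p in edges for p in pairs)
        )
        bottleneck = min(sub.edges[a, b]["occupancy"] for a, b in zip(nodes, nodes[1:]))
        pathways.append(
            Pathway(residues=list(nodes), support=co_occurring / n_models, bottleneck=bottleneck)
        )
    pathways.sort(key=lambda p: (-p.support, len(p.residues), [str(r) for r in p.residues]))
    return pathways


def pathway_table(pathways: list[Pathway]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "path": "->".join(str(r) for r in p.residues),
                "n_edges": len(p.residues) - 1,
                "support": p.support,
                "bottleneck": p.bottleneck,
            }
            for p in pathways
        ],
        columns=["path", "n_edges", "support", "bottleneck"],
    )
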