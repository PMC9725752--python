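"""Seeded generators for synthetic structures, ensembles, alignments and fitness tables.

Every generator is a pure function of its arguments (seed included) and
produces objects that satisfy the package's type invariants, so the whole
pipeline — and its command-line demos — can run end to end without any
deposited data.  Calpha traces use the 3.8 A spacing of real protein chains
so that default contact cutoffs behave realistically.

Geometry notes:

* ``ring`` builds a crown rather than a flat polygon: vertices alternate a
  small +/-z offset (even sizes only).  A strictly planar elastic network
  has one spurious zero mode per residue (no spring component out of
  plane); the crown keeps the fixture vertex-transitive — all residues are
  symmetry-equivalent, so per-residue flexibility is exactly uniform —
  while giving a clean 3-D spectrum with exactly six zero modes.
* ``square`` is intentionally planar (a minimal Hessian test case); its
  pseudo-inverse requires the threshold null-space mode.
* ``dumbbell`` joins two dense lobes through a thin 2-residue linker; the
  linker carries all inter-lobe connectivity, making its residues the
  network's hinge (lowest flexibility).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coevolution import AMINO_ACIDS, Msa, build_column_map
from .enm import Model, Residue, ResidueKey, Structure

__all__ = [
    "FixtureSpec",
    "make_structure",
    "make_chain",
    "make_ring",
    "make_square",
    "make_dumbbell",
    "make_msa",
    "make_fitness_table",
    "make_hbond_ensemble",
    "write_pdb",
]

CA_SPACING = 3.8  # Angstrom, canonical Calpha-Calpha distance


@dataclass(frozen=True)
class FixtureSpec:
    kind: str            # chain | ring | square | dumbbell
    size: int = 10
    seed: int = 0
    noise: float = 0.3   # Angstrom, off-lattice jitter where applicable


def _structure_from_coords(coords: np.ndarray, chain: str = "A", resname: str = "ALA") -> Structure:
    residues = [Residue(ResidueKey(chain, i + 1), resname) for i in range(len(coords))]
    return Structure(residues=residues, models=[Model(ca=np.asarray(coords, dtype=float))])


def make_structure(spec: FixtureSpec) -> Structure:
    if spec.kind == "chain":
        return make_chain(spec.size, seed=spec.seed, noise=spec.noise)
    if spec.kind == "ring":
        return make_ring(spec.size)
    if spec.kind == "square":
        return make_square()
    if spec.kind == "dumbbell":
        return make_dumbbell(spec.size, seed=spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_chain(n: int, seed: int = 0, noise: float = 0.3) -> Structure:
    """Near-collinear Calpha trace at 3.8 A spacing with seeded off-axis jitter."""
    if n < 2:
        raise ValueError("chain needs at least 2 residues")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * CA_SPACING
    coords[:, 1:] = rng.normal(scale=max(noise, 1e-3), size=(n, 2))
    return _structure_from_coords(coords)


def make_ring(n: int, z_offset: float = 0.5) -> Structure:
    """Vertex-transitive crown: N-gon with alternating +/-z/2 offsets, neighbors 3.8 A apart."""
    if n < 4 or n % 2:
        raise ValueError("ring fixture needs an even size >= 4")
    chord = np.sqrt(CA_SPACING**2 - z_offset**2)  # in-plane neighbor separation
    radius = chord / (2.0 * np.sin(np.pi / n))
    angles = 2.0 * np.pi * np.arange(n) / n
    coords = np.column_stack(
        [
            radius * np.cos(angles),
            radius * np.sin(angles),
            np.where(np.arange(n) % 2 == 0, z_offset / 2.0, -z_offset / 2.0),
        ]
    )
    return _structure_from_coords(coords)


def make_square(side: float = 1.0) -> Structure:
    """Four residues on a planar unit square (minimal Hessian test geometry)."""
    coords = side * np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    return _structure_from_coords(coords)


def make_dumbbell(
    lobe_size: int = 8,
    seed: int = 0,
    face_radius: float = 3.2,
    neck_gap: float = 2.3,
    helix_radius: float = 4.0,
    helix_rise: float = 2.6,
    jitter: float = 0.25,
) -> Structure:
    """Two lobes joined through a tight 2-residue neck — an hourglass hinge.

    Residue order: lobe A (1..k), linker (k+1, k+2), lobe B (k+3..2k+2), so
    the linker residues sit at 1-based indices k+1 and k+2.  Each lobe is a
    6-residue ring facing the neck plus, for ``lobe_size > 6``, an open
    helical tail behind it; the two linker residues lie on the neck axis,
    framed at short range by both face rings.  The neck is therefore the
    most tightly coordinated — stiffest — part of the network, and the soft
    modes are lobe reorientations with their displacement node at the neck:
    at the default size the two linker residues attain the two lowest
    flexibility values by construction.  Long tails (large ``lobe_size``)
    develop soft bending modes of their own, so hinge dominance is only
    guaranteed for compact lobes.
    """
    if lobe_size < 6:
        raise ValueError("lobe_size must be >= 6 (six residues form the neck-facing ring)")
    rng = np.random.default_rng(seed)
    half = neck_gap + CA_SPACING / 2.0  # face-plane |x|; linker atoms at +-1.9

    def lobe(sign: float) -> np.ndarray:
        ang = 2.0 * np.pi * np.arange(6) / 6 + (0.3 if sign > 0 else 0.0)
        face = np.column_stack(
            [np.full(6, sign * half), face_radius * np.cos(ang), face_radius * np.sin(ang)]
        )
        n_tail = lobe_size - 6
        t = np.arange(n_tail)
        theta = 2.0 * np.pi * t / 7.0
        tail = np.column_stack(
            [
                sign * (half + 2.5 + helix_rise * t),
                helix_radius * np.cos(theta),
                helix_radius * np.sin(theta),
            ]
        )
        return np.vstack([face, tail])

    linker = np.array([[-CA_SPACING / 2.0, 0.0, 0.0], [CA_SPACING / 2.0, 0.0, 0.0]])
    coords = np.vstack([lobe(-1.0), linker, lobe(+1.0)])
    coords += rng.normal(scale=jitter, size=coords.shape)
    return _structure_from_coords(coords)


# ---------------------------------------------------------------------------
# Synthetic alignments


def make_msa(
    n_seqs: int,
    n_cols: int,
    planted_pairs: list[tuple[int, int, float]] = (),
    conservation: float | np.ndarray = 0.5,
    seed: int = 0,
    chain: str = "A",
    offset: int = 1,
) -> Msa:
    """Random alignment with optional planted covarying column pairs.

    Unplanted columns draw independently per sequence: the column's
    consensus symbol with probability ``conservation``, otherwise uniform
    over the remaining 19.  A planted pair (a, b, strength) draws jointly:
    with probability ``strength`` one of two covarying symbol combinations
    (equiprobable), otherwise the two columns draw independently and
    uniformly from their respective two symbols — at strength 1 each column
    is binary-uniform and the pair carries exactly 1 bit of mutual
    information in the large-sample limit.  The reference row (row 0) is
    the consensus.
    """
    rng = np.random.default_rng(seed)
    cons = np.broadcast_to(np.asarray(conservation, dtype=float), (n_cols,))
    planted_cols: set[int] = set()
    for a, b, strength in planted_pairs:
        if not 0.0 <= strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        if a in planted_cols or b in planted_cols or a == b:
            raise ValueError("planted pairs must use disjoint columns")
        planted_cols.update((a, b))
        if not (0 <= a < n_cols and 0 <= b < n_cols):
            raise ValueError("planted column index out of range")

    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    consensus = rng.integers(0, 20, size=n_cols)
    grid = np.empty((n_seqs, n_cols), dtype="U1")

    for col in range(n_cols):
        if col in planted_cols:
            continue
        take_consensus = rng.random(n_seqs) < cons[col]
        others = rng.integers(0, 19, size=n_seqs)
        others[others >= consensus[col]] += 1  # uniform over the 19 non-consensus
        symbols = np.where(take_consensus, consensus[col], others)
        grid[:, col] = aa[symbols]

    for a, b, strength in planted_pairs:
        # Two covarying combinations over two symbols per column.
        sym_a = rng.choice(20, size=2, replace=False)
        sym_b = rng.choice(20, size=2, replace=False)
        covary = rng.random(n_seqs) < strength
        combo = rng.integers(0, 2, size=n_seqs)
        ia = np.where(covary, combo, rng.integers(0, 2, size=n_seqs))
        ib = np.where(covary, combo, rng.integers(0, 2, size=n_seqs))
        grid[:, a] = aa[sym_a[ia]]
        grid[:, b] = aa[sym_b[ib]]
        consensus[a] = sym_a[0]
        consensus[b] = sym_b[0]

    grid[0, :] = aa[consensus]  # reference row = consensus
    seqs = ["".join(row) for row in grid]
    ids = ["reference"] + [f"seq{i}" for i in range(1, n_seqs)]
    column_map = build_column_map(seqs[0], chain=chain, offset=offset)
    return Msa(ids=ids, seqs=seqs, reference_index=0, column_map=column_map)


# ---------------------------------------------------------------------------
# Synthetic fitness tables


#: Per-category effect models on the relative-fitness scale: category (1,1)
#: carries a strong two-tailed effect (enhancing and deleterious), (0,1) a
#: weaker two-tailed one, (1,0) a modest enhancing shift, (0,0) is neutral.
DEFAULT_EFFECTS: dict[str, dict[str, float | bool]] = {
    "(1,1)": {"mean": 0.5, "sd": 0.25, "two_tailed": True},
    "(1,0)": {"mean": 0.2, "sd": 0.2, "two_tailed": False},
    "(0,1)": {"mean": 0.25, "sd": 0.2, "two_tailed": True},
    "(0,0)": {"mean": 0.0, "sd": 0.05, "two_tailed": False},
}


def make_fitness_table(
    icdc: pd.DataFrame,
    effects: dict[str, dict[str, float | bool]] | None = None,
    n_subs_per_position: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-mutation fitness records drawn from each category's effect model.

    For every classified position, ``n_subs_per_position`` substitutions are
    drawn with values from the category's Gaussian; two-tailed categories
    flip the sign of the mean per record.
    """
    effects = DEFAULT_EFFECTS if effects is None else effects
    for cat in ("(1,1)", "(1,0)", "(0,1)", "(0,0)"):
        if cat not in effects:
            raise ValueError(f"effects missing category {cat}")
    rng = np.random.default_rng(seed)
    from .classify import THREE_TO_ONE

    rows = []
    for _, pos in icdc.iterrows():
        cat = pos["category"]
        if cat == "unclassified":
            continue
        spec = effects[cat]
        wt = THREE_TO_ONE.get(str(pos["resname"]), "A")
        subs = [a for a in AMINO_ACIDS if a != wt]
        chosen = rng.choice(subs, size=min(n_subs_per_position, len(subs)), replace=False)
        for sub in chosen:
            sign = rng.choice([-1.0, 1.0]) if spec.get("two_tailed") else 1.0
            value = sign * float(spec["mean"]) + rng.normal(scale=float(spec["sd"]))
            rows.append(
                {
                    "position": int(pos["resnum"]),
                    "wt": wt,
                    "sub": sub,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["position", "wt", "sub", "value"])


# ---------------------------------------------------------------------------
# Hydrogen-bond ensembles


def make_hbond_ensemble(
    n_models: int,
    planted_edges: list[tuple[tuple[int, int], float]],
    n_residues: int | None = None,
    seed: int = 0,
) -> Structure:
    """Multi-model structure realizing planted hydrogen-bond occupancies exactly.

    Nodes (0-based indices) become residues numbered 1, 3, 5, ... on a wide
    circle; each planted edge appears in exactly ``round(occupancy *
    n_models)`` models (seeded selection).  An edge (a, b) is realized by
    extending a's backbone N toward b's backbone O to 2.9 A in bonded
    models and parking it near its own Calpha otherwise — so each node can
    donate one edge and accept one edge (edge sets must be orientable into
    paths/cycles).  Construction self-checks that detection recovers
    exactly the planted per-model edges.
    """
    from .hbond import HbondCriteria, detect_hbonds

    if n_models < 1:
        raise ValueError("need at least one model")
    nodes: set[int] = set()
    for (a, b), occ in planted_edges:
        if not 0.0 < occ <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        nodes.update((a, b))
    n = max(nodes | {1}) + 1 if n_residues is None else n_residues
    rng = np.random.default_rng(seed)

    # Orient each edge donor -> acceptor; one donor and one acceptor slot per node.
    donor_used: set[int] = set()
    acceptor_used: set[int] = set()
    oriented: list[tuple[int, int, float]] = []
    for (a, b), occ in planted_edges:
        if a not in donor_used and b not in acceptor_used:
            d, acc = a, b
        elif b not in donor_used and a not in acceptor_used:
            d, acc = b, a
        else:
            raise ValueError(
                f"edge ({a},{b}) cannot be oriented: donor/acceptor slots exhausted "
                "(edge set must decompose into simple paths or cycles)"
            )
        donor_used.add(d)
        acceptor_used.add(acc)
        oriented.append((d, acc, occ))

    # Wide circular layout: every inter-node distance >= 12 A.
    radius = max(12.0, 12.0 / (2.0 * np.sin(np.pi / max(n, 3))))
    angles = 2.0 * np.pi * np.arange(n) / n
    centers = np.column_stack([radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)])

    residues = [Residue(ResidueKey("A", 2 * i + 1), "GLY") for i in range(n)]
    schedule: dict[tuple[int, int], np.ndarray] = {}
    for d, acc, occ in oriented:
        n_on = int(round(occ * n_models))
        on = np.zeros(n_models, dtype=bool)
        on[rng.choice(n_models, size=n_on, replace=False)] = True
        schedule[(d, acc)] = on

    models = []
    for m in range(n_models):
        atoms: list[dict[str, np.ndarray]] = []
        for i in range(n):
            atoms.append(
                {
                    "CA": centers[i].copy(),
                    "N": centers[i] + np.array([0.0, 0.0, 0.5]),
                    "O": centers[i] + np.array([0.0, 0.0, -0.5]),
                }
            )
        for d, acc, _ in oriented:
            u = centers[acc] - centers[d]
            dist = np.linalg.norm(u)
            u = u / dist
            atoms[acc]["O"] = centers[acc] - 2.0 * u  # acceptor O faces the donor
            if schedule[(d, acc)][m]:
                atoms[d]["N"] = centers[acc] - (2.0 + 2.9) * u  # 2.9 A from the O
            else:
                atoms[d]["N"] = centers[d] + 2.0 * u            # parked: gap >= 5 A
        models.append(Model(ca=centers.copy(), atoms=atoms))

    structure = Structure(residues=residues, models=models)

    # Self-check: detection must see exactly the planted on-edges per model.
    key = {i: residues[i].key for i in range(n)}
    for m in range(n_models):
        expected = {
            frozenset((key[d], key[acc]))
            for (d, acc), on in schedule.items()
            if on[m]
        }
        found = set(detect_hbonds(structure, model_index=m, criteria=HbondCriteria()))
        if found != expected:
            raise AssertionError(
                f"ensemble self-check failed in model {m}: planted {expected}, detected {found}"
            )
    return structure


# ---------------------------------------------------------------------------
# PDB output


def write_pdb(structure: Structure, path) -> None:
    """Write a structure (all models; full atoms when present) as a PDB file."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("fixture")
    for mi, model in enumerate(structure.models):
        builder.init_model(mi)
        current_chain = None
        for ri, res in enumerate(structure.residues):
            if res.key.chain != current_chain:
                builder.init_chain(res.key.chain)
                current_chain = res.key.chain
            builder.init_seg("    ")
            builder.init_residue(res.name, " ", res.key.number, res.key.icode or " ")
            atom_map = (
                model.atoms[ri] if model.atoms is not None else {"CA": model.ca[ri]}
            )
            for serial, (name, xyz) in enumerate(atom_map.items(), start=1):
                element = name.lstrip("0123456789")[:1]
                builder.init_atom(
                    name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                    name.center(4), serial, element=element,
                )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
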