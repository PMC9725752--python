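"""The ICDC classifier: binning positions by dynamics and co-evolution.

Each non-binding-site position gets a dynamics bit and a co-evolution bit.
The dynamics bit is 1 for rigid, strongly coupled positions (%DFI at or
below the rigid threshold and %DCI at or above the coupling threshold), 0
for flexible, weakly coupled positions (%DFI at or above the flexible
threshold and %DCI below the coupling threshold), and undefined otherwise
— intermediate positions are left unclassified rather than forced into a
bin, so category statistics stay uncontaminated.  The co-evolution bit is 1
when the position's rank-normalized coupling score with the binding site
reaches the co-evolution threshold.  Category (1,1) — rigid, dynamically
and co-evolutionarily coupled to the binding site — is the predicted
hotspot class for distal function-modulating mutations.

The module also proposes substitutions at candidate positions from the
amino acid types actually observed in the family alignment, optionally
after restricting the alignment to sequences whose binding-site composition
matches the reference protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coevolution import CouplingMatrix, Msa, SequenceWeights, site_coupling
from .enm import ResidueKey, Structure
from .response import DciProfile, DfiProfile

log = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "MutationProposal",
    "assign_category",
    "classify",
    "filter_msa_by_binding_site",
    "propose_substitutions",
]

CATEGORIES = ("(1,1)", "(1,0)", "(0,1)", "(0,0)", "unclassified")

#: Conservative-substitution classes for the optional similarity matching mode.
SIMILARITY_CLASSES = (
    frozenset("ILVM"),
    frozenset("FYW"),
    frozenset("KR"),
    frozenset("DE"),
    frozenset("ST"),
    frozenset("NQ"),
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds on the percentile/rank-normalized scales."""

    dfi_rigid: float = 0.2   # %DFI at or below -> rigid
    dfi_flex: float = 0.7    # %DFI at or above -> flexible
    dci: float = 0.7         # %DCI at or above -> dynamically coupled
    coevo: float = 0.6       # normalized co-evolution score at or above -> co-evolved


@dataclass(frozen=True)
class MutationProposal:
    position: ResidueKey
    wild_type: str
    substitution: str
    weighted_frequency: float
    supporting_sequences: int


def assign_category(
    pct_dfi: float, pct_dci: float, coevo_score: float, thresholds: Thresholds = Thresholds(),
    mode: str = "strict",
) -> tuple[str, int, str]:
    """Assign (dyn_bit, coevo_bit, category) to one position.

    ``strict`` leaves intermediate-%DFI or contradictory positions
    unclassified; ``nearest`` splits them at the midpoint of the rigid and
    flexible %DFI thresholds instead.
    """
    rigid = pct_dfi <= thresholds.dfi_rigid and pct_dci >= thresholds.dci
    flexible = pct_dfi >= thresholds.dfi_flex and pct_dci < thresholds.dci
    if rigid:
        dyn = "1"
    elif flexible:
        dyn = "0"
    elif mode == "nearest":
        mid = 0.5 * (thresholds.dfi_rigid + thresholds.dfi_flex)
        dyn = "1" if (pct_dfi <= mid and pct_dci >= thresholds.dci) else "0"
    else:
        dyn = "undefined"
    coevo_bit = 1 if coevo_score >= thresholds.coevo else 0
    category = "unclassified" if dyn == "undefined" else f"({dyn},{coevo_bit})"
    return dyn, coevo_bit, category


def classify(
    structure: Structure,
    dfi: DfiProfile,
    dci: DciProfile,
    coupling: CouplingMatrix,
    msa: Msa,
    binding_set: list[ResidueKey],
    thresholds: Thresholds = Thresholds(),
    coevo_mode: str = "max",
    dyn_mode: str = "strict",
) -> pd.DataFrame:
    """Build the per-position category table (binding-site positions excluded).

    Positions with no mapped alignment column get a co-evolution score of 0
    (logged); the binding-site coupling score of a mapped position is the
    max (or mean, per ``coevo_mode``) normalized score between its column
    and any binding-site column.
    """
    if not binding_set:
        raise ValueError("binding_set must be non-empty")
    binding = set(binding_set)
    col_of = {key: col for col, key in enumerate(msa.column_map) if key is not None}
    binding_cols = [col_of[k] for k in binding_set if k in col_of]
    for k in binding_set:
        if k not in col_of:
            log.info("binding residue %s has no mapped alignment column", k)
    rows = []
    unmapped = 0
    for i, res in enumerate(structure.residues):
        if res.key in binding:
            continue
        col = col_of.get(res.key)
        if col is None:
            unmapped += 1
            coevo_score = 0.0
        else:
            coevo_score = site_coupling(coupling, col, binding_cols, mode=coevo_mode)
        dyn, coevo_bit, category = assign_category(
            dfi.pct_dfi[i], dci.pct_dci[i], coevo_score, thresholds, mode=dyn_mode
        )
        rows.append(
            {
                "chain": res.key.chain,
                "resnum": res.key.number,
                "icode": res.key.icode,
                "resname": res.name,
                "pct_dfi": dfi.pct_dfi[i],
                "pct_dci": dci.pct_dci[i],
                "coevo_score": coevo_score,
                "dyn_bit": dyn,
                "coevo_bit": coevo_bit,
                "category": category,
            }
        )
    if unmapped:
        log.info("%d position(s) without mapped alignment columns scored coevo = 0", unmapped)
    if not rows:
        raise ValueError("no positions left to classify after excluding the binding site")
    return pd.DataFrame(rows)


def _matches(a: str, b: str, mode: str) -> bool:
    if a == b:
        return True
    if mode == "class":
        return any(a in cls and b in cls for cls in SIMILARITY_CLASSES)
    return False


def filter_msa_by_binding_site(
    msa: Msa,
    binding_columns: list[int],
    reference_composition: str | None = None,
    min_identity: float = 1.0,
    mode: str = "exact",
) -> Msa:
    """Keep sequences whose binding-site composition matches the reference.

    A sequence is retained when its residues at the binding columns match the
    reference composition at >= ``min_identity`` of positions (exact match by
    default, conservative-class match with ``mode="class"``).  The reference
    sequence is always retained.
    """
    if not binding_columns:
        raise ValueError("binding_columns must be non-empty")
    ref = reference_composition or "".join(
        msa.seqs[msa.reference_index][c] for c in binding_columns
    )
    if len(ref) != len(binding_columns):
        raise ValueError("reference_composition length differs from binding_columns")
    keep = []
    for i, seq in enumerate(msa.seqs):
        matched = sum(
            _matches(seq[c], r, mode) for c, r in zip(binding_columns, ref)
        )
        if matched / len(binding_columns) >= min_identity or i == msa.reference_index:
            keep.append(i)
    if len(keep) <= 1 and min_identity > 0:
        raise ValueError(
            "binding-site filter removed every non-reference sequence; lower min_identity"
        )
    return msa.subset(keep)


def propose_substitutions(
    msa: Msa,
    weights: SequenceWeights,
    position: ResidueKey,
    min_weighted_freq: float = 0.05,
) -> list[MutationProposal]:
    """Substitutions observed in the alignment at a position, by weighted frequency.

    Frequencies are computed over non-gap rows with the supplied sequence
    weights; proposals at or above ``min_weighted_freq`` are returned sorted
    by descending frequency, ties broken alphabetically.
    """
    col = msa.column_of(position)
    wild_type = msa.seqs[msa.reference_index][col]
    w = np.asarray(weights.weights, dtype=float)
    if w.shape[0] != msa.n_sequences:
        raise ValueError("weights do not match the alignment")
    tallies: dict[str, float] = {}
    support: dict[str, int] = {}
    total = 0.0
    for seq, wt in zip(msa.seqs, w):
        aa = seq[col]
        if aa in "-." or aa not in THREE_TO_ONE.values():
            continue
        total += wt
        tallies[aa] = tallies.get(aa, 0.0) + wt
        support[aa] = support.get(aa, 0) + 1
    if total == 0.0:
        return []
    proposals = [
        MutationProposal(
            position=position,
            wild_type=wild_type,
            substitution=aa,
            weighted_frequency=freq / total,
            supporting_sequences=support[aa],
        )
        for aa, freq in tallies.items()
        if aa != wild_type and freq / total >= min_weighted_freq
    ]
    proposals.sort(key=lambda p: (-p.weighted_frequency, p.substitution))
    return proposals


def proposals_frame(proposals: list[MutationProposal]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": str(p.position),
                "wt": p.wild_type,
                "substitution": p.substitution,
                "weighted_freq": p.weighted_frequency,
                "supporting_sequences": p.supporting_sequences,
            }
            for p in proposals
        ],
        columns=["position", "wt", "substitution", "weighted_freq", "supporting_sequences"],
    )
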