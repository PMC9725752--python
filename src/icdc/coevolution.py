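"""Column-pair co-evolution scores from a multiple sequence alignment.

The scorer is weighted mutual information with average-product correction
(APC).  Sequences are down-weighted by local redundancy (inverse neighbor
count at an identity threshold), joint column frequencies receive a small
uniform pseudocount, MI is computed in bits over pairwise-complete rows
(rows gapped at either column are dropped), and the APC term
``mean_a * mean_b / mean_all`` removes the background entropic/phylogenetic
signal that inflates every pair involving a variable column.  Corrected
scores are rank-normalized to (0, 1] so that downstream thresholds are
scale-free.  Externally computed L x L score matrices can be dropped in via
:func:`load_coupling_matrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .enm import ResidueKey
from .response import percentile_rank

log = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "Msa",
    "SequenceWeights",
    "CouplingMatrix",
    "read_msa",
    "write_msa",
    "compute_weights",
    "compute_mi",
    "apc_correct",
    "normalize_coupling",
    "site_coupling",
    "pair_table",
    "load_coupling_matrix",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)


def _encode(seq: str) -> np.ndarray:
    """Encode one aligned row: amino acid index, or -1 for gap/ambiguity."""
    return np.array([_AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int16)


@dataclass
class Msa:
    """An alignment plus the reference-row mapping of columns to residues."""

    ids: list[str]
    seqs: list[str]
    reference_index: int = 0
    column_map: list[ResidueKey | None] = field(default_factory=list)
    _encoded: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: sequences differ in length")
        if not 0 <= self.reference_index < len(self.seqs):
            raise ValueError("reference_index out of range")
        self.seqs = [s.upper() for s in self.seqs]
        ref = self.seqs[self.reference_index]
        for c in ref:
            if c not in _AA_INDEX and c not in "-.":
                raise ValueError(f"ambiguous character {c!r} in reference row")
        if not self.column_map:
            self.column_map = [None] * self.n_columns
        if len(self.column_map) != self.n_columns:
            raise ValueError("column_map length differs from alignment width")
        mapped = [k for k in self.column_map if k is not None]
        if len(mapped) != len(set(mapped)):
            raise ValueError("column_map maps two columns to the same residue")

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    @property
    def encoded(self) -> np.ndarray:
        if self._encoded is None:
            self._encoded = np.vstack([_encode(s) for s in self.seqs])
        return self._encoded

    def column_of(self, key: ResidueKey) -> int:
        for col, mapped in enumerate(self.column_map):
            if mapped == key:
                return col
        raise KeyError(f"residue {key} is not mapped to any alignment column")

    def subset(self, row_indices: list[int]) -> "Msa":
        if self.reference_index not in row_indices:
            row_indices = [self.reference_index] + list(row_indices)
        row_indices = sorted(set(row_indices))
        return Msa(
            ids=[self.ids[i] for i in row_indices],
            seqs=[self.seqs[i] for i in row_indices],
            reference_index=row_indices.index(self.reference_index),
            column_map=list(self.column_map),
        )


def build_column_map(reference_row: str, chain: str = "A", offset: int = 1) -> list[ResidueKey | None]:
    """Map non-gap reference columns to successive residue numbers from ``offset``."""
    out: list[ResidueKey | None] = []
    num = offset
    for c in reference_row:
        if c in "-.":
            out.append(None)
        else:
            out.append(ResidueKey(chain, num))
            num += 1
    return out


def read_msa(
    path: str | Path,
    fmt: str = "fasta",
    reference_id: str | None = None,
    chain: str = "A",
    offset: int = 1,
) -> Msa:
    """Read a FASTA or Stockholm alignment and anchor it on a reference row."""
    from Bio import AlignIO

    if fmt not in ("fasta", "stockholm"):
        raise ValueError("fmt must be 'fasta' or 'stockholm'")
    aln = AlignIO.read(str(path), fmt)
    ids = [rec.id for rec in aln]
    seqs = [str(rec.seq).upper() for rec in aln]
    if reference_id is None:
        ref_idx = 0
    else:
        try:
            ref_idx = ids.index(reference_id)
        except ValueError:
            raise KeyError(
                f"reference {reference_id!r} not in alignment; available ids: {', '.join(ids)}"
            ) from None
    column_map = build_column_map(seqs[ref_idx], chain=chain, offset=offset)
    return Msa(ids=ids, seqs=seqs, reference_index=ref_idx, column_map=column_map)


def write_msa(msa: Msa, path: str | Path, fmt: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import AlignIO

    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(msa.ids, msa.seqs)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


# ---------------------------------------------------------------------------
# Sequence weighting


@dataclass
class SequenceWeights:
    weights: np.ndarray  # per sequence, in (0, 1]
    identity_threshold: float

    @property
    def meff(self) -> float:
        return float(self.weights.sum())


def compute_weights(msa: Msa, identity_threshold: float = 0.8) -> SequenceWeights:
    """Inverse neighbor-count weights at the given pairwise-identity threshold.

    Identity between two rows is computed over columns where both are
    non-gap; a row's weight is 1 over the number of rows (itself included)
    at or above the threshold.
    """
    if msa.n_sequences < 2:
        raise ValueError("weighting needs at least 2 sequences")
    enc = msa.encoded
    m = msa.n_sequences
    present = enc >= 0
    neighbor_counts = np.zeros(m)
    # Chunked pairwise identity; O(M^2 L) but vectorized over rows.
    chunk = max(1, 2_000_000 // max(1, m * msa.n_columns) + 1)
    for start in range(0, m, chunk):
        stop = min(m, start + chunk)
        both = present[start:stop, None, :] & present[None, :, :]
        same = (enc[start:stop, None, :] == enc[None, :, :]) & both
        denom = both.sum(axis=2)
        ident = np.where(denom > 0, same.sum(axis=2) / np.maximum(denom, 1), 0.0)
        # Rows with no shared columns count only via the self-comparison.
        neighbor_counts[start:stop] += (ident >= identity_threshold).sum(axis=1)
    weights = 1.0 / neighbor_counts
    return SequenceWeights(weights=weights, identity_threshold=identity_threshold)


# ---------------------------------------------------------------------------
# Mutual information with APC


@dataclass
class CouplingMatrix:
    """Symmetric L x L co-evolution scores; invalid pairs (incl. diagonal) are NaN."""

    raw_mi: np.ndarray
    valid: np.ndarray                      # bool, symmetric, False on diagonal
    corrected: np.ndarray | None = None
    normalized: np.ndarray | None = None
    column_map: list[ResidueKey | None] | None = None

    @property
    def n_columns(self) -> int:
        return self.raw_mi.shape[0]


def compute_mi(
    msa: Msa,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.5,
    min_effective: float = 5.0,
) -> CouplingMatrix:
    """Weighted mutual information (bits) for every column pair.

    Joint frequencies use pairwise-complete rows only, weighted by sequence
    weights, with a uniform additive pseudocount of ``pseudocount / 400``
    per cell before normalization.  Pairs whose effective pairwise-complete
    count falls below ``min_effective`` are flagged invalid.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    w = np.ones(msa.n_sequences) if weights is None else np.asarray(weights.weights, float)
    enc = msa.encoded
    L = msa.n_columns
    raw = np.full((L, L), np.nan)
    valid = np.zeros((L, L), dtype=bool)
    cell = pseudocount / (_N_AA * _N_AA)
    for a in range(L):
        for b in range(a + 1, L):
            rows = (enc[:, a] >= 0) & (enc[:, b] >= 0)
            eff = w[rows].sum()
            if eff < min_effective:
                continue
            idx = enc[rows, a].astype(np.int64) * _N_AA + enc[rows, b]
            joint = np.bincount(idx, weights=w[rows], minlength=_N_AA * _N_AA)
            joint = joint.reshape(_N_AA, _N_AA) + cell
            joint /= joint.sum()
            fa = joint.sum(axis=1)
            fb = joint.sum(axis=0)
            nz = joint > 0
            mi = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(fa, fb)[nz])))
            raw[a, b] = raw[b, a] = mi
            valid[a, b] = valid[b, a] = True
    if not valid.any():
        raise ValueError(
            "no valid column pairs: alignment too gappy or too few effective "
            "sequences; a larger MSA is needed"
        )
    return CouplingMatrix(raw_mi=raw, valid=valid, column_map=list(msa.column_map))


def apc_correct(coupling: CouplingMatrix) -> CouplingMatrix:
    """Average-product correction: subtract ``mean_a * mean_b / mean_all``."""
    raw, valid = coupling.raw_mi, coupling.valid
    L = coupling.n_columns
    corrected = np.full((L, L), np.nan)
    counts = valid.sum(axis=1)
    col_mean = np.where(counts > 0, np.nansum(np.where(valid, raw, 0.0), axis=1) / np.maximum(counts, 1), 0.0)
    iu = np.triu_indices(L, k=1)
    pair_valid = valid[iu]
    mean_all = float(raw[iu][pair_valid].mean())
    if mean_all == 0.0:
        log.warning("mean MI is zero; APC correction skipped (corrected = raw)")
        corrected[valid] = raw[valid]
    else:
        apc = np.outer(col_mean, col_mean) / mean_all
        corrected[valid] = (raw - apc)[valid]
    coupling.corrected = corrected
    return coupling


def normalize_coupling(coupling: CouplingMatrix) -> CouplingMatrix:
    """Percentile-rank corrected scores over valid upper-triangle pairs."""
    if coupling.corrected is None:
        raise ValueError("run apc_correct before normalize_coupling")
    L = coupling.n_columns
    normalized = np.full((L, L), np.nan)
    iu = np.triu_indices(L, k=1)
    mask = coupling.valid[iu]
    vals = coupling.corrected[iu][mask]
    ranks = percentile_rank(vals)
    rows = iu[0][mask]
    cols = iu[1][mask]
    normalized[rows, cols] = ranks
    normalized[cols, rows] = ranks
    coupling.normalized = normalized
    return coupling


def site_coupling(
    coupling: CouplingMatrix, column: int, target_columns: list[int], mode: str = "max"
) -> float:
    """A column's co-evolution score with a target column set (invalid pairs -> 0).

    ``max`` (default): a single strong co-evolutionary link suffices;
    ``mean``: average over target columns.
    """
    if coupling.normalized is None:
        raise ValueError("run normalize_coupling first")
    scores = [
        coupling.normalized[column, t]
        for t in target_columns
        if t != column and np.isfinite(coupling.normalized[column, t])
    ]
    if not scores:
        return 0.0
    if mode == "max":
        return float(max(scores))
    if mode == "mean":
        return float(np.mean(scores))
    raise ValueError("mode must be 'max' or 'mean'")


def pair_table(coupling: CouplingMatrix) -> pd.DataFrame:
    """Flatten the upper triangle into a (col_a, col_b, scores, valid) table."""
    L = coupling.n_columns
    rows = []
    for a in range(L):
        for b in range(a + 1, L):
            rows.append(
                {
                    "col_a": a,
                    "col_b": b,
                    "raw_mi": coupling.raw_mi[a, b],
                    "corrected": np.nan if coupling.corrected is None else coupling.corrected[a, b],
                    "normalized": np.nan if coupling.normalized is None else coupling.normalized[a, b],
                    "valid": bool(coupling.valid[a, b]),
                }
            )
    return pd.DataFrame(rows)


def load_coupling_matrix(path: str | Path, column_map: list[ResidueKey | None] | None = None) -> CouplingMatrix:
    """Ingest an externally computed L x L score matrix as ready-normalized scores."""
    m = _io.load_matrix(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix")
    valid = np.isfinite(m)
    np.fill_diagonal(valid, False)
    cm = CouplingMatrix(raw_mi=m.copy(), valid=valid, corrected=m.copy(), column_map=column_map)
    return normalize_coupling(cm)
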