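"""Perturbation response scanning and the DFI / DCI profiles.

Perturbation response scanning (PRS) applies a unit force at one residue at a
time, in several directions, and reads the displacement response of every
other residue off the linear-response kernel: dR = K F.  The dynamic
flexibility index (DFI) of residue i is its share of the total displacement
response of the protein; low-DFI positions are hinges.  The dynamic coupling
index (DCI) of residue i relative to a functional-site set is its mean
response to perturbations at the functional sites divided by its mean
response to perturbations anywhere; values above 1 mark above-average
long-range coupling.  Both profiles are reported alongside their
within-protein percentile ranks (%DFI, %DCI), which is the scale the
classification thresholds operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enm import ResidueKey, ResponseKernel, Structure

__all__ = [
    "ForceSet",
    "ResponseMatrix",
    "DfiProfile",
    "DciProfile",
    "default_force_set",
    "random_force_set",
    "scan_responses",
    "percentile_rank",
    "compute_dfi",
    "compute_dci",
    "hinge_mask",
    "profile_frame",
]

#: Hinge percentile threshold: positions with %DFI below it are hinge sites.
HINGE_THRESHOLD = 0.2


@dataclass
class ForceSet:
    """Unit-force directions applied at each residue during scanning."""

    directions: np.ndarray  # (k, 3), each row unit norm
    label: str = "custom"

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if self.directions.shape[0] < 1 or self.directions.shape[1] != 3:
            raise ValueError("force set needs at least one 3-component direction")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("force directions must be unit vectors")


def default_force_set() -> ForceSet:
    """Seven deterministic near-isotropic directions: axes plus face/space diagonals."""
    raw = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
            [1, 1, 1],
        ],
        dtype=float,
    )
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    return ForceSet(directions=raw, label="default-7")


def random_force_set(k: int, seed: int) -> ForceSet:
    """``k`` seeded random unit vectors (uniform on the sphere)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(k, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return ForceSet(directions=v, label=f"random-{k}-seed{seed}")


@dataclass
class ResponseMatrix:
    """values[i, j] = direction-averaged |dR| of residue i to a unit force at j."""

    values: np.ndarray  # (N, N), nonnegative

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass
class DfiProfile:
    dfi: np.ndarray       # sums to 1
    pct_dfi: np.ndarray   # percentile ranks in (0, 1]


@dataclass
class DciProfile:
    dci: np.ndarray
    pct_dci: np.ndarray
    functional_indices: list[int]


def scan_responses(kernel: ResponseKernel, forces: ForceSet | None = None) -> ResponseMatrix:
    """Apply unit forces residue by residue and average response magnitudes.

    For direction d at residue j the 3N response is ``K @ F(j, d)``, which is
    the (:, j) column block of the kernel contracted with d; entry (i, j) is
    the mean over directions of the Euclidean norm of residue i's 3-vector
    response.

    With ``forces=None`` (the default) the direction average is taken
    analytically over the whole unit sphere — the exact isotropic limit of
    ever-denser direction sets.  For a 3x3 kernel block B with singular
    values s1, s2, s3, the spherical mean of |B d| is the Carlson symmetric
    integral R_G(s1^2, s2^2, s3^2); this makes the profiles exactly
    invariant under rigid rotations of the structure, so symmetric inputs
    give exactly symmetric profiles.  Finite direction sets remain available
    for per-direction scans and cross-checks.
    """
    n = kernel.n_residues
    k4 = kernel.matrix.reshape(n, 3, n, 3)
    if forces is None:
        from scipy.special import elliprg

        blocks = k4.transpose(0, 2, 1, 3)                 # (N, N, 3, 3)
        s = np.linalg.svd(blocks, compute_uv=False)       # (N, N, 3)
        values = elliprg(s[..., 0] ** 2, s[..., 1] ** 2, s[..., 2] ** 2)
        return ResponseMatrix(values=np.asarray(values, dtype=float))
    total = np.zeros((n, n))
    for d in forces.directions:
        resp = np.einsum("iajb,b->iaj", k4, d)      # (N, 3, N)
        total += np.linalg.norm(resp, axis=1)       # (N, N)
    return ResponseMatrix(values=total / len(forces.directions))


def percentile_rank(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Mid-rank percentile in (0, 1]: ties share a rank, max maps to 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty list")
    if np.any(np.isnan(values)):
        raise ValueError("NaN values cannot be ranked")
    return rankdata(values, method="average") / values.size


def compute_dfi(responses: ResponseMatrix) -> DfiProfile:
    """Per-residue share of the protein's total displacement response."""
    row = responses.values.sum(axis=1)
    grand = row.sum()
    if grand <= 0:
        raise ValueError("degenerate kernel: total response is zero")
    dfi = row / grand
    return DfiProfile(dfi=dfi, pct_dfi=percentile_rank(dfi))


def _resolve_indices(
    functional: Iterable[int | ResidueKey | str], structure: Structure | None, n: int
) -> list[int]:
    out: list[int] = []
    for item in functional:
        if isinstance(item, (int, np.integer)):
            idx = int(item)
            if not 0 <= idx < n:
                raise KeyError(f"functional residue index {idx} out of range 0..{n - 1}")
        else:
            if structure is None:
                raise ValueError("a Structure is required to resolve residue keys")
            key = ResidueKey.parse(item) if isinstance(item, str) else item
            idx = structure.index_of(key)
        out.append(idx)
    if not out:
        raise ValueError("functional set is empty")
    return out


def compute_dci(
    responses: ResponseMatrix,
    functional: Iterable[int | ResidueKey | str],
    structure: Structure | None = None,
) -> DciProfile:
    """Response to functional-site perturbations relative to the average site.

    dci_i = mean_{j in functional} values[i, j] / mean_{j} values[i, j].
    """
    n = responses.n_residues
    idx = _resolve_indices(functional, structure, n)
    num = responses.values[:, idx].mean(axis=1)
    den = responses.values.mean(axis=1)
    if np.any(den == 0):
        raise ValueError("degenerate response matrix: a residue has zero mean response")
    dci = num / den
    return DciProfile(dci=dci, pct_dci=percentile_rank(dci), functional_indices=idx)


def hinge_mask(profile: DfiProfile, threshold: float = HINGE_THRESHOLD) -> np.ndarray:
    """Boolean mask of hinge positions (%DFI strictly below the threshold)."""
    return profile.pct_dfi < threshold


def profile_frame(
    structure: Structure,
    dfi: DfiProfile,
    dci: DciProfile | None = None,
) -> pd.DataFrame:
    """Tabulate profiles with author residue numbering for CSV output."""
    data = {
        "chain": [r.key.chain for r in structure.residues],
        "resnum": [r.key.number for r in structure.residues],
        "icode": [r.key.icode for r in structure.residues],
        "resname": [r.name for r in structure.residues],
        "dfi": dfi.dfi,
        "pct_dfi": dfi.pct_dfi,
    }
    if dci is not None:
        data["dci"] = dci.dci
        data["pct_dci"] = dci.pct_dci
    return pd.DataFrame(data)
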