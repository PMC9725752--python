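"""Coarse-grained elastic network models and linear-response kernels.

The anisotropic network model (ANM) places Hookean springs between Calpha
atoms closer than a cutoff radius.  Each contact (i, j) contributes the 3x3
superblock -(gamma / d_ij^2) (r_j - r_i)(r_j - r_i)^T to the Hessian; the
distance-squared weighting makes close contacts stiffer and leaves the cutoff
as the only free geometric parameter.  The Moore-Penrose pseudo-inverse of
the Hessian -- or a covariance matrix supplied from molecular dynamics -- is
the linear-response kernel that all downstream flexibility and coupling
profiles are computed from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io

log = logging.getLogger(__name__)

__all__ = [
    "ResidueKey",
    "Residue",
    "Model",
    "Structure",
    "Hessian",
    "ResponseKernel",
    "read_structure",
    "build_hessian",
    "invert_kernel",
    "pseudoinverse",
    "load_covariance",
    "save_kernel",
]

#: Default ANM interaction cutoff (Angstrom): captures second-shell Calpha contacts.
DEFAULT_CUTOFF = 13.0


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue: chain, number, insertion code."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:42" or "A:42B"
        return f"{self.chain}:{self.number}{self.icode}"

    @classmethod
    def parse(cls, token: str) -> "ResidueKey":
        """Parse a ``chain:number[icode]`` token such as ``A:42`` or ``A:42B``."""
        chain, _, rest = token.strip().partition(":")
        if not rest:
            raise ValueError(f"cannot parse residue token {token!r}; expected chain:number")
        digits = rest
        icode = ""
        while digits and not digits[-1].isdigit():
            icode = digits[-1] + icode
            digits = digits[:-1]
        return cls(chain, int(digits), icode)


@dataclass(frozen=True)
class Residue:
    key: ResidueKey
    name: str = "ALA"


@dataclass
class Model:
    """One coordinate set: Calpha positions, optionally full atoms per residue."""

    ca: np.ndarray  # (N, 3) Angstrom
    atoms: list[dict[str, np.ndarray]] | None = None  # per residue: atom name -> xyz


@dataclass
class Structure:
    """Ordered residues with one or more coordinate models."""

    residues: list[Residue]
    models: list[Model]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a structure needs at least 2 residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in structure")
        if not self.models:
            raise ValueError("a structure needs at least one model")
        n = len(self.residues)
        for m in self.models:
            m.ca = np.asarray(m.ca, dtype=float)
            if m.ca.shape != (n, 3):
                raise ValueError(f"model has {m.ca.shape} coordinates, expected ({n}, 3)")
            if not np.all(np.isfinite(m.ca)):
                raise ValueError("non-finite coordinates in model")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coords(self, model: int = 0) -> np.ndarray:
        return self.models[model].ca

    def index_of(self, key: ResidueKey) -> int:
        for i, r in enumerate(self.residues):
            if r.key == key:
                return i
        raise KeyError(f"residue {key} not in structure")


@dataclass
class Hessian:
    """3N x 3N second-derivative matrix of the elastic network potential."""

    matrix: np.ndarray
    cutoff: float
    spring_constant: float

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ResponseKernel:
    """3N x 3N linear-response kernel (Hessian pseudo-inverse or supplied covariance)."""

    matrix: np.ndarray
    source: str  # "hessian-pseudoinverse" | "supplied-covariance"

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0] // 3


# ---------------------------------------------------------------------------
# Structure input


def read_structure(
    path: str | Path,
    model_policy: str = "first",
    include_hetatm: bool = False,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Residues lacking a Calpha in any model are dropped with a warning;
    alternate locations resolve to the highest-occupancy conformer (Bio.PDB
    default).  With ``model_policy="all"`` every MODEL record is kept as a
    coordinate set; residue lists must be reconcilable across models.
    """
    from Bio.PDB import PDBParser

    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    parser = PDBParser(QUIET=True)
    bio = parser.get_structure("s", str(path))
    bio_models = list(bio.get_models())
    if not bio_models:
        raise ValueError(f"{path}: no models found")
    if model_policy == "first":
        bio_models = bio_models[:1]

    def usable(res) -> bool:
        het = res.id[0].strip()
        if het and not include_hetatm:
            return False
        return "CA" in res

    # Residue order as encountered in the first model.
    order: list[ResidueKey] = []
    names: dict[ResidueKey, str] = {}
    per_model_keys: list[set[ResidueKey]] = []
    dropped: set[ResidueKey] = set()
    for mi, bm in enumerate(bio_models):
        keys_here: set[ResidueKey] = set()
        for chain in bm:
            for res in chain:
                het, num, icode = res.id
                if het.strip() and not include_hetatm:
                    continue
                key = ResidueKey(chain.id, num, icode.strip())
                if not usable(res):
                    dropped.add(key)
                    continue
                keys_here.add(key)
                if mi == 0:
                    order.append(key)
                    names[key] = res.get_resname().strip()
        per_model_keys.append(keys_here)

    common = set.intersection(*per_model_keys) if per_model_keys else set()
    kept = [k for k in order if k in common]
    dropped |= set(order) - set(kept)
    for key in sorted(dropped):
        log.warning("residue %s dropped (missing Calpha or absent from a model)", key)
    if len(kept) < 2:
        raise ValueError(f"{path}: fewer than 2 usable residues with Calpha coordinates")

    models: list[Model] = []
    for bm in bio_models:
        index: dict[ResidueKey, object] = {}
        for chain in bm:
            for res in chain:
                het, num, icode = res.id
                if het.strip() and not include_hetatm:
                    continue
                index[ResidueKey(chain.id, num, icode.strip())] = res
        ca = np.array([index[k]["CA"].get_coord() for k in kept], dtype=float)
        atoms = [
            {atom.get_name(): np.asarray(atom.get_coord(), dtype=float) for atom in index[k]}
            for k in kept
        ]
        models.append(Model(ca=ca, atoms=atoms))

    residues = [Residue(k, names.get(k, "UNK")) for k in kept]
    return Structure(residues=residues, models=models)


# ---------------------------------------------------------------------------
# Hessian construction and inversion


def build_hessian(
    structure: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    spring_constant: float = 1.0,
    model: int = 0,
) -> Hessian:
    """Build the distance-weighted anisotropic network Hessian.

    Off-diagonal superblock for a contact pair (i, j) with distance d <= cutoff:
    ``-(gamma / d^2) (r_j - r_i)(r_j - r_i)^T``; diagonal superblocks enforce
    translation invariance (row sums of superblocks vanish).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if spring_constant <= 0:
        raise ValueError("spring_constant must be positive")
    xyz = structure.coords(model)
    n = len(xyz)
    diff = xyz[None, :, :] - xyz[:, None, :]  # diff[i, j] = r_j - r_i
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    off = ~np.eye(n, dtype=bool)
    if np.any(d2[off] == 0.0):
        i, j = np.argwhere((d2 == 0.0) & off)[0]
        raise ValueError(f"coincident Calpha atoms for residues {i} and {j}")
    contact = (d2 <= cutoff**2) & off
    isolated = np.where(~contact.any(axis=1))[0]
    for i in isolated:
        log.warning("residue index %d has no network neighbor within %.1f A", i, cutoff)

    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contact[i, j]:
                continue
            v = diff[i, j]
            block = -(spring_constant / d2[i, j]) * np.outer(v, v)
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return Hessian(matrix=h, cutoff=cutoff, spring_constant=spring_constant)


def pseudoinverse(matrix: np.ndarray, null_modes: int | None = 6) -> np.ndarray:
    """Eigendecomposition pseudo-inverse discarding the null space.

    With integer ``null_modes`` the that many smallest-magnitude eigenvalues
    are discarded (deterministic for well-formed 3-D structures); with
    ``null_modes=None`` every eigenvalue below ``1e-9 * max|eigenvalue|`` is
    discarded instead (threshold mode, for degenerate geometries).
    """
    matrix = np.asarray(matrix, dtype=float)
    sym = 0.5 * (matrix + matrix.T)
    w, v = np.linalg.eigh(sym)
    mag = np.abs(w)
    wmax = mag.max()
    if wmax == 0.0:
        raise ValueError("zero matrix has no invertible modes")
    order = np.argsort(mag, kind="stable")
    if null_modes is None:
        keep = order[mag[order] > 1e-9 * wmax]
    else:
        keep = order[null_modes:]
    if keep.size == 0:
        raise ValueError("no modes retained after null-space removal")
    near_singular = int(np.sum(mag[keep] < 1e-10 * wmax))
    if near_singular:
        raise ValueError(
            f"{near_singular} near-singular mode(s) in the retained spectrum; "
            "structure likely collinear, planar or disconnected "
            "(consider null_modes=None threshold mode)"
        )
    vk = v[:, keep]
    return (vk / w[keep]) @ vk.T


def invert_kernel(hessian: Hessian, null_modes: int | None = 6) -> ResponseKernel:
    """Pseudo-invert an elastic network Hessian into a response kernel."""
    return ResponseKernel(
        matrix=pseudoinverse(hessian.matrix, null_modes=null_modes),
        source="hessian-pseudoinverse",
    )


# ---------------------------------------------------------------------------
# External covariance ingestion


def load_covariance(path: str | Path, n_residues: int) -> ResponseKernel:
    """Load a 3N x 3N covariance matrix (e.g. from MD) as a response kernel."""
    m = _io.load_matrix(path)
    expected = 3 * n_residues
    if m.shape != (expected, expected):
        raise ValueError(
            f"{path}: covariance is {m.shape[0]}x{m.shape[1]}, expected "
            f"{expected}x{expected} for N={n_residues}"
        )
    scale = np.abs(m).max()
    if scale > 0 and np.abs(m - m.T).max() > 1e-6 * scale:
        raise ValueError(f"{path}: covariance asymmetric beyond 1e-6 relative tolerance")
    return ResponseKernel(matrix=0.5 * (m + m.T), source="supplied-covariance")


def save_kernel(kernel: ResponseKernel, path: str | Path) -> None:
    _io.save_matrix(kernel.matrix, path, header=(f"source = {kernel.source}",))
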