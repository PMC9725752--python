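"""Plain-text matrix and profile I/O shared across the package.

Dense matrices are written one row per line, whitespace-delimited, with
optional ``#`` comment header lines; commas are accepted on input.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["load_matrix", "save_matrix", "write_table", "read_table", "sha256_of"]


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a dense numeric matrix from a whitespace- or comma-delimited file."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in line.replace(",", " ").split()])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric entry on line {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: no numeric rows found")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged rows (expected width {width})")
    return np.asarray(rows, dtype=float)


def save_matrix(matrix: np.ndarray, path: str | Path, header: tuple[str, ...] | list[str] = ()) -> None:
    """Write a dense matrix in the package's text format at full precision."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        np.savetxt(fh, matrix, fmt="%.17g")


def write_table(frame: pd.DataFrame, path: str | Path, metadata: dict[str, object] | None = None) -> None:
    """Write a DataFrame as CSV preceded by ``# key = value`` metadata lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
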