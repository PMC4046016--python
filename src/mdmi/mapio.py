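"""TSV interchange of covariation maps.

Native files carry a single '#' header line with method/correction metadata
followed by a full L x L tab-separated matrix (diagonal written as nan).
Headerless plain numeric matrices (whitespace- or comma-separated), as
exported by third-party covariation tools, are read back as 'external' maps.
"""

from __future__ import annotations

import io
import os
import warnings
from pathlib import Path

import numpy as np

from .core import DIAG_SENTINEL, METHOD_EXTERNAL, CovariationMap


def write_map(cmap: CovariationMap, path: str | Path) -> None:
    """Write a map as TSV with a metadata header, atomically."""
    path = Path(path)
    buf = io.StringIO()
    corrections = ",".join(cmap.corrections) if cmap.corrections else "none"
    buf.write(f"# method={cmap.method}\tcorrections={corrections}\tL={cmap.n_columns}\n")
    np.savetxt(buf, cmap.scores, delimiter="\t", fmt="%.12g")
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(buf.getvalue())
    os.replace(tmp, path)


def _parse_header(line: str) -> tuple[str, list[str]]:
    method = METHOD_EXTERNAL
    corrections: list[str] = []
    for token in line.lstrip("#").split():
        if token.startswith("method="):
            method = token.split("=", 1)[1]
        elif token.startswith("corrections="):
            value = token.split("=", 1)[1]
            if value and value != "none":
                corrections = value.split(",")
    return method, corrections


def read_map(path: str | Path) -> CovariationMap:
    """Read a native TSV map or a plain third-party numeric matrix."""
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path} is empty")
    method, corrections = METHOD_EXTERNAL, []
    if lines[0].startswith("#"):
        method, corrections = _parse_header(lines[0])
    body = "\n".join(l for l in lines if l and not l.startswith("#"))
    try:
        matrix = np.loadtxt(io.StringIO(body))
    except ValueError:
        matrix = np.loadtxt(io.StringIO(body), delimiter=",")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {matrix.shape}")
    off = ~np.eye(matrix.shape[0], dtype=bool)
    if not np.allclose(matrix[off], matrix.T[off], equal_nan=True, atol=1e-9):
        warnings.warn(f"{path}: matrix not symmetric; symmetrizing by averaging")
        matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, DIAG_SENTINEL)
    return CovariationMap(matrix, method=method, corrections=corrections)
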