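"""Distance-dependent covariation signal within secondary-structure elements.

For an element of length n the scores C[r, r+d] are laid out in a staggered
(n-1) x (n-1) matrix whose row r holds C[r, r+1] ... C[r, n]; the signal at
sequence distance d is the mean of the non-zero entries of column d.  Helix
and strand intervals come from PDB HELIX/SHEET header records translated to
alignment columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import CovariationMap
from .msa_io import ColumnStructureMap

HELIX = "helix"
STRAND = "strand"


@dataclass(frozen=True)
class SSElement:
    kind: str  # 'helix' or 'strand'
    start: int  # first alignment column, inclusive
    end: int  # last alignment column, inclusive

    def __post_init__(self) -> None:
        if self.kind not in (HELIX, STRAND):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.start > self.end or self.start < 0:
            raise ValueError(f"bad element interval ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SSAnnotation:
    elements: list[SSElement]

    def of_kind(self, kind: str) -> list[SSElement]:
        return [e for e in self.elements if e.kind == kind]


def _parse_helix_record(line: str) -> tuple[str, int, int]:
    # columns (1-based): initChainID 20, initSeqNum 22-25, endSeqNum 34-37
    return line[19], int(line[21:25]), int(line[33:37])


def _parse_sheet_record(line: str) -> tuple[str, int, int]:
    # columns (1-based): initChainID 22, initSeqNum 23-26, endSeqNum 34-37
    return line[21], int(line[22:26]), int(line[33:37])


def ss_from_pdb_header(
    pdb_path: str | Path, colmap: ColumnStructureMap, chain_id: str | None = None
) -> SSAnnotation:
    """Secondary-structure intervals from HELIX/SHEET records, in columns.

    Residue ranges are converted to alignment columns through the column map;
    elements not fully mappable are truncated to their mapped columns, and
    elements shorter than 2 mapped columns are dropped.
    """
    records: list[tuple[str, str, int, int]] = []
    for line in Path(pdb_path).read_text().splitlines():
        if line.startswith("HELIX"):
            records.append((HELIX, *_parse_helix_record(line)))
        elif line.startswith("SHEET"):
            records.append((STRAND, *_parse_sheet_record(line)))
    if not records:
        warnings.warn(f"no HELIX/SHEET records in {pdb_path}")
        return SSAnnotation([])

    res_to_col = colmap.residue_to_column
    elements: list[SSElement] = []
    for kind, chain, start_res, end_res in records:
        if chain_id is not None and chain != chain_id:
            continue
        cols = []
        for resseq in range(start_res, end_res + 1):
            for key in ((chain, resseq), resseq):
                if key in res_to_col:
                    cols.append(res_to_col[key])
                    break
        if len(cols) < 2:
            continue
        elements.append(SSElement(kind, min(cols), max(cols)))
    if not elements:
        warnings.warn("no mappable secondary-structure elements of length >= 2")
    return SSAnnotation(elements)


def staggered_matrix(scores: np.ndarray, element: SSElement) -> np.ndarray:
    """(n-1) x (n-1) staggered score matrix of an element of length n.

    Row r (0-based) holds the scores between position r and positions
    r+1 ... n-1 of the element; all other cells are 0.
    """
    n = element.length
    if n < 2:
        raise ValueError("element must span at least 2 columns")
    out = np.zeros((n - 1, n - 1))
    for r in range(n - 1):
        for d in range(1, n - r):
            value = scores[element.start + r, element.start + r + d]
            out[r, d - 1] = 0.0 if np.isnan(value) else value
    return out


def distance_signal(
    cmap: CovariationMap, element: SSElement
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean covariation score per sequence distance 1 .. n-1 of one element.

    Returns (distances, means, counts); a distance whose column of the
    staggered matrix holds no non-zero entry is reported as NaN with count 0.
    """
    m = staggered_matrix(cmap.scores, element)
    n_dist = m.shape[1]
    distances = np.arange(1, n_dist + 1)
    means = np.full(n_dist, np.nan)
    counts = np.zeros(n_dist, dtype=int)
    for d in range(n_dist):
        col = m[:, d]
        nonzero = col[col != 0.0]
        counts[d] = nonzero.size
        if nonzero.size:
            means[d] = nonzero.mean()
    return distances, means, counts


def minmax_normalize(cmap: CovariationMap) -> CovariationMap:
    """Scale off-diagonal scores onto [0, 1] (constant maps go to 0)."""
    s = cmap.scores
    off = cmap.offdiag_mask()
    vals = s[off]
    vals = vals[~np.isnan(vals)]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out = np.zeros_like(s)
    else:
        out = (s - lo) / (hi - lo)
    return CovariationMap(out, method=cmap.method, corrections=list(cmap.corrections))


def aggregate_signal(
    maps: Sequence[CovariationMap],
    annotations: Sequence[SSAnnotation],
    kind: str,
    normalize: str = "minmax",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean normalized signal vs distance over all elements of one kind.

    Each family map is min-max normalized over its off-diagonal entries
    before its elements' signals are pooled; per distance, values from all
    elements of all families are averaged, ignoring missing distances.
    """
    if len(maps) != len(annotations):
        raise ValueError("need one annotation per map")
    if normalize not in ("minmax", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    per_distance: dict[int, list[float]] = {}
    n_elements = 0
    for cmap, ann in zip(maps, annotations):
        elements = [e for e in ann.of_kind(kind) if e.length >= 2]
        if not elements:
            continue
        normed = minmax_normalize(cmap) if normalize == "minmax" else cmap
        for element in elements:
            n_elements += 1
            distances, means, _ = distance_signal(normed, element)
            for d, v in zip(distances, means):
                if not np.isnan(v):
                    per_distance.setdefault(int(d), []).append(float(v))
    if n_elements == 0:
        raise ValueError(f"no elements of kind {kind!r} in the annotations")
    max_d = max(per_distance) if per_distance else 0
    distances = np.arange(1, max_d + 1)
    means = np.full(max_d, np.nan)
    counts = np.zeros(max_d, dtype=int)
    for d in distances:
        vals = per_distance.get(int(d), [])
        counts[d - 1] = len(vals)
        if vals:
            means[d - 1] = float(np.mean(vals))
    return distances, means, counts
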