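"""Structure-based evaluation of covariation maps.

Contact maps are built from per-residue centroid distances (unweighted mean
of heavy-atom coordinates, side chains included) at a distance cutoff,
default 8 A.  Ranked top-L pair lists support a sequence-separation filter:
by default pairs must have more than ``min_sep`` intervening positions
(|j - i| > min_sep); the relaxed reading |j - i| >= min_sep is available via
``strict=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser

from .core import CovariationMap
from .msa_io import ColumnStructureMap


@dataclass
class ContactMap:
    """Centroid distances between mapped alignment columns plus a cutoff."""

    distances: np.ndarray  # (L, L), NaN where either column is unmapped
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2 or self.distances.shape[0] != self.distances.shape[1]:
            raise ValueError("distance matrix must be square")
        np.fill_diagonal(self.distances, np.nan)

    @property
    def n_columns(self) -> int:
        return self.distances.shape[0]

    @property
    def contacts(self) -> np.ndarray:
        """Boolean contact matrix; NaN distances are never contacts."""
        with np.errstate(invalid="ignore"):
            return self.distances < self.cutoff

    def is_mapped(self, i: int) -> bool:
        row = np.delete(self.distances[i], i)
        return bool(np.any(~np.isnan(row)))


@dataclass
class RankedPairList:
    """Top-scoring (i, j, score) pairs, i < j, non-increasing score."""

    pairs: list[tuple[int, int, float]]
    min_sequence_separation: int
    strict: bool = True

    def __post_init__(self) -> None:
        scores = [s for _, _, s in self.pairs]
        if any(scores[t] < scores[t + 1] for t in range(len(scores) - 1)):
            raise ValueError("pair scores must be non-increasing")
        for i, j, _ in self.pairs:
            if i >= j:
                raise ValueError("pairs must satisfy i < j")
            sep = j - i
            ok = sep > self.min_sequence_separation if self.strict else sep >= self.min_sequence_separation
            if not ok:
                raise ValueError(f"pair ({i}, {j}) violates the separation filter")

    @property
    def pair_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def residue_centroids(
    pdb_path: str | Path, chain_id: str, mode: str = "centroid"
) -> dict[int, np.ndarray]:
    """Per-residue reference coordinates from the first model of a PDB file.

    mode 'centroid': unweighted mean of heavy-atom coordinates (altloc blank
    or A).  mode 'cb': C-beta coordinate, falling back to C-alpha for glycine.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(pdb_path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found in {pdb_path}")
    chain = model[chain_id]
    out: dict[int, np.ndarray] = {}
    for residue in chain:
        hetflag, resseq, _ = residue.id
        if hetflag != " ":
            continue
        if mode == "cb":
            atom = residue["CB"] if "CB" in residue else residue.child_dict.get("CA")
            if atom is not None:
                out[resseq] = atom.get_coord().astype(float)
            continue
        coords = [
            atom.get_coord()
            for atom in residue
            if atom.element != "H" and atom.get_altloc() in (" ", "A")
        ]
        if coords:
            out[resseq] = np.mean(coords, axis=0)
    return out


def contact_map_from_pdb(
    pdb_path: str | Path,
    chain_id: str,
    colmap: ColumnStructureMap,
    cutoff: float = 8.0,
    mode: str = "centroid",
) -> ContactMap:
    """Distance/contact matrix over alignment columns via a column map.

    Columns mapped to residues missing from the structure get NaN distances
    with a warning.
    """
    centroids = residue_centroids(pdb_path, chain_id, mode=mode)
    length = colmap.n_columns
    coords = np.full((length, 3), np.nan)
    for col, residue in colmap.column_to_residue.items():
        if isinstance(residue, tuple):
            res_chain, resseq = residue
            if res_chain != chain_id:
                continue
        else:
            resseq = int(residue)
        if resseq in centroids:
            coords[col] = centroids[resseq]
        else:
            warnings.warn(f"residue {resseq} (column {col}) missing from structure")
    delta = coords[:, None, :] - coords[None, :, :]
    distances = np.sqrt((delta**2).sum(axis=2))
    return ContactMap(distances, cutoff=cutoff)


def _eligible(i: int, j: int, min_sep: int, strict: bool) -> bool:
    sep = abs(j - i)
    return sep > min_sep if strict else sep >= min_sep


def top_pairs(
    cmap: CovariationMap, n: int, min_sep: int = 0, strict: bool = True
) -> RankedPairList:
    """The n highest-scoring pairs passing the sequence-separation filter.

    Ties are broken by (i, j) lexicographic order.  If fewer than n pairs are
    eligible, all of them are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = cmap.scores
    length = cmap.n_columns
    candidates = [
        (i, j, float(s[i, j]))
        for i in range(length)
        for j in range(i + 1, length)
        if _eligible(i, j, min_sep, strict) and not np.isnan(s[i, j])
    ]
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    if len(candidates) < n:
        warnings.warn(
            f"only {len(candidates)} eligible pairs (requested {n}); returning all"
        )
    return RankedPairList(candidates[:n], min_sequence_separation=min_sep, strict=strict)


def eligible_contact_pairs(
    contacts: ContactMap, min_sep: int = 0, strict: bool = True
) -> list[tuple[int, int]]:
    """All contact pairs (i < j) passing the same separation filter."""
    c = contacts.contacts
    length = contacts.n_columns
    return [
        (i, j)
        for i in range(length)
        for j in range(i + 1, length)
        if _eligible(i, j, min_sep, strict) and c[i, j]
    ]


def tp_curve(ranked: RankedPairList, contacts: ContactMap) -> np.ndarray:
    """Cumulative percent of all eligible true contacts found in the ranking.

    curve[k-1] = 100 * (true contacts among the first k ranked pairs) /
    (total contact pairs passing the same separation filter).
    """
    total = len(
        eligible_contact_pairs(
            contacts, ranked.min_sequence_separation, ranked.strict
        )
    )
    if total == 0:
        raise ValueError("no contact pairs pass the separation filter")
    c = contacts.contacts
    hits = np.array([bool(c[i, j]) for i, j, _ in ranked.pairs])
    return 100.0 * np.cumsum(hits) / total


def overlap_percentage(a: RankedPairList, b: RankedPairList) -> float:
    """Percent of pairs shared by two equally sized ranked lists."""
    if len(a) != len(b):
        raise ValueError(f"ranked lists have different sizes: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty ranked lists")
    return 100.0 * len(a.pair_set & b.pair_set) / len(a)


def overlap_matrix(
    maps: Sequence[CovariationMap], n: int, min_sep: int = 0, strict: bool = True
) -> np.ndarray:
    """Pairwise top-n overlap percentages between methods (diagonal 100)."""
    lengths = {m.n_columns for m in maps}
    if len(lengths) != 1:
        raise ValueError("all maps must have the same number of columns")
    ranked = [top_pairs(m, n, min_sep, strict) for m in maps]
    k = len(maps)
    out = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = overlap_percentage(ranked[i], ranked[j])
    return out


def mean_overlap_matrix(
    per_family_maps: Sequence[Sequence[CovariationMap]],
    per_family_n: Sequence[int],
    min_sep: int = 0,
    strict: bool = True,
) -> np.ndarray:
    """Entrywise mean of per-family overlap matrices."""
    if len(per_family_maps) != len(per_family_n):
        raise ValueError("need one top-pair count per family")
    matrices = [
        overlap_matrix(maps, n, min_sep, strict)
        for maps, n in zip(per_family_maps, per_family_n)
    ]
    return np.mean(matrices, axis=0)
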