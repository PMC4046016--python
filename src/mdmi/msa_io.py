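"""Reading, encoding and structure-mapping of aligned sequences.

Alignments are stored as integer matrices over a fixed 21-symbol alphabet
(20 standard amino acids plus one gap class).  Ambiguous or non-standard
letters (B, Z, X, U, O, ...) and the '.' gap style all collapse to the gap
code so that contingency tables stay well populated for small alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET: tuple[str, ...] = tuple(AMINO_ACIDS) + (GAP,)
GAP_CODE: int = len(ALPHABET) - 1

_LETTER_TO_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class AlignmentError(ValueError):
    """Raised when an input alignment is malformed."""


class MappingError(ValueError):
    """Raised when a column-to-structure mapping cannot be built."""


@dataclass
class EncodedAlignment:
    """Integer-coded N x L alignment over a fixed symbol alphabet.

    Attributes
    ----------
    matrix : ndarray of shape (N, L)
        Integer codes; every entry indexes into ``alphabet``.
    sequence_ids : list of str
        One identifier per row.
    alphabet : tuple of str
        Ordered symbol list; the last entry is the gap class.
    reference_index : int or None
        Row index of the structure-bearing sequence, if any.
    """

    matrix: np.ndarray
    sequence_ids: list[str]
    alphabet: tuple[str, ...] = ALPHABET
    reference_index: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        n, length = self.matrix.shape
        if n < 2 or length < 2:
            raise AlignmentError(f"alignment must be at least 2x2, got {n}x{length}")
        if len(self.sequence_ids) != n:
            raise AlignmentError("number of sequence ids does not match matrix rows")
        if self.matrix.min() < 0 or self.matrix.max() >= len(self.alphabet):
            raise AlignmentError("matrix entry outside the alphabet range")
        if self.reference_index is not None and not (0 <= self.reference_index < n):
            raise AlignmentError("reference_index out of range")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def gap_fraction(self) -> float:
        return float(np.mean(self.matrix == GAP_CODE))

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]

    def row_letters(self, i: int) -> str:
        return "".join(self.alphabet[c] for c in self.matrix[i])

    def to_letters(self) -> list[str]:
        """Decode all rows back to strings."""
        lut = np.array(self.alphabet)
        return ["".join(r) for r in lut[self.matrix]]


def encode_letter(letter: str) -> int:
    """Map a residue letter to its code; anything non-standard is gap."""
    return _LETTER_TO_CODE.get(letter.upper(), GAP_CODE)


def encode_sequences(
    sequences: Sequence[str],
    ids: Sequence[str],
    reference_index: int | None = None,
) -> EncodedAlignment:
    """Encode equal-length letter strings into an :class:`EncodedAlignment`."""
    if not sequences:
        raise AlignmentError("no sequences to encode")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
    matrix = np.array(
        [[encode_letter(c) for c in seq] for seq in sequences], dtype=np.int64
    )
    return EncodedAlignment(matrix, list(ids), reference_index=reference_index)


def read_alignment(
    path: str | Path, format: str = "fasta", reference_id: str | None = None
) -> EncodedAlignment:
    """Read an aligned FASTA or Stockholm file into an EncodedAlignment.

    Letters are case-insensitive; '-' and '.' both become the gap code, as
    do ambiguous residue letters.  Unequal record lengths raise
    :class:`AlignmentError`.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(msa) == 0:
        raise AlignmentError(f"{path} contains no sequences")
    ids = [rec.id for rec in msa]
    seqs = [str(rec.seq) for rec in msa]
    ref = ids.index(reference_id) if reference_id is not None else None
    return encode_sequences(seqs, ids, reference_index=ref)


def write_alignment(aln: EncodedAlignment, path: str | Path) -> None:
    """Write the alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for seq_id, letters in zip(aln.sequence_ids, aln.to_letters()):
            fh.write(f">{seq_id}\n{letters}\n")


@dataclass
class ColumnStructureMap:
    """Partial, injective mapping from alignment columns to structure residues.

    Only columns where the reference sequence carries a non-gap symbol are
    mapped.  Residue identifiers are arbitrary hashables, conventionally
    ``(chain_id, residue_number)`` tuples.
    """

    column_to_residue: dict[int, Hashable]
    n_columns: int = 0
    _residue_to_column: dict[Hashable, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        values = list(self.column_to_residue.values())
        if len(set(values)) != len(values):
            raise MappingError("column-to-residue mapping is not injective")
        if self.column_to_residue:
            max_col = max(self.column_to_residue)
            if min(self.column_to_residue) < 0:
                raise MappingError("negative column index in mapping")
            if self.n_columns and max_col >= self.n_columns:
                raise MappingError("mapped column index beyond alignment length")
            if not self.n_columns:
                self.n_columns = max_col + 1
        self._residue_to_column = {r: c for c, r in self.column_to_residue.items()}

    @property
    def residue_to_column(self) -> dict[Hashable, int]:
        return self._residue_to_column

    def mapped_columns(self) -> list[int]:
        return sorted(self.column_to_residue)


def map_columns_to_structure(
    aln: EncodedAlignment,
    ref_row: int,
    residue_numbers: Sequence[Hashable],
) -> ColumnStructureMap:
    """Associate each non-gap column of a reference row with a residue id.

    The k-th non-gap column of row ``ref_row`` maps to ``residue_numbers[k]``.
    The count of non-gap symbols must equal ``len(residue_numbers)``.
    """
    if not (0 <= ref_row < aln.n_sequences):
        raise MappingError(f"reference row {ref_row} out of range")
    nongap_cols = np.flatnonzero(aln.matrix[ref_row] != GAP_CODE)
    if nongap_cols.size == 0:
        warnings.warn("reference row is all gaps; empty column-structure map")
        return ColumnStructureMap({}, n_columns=aln.n_columns)
    if nongap_cols.size != len(residue_numbers):
        raise MappingError(
            f"reference row has {nongap_cols.size} non-gap columns but "
            f"{len(residue_numbers)} residue identifiers were given"
        )
    mapping = {int(c): r for c, r in zip(nongap_cols, residue_numbers)}
    return ColumnStructureMap(mapping, n_columns=aln.n_columns)
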