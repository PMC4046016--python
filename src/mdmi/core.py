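"""Joint entropies of 1-4 alignment columns and 2D/3D/4D covariation maps.

All entropies are plug-in estimates in bits (log base 2) with the 0*log 0 = 0
convention.  The 3D score of a pair (i, j) is the conditional mutual
information I(Xi; Xj | Xk) averaged over every third column k; the 4D score
additionally conditions on a fourth column l, averaged first over l and then
over k.  Both reduce, term by term, to signed sums of joint entropies, which
is how they are computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msa_io import EncodedAlignment

#: Diagonal sentinel of covariation maps.
DIAG_SENTINEL = np.nan

METHOD_2D = "2D_MI"
METHOD_3D = "3D_MI"
METHOD_4D = "4D_MI"
METHOD_EXTERNAL = "external"


@dataclass
class CovariationMap:
    """Symmetric L x L residue-pair score matrix.

    The diagonal carries NaN (a sentinel, not a score) so that row statistics
    of downstream corrections never mix self-scores in.  ``corrections`` is an
    append-only, duplicate-free history of applied corrections.
    """

    scores: np.ndarray
    method: str = METHOD_EXTERNAL
    corrections: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("covariation map must be a square matrix")
        off = ~np.eye(self.scores.shape[0], dtype=bool)
        if not np.allclose(
            self.scores[off],
            self.scores.T[off],
            rtol=0.0,
            atol=1e-10,
            equal_nan=True,
        ):
            raise ValueError("covariation map must be symmetric off the diagonal")
        np.fill_diagonal(self.scores, DIAG_SENTINEL)
        if len(set(self.corrections)) != len(self.corrections):
            raise ValueError("corrections history contains duplicates")

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n_columns, dtype=bool)

    def with_scores(self, scores: np.ndarray, extra_correction: str | None = None) -> "CovariationMap":
        """Copy carrying new scores; optionally append one correction tag."""
        corrections = list(self.corrections)
        if extra_correction is not None:
            if extra_correction in corrections:
                raise ValueError(f"correction {extra_correction!r} already applied")
            corrections.append(extra_correction)
        return CovariationMap(scores.copy(), method=self.method, corrections=corrections)


# ---------------------------------------------------------------------------
# entropy primitives
# ---------------------------------------------------------------------------


def _combined_codes(aln: EncodedAlignment, columns: Sequence[int]) -> np.ndarray:
    """Collapse up to four columns into a single integer code per row."""
    a = len(aln.alphabet)
    code = aln.matrix[:, columns[0]].astype(np.int64)
    for c in columns[1:]:
        code = code * a + aln.matrix[:, c]
    return code


def _entropy_of_codes(code: np.ndarray) -> float:
    _, counts = np.unique(code, return_counts=True)
    p = counts / code.size
    return float(-(p * np.log2(p)).sum())


def _row_entropies(codes: np.ndarray) -> np.ndarray:
    """Plug-in entropy (bits) of each row of a 2D integer array."""
    r, n = codes.shape
    if r == 0:
        return np.empty(0)
    s = np.sort(codes, axis=1)
    first = np.ones((r, n), dtype=bool)
    first[:, 1:] = s[:, 1:] != s[:, :-1]
    idx = np.flatnonzero(first.ravel())
    runs = np.diff(np.append(idx, r * n))  # runs never cross row boundaries
    p = runs / n
    contrib = -p * np.log2(p)
    out = np.zeros(r)
    np.add.at(out, idx // n, contrib)
    return out


def _check_columns(aln: EncodedAlignment, columns: Sequence[int], k: int | None = None) -> None:
    if k is not None and len(columns) != k:
        raise ValueError(f"expected {k} column indices, got {len(columns)}")
    if not 1 <= len(columns) <= 4:
        raise ValueError("between 1 and 4 columns required")
    if len(set(columns)) != len(columns):
        raise ValueError(f"column indices must be distinct: {list(columns)}")
    for c in columns:
        if not 0 <= c < aln.n_columns:
            raise ValueError(f"column index {c} out of range [0, {aln.n_columns})")


def joint_entropy(aln: EncodedAlignment, columns: Sequence[int]) -> float:
    """Joint entropy H(X_c1, ..., X_ck) in bits, k in 1..4."""
    _check_columns(aln, columns)
    return _entropy_of_codes(_combined_codes(aln, columns))


def mi_2d(aln: EncodedAlignment, i: int, j: int) -> float:
    """Mutual information I(Xi; Xj) = H(Xi) + H(Xj) - H(Xi, Xj)."""
    _check_columns(aln, (i, j), 2)
    return (
        joint_entropy(aln, [i]) + joint_entropy(aln, [j]) - joint_entropy(aln, [i, j])
    )


def interaction_information_3(aln: EncodedAlignment, i: int, j: int, k: int) -> float:
    """Three-way interaction information (may be negative)."""
    _check_columns(aln, (i, j, k), 3)
    h = lambda *cols: joint_entropy(aln, cols)  # noqa: E731
    return (
        h(i) + h(j) + h(k) - h(i, j) - h(i, k) - h(j, k) + h(i, j, k)
    )


def interaction_information_4(
    aln: EncodedAlignment, i: int, j: int, k: int, l: int
) -> float:
    """Four-way interaction information from its fifteen entropy terms."""
    _check_columns(aln, (i, j, k, l), 4)
    h = lambda *cols: joint_entropy(aln, cols)  # noqa: E731
    return (
        (h(i) + h(j) + h(k) + h(l))
        - (h(i, j) + h(i, k) + h(i, l) + h(j, k) + h(j, l) + h(k, l))
        + (h(i, j, k) + h(i, j, l) + h(i, k, l) + h(j, k, l))
        - h(i, j, k, l)
    )


def cond_mi_given_one(aln: EncodedAlignment, i: int, j: int, k: int) -> float:
    """I(Xi; Xj | Xk) = H(Xi,Xk) - H(Xi,Xk,Xj) - H(Xk) + H(Xk,Xj)."""
    _check_columns(aln, (i, j, k), 3)
    h = lambda *cols: joint_entropy(aln, cols)  # noqa: E731
    return h(i, k) - h(i, k, j) - h(k) + h(k, j)


def cond_mi_given_two(aln: EncodedAlignment, i: int, j: int, k: int, l: int) -> float:
    """I(Xi; Xj | Xk, Xl) = -H(Xk,Xl) + H(Xi,Xk,Xl) + H(Xj,Xk,Xl) - H(Xi,Xj,Xk,Xl)."""
    _check_columns(aln, (i, j, k, l), 4)
    h = lambda *cols: joint_entropy(aln, cols)  # noqa: E731
    return -h(k, l) + h(i, k, l) + h(j, k, l) - h(i, j, k, l)


# ---------------------------------------------------------------------------
# map builders
# ---------------------------------------------------------------------------


def _single_and_pair_entropies(aln: EncodedAlignment) -> tuple[np.ndarray, np.ndarray]:
    """H of every column and of every unordered column pair.

    Returns (H1 of shape (L,), H2 of shape (L, L) symmetric with zero diag).
    """
    a = len(aln.alphabet)
    codes = aln.matrix.astype(np.int64)
    length = aln.n_columns
    h1 = _row_entropies(codes.T)
    h2 = np.zeros((length, length))
    for i in range(length - 1):
        pair_codes = codes[:, i][None, :] * a + codes[:, i + 1 :].T
        h = _row_entropies(pair_codes)
        h2[i, i + 1 :] = h
        h2[i + 1 :, i] = h
    return h1, h2


def build_map_2d(aln: EncodedAlignment) -> CovariationMap:
    """Standard pairwise MI map."""
    h1, h2 = _single_and_pair_entropies(aln)
    scores = h1[:, None] + h1[None, :] - h2
    np.fill_diagonal(scores, DIAG_SENTINEL)
    return CovariationMap(scores, method=METHOD_2D)


def build_map_3d(aln: EncodedAlignment) -> CovariationMap:
    """Pairwise conditional MI averaged over every third column.

    scores[i, j] = mean over k not in {i, j} of
    H(Xi,Xk) - H(Xi,Xk,Xj) - H(Xk) + H(Xk,Xj).
    """
    length = aln.n_columns
    if length < 3:
        raise ValueError("3D map requires at least 3 columns")
    a = len(aln.alphabet)
    codes = aln.matrix.astype(np.int64)
    h1, h2 = _single_and_pair_entropies(aln)

    # t3[i, j] accumulates sum over k of H(Xi, Xj, Xk); fill the upper
    # triangle from each unordered triple a < b < c then symmetrise.
    t3u = np.zeros((length, length))
    for i in range(length - 2):
        for j in range(i + 1, length - 1):
            pair_code = codes[:, i] * a + codes[:, j]
            rest = np.arange(j + 1, length)
            h = _row_entropies(pair_code[None, :] * a + codes[:, rest].T)
            t3u[i, j] += h.sum()
            t3u[i, rest] += h
            t3u[j, rest] += h
    t3 = t3u + t3u.T

    rs2 = h2.sum(axis=1)
    tot1 = h1.sum()
    scores = (
        rs2[:, None]
        + rs2[None, :]
        - 2.0 * h2
        - t3
        - (tot1 - h1[:, None] - h1[None, :])
    ) / (length - 2)
    np.fill_diagonal(scores, DIAG_SENTINEL)
    return CovariationMap(scores, method=METHOD_3D)


def build_map_4d(
    aln: EncodedAlignment, include_pair_in_x4: bool = False
) -> CovariationMap:
    """Pairwise conditional MI averaged over every third and fourth column.

    For a pair (i, j) the conditional MI given (Xk, Xl) is averaged first over
    l (l not in {i, j, k}) and then over k (k not in {i, j}).  Because every
    inner average runs over the same number of terms, this equals a flat mean
    over unordered conditioning pairs {k, l} drawn from the remaining columns.

    With ``include_pair_in_x4=True`` the fourth column may coincide with i or
    j; such terms are identically zero, so the alternative only rescales every
    entry by (L-3)/(L-1) and leaves all rankings unchanged.
    """
    length = aln.n_columns
    if length < 4:
        raise ValueError("4D map requires at least 4 columns")
    a = len(aln.alphabet)
    codes = aln.matrix.astype(np.int64)
    h1, h2 = _single_and_pair_entropies(aln)

    # m3[x, y]: sum of H over unordered triples containing both x and y.
    m3u = np.zeros((length, length))
    for i in range(length - 2):
        for j in range(i + 1, length - 1):
            pair_code = codes[:, i] * a + codes[:, j]
            rest = np.arange(j + 1, length)
            h = _row_entropies(pair_code[None, :] * a + codes[:, rest].T)
            m3u[i, j] += h.sum()
            m3u[i, rest] += h
            m3u[j, rest] += h
    m3 = m3u + m3u.T
    # each triple containing x contributes to m3[x, .] twice
    s3 = m3.sum(axis=1) / 2.0

    # m4[x, y]: sum of H over unordered quadruples containing both x and y.
    m4u = np.zeros((length, length))
    for i in range(length - 3):
        for j in range(i + 1, length - 2):
            pair_code = codes[:, i] * a + codes[:, j]
            for k in range(j + 1, length - 1):
                trip_code = pair_code * a + codes[:, k]
                rest = np.arange(k + 1, length)
                h = _row_entropies(trip_code[None, :] * a + codes[:, rest].T)
                hsum = h.sum()
                m4u[i, j] += hsum
                m4u[i, k] += hsum
                m4u[j, k] += hsum
                m4u[i, rest] += h
                m4u[j, rest] += h
                m4u[k, rest] += h
    m4 = m4u + m4u.T

    tot2 = h2.sum() / 2.0
    sum_h2_rest = tot2 - h2.sum(axis=1)[:, None] - h2.sum(axis=1)[None, :] + h2
    n_cond_pairs = (length - 2) * (length - 3) / 2.0
    scores = (
        -sum_h2_rest + s3[:, None] + s3[None, :] - 2.0 * m3 - m4
    ) / n_cond_pairs
    if include_pair_in_x4:
        scores = scores * (length - 3) / (length - 1)
    np.fill_diagonal(scores, DIAG_SENTINEL)
    return CovariationMap(scores, method=METHOD_4D)


def build_map(aln: EncodedAlignment, method: str) -> CovariationMap:
    """Dispatch on method name ('2d', '3d' or '4d', case-insensitive)."""
    key = method.lower().replace("_mi", "").replace("mi", "")
    builders = {"2d": build_map_2d, "3d": build_map_3d, "4d": build_map_4d}
    if key not in builders:
        raise ValueError(f"unknown map method {method!r}")
    return builders[key](aln)


def mean_offdiag(cmap: CovariationMap) -> float:
    """Mean score over off-diagonal entries (NaN-aware)."""
    off = cmap.offdiag_mask()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(cmap.scores[off]))


def n_conditioning_pairs(length: int) -> int:
    """Number of unordered conditioning pairs available to a 4D score."""
    return math.comb(length - 2, 2)
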