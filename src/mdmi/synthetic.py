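"""Synthetic aligned MSAs with planted dependency structure.

Background columns are drawn iid (uniform over the 20 amino acids by
default, with an optional gap fraction).  Planted dependencies:

* ``pair (a, b)``: column b copies column a per row with probability equal
  to the copy fidelity, otherwise it keeps its background draw.
* ``chain3 (a, b, c)``: the middle column b is the source; a and c each
  independently copy b with the given fidelity, so a and c are
  conditionally independent given b while still pairwise coupled.
* ``chain4 (a, b, c, d)``: a sequential chain b<-a, c<-b, d<-c of copies.
* ``fitness_block (cols...)``: a latent binary row variable selects one of
  two preferred symbols per column (with the given fidelity), correlating
  the block's columns without any direct copying.

Ground-truth labels distinguish direct pairs (copy edges), indirect pairs
(chain-induced) and latent pairs (shared-force correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import core, corrections
from .msa_io import ALPHABET, GAP_CODE, EncodedAlignment

KINDS = ("pair", "chain3", "chain4", "fitness_block")
_KIND_ARITY = {"pair": 2, "chain3": 3, "chain4": 4}


@dataclass(frozen=True)
class Dependency:
    kind: str
    columns: tuple[int, ...]
    fidelity: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown dependency kind {self.kind!r}")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("dependency columns must be distinct")
        expected = _KIND_ARITY.get(self.kind)
        if expected is not None and len(self.columns) != expected:
            raise ValueError(f"{self.kind} needs {expected} columns")
        if self.kind == "fitness_block" and len(self.columns) < 2:
            raise ValueError("fitness_block needs at least 2 columns")
        if not 0.0 < self.fidelity <= 1.0:
            raise ValueError("copy fidelity must be in (0, 1]")


@dataclass
class SyntheticSpec:
    n_sequences: int
    n_columns: int
    dependencies: list[Dependency] = field(default_factory=list)
    alphabet_size: int = len(ALPHABET)
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2 or self.n_columns < 2:
            raise ValueError("need at least 2 sequences and 2 columns")
        if not 2 <= self.alphabet_size <= len(ALPHABET):
            raise ValueError("alphabet_size must be in [2, 21]")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")
        for dep in self.dependencies:
            if max(dep.columns) >= self.n_columns:
                raise ValueError(f"dependency column out of range: {dep}")

    @property
    def n_background_symbols(self) -> int:
        """Symbols drawn by the background (amino acids only, gap excluded)."""
        return min(self.alphabet_size, len(ALPHABET) - 1)


@dataclass
class GroundTruth:
    direct_pairs: list[tuple[int, int]]
    indirect_pairs: list[tuple[int, int]]
    latent_pairs: list[tuple[int, int]]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"i": i, "j": j, "label": label}
            for label, pairs in (
                ("direct", self.direct_pairs),
                ("indirect", self.indirect_pairs),
                ("latent", self.latent_pairs),
            )
            for i, j in pairs
        ]
        return pd.DataFrame(rows, columns=["i", "j", "label"])


def _ordered(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def generate(spec: SyntheticSpec) -> tuple[EncodedAlignment, GroundTruth]:
    """Draw an alignment from the generative model; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_sequences, spec.n_columns
    q = spec.n_background_symbols
    matrix = rng.integers(0, q, size=(n, length))
    if spec.gap_fraction > 0:
        matrix[rng.random((n, length)) < spec.gap_fraction] = GAP_CODE

    direct: list[tuple[int, int]] = []
    indirect: list[tuple[int, int]] = []
    latent: list[tuple[int, int]] = []
    for dep in spec.dependencies:
        f = dep.fidelity
        if dep.kind == "pair":
            a, b = dep.columns
            mask = rng.random(n) < f
            matrix[mask, b] = matrix[mask, a]
            direct.append(_ordered(a, b))
        elif dep.kind == "chain3":
            a, b, c = dep.columns
            for target in (a, c):
                mask = rng.random(n) < f
                matrix[mask, target] = matrix[mask, b]
            direct += [_ordered(a, b), _ordered(b, c)]
            indirect.append(_ordered(a, c))
        elif dep.kind == "chain4":
            a, b, c, d = dep.columns
            for source, target in ((a, b), (b, c), (c, d)):
                mask = rng.random(n) < f
                matrix[mask, target] = matrix[mask, source]
            direct += [_ordered(a, b), _ordered(b, c), _ordered(c, d)]
            indirect += [_ordered(a, c), _ordered(b, d), _ordered(a, d)]
        else:  # fitness_block
            cols = dep.columns
            z = rng.integers(0, 2, size=n)
            for col in cols:
                preferred = rng.choice(q, size=2, replace=False)
                mask = rng.random(n) < f
                matrix[mask, col] = preferred[z[mask]]
            latent += [_ordered(x, y) for t, x in enumerate(cols) for y in cols[t + 1 :]]

    ids = [f"seq{i}" for i in range(n)]
    truth = GroundTruth(sorted(set(direct)), sorted(set(indirect)), sorted(set(latent)))
    return EncodedAlignment(matrix, ids), truth


def pair_copy_joint(fidelity: float, q: int) -> np.ndarray:
    """Exact joint distribution of (source, copy) under the pair model."""
    k = np.full((q, q), (1 - fidelity) / q)
    k[np.diag_indices(q)] += fidelity
    return k / q  # uniform source


def chain3_end_joint(fidelity: float, q: int) -> np.ndarray:
    """Exact joint distribution of the two chain ends (a, c) of a chain3."""
    k = np.full((q, q), (1 - fidelity) / q)
    k[np.diag_indices(q)] += fidelity  # K[x | b], columns indexed by b
    return (k / q) @ k.T


def mi_of_joint(joint: np.ndarray) -> float:
    """Mutual information (bits) of an exact 2D joint distribution."""
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float((joint[mask] * np.log2(joint[mask] / (px @ py)[mask])).sum())


def _pair_rank(cmap: core.CovariationMap, pair: tuple[int, int]) -> int:
    """1-based rank of a pair in the descending score order of a map."""
    s = cmap.scores
    length = cmap.n_columns
    ranked = sorted(
        (
            (i, j)
            for i in range(length)
            for j in range(i + 1, length)
            if not np.isnan(s[i, j])
        ),
        key=lambda p: (-s[p], p),
    )
    return ranked.index(pair) + 1


_METHOD_BUILDERS = {
    "2d": core.build_map_2d,
    "3d": core.build_map_3d,
    "4d": core.build_map_4d,
}


def planted_recovery_experiment(
    spec: SyntheticSpec,
    methods: Sequence[str] = ("2d", "3d"),
    n_seeds: int = 20,
    correct: bool = True,
) -> pd.DataFrame:
    """Rank of every ground-truth pair under each method, over replicate seeds.

    Each replicate redraws the alignment with seed = spec.seed + replicate
    index, builds the requested maps (optionally APC+ZPX2 corrected) and
    records the 1-based rank of every labelled pair.
    """
    rows = []
    for replicate in range(n_seeds):
        rep_spec = SyntheticSpec(
            n_sequences=spec.n_sequences,
            n_columns=spec.n_columns,
            dependencies=spec.dependencies,
            alphabet_size=spec.alphabet_size,
            gap_fraction=spec.gap_fraction,
            seed=spec.seed + replicate,
        )
        aln, truth = generate(rep_spec)
        for method in methods:
            cmap = _METHOD_BUILDERS[method.lower()](aln)
            if correct:
                cmap = corrections.standard_pipeline(cmap)
            for label, pairs in (
                ("direct", truth.direct_pairs),
                ("indirect", truth.indirect_pairs),
                ("latent", truth.latent_pairs),
            ):
                for pair in pairs:
                    rows.append(
                        {
                            "seed": rep_spec.seed,
                            "method": method,
                            "label": label,
                            "i": pair[0],
                            "j": pair[1],
                            "rank": _pair_rank(cmap, pair),
                        }
                    )
    return pd.DataFrame(rows)
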