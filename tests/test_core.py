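"""Entropy/MI primitives and map builders against independent oracles.

Oracles here are written from the definitions (tuple enumeration, stratified
sums, nested loops) and never call the code paths they check.
"""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdmi.core import (
    CovariationMap,
    build_map_2d,
    build_map_3d,
    build_map_4d,
    cond_mi_given_one,
    cond_mi_given_two,
    joint_entropy,
    mi_2d,
)
from mdmi.msa_io import EncodedAlignment

from conftest import alignment_from_columns, random_alignment

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_entropy(rows):
    """-sum p log2 p over observed tuples."""
    counts = Counter(map(tuple, rows))
    n = len(rows)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def oracle_joint_entropy(aln, cols):
    return oracle_entropy(aln.matrix[:, list(cols)].tolist())


def oracle_mi(aln, i, j):
    n = aln.n_sequences
    pij = Counter(zip(aln.matrix[:, i], aln.matrix[:, j]))
    pi = Counter(aln.matrix[:, i])
    pj = Counter(aln.matrix[:, j])
    total = 0.0
    for (a, b), c in pij.items():
        p = c / n
        total += p * math.log2(p / ((pi[a] / n) * (pj[b] / n)))
    return total


def oracle_cond_mi_one(aln, i, j, k):
    """Stratified sum: sum_x3 p(x3) I(Xi; Xj | Xk = x3)."""
    n = aln.n_sequences
    total = 0.0
    for value in np.unique(aln.matrix[:, k]):
        sub = aln.matrix[aln.matrix[:, k] == value]
        weight = len(sub) / n
        sub_aln_rows = sub[:, [i, j]]
        pij = Counter(map(tuple, sub_aln_rows.tolist()))
        pi = Counter(sub[:, i])
        pj = Counter(sub[:, j])
        m = len(sub)
        mi = 0.0
        for (a, b), c in pij.items():
            p = c / m
            mi += p * math.log2(p / ((pi[a] / m) * (pj[b] / m)))
        total += weight * mi
    return total


def oracle_cond_mi_two(aln, i, j, k, l):
    """Stratified sum over joint values of (Xk, Xl)."""
    n = aln.n_sequences
    kl = list(zip(aln.matrix[:, k], aln.matrix[:, l]))
    total = 0.0
    for value in set(kl):
        rows = np.array([t == value for t in kl])
        sub = aln.matrix[rows]
        weight = len(sub) / n
        pij = Counter(zip(sub[:, i], sub[:, j]))
        pi = Counter(sub[:, i])
        pj = Counter(sub[:, j])
        m = len(sub)
        mi = 0.0
        for (a, b), c in pij.items():
            p = c / m
            mi += p * math.log2(p / ((pi[a] / m) * (pj[b] / m)))
        total += weight * mi
    return total


def oracle_ii3(aln, i, j, k):
    h = lambda *c: oracle_joint_entropy(aln, c)  # noqa: E731
    return h(i) + h(j) + h(k) - h(i, j) - h(i, k) - h(j, k) + h(i, j, k)


def oracle_ii4(aln, i, j, k, l):
    h = lambda *c: oracle_joint_entropy(aln, c)  # noqa: E731
    return (
        h(i) + h(j) + h(k) + h(l)
        - h(i, j) - h(i, k) - h(i, l) - h(j, k) - h(j, l) - h(k, l)
        + h(i, j, k) + h(i, j, l) + h(i, k, l) + h(j, k, l)
        - h(i, j, k, l)
    )


def oracle_expansion_cond_mi_two(aln, i, j, k, l):
    """Chain-rule expansion: I(i;j) - II3(i,j,l) - II3(i,j,k) + II4(i,j,k,l)."""
    return (
        oracle_mi(aln, i, j)
        - oracle_ii3(aln, i, j, l)
        - oracle_ii3(aln, i, j, k)
        + oracle_ii4(aln, i, j, k, l)
    )


def oracle_map_3d(aln):
    length = aln.n_columns
    out = np.full((length, length), np.nan)
    for i in range(length):
        for j in range(length):
            if i == j:
                continue
            vals = [
                oracle_cond_mi_one(aln, i, j, k)
                for k in range(length)
                if k not in (i, j)
            ]
            out[i, j] = np.mean(vals)
    return out


def oracle_map_4d(aln):
    """Two-stage average exactly as specified: inner over l, outer over k."""
    length = aln.n_columns
    out = np.full((length, length), np.nan)
    for i in range(length):
        for j in range(length):
            if i == j:
                continue
            outer = []
            for k in range(length):
                if k in (i, j):
                    continue
                inner = [
                    oracle_cond_mi_two(aln, i, j, k, l)
                    for l in range(length)
                    if l not in (i, j, k)
                ]
                outer.append(np.mean(inner))
            out[i, j] = np.mean(outer)
    return out


# ---------------------------------------------------------------------------
# joint_entropy
# ---------------------------------------------------------------------------


class TestJointEntropy:
    def test_uniform_binary_column(self):
        aln = alignment_from_columns([0, 0, 1, 1], [2, 2, 2, 2])
        assert joint_entropy(aln, [0]) == pytest.approx(1.0)

    def test_independent_uniform_pair(self):
        aln = alignment_from_columns([0, 0, 1, 1], [0, 1, 0, 1])
        assert joint_entropy(aln, [0, 1]) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        aln = random_alignment(6, 3, 21, seed=seed)
        for cols in [[0], [0, 1], [0, 1, 2], [2, 0]]:
            assert joint_entropy(aln, cols) == pytest.approx(
                oracle_joint_entropy(aln, cols), abs=1e-12
            )

    def test_duplicate_columns_error(self):
        aln = random_alignment(5, 3)
        with pytest.raises(ValueError):
            joint_entropy(aln, [1, 1])

    def test_out_of_range_error(self):
        aln = random_alignment(5, 3)
        with pytest.raises(ValueError):
            joint_entropy(aln, [0, 7])


class TestMi2d:
    def test_identical_columns_mi_equals_entropy(self):
        aln = alignment_from_columns([0, 0, 1, 1], [0, 0, 1, 1])
        assert mi_2d(aln, 0, 1) == pytest.approx(1.0)

    def test_independent_columns_zero(self):
        aln = alignment_from_columns([0, 0, 1, 1], [0, 1, 0, 1])
        assert mi_2d(aln, 0, 1) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_definition_oracle(self, seed):
        aln = random_alignment(30, 4, 6, seed=seed)
        for i, j in itertools.combinations(range(4), 2):
            assert mi_2d(aln, i, j) == pytest.approx(oracle_mi(aln, i, j), abs=1e-12)

    def test_symmetry(self):
        aln = random_alignment(20, 3, 4, seed=9)
        assert mi_2d(aln, 0, 2) == pytest.approx(mi_2d(aln, 2, 0), abs=1e-14)

    def test_same_column_error(self):
        aln = random_alignment(5, 3)
        with pytest.raises(ValueError):
            mi_2d(aln, 1, 1)


class TestCondMiGivenOne:
    def test_constant_conditioner_returns_mi(self):
        aln = alignment_from_columns([0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 2, 2])
        assert cond_mi_given_one(aln, 0, 1, 2) == pytest.approx(mi_2d(aln, 0, 1))

    def test_conditioning_on_copy_of_member_zero(self):
        col = [0, 1, 0, 1, 2, 2]
        aln = alignment_from_columns(col, [0, 1, 1, 0, 2, 1], col)
        assert cond_mi_given_one(aln, 0, 1, 2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_stratified_oracle(self, seed):
        aln = random_alignment(30, 3, 4, seed=seed)
        assert cond_mi_given_one(aln, 0, 1, 2) == pytest.approx(
            oracle_cond_mi_one(aln, 0, 1, 2), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_interaction_information_identity(self, seed):
        # Eq: conditional MI == MI - three-way interaction information
        aln = random_alignment(25, 3, 5, seed=seed + 50)
        expected = oracle_mi(aln, 0, 1) - oracle_ii3(aln, 0, 1, 2)
        assert cond_mi_given_one(aln, 0, 1, 2) == pytest.approx(expected, abs=1e-10)

    def test_distinctness_error(self):
        aln = random_alignment(5, 3)
        with pytest.raises(ValueError):
            cond_mi_given_one(aln, 0, 1, 0)


class TestCondMiGivenTwo:
    def test_two_constant_conditioners_return_mi(self):
        aln = alignment_from_columns(
            [0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 2, 2], [3, 3, 3, 3]
        )
        assert cond_mi_given_two(aln, 0, 1, 2, 3) == pytest.approx(mi_2d(aln, 0, 1))

    def test_conditioning_on_copy_zero(self):
        col = [0, 1, 0, 1, 2, 2]
        aln = alignment_from_columns(col, [0, 1, 1, 0, 2, 1], col, [1, 0, 2, 1, 0, 2])
        assert cond_mi_given_two(aln, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_double_algebraic_identity(self, seed):
        aln = random_alignment(30, 4, 4, seed=seed)
        value = cond_mi_given_two(aln, 0, 1, 2, 3)
        assert value == pytest.approx(
            oracle_expansion_cond_mi_two(aln, 0, 1, 2, 3), abs=1e-9
        )
        assert value == pytest.approx(oracle_cond_mi_two(aln, 0, 1, 2, 3), abs=1e-9)

    def test_symmetric_in_pair_and_conditioners(self):
        aln = random_alignment(20, 4, 3, seed=4)
        assert cond_mi_given_two(aln, 0, 1, 2, 3) == pytest.approx(
            cond_mi_given_two(aln, 1, 0, 3, 2), abs=1e-12
        )

    def test_distinctness_error(self):
        aln = random_alignment(5, 4)
        with pytest.raises(ValueError):
            cond_mi_given_two(aln, 0, 1, 2, 2)


# ---------------------------------------------------------------------------
# map builders
# ---------------------------------------------------------------------------


class TestBuildMap2d:
    def test_copy_pair_dominates(self):
        col = [0, 1, 0, 1, 2, 2, 0, 1]
        aln = alignment_from_columns(col, col, [0, 0, 1, 1, 0, 1, 1, 0])
        cmap = build_map_2d(aln)
        assert cmap.scores[0, 1] > cmap.scores[0, 2]
        assert cmap.scores[0, 1] > cmap.scores[1, 2]

    def test_row_permutation_invariance(self, rng):
        aln = random_alignment(20, 4, 5, seed=3)
        perm = rng.permutation(20)
        shuffled = EncodedAlignment(aln.matrix[perm], [f"s{i}" for i in range(20)])
        np.testing.assert_allclose(
            build_map_2d(aln).scores, build_map_2d(shuffled).scores, equal_nan=True
        )

    def test_elementwise_oracle(self):
        aln = random_alignment(15, 5, 6, seed=11)
        cmap = build_map_2d(aln)
        for i, j in itertools.combinations(range(5), 2):
            assert cmap.scores[i, j] == pytest.approx(mi_2d(aln, i, j), abs=1e-12)

    def test_diagonal_sentinel(self):
        cmap = build_map_2d(random_alignment(10, 4, seed=0))
        assert np.isnan(np.diag(cmap.scores)).all()


class TestBuildMap3d:
    def test_three_columns_single_term(self):
        aln = random_alignment(20, 3, 4, seed=1)
        cmap = build_map_3d(aln)
        assert cmap.scores[0, 1] == pytest.approx(
            cond_mi_given_one(aln, 0, 1, 2), abs=1e-12
        )

    def test_triple_loop_oracle(self):
        aln = random_alignment(25, 6, 4, seed=17)
        np.testing.assert_allclose(
            build_map_3d(aln).scores, oracle_map_3d(aln), atol=1e-9, equal_nan=True
        )

    def test_planted_chain_scores_below_2d(self):
        # A and C independently copy B; noise columns added progressively.
        gen = np.random.default_rng(5)
        n = 2000
        b = gen.integers(0, 4, n)
        mask_a, mask_c = gen.random(n) < 0.9, gen.random(n) < 0.9
        a = np.where(mask_a, b, gen.integers(0, 4, n))
        c = np.where(mask_c, b, gen.integers(0, 4, n))
        diffs = []
        for n_noise in (1, 5):
            noise = gen.integers(0, 4, size=(n, n_noise))
            matrix = np.column_stack([a, b, c, noise])
            aln = EncodedAlignment(matrix, [f"s{i}" for i in range(n)])
            d2 = build_map_2d(aln).scores[0, 2]
            d3 = build_map_3d(aln).scores[0, 2]
            assert d3 < d2
            diffs.append(d2 - d3)
        assert diffs[1] < diffs[0]  # suppression dilutes with more columns

    def test_too_few_columns(self):
        with pytest.raises(ValueError):
            build_map_3d(random_alignment(10, 2, seed=0))


class TestBuildMap4d:
    def test_four_columns_two_ordered_choices(self):
        aln = random_alignment(20, 4, 3, seed=2)
        cmap = build_map_4d(aln)
        expected = 0.5 * (
            cond_mi_given_two(aln, 0, 1, 2, 3) + cond_mi_given_two(aln, 0, 1, 3, 2)
        )
        assert cmap.scores[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_all_identical_columns_oracle(self):
        col = [0, 1, 2, 0, 1, 2, 3, 3]
        aln = alignment_from_columns(col, col, col, col)
        cmap = build_map_4d(aln)
        np.testing.assert_allclose(
            cmap.scores, oracle_map_4d(aln), atol=1e-9, equal_nan=True
        )
        # conditioning on copies of the pair leaves nothing to transmit
        assert cmap.scores[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_quadruple_loop_oracle(self):
        aln = random_alignment(15, 6, 3, seed=23)
        np.testing.assert_allclose(
            build_map_4d(aln).scores, oracle_map_4d(aln), atol=1e-9, equal_nan=True
        )

    def test_include_pair_in_x4_rescales(self):
        aln = random_alignment(15, 6, 3, seed=23)
        base = build_map_4d(aln).scores
        alt = build_map_4d(aln, include_pair_in_x4=True).scores
        np.testing.assert_allclose(alt, base * 3 / 5, atol=1e-12, equal_nan=True)

    def test_too_few_columns(self):
        with pytest.raises(ValueError):
            build_map_4d(random_alignment(10, 3, seed=0))


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_entropy_monotone_in_column_set(seed):
    aln = random_alignment(12, 4, 5, seed=seed)
    sets = [[0], [0, 1], [0, 1, 2], [0, 1, 2, 3]]
    values = [joint_entropy(aln, s) for s in sets]
    for lo, hi in zip(values, values[1:]):
        assert hi >= lo - 1e-12


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_conditional_mi_equals_mi_minus_interaction_information(seed):
    aln = random_alignment(15, 3, 6, seed=seed)
    lhs = cond_mi_given_one(aln, 0, 1, 2)
    rhs = mi_2d(aln, 0, 1) - oracle_ii3(aln, 0, 1, 2)
    assert lhs == pytest.approx(rhs, abs=1e-9)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_cond_mi_nonnegative(seed):
    aln = random_alignment(20, 3, 4, seed=seed)
    assert cond_mi_given_one(aln, 0, 1, 2) >= -1e-12


def test_map_builders_row_permutation_invariant(rng):
    aln = random_alignment(18, 5, 4, seed=8)
    perm = rng.permutation(18)
    shuffled = EncodedAlignment(aln.matrix[perm], aln.sequence_ids)
    for builder in (build_map_2d, build_map_3d, build_map_4d):
        np.testing.assert_allclose(
            builder(aln).scores, builder(shuffled).scores, atol=1e-12, equal_nan=True
        )


def test_iid_maps_shrink_toward_zero_with_n():
    """On iid columns all map means are pure finite-sample bias.

    The bias decreases with N and every method converges toward 0.  (The
    conditional estimators carry a *larger* bias than plain MI at small N
    because stratification shrinks the per-table sample size; what matters is
    that all of it vanishes as N grows.)
    """
    from mdmi.core import mean_offdiag

    means = {}
    for n in (50, 500, 5000):
        aln = random_alignment(n, 6, 4, seed=99)
        means[n] = {
            "2d": mean_offdiag(build_map_2d(aln)),
            "3d": mean_offdiag(build_map_3d(aln)),
            "4d": mean_offdiag(build_map_4d(aln)),
        }
    for method in ("2d", "3d", "4d"):
        assert means[50][method] > means[500][method] > means[5000][method]
        assert means[5000][method] < 0.05


def test_covariation_map_rejects_asymmetry():
    bad = np.array([[np.nan, 1.0], [2.0, np.nan]])
    with pytest.raises(ValueError):
        CovariationMap(bad)
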