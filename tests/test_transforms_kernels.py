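"""CSS/clr transforms and G/B kernel construction against manual oracles."""

from fractions import Fraction

import numpy as np
import pytest

from microbiability import (
    AbundanceTable,
    GenotypeMatrix,
    clr_transform,
    compute_B,
    compute_G,
    css_normalize,
)
from microbiability.kernels import TransformedAbundances
from microbiability.synthetic import SimulationConfig, simulate_genotypes


def _abund(counts):
    c = np.asarray(counts)
    return AbundanceTable(
        [f"s{k}" for k in range(c.shape[0])],
        [f"f{k}" for k in range(c.shape[1])],
        c,
    )


# ---------------------------------------------------------------------------
# CSS
# ---------------------------------------------------------------------------


def test_css_scale_invariance():
    a = _abund([[10, 0, 5, 25, 40, 20], [30, 0, 15, 75, 120, 60]])
    t = css_normalize(a)
    np.testing.assert_allclose(t.values[0], t.values[1])


def test_css_single_feature_degenerate():
    t = css_normalize(_abund([[7], [123]]), scale=1000)
    np.testing.assert_allclose(t.values, 1000.0)


def test_css_matches_frozen_manual_table():
    # hand-worked once: median of positive counts per sample, cumulative sum
    # of counts <= that median, entries = count / s * 1000
    counts = [
        [10, 0, 5, 25, 40, 20],   # median of positives 20 -> s = 35
        [1, 2, 3, 4, 0, 90],      # median 3            -> s = 6
        [7, 7, 7, 7, 7, 7],       # median 7            -> s = 42
        [0, 0, 12, 8, 30, 50],    # median 21           -> s = 20
    ]
    s_manual = [35, 6, 42, 20]
    expected = np.array(
        [
            [float(Fraction(c, s) * 1000) for c in row]
            for row, s in zip(counts, s_manual)
        ]
    )
    t = css_normalize(_abund(counts), quantile=0.5, scale=1000)
    np.testing.assert_allclose(t.values, expected, rtol=1e-12)


def test_css_all_zero_sample_errors():
    with pytest.raises(ValueError, match="all-zero"):
        css_normalize(_abund([[1, 2], [0, 0]]))


# ---------------------------------------------------------------------------
# clr
# ---------------------------------------------------------------------------


def test_clr_uniform_row_is_zero_and_rows_center():
    t = clr_transform(_abund([[4, 4, 4], [1, 9, 99]]))
    np.testing.assert_allclose(t.values[0], 0.0, atol=1e-12)
    np.testing.assert_allclose(t.values.sum(axis=1), 0.0, atol=1e-8)


def test_clr_compositional_scale_invariance():
    # multiplying a row by a constant leaves clr of the (pseudocounted)
    # composition unchanged when the pseudocount scales along
    a = _abund([[2, 8, 40]])
    b = _abund([[6, 24, 120]])
    ta = clr_transform(a, pseudocount=1)
    tb = clr_transform(b, pseudocount=3)
    np.testing.assert_allclose(ta.values, tb.values, atol=1e-12)


def test_clr_arithmetic_oracle():
    t = clr_transform(_abund([[1, 9, 99]]), pseudocount=1)
    logs = np.log([2.0, 10.0, 100.0])
    np.testing.assert_allclose(t.values[0], logs - logs.mean(), atol=1e-12)


# ---------------------------------------------------------------------------
# G kernel
# ---------------------------------------------------------------------------


def _geno(d):
    d = np.asarray(d, dtype=float)
    return GenotypeMatrix(
        [f"i{k}" for k in range(d.shape[0])],
        [f"s{k}" for k in range(d.shape[1])],
        d,
    )


def test_G_matches_hand_worked_fixture():
    # worked by hand in exact fractions: after re-polarizing column 4,
    # p = (1/2, 1/3, 1/2, 1/3), denom = 17/9, G = 9/17 * SS'
    g = compute_G(_geno([[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 1]]))
    expected = np.array(
        [
            [20 / 17, -10 / 17, -10 / 17],
            [-10 / 17, 14 / 17, -4 / 17],
            [-10 / 17, -4 / 17, 14 / 17],
        ]
    )
    np.testing.assert_allclose(g.values, expected, atol=1e-12)
    assert g.denom == pytest.approx(17 / 9, abs=1e-15)


def test_G_duplicate_individuals_share_rows():
    g = compute_G(_geno([[0, 1, 2], [0, 1, 2], [2, 1, 0]]))
    np.testing.assert_allclose(g.values[0], g.values[1], atol=1e-12)
    assert g.values[0, 1] == pytest.approx(g.values[0, 0])


def test_G_allele_flip_invariance(rng):
    d = rng.binomial(2, rng.uniform(0.1, 0.5, 40), size=(30, 40)).astype(float)
    g1 = compute_G(_geno(d))
    g2 = compute_G(_geno(2.0 - d))
    np.testing.assert_allclose(g1.values, g2.values, atol=1e-10)


def test_G_mean_diagonal_near_one_under_hwe():
    cfg = SimulationConfig(n_individuals=500, n_snps=3_000, seed=5)
    g = compute_G(simulate_genotypes(cfg))
    assert 0.95 <= np.diag(g.values).mean() <= 1.05


def test_G_permutation_equivariance(rng):
    d = rng.binomial(2, rng.uniform(0.1, 0.5, 50), size=(25, 50)).astype(float)
    g = compute_G(_geno(d))
    perm = rng.permutation(25)
    gp = compute_G(
        GenotypeMatrix(
            [f"i{k}" for k in perm], [f"s{k}" for k in range(50)], d[perm]
        )
    )
    np.testing.assert_allclose(gp.values, g.values[np.ix_(perm, perm)], atol=1e-10)


def test_G_monomorphic_column_excluded():
    with pytest.warns(UserWarning, match="monomorphic"):
        g = compute_G(_geno([[0, 1], [0, 1], [0, 2]]))
    assert g.dropped == ["s0"]


def test_G_missing_dosages_mean_imputed(rng):
    d = rng.binomial(2, 0.3, size=(20, 10)).astype(float)
    gd = compute_G(_geno(d))
    dm = d.copy()
    dm[3, 2] = np.nan
    # imputing by the column mean of the remaining calls reproduces compute_G
    dm_imp = dm.copy()
    dm_imp[3, 2] = np.nanmean(dm[:, 2])
    gm = compute_G(_geno(dm))
    S = dm_imp - np.nanmean(dm, axis=0)
    p = np.nanmean(dm, axis=0) / 2
    p = np.minimum(p, 1 - p)
    denom = 2 * np.sum(p * (1 - p))
    np.testing.assert_allclose(gm.values, S @ S.T / denom, atol=1e-10)
    assert not np.allclose(gm.values, gd.values)


# ---------------------------------------------------------------------------
# B kernel
# ---------------------------------------------------------------------------


def _css_like(values):
    v = np.asarray(values, dtype=float)
    return TransformedAbundances(
        [f"s{k}" for k in range(v.shape[0])],
        [f"f{k}" for k in range(v.shape[1])],
        v,
        transform="css",
    )


def test_B_matches_hand_worked_fixture():
    # column means all 3; centred columns scaled by sample SD; B = MM'/5
    t = _css_like(
        [
            [1, 2, 3, 4, 5],
            [5, 4, 3, 2, 1],
            [1, 3, 5, 3, 1],
            [5, 3, 1, 3, 5],
        ]
    )
    expected = np.array(
        [
            [0.9, -0.9, 0.0, 0.0],
            [-0.9, 0.9, 0.0, 0.0],
            [0.0, 0.0, 0.6, -0.6],
            [0.0, 0.0, -0.6, 0.6],
        ]
    )
    b = compute_B(t)
    np.testing.assert_allclose(b.values, expected, atol=1e-12)
    assert b.denom == 5


def test_B_entrywise_matrix_product_oracle(rng):
    v = rng.gamma(2.0, size=(4, 5)) * 100
    b = compute_B(_css_like(v))
    # independent entry-wise computation with explicit loops
    M = np.empty_like(v)
    for j in range(5):
        col = v[:, j]
        M[:, j] = (col - col.mean()) / col.std(ddof=1)
    expect = np.empty((4, 4))
    for i in range(4):
        for k in range(4):
            expect[i, k] = sum(M[i, j] * M[k, j] for j in range(5)) / 5
    np.testing.assert_allclose(b.values, expect, atol=1e-12)


def test_B_duplicate_profiles_and_diag(rng):
    v = rng.gamma(2.0, size=(10, 30)) * 50
    v[1] = v[0]
    b = compute_B(_css_like(v))
    np.testing.assert_allclose(b.values[0], b.values[1], atol=1e-10)
    assert 0.9 <= np.diag(b.values).mean() <= 1.1


def test_B_requires_css_and_drops_constant_columns(rng):
    with pytest.raises(ValueError, match="CSS"):
        compute_B(
            TransformedAbundances(["a"], ["f0"], np.ones((1, 1)), transform="clr")
        )
    v = rng.gamma(2.0, size=(8, 4)) * 50
    v[:, 2] = 7.0
    with pytest.warns(UserWarning, match="zero-variance"):
        b = compute_B(_css_like(v))
    assert b.dropped == ["f2"] and b.denom == 3


def test_B_asv_vs_genus_level_differ(small_cohort):
    from microbiability import aggregate_to_genus, css_normalize

    asv_b = compute_B(css_normalize(small_cohort.microbiome))
    gen_b = compute_B(css_normalize(aggregate_to_genus(small_cohort.microbiome)))
    assert not np.allclose(asv_b.values, gen_b.values, atol=1e-3)


def test_kernels_are_psd(small_cohort):
    from microbiability import css_normalize

    G = compute_G(small_cohort.genotypes)
    B = compute_B(css_normalize(small_cohort.microbiome))
    G.validate()
    B.validate()


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=12),
    st.integers(min_value=2, max_value=9),
)
def test_clr_row_centering_and_scale_invariance_property(row, mult):
    a1 = _abund([row])
    a2 = _abund([[mult * c for c in row]])
    t1 = clr_transform(a1, pseudocount=1.0)
    t2 = clr_transform(a2, pseudocount=float(mult))
    assert abs(t1.values.sum()) < 1e-8
    np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=5_000), min_size=2, max_size=10))
def test_css_proportional_rows_identical_property(row):
    a = _abund([row, [3 * c for c in row]])
    t = css_normalize(a)
    np.testing.assert_allclose(t.values[0], t.values[1], rtol=1e-12)
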