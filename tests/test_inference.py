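import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import allelic as al
from allelic.inference import TestConfig
from conftest import make_matrix


def brute_signed_rank(x1, x2):
    """Independent midrank implementation: rank_i = 1 + #smaller + #ties/2."""
    d = [b - a for a, b in zip(x1, x2)]
    nz = [v for v in d if v != 0]
    total = 0.0
    for v in nz:
        smaller = sum(1 for w in nz if abs(w) < abs(v))
        ties = sum(1 for w in nz if abs(w) == abs(v)) - 1
        rank = 1 + smaller + ties / 2
        total += np.sign(v) * rank
    return total


# ---------------------------------------------------------------------------
# signed-rank statistic


def test_signed_rank_identity_and_hand_example():
    assert al.signed_rank_stat([5, 1, 9], [5, 1, 9]) == 0.0
    # d = (5, 2, 1, 6) -> ranks (3, 2, 1, 4), all positive -> W = 10
    assert al.signed_rank_stat([10, 12, 8, 20], [15, 14, 9, 26]) == 10.0


def test_signed_rank_exact_sign_flip_tail():
    """Two-sided exact p over all 2^4 sign flips of d=(5,2,1,6) is 2/16."""
    x1, x2 = [10, 12, 8, 20], [15, 14, 9, 26]
    w_obs = al.signed_rank_stat(x1, x2)
    d = np.array(x2) - np.array(x1)
    null = [
        brute_signed_rank(np.zeros(4), eps * d)
        for eps in map(np.array, itertools.product([-1, 1], repeat=4))
    ]
    p = np.mean([abs(w) >= abs(w_obs) for w in null])
    assert p == pytest.approx(0.125)


@given(
    st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)),
        min_size=2,
        max_size=10,
    )
)
def test_signed_rank_matches_enumeration_oracle(pairs):
    x1 = [a for a, _ in pairs]
    x2 = [b for _, b in pairs]
    assert al.signed_rank_stat(x1, x2) == pytest.approx(brute_signed_rank(x1, x2))


def test_signed_rank_agrees_with_classical_wilcoxon(rng):
    """Without zeros/ties, W = 2 W+ - n(n+1)/2 with W+ from scipy."""
    from scipy.stats import wilcoxon

    for n in (4, 6, 10):
        for _ in range(10):
            d = rng.normal(size=n)
            while (d == 0).any() or len(set(np.abs(d))) < n:
                d = rng.normal(size=n)
            w = al.signed_rank_stat(np.zeros(n), d)
            wplus = wilcoxon(d, alternative="greater").statistic
            assert w == pytest.approx(2 * wplus - n * (n + 1) / 2)


def test_signed_rank_input_validation():
    with pytest.raises(ValueError):
        al.signed_rank_stat([1.0], [2.0])


# ---------------------------------------------------------------------------
# global AI test


def test_global_maximal_concordance_stat():
    """a2 = 2*a1 in all 10 samples and bootstraps: W = 10*11/2 = 55 and the
    p-value is the smallest attainable tail."""
    rng = np.random.default_rng(1)
    a1 = rng.integers(20, 200, size=(1, 10)).astype(float)
    counts = np.stack([a1, 2 * a1], axis=-1)
    m = make_matrix(counts, np.repeat(counts[None], 3, axis=0))
    res = al.global_ai_test(m, TestConfig(seed=0))
    assert res.stat[0] == pytest.approx(55.0)
    null = 55.0  # max |stat|; minimal attainable p given the pooled null
    assert res.pvalues[0] == min(res.pvalues)


def test_global_allele_swap_antisymmetry(small_sim):
    """Swapping allele labels negates statistics, p-values unchanged."""
    m, _ = al.prepare(small_sim.matrix, small_sim.tss_map)
    cfg = TestConfig(seed=42)
    res = al.global_ai_test(m, cfg)
    res_sw = al.global_ai_test(m.swap_alleles(), cfg)
    np.testing.assert_allclose(res_sw.stat, -res.stat, atol=1e-12)
    np.testing.assert_allclose(res_sw.log2fc, -res.log2fc, atol=1e-12)
    np.testing.assert_array_equal(res_sw.pvalues, res.pvalues)
    np.testing.assert_array_equal(res_sw.qvalues, res.qvalues)


def test_global_null_calibration(null_sim):
    """Under a complete null, ~5% of p-values fall below 0.05."""
    m, _ = al.prepare(null_sim.matrix)
    res = al.global_ai_test(m, TestConfig(seed=5))
    frac = (res.pvalues < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(res.pvalues))
    assert abs(frac - 0.05) <= 3 * se


def test_results_bit_reproducible(small_sim):
    m, _ = al.prepare(small_sim.matrix, small_sim.gene_map)
    r1 = al.global_ai_test(m, TestConfig(seed=9))
    r2 = al.global_ai_test(m, TestConfig(seed=9))
    assert r1.table.equals(r2.table)
    r3 = al.global_ai_test(m, TestConfig(seed=10))
    assert not np.array_equal(r1.pvalues, r3.pvalues)


# ---------------------------------------------------------------------------
# dynamic AI test


def test_dynamic_null_and_perfect_correlation():
    S = 6
    cov = np.arange(1.0, S + 1)
    # x1 == x2 -> LFC == 0 -> stat 0, p ~ 1
    base = np.full((4, S), 50.0)
    m0 = make_matrix(np.stack([base, base], axis=-1))
    res0 = al.dynamic_ai_test(m0, cov, TestConfig(seed=0))
    assert np.allclose(res0.stat, 0.0)
    assert (res0.pvalues > 0.9).all()

    # LFC exactly linear in covariate: x1 = 0, x2 = 5*(2^(0.2 s) - 1), c=5
    c = 5.0
    x2 = c * (2 ** (0.2 * cov) - 1)
    counts = np.stack([np.zeros((1, S)), x2[None, :]], axis=-1)
    m1 = make_matrix(counts)
    res1 = al.dynamic_ai_test(m1, cov, TestConfig(seed=0))
    assert res1.stat[0] == pytest.approx(1.0)


def test_dynamic_single_bootstrap_matches_direct_formula(rng):
    """B=1 Pearson statistic equals corr(log2((a2+5)/(a1+5)), covariate)."""
    S, F = 8, 5
    counts = rng.poisson(80, size=(F, S, 2)).astype(float)
    cov = rng.normal(size=S)
    m = make_matrix(counts)
    res = al.dynamic_ai_test(m, cov, TestConfig(seed=0))
    lfc = np.log2((counts[..., 1] + 5) / (counts[..., 0] + 5))
    expected = [np.corrcoef(lfc[i], cov)[0, 1] for i in range(F)]
    np.testing.assert_allclose(res.stat, expected, atol=1e-12)


def test_dynamic_spearman_rank_based(rng):
    from scipy.stats import spearmanr

    S = 9
    counts = rng.poisson(60, size=(3, S, 2)).astype(float)
    cov = rng.normal(size=S)
    res = al.dynamic_ai_test(
        make_matrix(counts), cov, TestConfig(seed=0, correlation="spearman")
    )
    lfc = np.log2((counts[..., 1] + 5) / (counts[..., 0] + 5))
    expected = [spearmanr(lfc[i], cov).statistic for i in range(3)]
    np.testing.assert_allclose(res.stat, expected, atol=1e-12)


def test_dynamic_validation():
    m = make_matrix(np.ones((2, 4, 2)))
    with pytest.raises(ValueError, match="constant"):
        al.dynamic_ai_test(m, np.ones(4), TestConfig())
    with pytest.raises(ValueError, match="distinct"):
        al.dynamic_ai_test(m, np.array([1.0, 1.0, 2.0, 2.0]), TestConfig())


# ---------------------------------------------------------------------------
# differential AI test


def test_differential_extremes_and_label_symmetry(rng):
    S = 8
    group = np.array(["A"] * 4 + ["B"] * 4)
    # group A LFC ~ +1 (a2 = 2*a1), group B LFC ~ -1 (a2 = a1/2)
    a1 = np.full((3, S), 400.0)
    a2 = np.concatenate([2 * a1[:, :4], a1[:, 4:] / 2], axis=1)
    m = make_matrix(np.stack([a1, a2], axis=-1))
    res = al.differential_ai_test(m, group, TestConfig(seed=1))
    # maximal centered rank sum: group B holds ranks 1..4 -> 10 - 18 = -8
    assert np.allclose(res.stat, -8.0)

    res_flip = al.differential_ai_test(m, group[::-1].copy(), TestConfig(seed=1))
    np.testing.assert_allclose(res_flip.stat, 8.0)

    # identical LFC distributions: a2 = 2*a1 everywhere -> centered stat 0
    m0 = make_matrix(np.stack([a1, 2 * a1], axis=-1))
    res0 = al.differential_ai_test(m0, group, TestConfig(seed=1))
    assert np.allclose(res0.stat, 0.0)
    assert (res0.pvalues > 0.9).all()


def test_differential_null_uniform(rng):
    """iid LFCs in both groups give roughly uniform p-values."""
    counts = rng.poisson(100, size=(400, 8, 2)).astype(float)
    m = make_matrix(counts)
    group = np.array(["A"] * 4 + ["B"] * 4)
    res = al.differential_ai_test(m, group, TestConfig(seed=3))
    frac = (res.pvalues < 0.1).mean()
    assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 400) + 0.02


def test_differential_validation():
    m = make_matrix(np.ones((2, 4, 2)))
    with pytest.raises(ValueError):
        al.differential_ai_test(m, np.array(["A", "A", "A", "B"]), TestConfig())


# ---------------------------------------------------------------------------
# q-values


def test_pooled_pvalues_and_qvalue_examples(rng):
    # all observed stats 0 under a symmetric null -> p near 1, q near pi0
    null = rng.normal(size=5000)
    obs = np.zeros(100)
    p, q = al.qvalue_from_null(obs, null)
    assert (p > 0.99).all()
    assert np.allclose(q, q[0])  # all equal

    with pytest.raises(ValueError):
        al.pooled_pvalues(obs, np.array([]))


def test_pi0_estimate_near_one_for_uniform(rng):
    p = rng.uniform(size=20000)
    assert al.estimate_pi0(p) == pytest.approx(1.0, abs=0.06)


def test_qvalues_equal_scaled_bh(rng):
    """q = pi0 * BH(p) on a fixed p-vector (statsmodels as oracle)."""
    from statsmodels.stats.multitest import multipletests

    null = np.sort(rng.normal(size=2000))
    obs = rng.normal(size=300) * 2
    p, q = al.qvalue_from_null(obs, null)
    pi0 = al.estimate_pi0(p)
    bh = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, np.minimum(pi0 * bh, 1.0), atol=1e-12)
    # monotone nondecreasing in p
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_config_validation():
    with pytest.raises(ValueError):
        TestConfig(n_perm=0)
    with pytest.raises(ValueError):
        TestConfig(pseudocount=0)
    with pytest.raises(ValueError):
        TestConfig(correlation="kendall")
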