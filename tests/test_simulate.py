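import numpy as np
import pandas as pd
import pytest

import allelic as al


def design_small(**kw):
    base = dict(n_genes=150, n_concordant=25, n_discordant=25,
                library_size=300_000.0, n_bootstraps=5)
    base.update(kw)
    return al.SimDesign.desk(**base)


# ---------------------------------------------------------------------------
# gene models


def test_ai_genes_satisfy_eligibility_criteria(rng):
    models = al.build_gene_models(design_small(), rng)
    ai = models[models["ai_class"] != "balanced"]
    for gene, sub in ai.groupby("gene_id"):
        k = len(sub)
        assert 3 <= k <= 6  # isoform count
        tss_counts = sub["tss"].value_counts()
        assert len(tss_counts) >= 2  # >= 2 distinct TSS
        assert (tss_counts >= 2).any()  # >= 2 isoforms share a TSS
    # isoform-count histogram of AI genes supported on {3,...,6}
    sizes = ai.groupby("gene_id").size()
    assert set(sizes.unique()) <= {3, 4, 5, 6}


def test_background_gene_isoform_range(rng):
    models = al.build_gene_models(design_small(), rng)
    sizes = models.groupby("gene_id").size()
    assert sizes.min() >= 1 and sizes.max() <= 6


def test_models_deterministic_under_seed():
    m1 = al.build_gene_models(design_small(), np.random.default_rng(7))
    m2 = al.build_gene_models(design_small(), np.random.default_rng(7))
    pd.testing.assert_frame_equal(m1, m2)


def test_infeasible_design_rejected():
    with pytest.raises(ValueError):
        al.SimDesign(n_genes=10, n_concordant=20, n_discordant=0)


# ---------------------------------------------------------------------------
# abundances


def test_concordant_folds_are_25_percent(small_sim):
    conc = small_sim.truth[small_sim.truth["status"] == "concordant"]
    assert set(np.round(conc["fold"], 10)) <= {0.75, 1.25}
    # per gene, all isoforms share one direction
    for _, sub in conc.groupby("gene_id"):
        assert sub["fold"].nunique() == 1


def test_discordant_fold_formula_and_balance(small_sim):
    """Selected TSS group of size n gets fold 1 + 1/(2n); the rest share a
    common down-factor; paternal gene total equals maternal exactly."""
    disc = small_sim.truth[small_sim.truth["status"] == "discordant"]
    assert len(disc) > 0
    for gene, sub in disc.groupby("gene_id"):
        up = sub[sub["direction"] == 1]
        down = sub[sub["direction"] == -1]
        n = len(up)
        assert n >= 1 and len(down) >= 1
        assert up["tss_group"].nunique() == 1
        np.testing.assert_allclose(up["fold"], 1 + 1 / (2 * n), atol=1e-12)
        assert down["fold"].nunique() == 1  # equal-rate down-scaling
        assert (down["fold"] < 1).all()
        np.testing.assert_allclose(
            sub["paternal"].sum(), sub["maternal"].sum(), rtol=0, atol=1e-12
        )


def test_single_isoform_selected_tss_fold():
    """n = 1 isoform at the selected TSS gives up-factor 1.5."""
    models = pd.DataFrame(
        {
            "tx_id": ["g.t1", "g.t2", "g.t3", "g.t4"],
            "gene_id": "g",
            "chrom": "sim1",
            "strand": "+",
            "tss": [100, 400, 400, 400],
            "length": 1000,
            "ai_class": "discordant",
        }
    )
    folds = set()
    for seed in range(6):
        truth = al.assign_abundances(models, design_small(), np.random.default_rng(seed))
        n_up = (truth["direction"] == 1).sum()
        up_fold = truth.loc[truth["direction"] == 1, "fold"].iloc[0]
        folds.add((n_up, round(up_fold, 10)))
    assert (1, 1.5) in folds or (3, round(1 + 1 / 6, 10)) in folds
    for n_up, fold in folds:
        assert fold == round(1 + 1 / (2 * n_up), 10)


def test_balanced_transcripts_fold_one(small_sim):
    bal = small_sim.truth[small_sim.truth["status"] == "balanced"]
    np.testing.assert_array_equal(bal["fold"].to_numpy(), 1.0)


# ---------------------------------------------------------------------------
# expected counts and NB sampling


def test_expected_counts_normalization_and_length_ratio():
    truth = pd.DataFrame(
        {
            "maternal": [1.0, 1.0],
            "paternal": [1.0, 1.0],
            "length": [100, 300],
        }
    )
    design = design_small(library_size=8000.0)
    mu = al.expected_counts(truth, design)
    assert mu.sum() == pytest.approx(8000.0)
    assert mu[1, 0] / mu[0, 0] == pytest.approx(3.0)  # 1:3 by length
    # doubling abundance doubles mu before renormalization
    truth2 = truth.assign(maternal=[2.0, 1.0])
    mu2 = al.expected_counts(truth2, design)
    assert mu2[0, 0] / mu2[1, 0] == pytest.approx(2 * mu[0, 0] / mu[1, 0])

    with pytest.raises(ValueError):
        al.expected_counts(truth.assign(maternal=0.0, paternal=0.0), design)


def test_nb_sampling_moments(rng):
    mu = np.full((2000, 2), 1000.0)
    counts = al.sample_counts(mu, nb_size=100.0, n_samples=1, rng=rng)
    var = counts.var()
    assert var == pytest.approx(1000 + 1000**2 / 100, rel=0.1)  # 11,000
    # near-Poisson limit for huge size
    c2 = al.sample_counts(mu, nb_size=1e9, n_samples=1, rng=rng)
    assert c2.var() == pytest.approx(1000, rel=0.1)
    # mu = 0 -> always 0
    z = al.sample_counts(np.zeros((5, 2)), 100.0, 3, rng)
    assert (z == 0).all()


# ---------------------------------------------------------------------------
# bootstrap emulation


def test_bootstraps_degenerate_rho_zero(rng):
    counts = rng.poisson(50, size=(10, 3, 2)).astype(float)
    point, boots = al.emulate_bootstraps(counts, rho=0.0, B=4, rng=rng)
    np.testing.assert_array_equal(point, counts)
    for b in range(4):
        np.testing.assert_array_equal(boots[b], counts)


def test_bootstraps_rho_one_equal_split(rng):
    counts = rng.poisson(50, size=(10, 3, 2)).astype(float)
    point, boots = al.emulate_bootstraps(counts, rho=1.0, B=50, rng=rng)
    totals = counts.sum(axis=2)
    np.testing.assert_allclose(point[..., 0], totals / 2)
    np.testing.assert_allclose(point[..., 1], totals / 2)
    # replicate splits centered at 50/50
    prop = boots[..., 0].mean(axis=0) / np.maximum(totals, 1)
    assert abs(prop.mean() - 0.5) < 0.02


def test_bootstraps_preserve_totals(rng):
    counts = rng.poisson(80, size=(20, 4, 2)).astype(float)
    for resample in (False, True):
        point, boots = al.emulate_bootstraps(
            counts, rho=0.3, B=6, rng=rng, resample_totals=resample
        )
        np.testing.assert_allclose(point.sum(axis=2), counts.sum(axis=2), atol=1e-9)
        # per-sample totals equal observed in every replicate
        np.testing.assert_allclose(
            boots.sum(axis=(1, 3)),
            np.broadcast_to(counts.sum(axis=(0, 2)), (6, 4)),
            atol=1e-9,
        )


def test_half_split_mode_expectation_oracle(rng):
    """Blind 50/50 mode: replicate-mean allelic proportion converges to
    (1-rho)p + rho/2."""
    rho, p = 0.4, 0.8
    t = 4000
    counts = np.tile(np.array([t * p, t * (1 - p)]), (200, 1, 1)).reshape(200, 1, 2)
    point, boots = al.emulate_bootstraps(
        counts, rho=rho, B=30, rng=rng, em_apportion=False
    )
    prop = boots[..., 0].mean() / t
    assert prop == pytest.approx((1 - rho) * p + rho / 2, abs=0.01)


def test_em_mode_point_estimates_unbiased(rng):
    """EM apportionment: point estimates are unbiased for the true counts."""
    rho, p = 0.4, 0.8
    t = 4000
    counts = np.tile(np.array([t * p, t * (1 - p)]), (400, 1, 1)).reshape(400, 1, 2)
    point, _ = al.emulate_bootstraps(counts, rho=rho, B=1, rng=rng)
    assert point[..., 0].mean() / t == pytest.approx(p, abs=0.005)


# ---------------------------------------------------------------------------
# full dataset


def test_dataset_deterministic_and_consistent(small_sim):
    again = al.simulate_dataset(small_sim.design, seed=11)
    np.testing.assert_array_equal(again.matrix.counts, small_sim.matrix.counts)
    np.testing.assert_array_equal(again.matrix.bootstraps, small_sim.matrix.bootstraps)
    pd.testing.assert_frame_equal(again.truth, small_sim.truth)
    assert len(small_sim.truth) == small_sim.matrix.n_features
    # truth table covers exactly the simulated transcripts
    assert small_sim.truth["tx_id"].tolist() == small_sim.matrix.feature_ids


def test_full_pipeline_smoke(small_sim):
    """simulate -> aggregate -> filter -> all three tests run end to end."""
    m, _ = al.prepare(small_sim.matrix, small_sim.tss_map)
    model = al.AllelicImbalance(m, small_sim.metadata)
    cfg = al.TestConfig(n_perm=20, seed=0)
    res = model.fit_global(cfg)
    assert set(res.table.columns) >= {"feature_id", "stat", "log2fc", "pvalue", "qvalue"}
    assert ((res.pvalues > 0) & (res.pvalues <= 1)).all()
    model.fit_dynamic(config=cfg)
    group = np.array(["A", "B"] * (small_sim.matrix.n_samples // 2))
    model.fit_differential(group, cfg)
    assert "significant at" in res.summary()
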