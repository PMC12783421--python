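"""Synthetic-data generators: determinism, moments, structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brownfish.simulate import (EvidenceProfile, JSDMTruth, SimConfig, ZINBTruth,
                                gen_browning_metrics, gen_community_occurrence,
                                gen_counts_zinb, gen_evidence_table,
                                gen_phylogeny_and_traits, gen_spatial_lakes,
                                simulate_all)


def test_config_validation():
    with pytest.raises(ValueError, match="missing rates"):
        SimConfig(missing_rates=(0.6, 0.1, 0.1))
    with pytest.raises(ValueError, match="share sign"):
        SimConfig(loading_vector=(1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="degenerate"):
        SimConfig(spatial_domain=(0, 0, 0, 1))
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(evidence_profile=EvidenceProfile(
            category_probs={"foraging": 0.9, "growth": 0.9,
                            "survival": 0.1, "other": 0.1}))


def test_generators_deterministic():
    cfg = SimConfig(n_lakes=60, n_species=5, seed=8)
    a1, _ = gen_browning_metrics(cfg)
    a2, _ = gen_browning_metrics(cfg)
    pd.testing.assert_frame_equal(a1, a2)
    s1 = gen_spatial_lakes(cfg)
    pd.testing.assert_frame_equal(s1, gen_spatial_lakes(cfg))
    e1 = gen_evidence_table(cfg)
    assert e1.to_csv(index=False) == gen_evidence_table(cfg).to_csv(index=False)


# -- browning metrics ------------------------------------------------------

def test_noiseless_rank_one_gives_full_pca_variance():
    cfg = SimConfig(n_lakes=200, seed=1, noise_sd=(0.0, 0.0, 0.0),
                    missing_rates=(0.0, 0.0, 0.0))
    df, truth = gen_browning_metrics(cfg)
    T = truth["transformed"]
    # transformed metrics are exact linear functions of the latent factor
    for k in range(3):
        r = np.corrcoef(T[:, k], truth["latent"])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12
    Z = (T - T.mean(0)) / T.std(0)
    w = np.linalg.eigvalsh(np.cov(Z.T))
    assert w.max() / w.sum() == pytest.approx(1.0, abs=1e-10)


def test_missing_counts_at_survey_rates():
    cfg = SimConfig(n_lakes=1827, seed=4)
    df, _ = gen_browning_metrics(cfg)
    n_missing = df[["doc", "secchi", "colour"]].isna().sum().to_numpy()
    for count, rate in zip(n_missing, (0.102, 0.108, 0.013)):
        se = np.sqrt(1827 * rate * (1 - rate))
        assert abs(count - 1827 * rate) < 3 * se
    # raw metrics positive wherever observed
    assert (df[["doc", "secchi", "colour"]].min() > 0).all()
    # at least one metric observed per lake
    assert df[["doc", "secchi", "colour"]].notna().any(axis=1).all()


def test_dominant_factor_variance_share():
    cfg = SimConfig(n_lakes=800, seed=12, missing_rates=(0.0, 0.0, 0.0))
    _, truth = gen_browning_metrics(cfg)
    Z = truth["transformed"]
    Z = (Z - Z.mean(0)) / Z.std(0)
    # independent eigen-decomposition oracle on the complete matrix
    w = np.linalg.eigvalsh(np.cov(Z.T))
    share = w.max() / w.sum()
    assert abs(share - 0.86) < 0.05


# -- spatial lakes ---------------------------------------------------------

def test_zero_amplitude_trend():
    cfg = SimConfig(n_lakes=50, seed=2, trend_amplitude=0.0)
    lakes = gen_spatial_lakes(cfg)
    np.testing.assert_allclose(lakes["trend_value"], 0.0)


def test_bowl_minimum_at_domain_centre():
    cfg = SimConfig(n_lakes=4000, seed=3, trend_amplitude=1.0,
                    spatial_domain=(0.0, 10.0, 20.0, 40.0))
    lakes = gen_spatial_lakes(cfg)
    # grid-search oracle: the lake nearest the centre has ~minimal trend
    c = np.array([5.0, 30.0])
    dist = np.hypot(lakes.easting - c[0], lakes.northing - c[1])
    near = lakes.loc[dist.nsmallest(10).index, "trend_value"]
    assert near.mean() < lakes["trend_value"].quantile(0.02)
    assert lakes["trend_value"].idxmin() in dist.nsmallest(100).index


# -- ZINB counts -----------------------------------------------------------

def _tiny_cfg(**kw):
    base = dict(n_lakes=40, n_species=2, seed=6, trend_amplitude=0.0)
    base.update(kw)
    return SimConfig(**base)


def test_pi_one_gives_all_zero():
    cfg = _tiny_cfg(zinb_truth=ZINBTruth(
        beta0=(1.0, 1.0), beta1=(0.5, -0.5), beta2=(0.0, 0.0),
        structural_zero_logit=(40.0, 40.0), sigma_delta=0.0))
    lakes = gen_spatial_lakes(cfg)
    data, _ = gen_counts_zinb(cfg, lakes, np.zeros(40))
    assert np.all(data.counts == 0)


def test_poisson_limit_moment_check():
    truth = ZINBTruth(beta0=(1.0, 0.5), beta1=(0.4, -0.4), beta2=(0.0, 0.0),
                      structural_zero_logit=(-40.0, -40.0), sigma_gamma=0.0,
                      sigma_lambda=0.0, sigma_delta=0.0, phi=1e6)
    means = np.zeros((30, 2))
    xbar = 0.0
    for rep in range(30):
        cfg = _tiny_cfg(n_lakes=200, seed=700 + rep, zinb_truth=truth)
        lakes = gen_spatial_lakes(cfg)
        x = np.zeros(200)
        data, _ = gen_counts_zinb(cfg, lakes, x)
        means[rep] = data.counts.mean(axis=1)
    expected = np.exp([1.0, 0.5])
    se = means.std(axis=0) / np.sqrt(30)
    assert np.all(np.abs(means.mean(axis=0) - expected) < 3 * se)


def test_single_cell_zinb_moments():
    """Empirical mean and variance over many replicate draws of one cell
    match the closed-form ZINB moments (1-pi)mu and
    (1-pi)mu(1 + mu/phi + pi*mu)."""
    truth = ZINBTruth(beta0=(1.2, 0.8), beta1=(0.0, 0.0), beta2=(0.0, 0.0),
                      structural_zero_logit=(-0.847, -0.847),  # pi = 0.3
                      sigma_gamma=0.0, sigma_lambda=0.0, sigma_delta=0.0,
                      phi=1.5)
    n_rep = 10_000
    cfg = _tiny_cfg(n_lakes=n_rep, seed=13, zinb_truth=truth)
    lakes = gen_spatial_lakes(cfg)
    data, t = gen_counts_zinb(cfg, lakes, np.zeros(n_rep))
    y = data.counts[0]
    mu, pi, phi = np.exp(1.2), 0.3, 1.5
    m = (1 - pi) * mu
    v = (1 - pi) * mu * (1 + mu / phi + pi * mu)
    # brute-force oracle: same moments from the pmf summed to a far tail
    ks = np.arange(0, 2000)
    from brownfish.zinb import zinb_logpmf
    p = np.exp(zinb_logpmf(ks, mu, phi, pi))
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert (ks * p).sum() == pytest.approx(m, abs=1e-9)
    assert ((ks - m) ** 2 * p).sum() == pytest.approx(v, rel=1e-9)
    se_m = np.sqrt(v / n_rep)
    assert abs(y.mean() - m) < 3 * se_m
    mc4 = ((ks - m) ** 4 * p).sum()
    se_v = np.sqrt((mc4 - v ** 2) / n_rep)
    assert abs(y.var() - v) < 3 * se_v


def test_overflow_guard():
    truth = ZINBTruth(beta0=(25.0, 1.0), beta1=(0.0, 0.0), beta2=(0.0, 0.0),
                      structural_zero_logit=(0.0, 0.0))
    cfg = _tiny_cfg(zinb_truth=truth)
    lakes = gen_spatial_lakes(cfg)
    with pytest.raises(ValueError, match="overflow"):
        gen_counts_zinb(cfg, lakes, np.zeros(40))


# -- phylogeny and traits --------------------------------------------------

def test_two_species_tree_structure():
    cfg = SimConfig(n_lakes=10, n_species=2, seed=9)
    tree, traits, _ = gen_phylogeny_and_traits(cfg)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    assert len(internal) == 1
    from brownfish.phylo import phylo_vcv
    V, _ = phylo_vcv(tree)
    # the two tips diverge at the root: shared branch length is zero, and
    # each diagonal entry is that tip's root-to-tip distance
    assert V[0, 1] == pytest.approx(0.0, abs=1e-9)
    assert V[0, 0] == pytest.approx(
        tree.seed_node.child_nodes()[0].edge.length, abs=1e-9)
    assert len(traits) == 2
    assert traits[["eye_ratio", "mouth_size", "mouth_position"]].notna().all().all()


def test_zero_brownian_rate_constant_traits():
    cfg = SimConfig(n_lakes=10, n_species=6, seed=10,
                    jsdm_truth=JSDMTruth(brownian_rate=0.0))
    _, traits, _ = gen_phylogeny_and_traits(cfg)
    for col in ("eye_ratio", "mouth_size", "mouth_position"):
        assert traits[col].nunique() == 1


def test_star_tree_traits_uncorrelated_across_replicates():
    import dendropy
    star = "(" + ",".join(f"sp{i + 1}:1" for i in range(4)) + ");"
    vals = []
    for rep in range(300):
        cfg = SimConfig(n_lakes=10, n_species=4, seed=2000 + rep,
                        jsdm_truth=JSDMTruth(brownian_rate=4.0))
        tree = dendropy.Tree.get(data=star, schema="newick")
        _, traits, _ = gen_phylogeny_and_traits(cfg, tree=tree)
        vals.append(traits["eye_ratio"].to_numpy()[:2])
    vals = np.array(vals)
    r = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
    assert abs(r) < 3.5 / np.sqrt(300)


# -- community occurrence --------------------------------------------------

def test_null_community_prevalence_half():
    cfg = SimConfig(n_lakes=400, n_species=6, seed=14,
                    jsdm_truth=JSDMTruth(trait_intercept=0.0,
                                         trait_slopes=(0.0, 0.0, 0.0),
                                         resid_sd=0.0, intercept_mean=0.0,
                                         intercept_sd=0.0, spatial_sd=0.0))
    lakes = gen_spatial_lakes(cfg)
    tree, traits, _ = gen_phylogeny_and_traits(cfg)
    occ, truth = gen_community_occurrence(cfg, lakes,
                                          np.zeros(400), traits, tree)
    np.testing.assert_allclose(truth["prob"], 0.5)
    prev = occ.presence.mean()
    assert abs(prev - 0.5) < 3 / np.sqrt(400 * 6)


def test_eye_trait_drives_slopes_across_replicates():
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = SimConfig(n_lakes=10, n_species=25, seed=500 + rep)
        tree, traits, _ = gen_phylogeny_and_traits(cfg)
        lakes = gen_spatial_lakes(cfg)
        occ, truth = gen_community_occurrence(
            cfg, lakes, np.zeros(10), traits, tree)
        r = stats.spearmanr(traits["eye_ratio"], truth["slopes"]).statistic
        hits += r > 0
    assert hits >= 0.95 * n_rep


def test_tiny_spatial_range_gives_no_autocorrelation():
    cfg = SimConfig(n_lakes=250, n_species=4, seed=15,
                    jsdm_truth=JSDMTruth(spatial_range=1e-6, spatial_sd=1.0))
    lakes = gen_spatial_lakes(cfg)
    tree, traits, _ = gen_phylogeny_and_traits(cfg)
    occ, truth = gen_community_occurrence(
        cfg, lakes, np.zeros(250), traits, tree)
    w = truth["spatial"]
    coords = occ.coords
    d = np.hypot(coords[:, 0][:, None] - coords[:, 0][None],
                 coords[:, 1][:, None] - coords[:, 1][None])
    near = (d < 10) & (d > 0)
    # Moran-type statistic with a permutation oracle
    W = near / max(near.sum(), 1)
    z = (w - w.mean()) / w.std()
    moran = float(z @ W @ z)
    rng = np.random.default_rng(0)
    null = []
    for _ in range(200):
        zp = rng.permutation(z)
        null.append(float(zp @ W @ zp))
    lo, hi = np.percentile(null, [0.5, 99.5])
    assert lo <= moran <= hi


# -- evidence table --------------------------------------------------------

def test_corpus_size_near_published_mean():
    cfg = SimConfig(n_lakes=10, n_species=2, seed=16)
    df = gen_evidence_table(cfg)
    assert df["study_id"].nunique() == 59
    # 59 papers x mean 5.17 datasets -> ~305 within sampling error
    sd = np.sqrt(59 * 4.17)  # Poisson part of the per-paper distribution
    assert abs(len(df) - 305) < 3 * sd
    assert df.loc[df.browning_metric == "Secchi",
                  "metric_darkness_polarity"].eq(-1).all()


def test_all_none_profile_single_cell():
    cfg = SimConfig(n_lakes=10, n_species=2, seed=17,
                    evidence_profile=EvidenceProfile(
                        effect_probs={"none": 1.0, "neg_linear": 0.0,
                                      "pos_linear": 0.0, "neg_quad": 0.0,
                                      "pos_quad": 0.0}))
    df = gen_evidence_table(cfg)
    from brownfish.evidence import normalize_table, tally_by_category
    t = tally_by_category(normalize_table(df))
    assert (t["none"] == t["n_datasets"]).all()


# -- full pipeline output --------------------------------------------------

def test_simulate_all_writes_artifacts(tmp_path):
    cfg = SimConfig(n_lakes=60, n_species=4, seed=18,
                    zinb_truth=ZINBTruth(beta0=(1.0,) * 4, beta1=(0.5, -0.5, 0.2, -0.2),
                                         beta2=(-0.05,) * 4,
                                         structural_zero_logit=(-1.0,) * 4))
    out = simulate_all(cfg, tmp_path)
    for name in ("lakes.csv", "counts.csv", "occurrence.csv", "traits.csv",
                 "tree.nwk", "evidence.csv", "truth.json"):
        assert (tmp_path / name).exists()
    # truths sufficient for downstream recovery tests: schema check
    import json
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert set(truth) >= {"latent_browning", "zinb", "community_slopes",
                          "community_theta"}
    assert len(truth["latent_browning"]) == 60
    assert len(truth["zinb"]["beta1"]) == 4
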