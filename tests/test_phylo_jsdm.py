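"""Phylogenetic covariance, spatial correlation, Tjur R2, JSDM machinery."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from brownfish.jsdm import (OccurrenceDataset, ProbitJSDM, filter_contiguous_lakes,
                            tjur_r2, validate_trait_table, variance_partition)
from brownfish.phylo import blended_species_cov, phylo_vcv, spatial_correlation
from brownfish.simulate import SimConfig, gen_phylogeny_and_traits
from brownfish.zinb import SamplerSchedule


# -- phylogenetic vcv ------------------------------------------------------

def test_two_species_tree_hand_computation():
    V, labels = phylo_vcv("((A:1,B:1):1);")
    assert sorted(labels) == ["A", "B"]
    np.testing.assert_allclose(np.diag(V), 2.0)
    assert V[0, 1] == pytest.approx(1.0)


def test_star_tree_identity():
    V, _ = phylo_vcv("(A:1,B:1,C:1,D:1);")
    np.testing.assert_allclose(V, np.eye(4), atol=1e-12)


def _path_sum_oracle(tree, labels):
    """Recursive oracle: shared root-path length to the MRCA of each pair."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(edges))
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is nb:
                    shared += na.edge.length
                else:
                    break
            V[i, j] = shared
    return V


def test_vcv_matches_path_sum_oracle_on_random_trees():
    for seed in range(5):
        cfg = SimConfig(n_lakes=10, n_species=12, seed=seed)
        tree, _, _ = gen_phylogeny_and_traits(cfg)
        V, labels = phylo_vcv(tree)
        oracle = _path_sum_oracle(tree, labels)
        np.testing.assert_allclose(V, oracle, atol=1e-10)
        assert np.ptp(np.diag(V)) < 1e-8  # ultrametric: constant depth


def test_vcv_tip_reordering():
    newick = "((A:1,B:1):1,(C:0.5,D:0.5):1.5);"
    V1, l1 = phylo_vcv(newick, taxa=["A", "B", "C", "D"])
    V2, l2 = phylo_vcv(newick, taxa=["D", "B", "A", "C"])
    perm = [l1.index(t) for t in l2]
    np.testing.assert_allclose(V2, V1[np.ix_(perm, perm)], atol=1e-12)


def test_vcv_errors():
    with pytest.raises(ValueError, match="branch lengths"):
        phylo_vcv("((A,B),C);")
    with pytest.raises(ValueError, match="zero total"):
        phylo_vcv("((A:0,B:0):0,C:0);")


def test_blended_cov():
    V, _ = phylo_vcv("((A:1,B:1):1,C:2);")
    C0 = blended_species_cov(V, 0.0)
    np.testing.assert_allclose(C0, np.eye(3))
    C1 = blended_species_cov(V, 1.0)
    np.testing.assert_allclose(np.diag(C1), 1.0)
    assert C1[0, 1] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        blended_species_cov(V, 1.5)


# -- spatial correlation ---------------------------------------------------

def test_spatial_correlation_closed_forms():
    coords = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
    C = spatial_correlation(coords, range_param=5.0)
    assert C[0, 1] == pytest.approx(np.exp(-1.0))
    C = spatial_correlation(coords, range_param=1e9)
    assert C[0, 1] == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_allclose(np.diag(C), 1.0)
    with pytest.raises(ValueError):
        spatial_correlation(coords, 0.0)


def test_spatial_correlation_psd_after_jitter():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = rng.integers(5, 25)
        pts = rng.uniform(0, 10, (n, 2))
        if rng.random() < 0.3:
            pts[1] = pts[0]  # force a duplicate
            with pytest.warns(UserWarning, match="jitter"):
                C = spatial_correlation(pts, rng.uniform(0.5, 20))
        else:
            C = spatial_correlation(pts, rng.uniform(0.5, 20))
        assert np.linalg.eigvalsh(C).min() > -1e-10


def test_geodesic_distance_used_for_latlon():
    coords = np.array([[0.0, 0.0], [0.0, 90.0]])  # quarter circumference
    C = spatial_correlation(coords, range_param=10007.5, geodesic=True)
    assert C[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-3)


# -- Tjur R2 ---------------------------------------------------------------

def test_tjur_trivial_and_oracle():
    y = np.array([1, 1, 0, 0, 1])
    assert tjur_r2(y, y.astype(float)) == pytest.approx(1.0)
    assert tjur_r2(y, np.full(5, 0.4)) == pytest.approx(0.0)
    rng = np.random.default_rng(2)
    for _ in range(20):
        y = rng.integers(0, 2, 40)
        if y.min() == y.max():
            continue
        p = rng.random(40)
        expected = p[y == 1].mean() - p[y == 0].mean()
        assert tjur_r2(y, p) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        tjur_r2(np.ones(5, dtype=int), np.full(5, 0.5))


# -- lake filter and trait table -------------------------------------------

def test_filter_contiguous_lakes():
    rng = np.random.default_rng(0)
    inside = pd.DataFrame({"easting": rng.uniform(0, 100, 303),
                           "northing": rng.uniform(0, 100, 303),
                           "region": "core"})
    outside = pd.DataFrame({"easting": rng.uniform(200, 300, 29),
                            "northing": rng.uniform(200, 300, 29),
                            "region": "sparse"})
    lakes = pd.concat([inside, outside], ignore_index=True)
    kept, n_excluded = filter_contiguous_lakes(lakes, bounds=(0, 100, 0, 100))
    assert len(kept) == 303 and n_excluded == 29
    kept2, n2 = filter_contiguous_lakes(lakes, regions={"core"})
    assert len(kept2) == 303 and n2 == 29
    with pytest.raises(ValueError):
        filter_contiguous_lakes(lakes)


def test_trait_table_validation():
    t = pd.DataFrame({"species_id": ["a", "b"], "eye_ratio": [0.3, 0.4],
                      "mouth_size": [0.5, 0.6], "mouth_position": [0.2, 0.9]})
    out = validate_trait_table(t, ["b", "a"])
    assert list(out.index) == ["b", "a"]
    with pytest.raises(ValueError, match="missing from"):
        validate_trait_table(t, ["a", "c"])
    t.loc[0, "eye_ratio"] = -1
    with pytest.raises(ValueError, match="positive"):
        validate_trait_table(t, ["a", "b"])


# -- variance partition ----------------------------------------------------

class _FakeModel:
    pass


def _fake_results(b, w, x, species):
    from brownfish.jsdm import JSDMResults
    res = JSDMResults.__new__(JSDMResults)
    model = _FakeModel()
    model._xs = x - x.mean()
    model.data = _FakeModel()
    model.data.species_ids = species
    res.model = model
    res.draws = {"b": b[None], "w": w[None]}
    return res


def test_variance_partition_construction():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 100)
    b = np.tile([1.0, -1.0], (50, 1))
    # spatial term forced to zero -> browning proportion 1
    res = _fake_results(b, np.zeros((50, 100)), x, ["s1", "s2"])
    vp = variance_partition(res, res.model.data)
    np.testing.assert_allclose(vp["browning_prop"], 1.0)
    np.testing.assert_allclose(vp["browning_prop"] + vp["spatial_prop"], 1.0,
                               atol=1e-10)
    # nonzero spatial: proportions still sum to one exactly
    w = rng.normal(0, 0.7, (50, 100))
    res = _fake_results(b, w, x, ["s1", "s2"])
    vp = variance_partition(res, res.model.data)
    np.testing.assert_allclose(vp["browning_prop"] + vp["spatial_prop"], 1.0,
                               atol=1e-10)
    assert ((vp["browning_prop"] > 0) & (vp["browning_prop"] < 1)).all()


# -- nesting property ------------------------------------------------------

def test_star_phylogeny_matches_unstructured_model():
    """With a star tree, estimating rho freely and fixing rho = 0 target the
    same model; posterior trait effects agree within Monte-Carlo error."""
    cfg = SimConfig(n_lakes=100, n_species=12, seed=33)
    from brownfish.simulate import (gen_community_occurrence, gen_spatial_lakes)
    star = "(" + ",".join(f"sp{i + 1}:1" for i in range(12)) + ");"
    tree = dendropy.Tree.get(data=star, schema="newick")
    lakes = gen_spatial_lakes(cfg)
    x = cfg.rng("browning").standard_normal(100)
    _, traits, _ = gen_phylogeny_and_traits(cfg, tree=tree)
    occ, _ = gen_community_occurrence(cfg, lakes, x, traits, tree)
    V, _ = phylo_vcv(tree, taxa=occ.species_ids)
    sched = SamplerSchedule(2, 1200, 500, 1, seed=4)
    res_free = ProbitJSDM(occ, traits, V).fit(sched)
    res_zero = ProbitJSDM(occ, traits, V, rho_fixed=0.0).fit(sched)
    th1 = res_free.stacked("theta").mean(axis=0)
    th2 = res_zero.stacked("theta").mean(axis=0)
    np.testing.assert_allclose(th1, th2, atol=0.15)
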