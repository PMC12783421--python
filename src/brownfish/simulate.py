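"""Seeded synthetic lake-survey data with the structure the models assume.

The government survey data behind the original analyses are not public,
so every pipeline stage is exercised on synthetic data that emulates their
statistical structure: three browning metrics driven by one dominant
latent factor (~86% of shared variance) with roughly 10%, 11% and 1%
missingness; overdispersed zero-heavy counts for a handful of species
across hundreds of lakes with species-specific quadratic responses, lake
noise and a smooth spatial trend; presence-absence communities whose
browning responses are partly explained by relative eye size and
phylogeny; and a literature evidence table with per-dataset effect
directions.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` child streams (one per generator, fixed
order), so each generator is a pure function of its config and the
generators are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .transform import TransformSpec, invert_boxcox
from .zinb import AbundanceDataset, ZINBParams
from .jsdm import OccurrenceDataset
from .phylo import blended_species_cov, phylo_vcv, spatial_correlation

_STREAMS = ("browning", "spatial", "counts", "phylo", "community", "evidence")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ZINBTruth:
    """Generating parameters of the count model (one entry per species)."""

    beta0: tuple = (1.5, 1.2, 1.0, 0.8, 1.4, 1.0, 1.2, 0.6)
    beta1: tuple = (0.8, -0.8, 0.5, -0.5, 0.3, -0.3, 0.8, -0.8)
    beta2: tuple = (-0.1,) * 8
    structural_zero_logit: tuple = (-1.4, -0.8, -0.4, 0.0, -1.4, -0.8, 0.4, -2.2)
    sigma_gamma: float = 0.3
    sigma_lambda: float = 0.4
    sigma_delta: float = 0.5
    phi: float = 1.5


@dataclass
class JSDMTruth:
    """Generating parameters of the community model."""

    trait_intercept: float = -0.2          # community-mean browning slope
    trait_slopes: tuple = (0.5, 0.0, -0.15)  # eye_ratio, mouth_size, mouth_position
    resid_sd: float = 0.3                  # phylogenetic residual SD of slopes
    phylo_weight: float = 0.5              # rho blending phylogeny and identity
    intercept_mean: float = 0.0
    intercept_sd: float = 0.7
    spatial_range: float = 20.0            # exponential decay range (domain units)
    spatial_sd: float = 0.7
    brownian_rate: float = 1.0             # BM rate of trait evolution
    trait_centres: tuple = (-0.6, -0.4, 0.0)  # logistic squash centres


@dataclass
class EvidenceProfile:
    """Category / effect-class mix of the synthetic literature corpus."""

    n_papers: int = 59
    datasets_per_paper_mean: float = 5.17
    max_per_paper: int = 16
    category_probs: dict = field(default_factory=lambda: {
        "foraging": 0.30, "growth": 0.28, "survival": 0.10, "other": 0.32})
    metric_probs: dict = field(default_factory=lambda: {
        "DOC": 0.4, "TOC": 0.1, "colour": 0.2, "Secchi": 0.3})
    effect_probs: dict = field(default_factory=lambda: {
        "none": 0.35, "neg_linear": 0.30, "pos_linear": 0.20,
        "neg_quad": 0.05, "pos_quad": 0.10})
    mortality_prob: float = 0.4            # survival records reported as mortality


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror the abundance survey scale (871 lakes, 8 species) and
    the browning-metric missingness of the pooled lake compilation.
    """

    n_lakes: int = 871
    n_species: int = 8
    seed: int = 0
    loading_vector: tuple = (1.0, -1.0, 1.0)        # DOC, Secchi, colour
    noise_sd: tuple = (0.52, 0.52, 0.52)
    missing_rates: tuple = (0.102, 0.108, 0.013)
    transform_lambdas: tuple = (0.0, 0.25, 0.25)    # log, fourth-root, fourth-root
    transform_centres: tuple = (1.8, 1.2, 6.0)      # transformed-scale locations
    transform_scales: tuple = (0.6, 0.5, 1.6)
    spatial_domain: tuple = (0.0, 100.0, 0.0, 100.0)
    trend_amplitude: float = 0.5
    zinb_truth: ZINBTruth = field(default_factory=ZINBTruth)
    jsdm_truth: JSDMTruth = field(default_factory=JSDMTruth)
    evidence_profile: EvidenceProfile = field(default_factory=EvidenceProfile)

    def __post_init__(self) -> None:
        if self.n_lakes < 1 or self.n_species < 1:
            raise ValueError("n_lakes and n_species must be positive")
        if any(not 0 <= r < 0.5 for r in self.missing_rates):
            raise ValueError("missing rates must be in [0, 0.5)")
        if self.zinb_truth.phi <= 0:
            raise ValueError("phi must be positive")
        doc_l, secchi_l, colour_l = self.loading_vector
        if doc_l * colour_l <= 0 or doc_l * secchi_l >= 0:
            raise ValueError("DOC and colour loadings must share sign; "
                             "Secchi must oppose them")
        u0, u1, v0, v1 = self.spatial_domain
        if not (u1 > u0 and v1 > v0):
            raise ValueError("degenerate spatial domain")
        for probs in (self.evidence_profile.category_probs,
                      self.evidence_profile.metric_probs,
                      self.evidence_profile.effect_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError("evidence profile probabilities must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child stream of the master seed (documented split scheme)."""
        idx = _STREAMS.index(stream)
        child = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[idx]
        return np.random.default_rng(child)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("zinb_truth", ZINBTruth), ("jsdm_truth", JSDMTruth),
                         ("evidence_profile", EvidenceProfile)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def gen_browning_metrics(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Three raw-scale browning metrics driven by one latent factor.

    Transformed metric k for lake i is
    ``centre_k + scale_k * (loading_k * z_i + eps_ik)`` with z ~ N(0,1),
    mapped to the raw scale by the inverse Box-Cox transform.  Lakes whose
    inverse transform leaves the positive domain are redrawn (rejection
    documented in the returned truth; an error is raised if more than half
    of all draws are rejected).  Missingness is completely at random per
    metric.  Returns the lake table and a truth dict holding the latent
    factor and complete transformed values.
    """
    rng = cfg.rng("browning")
    n = cfg.n_lakes
    lam = cfg.transform_lambdas
    specs = [TransformSpec(m, l) for m, l in zip(("doc", "secchi", "colour"), lam)]

    z = np.empty(n)
    T = np.empty((n, 3))
    raw = np.empty((n, 3))
    todo = np.arange(n)
    n_rejected = 0
    n_drawn = 0
    while todo.size:
        k = todo.size
        z_new = rng.standard_normal(k)
        eps = rng.standard_normal((k, 3)) * np.asarray(cfg.noise_sd)
        t_new = (np.asarray(cfg.transform_centres)
                 + np.asarray(cfg.transform_scales)
                 * (np.outer(z_new, np.asarray(cfg.loading_vector)) + eps))
        raw_new = np.column_stack(
            [invert_boxcox(t_new[:, j], specs[j]) for j in range(3)])
        ok = np.isfinite(raw_new).all(axis=1) & (raw_new > 0).all(axis=1)
        n_drawn += k
        n_rejected += int((~ok).sum())
        z[todo[ok]] = z_new[ok]
        T[todo[ok]] = t_new[ok]
        raw[todo[ok]] = raw_new[ok]
        todo = todo[~ok]
        if n_drawn >= 2 * n and n_rejected / n_drawn > 0.5:
            raise RuntimeError(
                f"inverse-transform rejection rate {n_rejected / n_drawn:.0%} "
                "exceeds 50%; the transform/centre/scale configuration is "
                "not invertible at this noise level")

    # MCAR masks; lakes losing all three metrics are re-masked (retained
    # lakes must keep at least one observed metric)
    mask = np.column_stack([rng.random(n) < r for r in cfg.missing_rates])
    for _ in range(100):
        all_missing = mask.all(axis=1)
        if not all_missing.any():
            break
        k = int(all_missing.sum())
        mask[all_missing] = np.column_stack(
            [rng.random(k) < r for r in cfg.missing_rates])
    mask[mask.all(axis=1)] = False
    observed = np.where(mask, np.nan, raw)

    df = pd.DataFrame({
        "lake_id": [f"lake{i + 1}" for i in range(n)],
        "doc": observed[:, 0], "secchi": observed[:, 1], "colour": observed[:, 2],
    })
    truth = {"latent": z, "transformed": T, "raw_complete": raw,
             "rejection_rate": n_rejected / n_drawn, "specs": specs}
    return df, truth


def gen_spatial_lakes(cfg: SimConfig) -> pd.DataFrame:
    """Lake coordinates (uniform over the domain) with a smooth trend.

    The trend is a deterministic quadratic bowl centred in the domain,
    standardized over the domain and scaled by ``trend_amplitude`` — a
    known target for the thin-plate surface to recover (a GP draw would
    leave no exact truth).
    """
    rng = cfg.rng("spatial")
    u0, u1, v0, v1 = cfg.spatial_domain
    n = cfg.n_lakes
    u = rng.uniform(u0, u1, n)
    v = rng.uniform(v0, v1, n)
    su = (u - (u0 + u1) / 2) / ((u1 - u0) / 2)
    sv = (v - (v0 + v1) / 2) / ((v1 - v0) / 2)
    q = su ** 2 + sv ** 2 - 2.0 / 3.0          # mean 0 under the uniform
    q = q / np.sqrt(8.0 / 45.0)                # unit variance under the uniform
    return pd.DataFrame({
        "lake_id": [f"lake{i + 1}" for i in range(n)],
        "easting": u, "northing": v,
        "trend_value": cfg.trend_amplitude * q,
    })


def gen_counts_zinb(cfg: SimConfig, lakes: pd.DataFrame,
                    bpc1_scores: np.ndarray) -> tuple[AbundanceDataset, dict]:
    """Forward-simulate the zero-inflated negative binomial hierarchy.

    For each species x lake cell: a structural-zero indicator from the
    logit model (species intercept + lake effect), otherwise a negative
    binomial count whose log-mean follows the species' quadratic browning
    response plus the spatial trend and lake effect.  All latent draws are
    stored for recovery tests.
    """
    rng = cfg.rng("counts")
    S = cfg.n_species
    tr = cfg.zinb_truth
    for name in ("beta0", "beta1", "beta2", "structural_zero_logit"):
        if len(getattr(tr, name)) < S:
            raise ValueError(f"zinb_truth.{name} shorter than n_species")
    x = np.asarray(bpc1_scores, dtype=float)
    n = x.size
    if len(lakes) != n:
        raise ValueError("one bpc1 score per lake required")
    trend = lakes["trend_value"].to_numpy(float) if "trend_value" in lakes else np.zeros(n)

    gamma = rng.normal(0, tr.sigma_gamma, S)
    lam = rng.normal(0, tr.sigma_lambda, n)
    delta = rng.normal(0, tr.sigma_delta, n)
    b0 = np.asarray(tr.beta0[:S])
    b1 = np.asarray(tr.beta1[:S])
    b2 = np.asarray(tr.beta2[:S])
    eta = np.asarray(tr.structural_zero_logit[:S])

    log_mu = ((b0 + gamma)[:, None] + b1[:, None] * x[None, :]
              + b2[:, None] * x[None, :] ** 2 + (trend + lam)[None, :])
    if np.any(log_mu > 20):
        i, j = np.unravel_index(np.argmax(log_mu), log_mu.shape)
        raise ValueError(
            f"log-mean overflow ({log_mu[i, j]:.1f} > 20) for species {i} "
            f"lake {j}: beta0={b0[i]}, beta1={b1[i]}, beta2={b2[i]}, x={x[j]:.2f}")
    mu = np.exp(log_mu)
    pi = expit(eta[:, None] + delta[None, :])
    structural = rng.random((S, n)) < pi
    p = tr.phi / (tr.phi + mu)
    counts = rng.negative_binomial(tr.phi, p)
    counts[structural] = 0

    coords = (lakes[["easting", "northing"]].to_numpy(float)
              if {"easting", "northing"} <= set(lakes.columns) else None)
    data = AbundanceDataset(counts=counts, x=x, coords=coords,
                            lake_ids=list(lakes["lake_id"]), trend=trend)
    params = ZINBParams(beta0=b0, beta1=b1, beta2=b2, eta=eta, lam=lam,
                        delta=delta, phi=tr.phi, gamma=gamma,
                        sigma={"gamma": tr.sigma_gamma, "lambda": tr.sigma_lambda,
                               "delta": tr.sigma_delta})
    truth = {"params": params, "structural": structural, "mu": mu, "pi": pi}
    return data, truth


def gen_phylogeny_and_traits(cfg: SimConfig,
                             tree: dendropy.Tree | None = None
                             ) -> tuple[dendropy.Tree, pd.DataFrame, dict]:
    """Pure-birth ultrametric phylogeny and Brownian ratio traits.

    Traits evolve by Brownian motion along the tree (rate
    ``jsdm_truth.brownian_rate``) and are squashed to (0, 1) ratios by a
    logistic map about per-trait centres — morphological ratios are
    bounded, so the squash keeps synthetic traits in a realistic range.
    A tree may be supplied (e.g. a star tree) to override the simulation.
    """
    rng = cfg.rng("phylo")
    S = cfg.n_species
    if S < 2:
        raise ValueError("need at least 2 species")
    if tree is None:
        tree = _pure_birth_tree(S, rng)
    names = ("eye_ratio", "mouth_size", "mouth_position")
    tr = cfg.jsdm_truth
    latent = {}
    for name in names:
        latent[name] = _brownian_on_tree(tree, tr.brownian_rate, rng)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    cols = {"species_id": labels}
    for k, name in enumerate(names):
        vals = np.array([latent[name][lab] for lab in labels])
        cols[name] = expit(tr.trait_centres[k] + vals)
    traits = pd.DataFrame(cols)
    return tree, traits, {"latent_traits": latent}


def _pure_birth_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Yule tree: exponential waiting times, uniform lineage splits;
    ultrametric by construction (depth normalized to 1)."""
    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.age_tmp = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            active.append(child)
            node.add_child(child)
    t_end = t + rng.exponential(1.0 / len(active))
    # assign branch lengths from split times; leaves end at t_end
    def _assign(node, start):
        stop = getattr(node, "split_time", t_end)
        node.edge.length = (stop - start) / t_end  # normalize depth to 1
        for ch in node.child_nodes():
            _assign(ch, stop)
    for ch in tree.seed_node.child_nodes():
        _assign(ch, getattr(tree.seed_node, "split_time", 0.0))
    tree.seed_node.edge.length = getattr(tree.seed_node, "split_time", 0.0) / t_end
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = taxa[i]
    return tree


def _brownian_on_tree(tree: dendropy.Tree, rate: float,
                      rng: np.random.Generator) -> dict:
    """Brownian increments (variance rate * branch length) accumulated
    from a root value of 0; returns tip-label -> value."""
    values = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = 0.0 if parent is None else values[id(parent)]
        bl = node.edge.length or 0.0
        values[id(node)] = base + (np.sqrt(rate * bl) * rng.standard_normal()
                                   if bl > 0 else 0.0)
    return {lf.taxon.label: values[id(lf)] for lf in tree.leaf_node_iter()}


def gen_community_occurrence(cfg: SimConfig, lakes: pd.DataFrame,
                             bpc1_scores: np.ndarray, traits: pd.DataFrame,
                             tree: dendropy.Tree
                             ) -> tuple[OccurrenceDataset, dict]:
    """Presence-absence communities from the probit trait/phylo/space model.

    Species browning slopes are the trait-regression mean plus a
    phylogenetically correlated residual; occurrence probability is the
    standard-normal CDF of (species intercept + slope * bpc1 + spatial GP
    effect).  True slopes and all latent draws are stored.
    """
    rng = cfg.rng("community")
    tr = cfg.jsdm_truth
    species = list(traits["species_id"])
    S = len(species)
    V, order = phylo_vcv(tree, taxa=species)
    C = blended_species_cov(V, tr.phylo_weight)

    tz = traits.set_index("species_id").loc[species, ["eye_ratio", "mouth_size",
                                                      "mouth_position"]]
    tz = (tz - tz.mean()) / tz.std(ddof=0)
    mean_slope = tr.trait_intercept + tz.to_numpy() @ np.asarray(tr.trait_slopes)
    resid = tr.resid_sd * (np.linalg.cholesky(C + 1e-10 * np.eye(S))
                           @ rng.standard_normal(S))
    b = mean_slope + resid
    a = rng.normal(tr.intercept_mean, tr.intercept_sd, S)

    coords = lakes[["easting", "northing"]].to_numpy(float)
    R = spatial_correlation(coords, tr.spatial_range)
    w = tr.spatial_sd * (np.linalg.cholesky(R + 1e-8 * np.eye(len(R)))
                         @ rng.standard_normal(len(R)))
    x = np.asarray(bpc1_scores, dtype=float)
    from scipy.special import ndtr
    P = ndtr(a[None, :] + np.outer(x, b) + w[:, None])
    Y = (rng.random(P.shape) < P).astype(np.int8)
    data = OccurrenceDataset(presence=Y, x=x, coords=coords,
                             species_ids=species, lake_ids=list(lakes["lake_id"]))
    truth = {"slopes": b, "mean_slope": mean_slope, "intercepts": a,
             "spatial": w, "prob": P,
             "theta": (tr.trait_intercept,) + tuple(tr.trait_slopes)}
    return data, truth


def gen_evidence_table(cfg: SimConfig) -> pd.DataFrame:
    """Synthetic literature corpus with the published corpus shape.

    Papers contribute ``1 + Poisson(mean - 1)`` datasets (capped at the
    published per-paper maximum), so the total dataset count matches the
    configured mean within sampling error; categories, metrics and effect
    classes are drawn from the configured profile, and some survival
    records are reported as mortality (response polarity -1).
    """
    rng = cfg.rng("evidence")
    prof = cfg.evidence_profile
    from .evidence import METRIC_POLARITY
    rows = []
    ds = 0
    for p in range(prof.n_papers):
        k = 1 + rng.poisson(prof.datasets_per_paper_mean - 1.0)
        k = min(k, prof.max_per_paper)
        for _ in range(k):
            cat = rng.choice(list(prof.category_probs),
                             p=list(prof.category_probs.values()))
            metric = rng.choice(list(prof.metric_probs),
                                p=list(prof.metric_probs.values()))
            effect = rng.choice(list(prof.effect_probs),
                                p=list(prof.effect_probs.values()))
            mortality = cat == "survival" and rng.random() < prof.mortality_prob
            rows.append({
                "study_id": f"paper{p + 1:02d}",
                "dataset_id": f"ds{ds:04d}",
                "response_category": cat,
                "browning_metric": metric,
                "metric_darkness_polarity": METRIC_POLARITY[metric],
                "response_polarity": -1 if mortality else 1,
                "reported_effect": effect,
            })
            ds += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full-pipeline output
# --------------------------------------------------------------------------

def simulate_all(cfg: SimConfig, outdir) -> dict:
    """Run every generator and write the CSV/newick/JSON artifact set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics, btruth = gen_browning_metrics(cfg)
    spatial = gen_spatial_lakes(cfg)
    lakes = metrics.merge(spatial, on="lake_id")
    lakes.to_csv(outdir / "lakes.csv", index=False)

    x = btruth["latent"]
    counts_data, ctruth = gen_counts_zinb(cfg, lakes, x)
    long = []
    for i, sp in enumerate(counts_data.species_ids):
        for j, lid in enumerate(counts_data.lake_ids):
            long.append({"species_id": sp, "lake_id": lid,
                         "count": int(counts_data.counts[i, j])})
    pd.DataFrame(long).to_csv(outdir / "counts.csv", index=False)

    tree, traits, _ = gen_phylogeny_and_traits(cfg)
    traits.to_csv(outdir / "traits.csv", index=False)
    tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    occ, otruth = gen_community_occurrence(cfg, lakes, x, traits, tree)
    occ_df = pd.DataFrame(occ.presence, columns=occ.species_ids)
    occ_df.insert(0, "lake_id", occ.lake_ids)
    occ_df.to_csv(outdir / "occurrence.csv", index=False)

    gen_evidence_table(cfg).to_csv(outdir / "evidence.csv", index=False)

    truth = {
        "latent_browning": btruth["latent"].tolist(),
        "rejection_rate": btruth["rejection_rate"],
        "zinb": {k: np.asarray(v).tolist() for k, v in
                 asdict(ctruth["params"]).items() if v is not None and k != "sigma"},
        "zinb_sigma": ctruth["params"].sigma,
        "community_slopes": otruth["slopes"].tolist(),
        "community_theta": list(otruth["theta"]),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return {"lakes": lakes, "counts": counts_data, "tree": tree,
            "traits": traits, "occurrence": occ}
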