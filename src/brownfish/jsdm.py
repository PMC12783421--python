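"""Reduced joint species distribution model (probit, traits, phylogeny, space).

Occurrence of species s in lake l is probit-Bernoulli,

    y_ls ~ Bernoulli( Phi( a_s + b_s * bpc1_l + w_l ) ),

where the species-specific browning slopes b_s are themselves modelled by
a trait regression with phylogenetically correlated residuals,

    b ~ N( T theta, sigma^2 [ rho * C_phylo + (1 - rho) * I ] ),

T carrying an intercept plus the three standardized morphological traits
(eye ratio, mouth size, mouth position), and w is a zero-mean Gaussian
process over lakes with exponentially decaying correlation exp(-d/range).
This is a deliberate reduction of latent-factor JSDM machinery: the
spatial term is an explicit GP random effect rather than spatially
structured latent factors.

Fitting is by Gibbs sampling with probit data augmentation (truncated
normal latent variables), conjugate Gaussian/inverse-gamma updates for
coefficients and variances, and griddy-Gibbs steps for the phylogenetic
weight rho (uniform prior on a [0,1] grid) and the spatial range
(uniform prior on a log-spaced grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .phylo import blended_species_cov, spatial_correlation
from .zinb import SamplerSchedule, retained_draw_count

TRAIT_COLUMNS = ("eye_ratio", "mouth_size", "mouth_position")


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class OccurrenceDataset:
    """Lakes x species presence-absence with the browning score and coords."""

    presence: np.ndarray          # (L, S) 0/1
    x: np.ndarray                 # (L,) bpc1
    coords: np.ndarray            # (L, 2)
    species_ids: list | None = None
    lake_ids: list | None = None
    geodesic: bool = False

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        self.presence = self.presence.astype(np.int8)
        L, S = self.presence.shape
        self.x = np.asarray(self.x, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.x.shape != (L,) or self.coords.shape != (L, 2):
            raise ValueError("x / coords shapes inconsistent with presence")
        if self.species_ids is None:
            self.species_ids = [f"sp{i + 1}" for i in range(S)]
        if self.lake_ids is None:
            self.lake_ids = [f"lake{j + 1}" for j in range(L)]
        prev = self.presence.mean(axis=0)
        self.degenerate_species = [
            self.species_ids[i] for i in np.flatnonzero((prev == 0) | (prev == 1))
        ]

    @property
    def n_lakes(self) -> int:
        return self.presence.shape[0]

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]


def validate_trait_table(traits: pd.DataFrame, species: list[str]) -> pd.DataFrame:
    """Check the three focal ratio traits exist, cover all species, and are
    positive; returns the table reindexed to ``species`` order."""
    missing_cols = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing_cols:
        raise ValueError(f"trait table lacks {missing_cols}")
    if "species_id" in traits.columns:
        traits = traits.set_index("species_id")
    absent = [s for s in species if s not in traits.index]
    if absent:
        raise ValueError(f"species missing from trait table: {absent}")
    t = traits.loc[species, list(TRAIT_COLUMNS)].astype(float)
    if t.isna().any().any() or (t <= 0).any().any():
        raise ValueError("traits must be positive and complete")
    return t


def filter_contiguous_lakes(lakes: pd.DataFrame,
                            bounds: tuple[float, float, float, float] | None = None,
                            regions: set | None = None,
                            region_col: str = "region") -> tuple[pd.DataFrame, int]:
    """Drop geographically sparse lakes before fitting the spatial term.

    Either a planar bounding box ``(u_min, u_max, v_min, v_max)`` on
    easting/northing, or an explicit set of retained region tags.  Returns
    the retained table and the number excluded.  Sparse outlying lakes
    destabilize the spatial-correlation range estimate, hence the filter.
    """
    if (bounds is None) == (regions is None):
        raise ValueError("give exactly one of bounds or regions")
    if bounds is not None:
        u0, u1, v0, v1 = bounds
        keep = (lakes["easting"].between(u0, u1)
                & lakes["northing"].between(v0, v1))
    else:
        keep = lakes[region_col].isin(regions)
    kept = lakes.loc[keep].reset_index(drop=True)
    return kept, int((~keep).sum())


# --------------------------------------------------------------------------
# descriptive statistics
# --------------------------------------------------------------------------

def tjur_r2(observed, fitted_prob) -> float:
    """Tjur's coefficient of discrimination: mean fitted probability among
    presences minus mean among absences."""
    y = np.asarray(observed)
    p = np.asarray(fitted_prob, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("observed must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present for Tjur R2")
    return float(p[y == 1].mean() - p[y == 0].mean())


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JSDMPriors:
    intercept_sd: float = 2.0       # normal prior on species intercepts
    theta_sd: float = 2.0           # normal prior on trait coefficients
    sigma2_shape: float = 2.0       # inverse-gamma on residual slope variance
    sigma2_rate: float = 1.0
    sigw2_shape: float = 2.0        # inverse-gamma on spatial GP variance
    sigw2_rate: float = 1.0
    rho_grid_size: int = 21         # uniform prior on [0,1] via a grid
    n_range_grid: int = 15          # uniform prior over log-spaced ranges


class ProbitJSDM:
    """Joint probit occurrence model with trait, phylogeny and space.

    Parameters
    ----------
    data : OccurrenceDataset
    traits : DataFrame
        One row per species, columns eye_ratio / mouth_size / mouth_position.
    phylo_cov : (S, S) array
        Brownian variance-covariance from :func:`brownfish.phylo.phylo_vcv`,
        in the same species order as ``data``.
    range_bounds : (lo, hi), optional
        Support of the uniform prior on the spatial decay range; defaults
        to (5%, 100%) of the maximum inter-lake distance.
    """

    def __init__(self, data: OccurrenceDataset, traits: pd.DataFrame,
                 phylo_cov: np.ndarray, priors: JSDMPriors | None = None,
                 range_bounds: tuple[float, float] | None = None,
                 rho_fixed: float | None = None):
        self.data = data
        self.priors = priors or JSDMPriors()
        self.rho_fixed = rho_fixed
        if data.n_species < 2 or data.n_lakes < 50:
            raise ValueError("need >=2 species and >=50 lakes")
        if data.degenerate_species:
            warnings.warn(
                "species with zero or full prevalence retained but flagged: "
                f"{data.degenerate_species}")
        t = validate_trait_table(traits, data.species_ids)
        tz = (t - t.mean()) / t.std(ddof=0)
        self.T = np.column_stack([np.ones(data.n_species), tz.to_numpy()])
        self.trait_names = ("intercept",) + TRAIT_COLUMNS
        V = np.asarray(phylo_cov, dtype=float)
        if V.shape != (data.n_species, data.n_species):
            raise ValueError("phylo_cov shape mismatch")
        self.phylo_cov = V
        from scipy.spatial.distance import cdist
        dmax = float(cdist(data.coords, data.coords).max())
        self.range_bounds = range_bounds or (0.05 * dmax, dmax)
        self._xs = (data.x - data.x.mean())  # centred; scale kept (bpc1 units)

    # -- precomputations ---------------------------------------------------
    def _grids(self):
        pri = self.priors
        S = self.data.n_species
        if self.rho_fixed is not None:
            rho_grid = np.array([float(self.rho_fixed)])
        else:
            rho_grid = np.linspace(0.0, 1.0, pri.rho_grid_size)
        rho_mats = []
        for r in rho_grid:
            C = blended_species_cov(self.phylo_cov, r)
            sign, logdet = np.linalg.slogdet(C)
            rho_mats.append((np.linalg.inv(C), logdet))
        range_grid = np.geomspace(self.range_bounds[0], self.range_bounds[1],
                                  pri.n_range_grid)
        range_mats = []
        for rg in range_grid:
            R = spatial_correlation(self.data.coords, rg,
                                    geodesic=self.data.geodesic)
            R = R + 1e-8 * np.eye(len(R))
            sign, logdet = np.linalg.slogdet(R)
            range_mats.append((np.linalg.inv(R), logdet))
        return rho_grid, rho_mats, range_grid, range_mats

    def _run_chain(self, schedule, rng, grids):
        rho_grid, rho_mats, range_grid, range_mats = grids
        pri = self.priors
        Y = self.data.presence
        L, S = Y.shape
        x = self._xs
        Tm = self.T
        sum_x, sum_x2 = x.sum(), (x ** 2).sum()

        # state
        a = ndtri(np.clip(Y.mean(axis=0), 0.02, 0.98))
        b = np.zeros(S)
        theta = np.zeros(Tm.shape[1])
        sigma2 = 0.5
        rho_idx = len(rho_grid) // 2
        w = np.zeros(L)
        sigw2 = 0.5
        range_idx = len(range_grid) // 2
        z = np.where(Y == 1, 0.5, -0.5).astype(float)

        n_keep = (schedule.n_iter - schedule.burn_in) // schedule.thin
        keep = []
        IS = np.eye(S)
        pos = Y == 1

        for t in range(schedule.n_iter):
            # latent probit variables: truncated normal per cell
            mean = a[None, :] + np.outer(x, b) + w[:, None]
            u = rng.random((L, S))
            p_lo = ndtr(-mean)                 # P(z < 0)
            q = np.where(pos, p_lo + u * (1 - p_lo), u * p_lo)
            z = mean + ndtri(np.clip(q, 1e-12, 1 - 1e-12))

            # joint (a, b) update: Gaussian with phylo-coupled b block
            Ki, _ = rho_mats[rho_idx]
            Kb = Ki / sigma2                   # prior precision of b
            resid = z - w[:, None]
            r_a = resid.sum(axis=0)
            r_b = x @ resid
            P = np.zeros((2 * S, 2 * S))
            P[:S, :S] = (L + 1.0 / pri.intercept_sd ** 2) * IS
            P[:S, S:] = sum_x * IS
            P[S:, :S] = sum_x * IS
            P[S:, S:] = sum_x2 * IS + Kb
            rhs = np.concatenate([r_a, r_b + Kb @ (Tm @ theta)])
            cF = np.linalg.cholesky(P)
            m = np.linalg.solve(cF.T, np.linalg.solve(cF, rhs))
            draw = m + np.linalg.solve(cF.T, rng.standard_normal(2 * S))
            a, b = draw[:S], draw[S:]

            # trait regression coefficients
            Pt = Tm.T @ Kb @ Tm + IS[: Tm.shape[1], : Tm.shape[1]] / pri.theta_sd ** 2
            rt = Tm.T @ (Kb @ b)
            cF = np.linalg.cholesky(Pt)
            mt = np.linalg.solve(cF.T, np.linalg.solve(cF, rt))
            theta = mt + np.linalg.solve(cF.T, rng.standard_normal(len(mt)))

            # residual slope variance (conjugate inverse-gamma)
            r = b - Tm @ theta
            quad = r @ rho_mats[rho_idx][0] @ r
            sigma2 = 1.0 / rng.gamma(pri.sigma2_shape + S / 2.0,
                                     1.0 / (pri.sigma2_rate + 0.5 * quad))

            # phylogenetic weight rho: griddy Gibbs on [0, 1]
            lp = np.array([-0.5 * ld - 0.5 * (r @ Ci @ r) / sigma2
                           for Ci, ld in rho_mats])
            lp -= lp.max()
            pr = np.exp(lp)
            rho_idx = rng.choice(len(rho_grid), p=pr / pr.sum())

            # spatial GP: conjugate Gaussian given z
            Ri, _ = range_mats[range_idx]
            Q = Ri / sigw2 + S * np.eye(L)
            rw = (z - a[None, :] - np.outer(x, b)).sum(axis=1)
            cF = np.linalg.cholesky(Q)
            mw = np.linalg.solve(cF.T, np.linalg.solve(cF, rw))
            w = mw + np.linalg.solve(cF.T, rng.standard_normal(L))

            # level swap between intercepts and the GP (a + c, w - c): the
            # likelihood is invariant, so only the priors weigh in; this
            # decorrelates the two weakly separated levels
            prec_c = (S / pri.intercept_sd ** 2
                      + float(np.ones(L) @ Ri @ np.ones(L)) / sigw2)
            mean_c = (-a.sum() / pri.intercept_sd ** 2
                      + float(np.ones(L) @ Ri @ w) / sigw2) / prec_c
            c_shift = mean_c + rng.standard_normal() / np.sqrt(prec_c)
            a = a + c_shift
            w = w - c_shift

            # GP variance and decay range
            sigw2 = 1.0 / rng.gamma(pri.sigw2_shape + L / 2.0,
                                    1.0 / (pri.sigw2_rate + 0.5 * (w @ range_mats[range_idx][0] @ w)))
            lp = np.array([-0.5 * ld - 0.5 * (w @ Ri_ @ w) / sigw2
                           for Ri_, ld in range_mats])
            lp -= lp.max()
            pr = np.exp(lp)
            range_idx = rng.choice(len(range_grid), p=pr / pr.sum())

            if t >= schedule.burn_in and (t - schedule.burn_in) % schedule.thin == 0:
                if len(keep) < n_keep:
                    keep.append({
                        "a": a.copy(), "b": b.copy(), "theta": theta.copy(),
                        "sigma2": sigma2, "rho": rho_grid[rho_idx],
                        "sigw2": sigw2, "range": range_grid[range_idx],
                        "w": w.copy(),
                    })
        return keep

    def fit(self, schedule: SamplerSchedule | None = None) -> "JSDMResults":
        """Gibbs-sample the posterior (default schedule: 3 chains x 10000,
        burn-in 5000, thin 5)."""
        schedule = schedule or SamplerSchedule(n_chains=3, n_iter=10_000,
                                               burn_in=5000, thin=5)
        grids = self._grids()
        seeds = np.random.SeedSequence(schedule.seed).spawn(schedule.n_chains)
        chains = [self._run_chain(schedule, np.random.default_rng(s), grids)
                  for s in seeds]
        return JSDMResults(self, schedule, chains)


class JSDMResults:
    """Posterior draws and summaries of the community model."""

    def __init__(self, model: ProbitJSDM, schedule: SamplerSchedule, chains: list):
        self.model = model
        self.schedule = schedule
        self.draws: dict[str, np.ndarray] = {}
        for key in ("a", "b", "theta", "w"):
            self.draws[key] = np.array([[d[key] for d in ch] for ch in chains])
        for key in ("sigma2", "rho", "sigw2", "range"):
            self.draws[key] = np.array([[d[key] for d in ch] for ch in chains])
        self.n_retained = sum(len(ch) for ch in chains)
        assert self.n_retained == retained_draw_count(schedule)
        self.rhat = self._compute_rhat()
        self.converged = bool(all(v < 1.1 for v in self.rhat.values()))

    def _compute_rhat(self) -> dict[str, float]:
        out = {}
        for key in ("a", "b", "theta"):
            r = az.rhat(az.convert_to_dataset(self.draws[key]))["x"].values
            for i, val in enumerate(np.atleast_1d(r)):
                out[f"{key}[{i}]"] = float(val)
        for key in ("sigma2", "sigw2"):
            out[key] = float(az.rhat(az.convert_to_dataset(self.draws[key]))["x"].values)
        return out

    def stacked(self, key: str) -> np.ndarray:
        arr = self.draws[key]
        return arr.reshape(-1, *arr.shape[2:])

    def trait_effects(self) -> pd.DataFrame:
        """Posterior mean and 95% CrI of the trait-regression coefficients
        (per SD of trait; the intercept is the community-mean slope)."""
        th = self.stacked("theta")
        rows = []
        for i, name in enumerate(self.model.trait_names):
            d = th[:, i]
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append({"trait": name, "coefficient": d.mean(), "sd": d.std(),
                         "lo95": lo, "hi95": hi,
                         "excludes_zero": bool(lo > 0 or hi < 0)})
        return pd.DataFrame(rows)

    def fitted_probabilities(self) -> np.ndarray:
        """Posterior-mean occurrence probability per (lake, species)."""
        a = self.stacked("a")
        b = self.stacked("b")
        w = self.stacked("w")
        x = self.model._xs
        probs = np.zeros((self.model.data.n_lakes, self.model.data.n_species))
        for t in range(a.shape[0]):
            probs += ndtr(a[t][None, :] + np.outer(x, b[t]) + w[t][:, None])
        return probs / a.shape[0]

    def tjur_table(self) -> pd.DataFrame:
        """Tjur R2 per species from posterior-mean probabilities; species
        with one observed class are reported as NaN with a flag."""
        p = self.fitted_probabilities()
        rows = []
        for i, name in enumerate(self.model.data.species_ids):
            y = self.model.data.presence[:, i]
            if y.min() == y.max():
                rows.append({"species": name, "tjur_r2": np.nan, "degenerate": True})
            else:
                rows.append({"species": name, "tjur_r2": tjur_r2(y, p[:, i]),
                             "degenerate": False})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        te = self.trait_effects().rename(columns={"trait": "parameter"})
        extra = []
        for key in ("sigma2", "rho", "sigw2", "range"):
            d = self.stacked(key)
            lo, hi = np.percentile(d, [2.5, 97.5])
            extra.append({"parameter": key, "coefficient": d.mean(), "sd": d.std(),
                          "lo95": lo, "hi95": hi, "excludes_zero": bool(lo > 0)})
        return pd.concat([te, pd.DataFrame(extra)], ignore_index=True).set_index("parameter")


def variance_partition(results: JSDMResults, data: OccurrenceDataset | None = None
                       ) -> pd.DataFrame:
    """Share of predictor variance due to browning vs the spatial term.

    Per species and per draw, the variance across lakes of the browning
    contribution b_s * bpc1 and of the spatial effect w are each divided
    by their sum (so the two proportions add to 1 by construction); the
    posterior mean proportion is reported per species, along with the mean
    across species.  Draws where both variances vanish are flagged and
    skipped.
    """
    data = data or results.model.data
    x = results.model._xs
    b = results.stacked("b")          # (T, S)
    w = results.stacked("w")          # (T, L)
    var_x = x.var()
    vb = (b ** 2) * var_x             # (T, S)
    vw = w.var(axis=1)                # (T,)
    total = vb + vw[:, None]
    ok = total > 0
    prop = np.full_like(vb, np.nan)
    prop[ok] = vb[ok] / total[ok]
    rows = []
    for i, name in enumerate(data.species_ids):
        col = prop[:, i]
        col = col[np.isfinite(col)]
        browning = float(col.mean()) if col.size else np.nan
        rows.append({"species": name, "browning_prop": browning,
                     "spatial_prop": 1.0 - browning if np.isfinite(browning) else np.nan,
                     "undefined": col.size == 0})
    out = pd.DataFrame(rows)
    return out
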