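"""Zero-inflated negative binomial hierarchical model for fish counts.

Counts y_ij of species i in lake j are modelled as a two-part mixture:
with probability pi_ij the count is a structural zero (the species cannot
occur in that lake); otherwise it is negative binomial with mean mu_ij and
dispersion phi (variance mu + mu^2/phi).  The NB mean is log-linear in the
browning score x_j with species-specific intercepts and linear/quadratic
slopes, a two-dimensional thin-plate trend surface f(u_j, v_j), and a
lake-level random effect lambda_j that absorbs unmeasured effort and local
environment (the catch-equation rationale: catchability and effort enter
log-additively, so unknown effort is estimated as a lake random effect
rather than supplied as an offset).  The structural-zero probability is
logit-linear in species and lake random effects.

Fitting is fully Bayesian via an adaptive Metropolis-within-Gibbs sampler:
species-level and lake-level parameters factorize conditionally, so whole
blocks are proposed and accepted element-wise in vectorized sweeps.
Proposal scales adapt during burn-in only, leaving the retained chains
Markovian.  Gelman-Rubin diagnostics come from arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .splines import build_thinplate_basis

__all__ = [
    "AbundanceDataset",
    "ZINBParams",
    "SamplerSchedule",
    "ZINBPriors",
    "zinb_logpmf",
    "linear_predictors",
    "retained_draw_count",
    "ZINBAbundanceModel",
    "ZINBResults",
]


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class AbundanceDataset:
    """Species-by-lake count matrix with the browning predictor.

    ``counts`` is dense (every species/lake cell present, zeros allowed),
    ``x`` is the per-lake predictor (BPC1 or log DOC), ``coords`` the planar
    easting/northing used by the spatial trend.  ``trend`` optionally holds
    known per-lake trend-surface values (used by the synthetic generator).
    """

    counts: np.ndarray
    x: np.ndarray
    coords: np.ndarray | None = None
    species_ids: list | None = None
    lake_ids: list | None = None
    trend: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.x = np.asarray(self.x, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be species x lakes")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        s, n = self.counts.shape
        if s < 2:
            raise ValueError("need at least 2 species")
        if self.x.shape != (n,):
            raise ValueError("x must have one value per lake")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValueError("coords must be (n_lakes, 2)")
        if self.species_ids is None:
            self.species_ids = [f"sp{i + 1}" for i in range(s)]
        if self.lake_ids is None:
            self.lake_ids = [f"lake{j + 1}" for j in range(n)]

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_lakes(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, lakes: pd.DataFrame,
                        predictor: str = "bpc1") -> "AbundanceDataset":
        """Build from long-format counts (species_id, lake_id, count) and a
        lake table carrying the predictor column and easting/northing."""
        lakes = lakes.set_index("lake_id") if "lake_id" in lakes.columns else lakes
        wide = counts.pivot_table(index="species_id", columns="lake_id",
                                  values="count", fill_value=0)
        wide = wide[[lid for lid in lakes.index if lid in wide.columns]]
        lakes = lakes.loc[wide.columns]
        coords = None
        if {"easting", "northing"} <= set(lakes.columns):
            coords = lakes[["easting", "northing"]].to_numpy(float)
        return cls(
            counts=wide.to_numpy().astype(np.int64),
            x=lakes[predictor].to_numpy(float),
            coords=coords,
            species_ids=list(wide.index),
            lake_ids=list(wide.columns),
        )


@dataclass
class ZINBParams:
    """One full parameter point of the hierarchy (truth or a draw)."""

    beta0: np.ndarray          # species intercepts, log scale
    beta1: np.ndarray          # species linear browning slopes
    beta2: np.ndarray          # species quadratic slopes
    eta: np.ndarray            # species structural-zero logit intercepts
    lam: np.ndarray            # lake random effects, NB part
    delta: np.ndarray          # lake random effects, logit part
    phi: float                 # shared NB dispersion (> 0)
    gamma: np.ndarray | None = None       # species random effect, NB part
    spline_coefs: np.ndarray | None = None
    sigma: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.gamma is None:
            self.gamma = np.zeros_like(np.asarray(self.beta0, dtype=float))


@dataclass(frozen=True)
class SamplerSchedule:
    """MCMC bookkeeping: chains, total iterations, burn-in, thinning."""

    n_chains: int = 4
    n_iter: int = 7000
    burn_in: int = 5000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("chains, iterations and thin must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if (self.n_iter - self.burn_in) % self.thin != 0:
            warnings.warn(
                "post-burn-in iterations not divisible by thin; "
                "the remainder is discarded"
            )


def retained_draw_count(schedule: SamplerSchedule) -> int:
    """Number of retained posterior draws implied by a schedule.

    E.g. 4 chains of 7000 iterations with burn-in 5000 and thinning 2
    retain 4 * (7000-5000)/2 = 4000 draws.
    """
    per_chain = (schedule.n_iter - schedule.burn_in) // schedule.thin
    return schedule.n_chains * per_chain


@dataclass(frozen=True)
class ZINBPriors:
    """Weakly-informative defaults, diffuse at the scale of survey counts."""

    beta_sd: float = 2.5          # normal(0, beta_sd) on beta0/beta1/beta2, eta
    sigma_scale: float = 1.0      # half-normal(0, sigma_scale) on RE sds
    phi_rate: float = 0.2         # exponential(rate) on phi
    spline_sd: float = 2.5        # normal(0, spline_sd) on spline coefs
    spline_penalty_weight: float = 1.0


# --------------------------------------------------------------------------
# likelihood primitives
# --------------------------------------------------------------------------

def zinb_logpmf(y, mu, phi, pi):
    """Log pmf of the zero-inflated negative binomial.

    ``p(0) = pi + (1-pi) NB(0 | mu, phi)`` and
    ``p(y) = (1-pi) NB(y | mu, phi)`` for y > 0, with the NB parameterized
    by mean mu and dispersion phi so that Var = mu + mu^2/phi.
    Broadcasts over array arguments.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be positive")
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")

    y, mu, phi, pi = np.broadcast_arrays(y, mu, phi, pi)
    y = y.astype(float)
    log_ratio = np.log(phi) - np.log(phi + mu)          # log(phi/(phi+mu))
    nb = (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
          + phi * log_ratio + y * (np.log(mu) - np.log(phi + mu)))
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    zero = y == 0
    out = np.where(zero,
                   np.logaddexp(log_pi, log_1mpi + phi * log_ratio),
                   log_1mpi + nb)
    return out if out.ndim else float(out)


def linear_predictors(params: ZINBParams, data: AbundanceDataset,
                      spline_design: np.ndarray | None = None):
    """Exact array contract for the two linear predictors.

    ``log mu_ij = beta0_i + beta1_i x_j + beta2_i x_j^2 + f(u_j, v_j)
    + gamma_i + lambda_j`` and ``logit pi_ij = eta_i + delta_j``.  The
    surface f is ``data.trend`` (known values) plus ``spline_design @
    spline_coefs`` when a basis and coefficients are supplied.
    """
    x = data.x
    n = data.n_lakes
    f = np.zeros(n)
    if data.trend is not None:
        f = f + np.asarray(data.trend, dtype=float)
    if params.spline_coefs is not None:
        if spline_design is None:
            raise ValueError("spline_coefs given but no spline_design")
        f = f + spline_design @ params.spline_coefs
    b0 = np.asarray(params.beta0, float)
    b1 = np.asarray(params.beta1, float)
    b2 = np.asarray(params.beta2, float)
    g = np.asarray(params.gamma, float)
    if not (b0.shape == b1.shape == b2.shape == g.shape
            == np.asarray(params.eta, float).shape):
        raise ValueError("species-level parameter shapes differ")
    if np.asarray(params.lam).shape != (n,) or np.asarray(params.delta).shape != (n,):
        raise ValueError("lake-level parameter shapes differ from n_lakes")
    log_mu = ((b0 + g)[:, None] + b1[:, None] * x[None, :]
              + b2[:, None] * x[None, :] ** 2 + (f + params.lam)[None, :])
    logit_pi = np.asarray(params.eta, float)[:, None] + np.asarray(params.delta, float)[None, :]
    return log_mu, logit_pi


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

def _mixture_loglik(y, zero_mask, log_mu, logit_pi, phi, const_k):
    """S x N log-likelihood matrix; const_k caches the phi-dependent
    gammaln terms (they change only when phi does)."""
    log_mu = np.clip(log_mu, -30.0, 30.0)
    mu = np.exp(log_mu)
    log_phi_mu = np.log(phi + mu)
    log_phi = np.log(phi)
    nb_zero = phi * (log_phi - log_phi_mu)
    log_1mpi = -np.logaddexp(0.0, logit_pi)       # log(1 - pi)
    log_pi = logit_pi + log_1mpi                  # log(pi)
    nb = const_k + phi * (log_phi - log_phi_mu) + y * (log_mu - log_phi_mu)
    return np.where(zero_mask,
                    np.logaddexp(log_pi, log_1mpi + nb_zero),
                    log_1mpi + nb)


class _AdaptiveScales:
    """Per-coordinate Robbins-Monro proposal-scale adaptation."""

    def __init__(self, shapes: dict, target_scalar=0.44, target_joint=0.25):
        self.scales = {k: np.full(s, 0.2) if isinstance(s, int) else 0.2
                       for k, s in shapes.items()}
        self.targets = {k: (target_joint if np.isscalar(self.scales[k]) else target_scalar)
                        for k in self.scales}

    def adapt(self, key, accepted, t):
        gain = min(0.25, 2.0 / (t + 1) ** 0.6)
        tgt = self.targets[key]
        self.scales[key] = self.scales[key] * np.exp(gain * (accepted - tgt))


_TOP_LEVEL = ("beta0", "beta1", "beta2", "eta", "phi", "sigma_lam", "sigma_delta")


class ZINBAbundanceModel:
    """Hierarchical ZINB regression of species counts on a browning score.

    Parameters
    ----------
    data : AbundanceDataset
        Dense species x lake counts, predictor, optional coordinates.
    n_spline_basis : int
        Dimension of the thin-plate trend basis (0 disables the surface).
    quadratic : bool
        Include the species-specific quadratic browning term.
    priors : ZINBPriors

    The predictor is centred and scaled internally; results report slopes
    on both the standardized and the original scale.  The species random
    effect gamma_i of the generating model is absorbed into the species
    intercepts (the two are not separately identifiable), and eta_i is a
    free per-species parameter of the structural-zero part.
    """

    def __init__(self, data: AbundanceDataset, n_spline_basis: int = 20,
                 quadratic: bool = True, priors: ZINBPriors | None = None):
        if data.n_lakes < 20:
            raise ValueError("need at least 20 lakes to fit")
        self.data = data
        self.priors = priors or ZINBPriors()
        self.quadratic = quadratic
        self._x_mean = float(np.mean(data.x))
        self._x_sd = float(np.std(data.x)) or 1.0
        self._xs = (data.x - self._x_mean) / self._x_sd
        self.n_spline_basis = n_spline_basis
        if n_spline_basis and data.coords is not None:
            design, penalty, info = build_thinplate_basis(data.coords, n_spline_basis)
            # drop the intercept column and centre: identifiable next to beta0
            sm = design[:, 1:]
            self._spline_design = sm - sm.mean(axis=0)
            self._spline_penalty = penalty[1:, 1:]
            self._spline_info = info
        else:
            self._spline_design = None
            self._spline_penalty = None
            self._spline_info = None

    # -- one chain ---------------------------------------------------------
    def _run_chain(self, schedule: SamplerSchedule, rng: np.random.Generator):
        y = self.data.counts.astype(float)
        zero = self.data.counts == 0
        S, N = y.shape
        xs, xs2 = self._xs, self._xs ** 2
        pri = self.priors
        D = self._spline_design
        n_c = 0 if D is None else D.shape[1]
        if D is not None:
            prior_prec = (np.eye(n_c) / pri.spline_sd ** 2
                          + pri.spline_penalty_weight * self._spline_penalty)

        # initial state
        b0 = np.log(y.mean(axis=1) + 0.1) + rng.normal(0, 0.3, S)
        b1 = rng.normal(0, 0.2, S)
        b2 = np.zeros(S)
        eta = np.full(S, logit(np.clip(zero.mean(axis=1), 0.05, 0.8)))
        lam = np.zeros(N)
        delta = np.zeros(N)
        coefs = np.zeros(n_c)
        phi = 1.0
        sig_lam, sig_del = 0.5, 0.5

        const_k = gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)

        def species_part():
            out = b0[:, None] + b1[:, None] * xs[None, :]
            if self.quadratic:
                out = out + b2[:, None] * xs2[None, :]
            return out

        f = np.zeros(N) if D is None else D @ coefs
        A = species_part()
        log_mu = A + (f + lam)[None, :]
        logit_pi = eta[:, None] + delta[None, :]
        ll = _mixture_loglik(y, zero, log_mu, logit_pi, phi, const_k)

        shapes = {"b0": S, "b1": S, "eta": S, "lam": N, "delta": N,
                  "phi": None, "coefs": None, "sig_lam": None, "sig_del": None,
                  "resc_lam": None, "resc_del": None}
        if self.quadratic:
            shapes["b2"] = S
        ad = _AdaptiveScales(shapes)

        keep = []
        n_keep = (schedule.n_iter - schedule.burn_in) // schedule.thin
        species_blocks = [("b0", np.ones(N))]
        species_blocks.append(("b1", xs))
        if self.quadratic:
            species_blocks.append(("b2", xs2))
        state = {"b0": b0, "b1": b1, "b2": b2, "eta": eta}

        for t in range(schedule.n_iter):
            adapting = t < schedule.burn_in
            # species-level NB coefficients: vectorized row-wise MH
            for key, basis in species_blocks:
                cur = state[key]
                step = ad.scales[key] * rng.standard_normal(S)
                prop = cur + step
                log_mu_p = log_mu + step[:, None] * basis[None, :]
                ll_p = _mixture_loglik(y, zero, log_mu_p, logit_pi, phi, const_k)
                dprior = (cur ** 2 - prop ** 2) / (2 * pri.beta_sd ** 2)
                acc = (np.log(rng.random(S))
                       < ll_p.sum(axis=1) - ll.sum(axis=1) + dprior)
                cur[acc] = prop[acc]
                log_mu[acc] = log_mu_p[acc]
                ll[acc] = ll_p[acc]
                if adapting:
                    ad.adapt(key, acc.astype(float), t)

            # species structural-zero intercepts
            step = ad.scales["eta"] * rng.standard_normal(S)
            prop = eta + step
            logit_pi_p = logit_pi + step[:, None]
            ll_p = _mixture_loglik(y, zero, log_mu, logit_pi_p, phi, const_k)
            dprior = (eta ** 2 - prop ** 2) / (2 * pri.beta_sd ** 2)
            acc = np.log(rng.random(S)) < ll_p.sum(axis=1) - ll.sum(axis=1) + dprior
            eta[acc] = prop[acc]
            logit_pi[acc] = logit_pi_p[acc]
            ll[acc] = ll_p[acc]
            if adapting:
                ad.adapt("eta", acc.astype(float), t)

            # lake random effects, NB part: vectorized column-wise MH
            step = ad.scales["lam"] * rng.standard_normal(N)
            prop = lam + step
            log_mu_p = log_mu + step[None, :]
            ll_p = _mixture_loglik(y, zero, log_mu_p, logit_pi, phi, const_k)
            dprior = (lam ** 2 - prop ** 2) / (2 * sig_lam ** 2)
            acc = np.log(rng.random(N)) < ll_p.sum(axis=0) - ll.sum(axis=0) + dprior
            lam[acc] = prop[acc]
            log_mu[:, acc] = log_mu_p[:, acc]
            ll[:, acc] = ll_p[:, acc]
            if adapting:
                ad.adapt("lam", acc.astype(float), t)

            # lake random effects, logit part
            step = ad.scales["delta"] * rng.standard_normal(N)
            prop = delta + step
            logit_pi_p = logit_pi + step[None, :]
            ll_p = _mixture_loglik(y, zero, log_mu, logit_pi_p, phi, const_k)
            dprior = (delta ** 2 - prop ** 2) / (2 * sig_del ** 2)
            acc = np.log(rng.random(N)) < ll_p.sum(axis=0) - ll.sum(axis=0) + dprior
            delta[acc] = prop[acc]
            logit_pi[:, acc] = logit_pi_p[:, acc]
            ll[:, acc] = ll_p[:, acc]
            if adapting:
                ad.adapt("delta", acc.astype(float), t)

            # spline coefficients: joint random walk
            if n_c:
                prop = coefs + ad.scales["coefs"] * rng.standard_normal(n_c)
                f_p = D @ prop
                log_mu_p = log_mu + (f_p - f)[None, :]
                ll_p = _mixture_loglik(y, zero, log_mu_p, logit_pi, phi, const_k)
                dprior = 0.5 * (coefs @ prior_prec @ coefs - prop @ prior_prec @ prop)
                a = min(1.0, np.exp(min(0.0, ll_p.sum() - ll.sum() + dprior)))
                if rng.random() < a:
                    coefs, f, log_mu, ll = prop, f_p, log_mu_p, ll_p
                if adapting:
                    ad.adapt("coefs", a, t)

            # dispersion phi (log walk, exponential prior)
            prop_log = np.log(phi) + ad.scales["phi"] * rng.standard_normal()
            phi_p = np.exp(prop_log)
            const_p = gammaln(y + phi_p) - gammaln(phi_p) - gammaln(y + 1.0)
            ll_p = _mixture_loglik(y, zero, log_mu, logit_pi, phi_p, const_p)
            dlp = (ll_p.sum() - ll.sum()
                   - pri.phi_rate * (phi_p - phi)
                   + (prop_log - np.log(phi)))       # log-scale Jacobian
            a = min(1.0, np.exp(min(0.0, dlp)))
            if rng.random() < a:
                phi, const_k, ll = phi_p, const_p, ll_p
            if adapting:
                ad.adapt("phi", a, t)

            # joint rescale moves (sigma, effects) -> (c*sigma, c*effects):
            # travels along the scale/effect funnel; the Gaussian prior and
            # the transform Jacobian cancel, leaving likelihood x hyperprior
            logc = ad.scales["resc_lam"] * rng.standard_normal()
            c = np.exp(logc)
            lam_p = c * lam
            log_mu_p = log_mu + (lam_p - lam)[None, :]
            ll_p = _mixture_loglik(y, zero, log_mu_p, logit_pi, phi, const_k)
            s_p = c * sig_lam
            dlp = (ll_p.sum() - ll.sum()
                   + (sig_lam ** 2 - s_p ** 2) / (2 * pri.sigma_scale ** 2)
                   + logc)
            a = min(1.0, np.exp(min(0.0, dlp)))
            if rng.random() < a:
                lam, log_mu, ll, sig_lam = lam_p, log_mu_p, ll_p, s_p
            if adapting:
                ad.adapt("resc_lam", a, t)

            logc = ad.scales["resc_del"] * rng.standard_normal()
            c = np.exp(logc)
            delta_p = c * delta
            logit_pi_p = logit_pi + (delta_p - delta)[None, :]
            ll_p = _mixture_loglik(y, zero, log_mu, logit_pi_p, phi, const_k)
            s_p = c * sig_del
            dlp = (ll_p.sum() - ll.sum()
                   + (sig_del ** 2 - s_p ** 2) / (2 * pri.sigma_scale ** 2)
                   + logc)
            a = min(1.0, np.exp(min(0.0, dlp)))
            if rng.random() < a:
                delta, logit_pi, ll, sig_del = delta_p, logit_pi_p, ll_p, s_p
            if adapting:
                ad.adapt("resc_del", a, t)

            # random-effect scales (half-normal priors), log-scale MH
            for key, vec in (("sig_lam", lam), ("sig_del", delta)):
                cur = sig_lam if key == "sig_lam" else sig_del
                prop = np.exp(np.log(cur) + ad.scales[key] * rng.standard_normal())
                def _lp(s, v=vec):
                    return (-v.size * np.log(s) - v @ v / (2 * s ** 2)
                            - s ** 2 / (2 * pri.sigma_scale ** 2) + np.log(s))
                a = min(1.0, np.exp(min(0.0, _lp(prop) - _lp(cur))))
                if rng.random() < a:
                    if key == "sig_lam":
                        sig_lam = prop
                    else:
                        sig_del = prop
                if adapting:
                    ad.adapt(key, a, t)

            if t >= schedule.burn_in and (t - schedule.burn_in) % schedule.thin == 0:
                if len(keep) < n_keep:
                    keep.append({
                        "beta0": b0.copy(), "beta1": b1.copy(), "beta2": b2.copy(),
                        "eta": eta.copy(), "phi": phi,
                        "sigma_lam": sig_lam, "sigma_delta": sig_del,
                        "spline_coefs": coefs.copy() if n_c else None,
                        "f_mean": float(f.mean()),
                    })
        return keep

    def fit(self, schedule: SamplerSchedule | None = None) -> "ZINBResults":
        """Run the sampler and return posterior draws with diagnostics."""
        schedule = schedule or SamplerSchedule()
        seeds = np.random.SeedSequence(schedule.seed).spawn(schedule.n_chains)
        chains = [self._run_chain(schedule, np.random.default_rng(s)) for s in seeds]
        return ZINBResults(self, schedule, chains)


class ZINBResults:
    """Posterior draws, convergence diagnostics and summaries of a fit.

    Draw arrays are indexed ``(chain, draw, ...)``.  Slopes are stored on
    the standardized predictor scale and exposed on the original scale via
    :meth:`coefficients_original_scale`.
    """

    def __init__(self, model: ZINBAbundanceModel, schedule: SamplerSchedule,
                 chains: list):
        self.model = model
        self.schedule = schedule
        S = model.data.n_species
        nk = len(chains[0])
        self.draws: dict[str, np.ndarray] = {}
        for key in ("beta0", "beta1", "beta2", "eta"):
            self.draws[key] = np.array(
                [[d[key] for d in ch] for ch in chains])           # (C, K, S)
        for key in ("phi", "sigma_lam", "sigma_delta", "f_mean"):
            self.draws[key] = np.array(
                [[d[key] for d in ch] for ch in chains])           # (C, K)
        if chains[0][0]["spline_coefs"] is not None:
            self.draws["spline_coefs"] = np.array(
                [[d["spline_coefs"] for d in ch] for ch in chains])
        self.n_retained = schedule.n_chains * nk
        assert self.n_retained == retained_draw_count(schedule)
        self.rhat = self._compute_rhat()
        self.converged = bool(all(v < 1.1 for v in self.rhat.values()))

    def _compute_rhat(self) -> dict[str, float]:
        out = {}
        for key in ("beta0", "beta1", "beta2", "eta"):
            arr = self.draws[key]
            if np.ptp(arr) == 0:      # quadratic disabled -> constant zeros
                continue
            r = az.rhat(az.convert_to_dataset(arr))["x"].values
            for i, val in enumerate(np.atleast_1d(r)):
                out[f"{key}[{i}]"] = float(val)
        for key in ("phi", "sigma_lam", "sigma_delta"):
            out[key] = float(az.rhat(az.convert_to_dataset(self.draws[key]))["x"].values)
        return out

    # -- reporting ---------------------------------------------------------
    def stacked(self, key: str) -> np.ndarray:
        """Draws with chains stacked: (n_retained, ...)."""
        arr = self.draws[key]
        return arr.reshape(-1, *arr.shape[2:])

    def coefficients_original_scale(self) -> dict[str, np.ndarray]:
        """Back-transform slopes from the standardized to the raw x scale."""
        m, s = self.model._x_mean, self.model._x_sd
        b0, b1, b2 = (self.stacked(k) for k in ("beta0", "beta1", "beta2"))
        return {
            "beta0": b0 - b1 * m / s + b2 * m ** 2 / s ** 2,
            "beta1": b1 / s - 2 * b2 * m / s ** 2,
            "beta2": b2 / s ** 2,
        }

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% interval and R-hat per top-level parameter."""
        rows = []
        orig = self.coefficients_original_scale()
        sp = self.model.data.species_ids
        for key in ("beta0", "beta1", "beta2"):
            draws = orig[key]
            for i, name in enumerate(sp):
                d = draws[:, i]
                rows.append(self._row(f"{key}[{name}]", d,
                                      self.rhat.get(f"{key}[{i}]", np.nan)))
        for i, name in enumerate(sp):
            d = self.stacked("eta")[:, i]
            rows.append(self._row(f"eta[{name}]", d, self.rhat.get(f"eta[{i}]", np.nan)))
        for key in ("phi", "sigma_lam", "sigma_delta"):
            rows.append(self._row(key, self.stacked(key), self.rhat[key]))
        return pd.DataFrame(rows).set_index("parameter")

    @staticmethod
    def _row(name, d, rhat):
        lo, hi = np.percentile(d, [2.5, 97.5])
        return {"parameter": name, "mean": d.mean(), "sd": d.std(),
                "hdi_2.5%": lo, "hdi_97.5%": hi, "r_hat": rhat}

    def structural_zero_probs(self) -> np.ndarray:
        """Posterior draws of the species-level structural-zero probability
        (inverse-logit of eta), shape (n_retained, S)."""
        return expit(self.stacked("eta"))

    def to_dataframe(self) -> pd.DataFrame:
        """All retained draws in long columnar form (one row per draw)."""
        cols = {}
        for key in ("beta0", "beta1", "beta2", "eta"):
            arr = self.stacked(key)
            for i, name in enumerate(self.model.data.species_ids):
                cols[f"{key}[{name}]"] = arr[:, i]
        for key in ("phi", "sigma_lam", "sigma_delta", "f_mean"):
            cols[key] = self.stacked(key)
        nk = self.draws["phi"].shape[1]
        cols["chain"] = np.repeat(np.arange(self.schedule.n_chains), nk)
        cols["draw"] = np.tile(np.arange(nk), self.schedule.n_chains)
        return pd.DataFrame(cols)
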