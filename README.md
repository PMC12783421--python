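# brownfish

Freshwater **browning** — the darkening of lakes by terrestrial dissolved
organic carbon (DOC) and iron — alters light, heat and food webs, with
consequences for fish. `brownfish` implements, as a tested and reusable
pipeline, a set of analyses linking browning to fish at three levels of
organization, together with a seeded synthetic-data generator that emulates
the statistical structure of the (undeposited) government lake surveys these
analyses were designed for.

The package is aimed at quantitative ecologists and biostatisticians who
want to apply the same models to their own lake-survey data, or to study
the behaviour of the estimators under known truth.

## What it computes

**1. A composite browning index (BPC1).** Three partially missing metrics —
DOC (mg l⁻¹), Secchi transparency (m), water colour (mg Pt l⁻¹) — are
Box-Cox transformed (exponent chosen by profile log-likelihood on a grid),
standardized, and fed to a Bayesian probabilistic PCA with an
automatic-relevance shrinkage prior. The EM fitter imputes missing entries
in its E-step, so lakes with partial records are retained. The oriented
first-component score is the browning index (larger = browner); a nomogram
maps scores back to raw metric values.

**2. A zero-inflated negative binomial (ZINB) abundance model.** Counts
y_ij of species *i* in lake *j* follow a mixture of structural zeros
(probability π_ij, logit-linear in species and lake random effects) and a
negative binomial with dispersion φ and log-mean

log μ_ij = β₀ᵢ + β₁ᵢ x_j + β₂ᵢ x_j² + f(u_j, v_j) + λ_j,

where x is BPC1 (or log DOC in a sensitivity mode), f is a low-rank
thin-plate spline trend surface on easting/northing, and λ_j is a lake
random effect that absorbs unknown sampling effort and catchability (the
catch-equation argument: both enter log-additively, so they are estimated
rather than supplied as offsets). Fitting is by an adaptive
Metropolis-within-Gibbs sampler; convergence is monitored with
Gelman–Rubin diagnostics (arviz).

**3. Mean position along the gradient.** For each retained posterior draw,
counts are simulated from the fitted ZINB at M = 2001 equidistant BPC1
values spanning the observed range; the count-weighted average
B = Σⱼ cⱼxⱼ / Σⱼ cⱼ summarizes where a species' predicted abundance
concentrates, reported as a posterior mean with a 95% credible interval.

**4. A reduced joint species distribution model (JSDM).** Presence–absence
z_ls ~ Bernoulli(Φ(a_s + b_s·BPC1_l + w_l)) with species browning slopes
b_s modelled by a trait regression (relative eye size, mouth size, mouth
position) plus a phylogenetically correlated residual
(covariance σ²[ρ·C_phylo + (1−ρ)·I], Brownian C from a newick tree) and a
spatial Gaussian-process effect w with exponential distance decay. Gibbs
sampling with probit data augmentation; outputs include trait effects,
browning-vs-space variance partitioning and Tjur R² per species.

**5. Literature evidence tallies.** Reported browning–fish effects are
normalized to a common "increasing darkness" polarity (Secchi flips;
mortality is recoded to survival) and cross-tabulated by response category
with corpus bookkeeping (papers, datasets, datasets per paper).

## Worked example

```python
import numpy as np
from brownfish import (SimConfig, ZINBTruth, gen_browning_metrics, gen_spatial_lakes,
                       gen_counts_zinb, fit_browning_index, ZINBAbundanceModel,
                       SamplerSchedule, species_positions)

cfg = SimConfig(n_lakes=300, n_species=6, seed=42, trend_amplitude=0.0,
                zinb_truth=ZINBTruth(
                    beta0=(1.5, 1.2, 1.0, 0.8, 1.4, 1.0),
                    beta1=(0.8, -0.8, 0.8, -0.8, 0.8, -0.8),
                    beta2=(-0.1,) * 6,
                    structural_zero_logit=(-2.2, -2.2, -2.2, 0.4, 0.4, 0.4)))

lakes, _ = gen_browning_metrics(cfg)
index = fit_browning_index(lakes)
print(f"BPC1 explains {index.variance_explained:.1%} of metric variance")
print("correlations:", {m: round(r, 2) for m, r in index.correlations.items()})

coords = gen_spatial_lakes(cfg)
data, truth = gen_counts_zinb(cfg, coords, index.bpc1)
model = ZINBAbundanceModel(data, n_spline_basis=0)
results = model.fit(SamplerSchedule(n_chains=2, n_iter=3000, burn_in=1500,
                                    thin=3, seed=1))
print("converged:", results.converged)
print(results.summary().loc[["beta1[sp1]", "beta1[sp2]", "phi"]].round(2))
positions = species_positions(results, m=2001, seed=1)
print(positions.round(2))
```

prints

```
BPC1 explains 84.7% of metric variance
correlations: {'doc': 0.92, 'secchi': -0.92, 'colour': 0.93}
converged: True
            mean    sd  hdi_2.5%  hdi_97.5%  r_hat
parameter
beta1[sp1]  0.68  0.09      0.52       0.86   1.03
beta1[sp2] -0.96  0.09     -1.14      -0.77   1.02
phi         1.60  0.20      1.20       1.97   1.01
  species  mean_B  lo95  hi95  n_dropped
0     sp6   -2.71 -3.35 -1.45          0
1     sp4   -1.95 -2.91 -0.95          0
2     sp2   -1.49 -2.04 -1.06          0
3     sp1    0.85  0.64  1.04          0
4     sp5    0.97  0.73  1.21          0
5     sp3    1.01  0.77  1.23          0
```

The index is dominated by one factor with the expected sign pattern
(+DOC, −Secchi, +colour). The fitted browning slopes recover the
generating ±0.8 values (the mild attenuation of β₁[sp1] reflects using the
*estimated* index as the predictor), and the mean-position statistic ranks
every positively responding species above every negative one, with 95%
intervals well separated from the gradient midpoint.

A command-line interface mirrors the library:
`brownfish simulate | index | fit-abundance | position | fit-community |
tally` (see `brownfish --help`).

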