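# Methods

This note documents the models implemented in `brownfish`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Composite browning index

**Transforms.** Each metric (DOC, Secchi, colour) is Box-Cox transformed
with the exponent λ maximizing the normal profile log-likelihood over a
201-point grid on [−1, 1]. Ties (within 1e-9 of the maximum) are broken
toward the nearest canonical exponent {0, 1/4, 1/2, 1}, so flat profiles
yield recognizable transforms (log, fourth root). Zeros are accommodated
by a half-minimum shift; negative values are rejected.

**Model.** After column standardization on observed entries, the matrix is
fitted by probabilistic PCA, y = Wx + μ + ε with isotropic noise and an
automatic-relevance (ARD) prior on the columns of W (precision α_k updated
as d/‖w_k‖²), which shrinks irrelevant components so single-component
extraction is well defined. The EM fitter handles missing entries exactly:
the E-step computes the latent posterior from each row's observed subset
(grouped by missingness pattern) and fills missing entries with their
conditional expectation; the M-step updates W, σ² and the ARD precisions.
Convergence is declared when the relative change of the penalized
observed-data log-likelihood falls below 1e-6 (default; max 2000
iterations, error with the objective trace otherwise). A debug flag
asserts the objective is non-decreasing each iteration.

Variance explained is model-based: eigen-structure of WWᵀ + σ²I, so the
three component fractions sum to 1 when all are extracted and are
non-increasing. Scores are rotated to principal axes and oriented so BPC1
correlates positively with transformed DOC (the PCA sign is arbitrary;
"browner = larger" is the convention throughout).

**Standardization choice.** Whether columns were centred or z-scored
before the original analysis is not stated anywhere we could rely on;
z-scoring was chosen so loadings are comparable across metrics measured in
different units, and is flagged here as a package decision. ARD
hyperpriors are the uninformative defaults of the classic algorithm.

**Nomogram.** For a grid of scores, predicted transformed values
(loading × score × column SD + column mean) are inverse-transformed to the
measurement scale; each column is monotone in the score with direction
given by the loading sign. Scores outside the inverse-transform domain are
clipped with a warning.

## ZINB abundance model

**Likelihood.** p(y=0) = π + (1−π)NB(0|μ,φ); p(y) = (1−π)NB(y|μ,φ) for
y > 0, NB parameterized by mean μ and dispersion φ (variance μ + μ²/φ),
φ shared across species. The printed two-branch form of the mixture is
implemented in the standard way (the zero branch includes both structural
and sampling zeros). log μ carries species intercepts, linear and
quadratic browning terms, the spatial smooth and a lake effect; logit π
carries species intercepts and a lake effect. The quadratic term enters
the count mean only, never the zero-inflation part.

**Identifiability.** The generating model distinguishes species fixed
intercepts β₀ᵢ from a species random effect γᵢ; one dataset cannot
separate them, so the fitter absorbs γᵢ into species-specific intercepts
(and the zero-inflation species effect ηᵢ is a free per-species
parameter). The generator keeps both, and recovery tests compare against
their sum.

**Spatial smooth.** Low-rank thin-plate regression basis: a {1, u, v}
null space plus r²log r kernel columns about farthest-point (maximin)
knots, reparameterized onto the subspace orthogonal to the plane at the
knots so the bending-energy penalty is positive semi-definite. Default
basis dimension 20 (no dimension is prescribed anywhere; 20 is a common
low-rank choice at a few hundred sites). In the model the smooth is
centred and its intercept dropped for identifiability next to β₀ᵢ.

**Priors.** Not stated for the original fits (a general-purpose package's
defaults were used there); here they are explicit and weakly informative
at survey-count scale: normal(0, 2.5) on all regression coefficients and
ηᵢ, half-normal(0, 1) on random-effect SDs, exponential(rate 0.2) on φ,
normal(0, 2.5) on spline coefficients combined with the bending-energy
penalty as a Gaussian precision. The predictor is centred and scaled
internally; slopes are reported back on the original scale.

**Sampler.** Adaptive Metropolis-within-Gibbs. Species-level parameters
are conditionally independent across species given the shared parameters,
and lake effects across lakes, so whole blocks are proposed and
accepted element-wise in vectorized sweeps; the φ-dependent gammaln terms
are cached between φ updates. Two extra moves travel along the
scale/effect funnels: (σ, effects) → (cσ, c·effects) joint rescalings for
both lake-effect vectors, whose Gaussian-prior and Jacobian terms cancel.
Proposal scales adapt by Robbins–Monro toward 0.44 (scalar) / 0.25
(joint) acceptance during burn-in only, so retained draws come from a
fixed Markov kernel. Default schedule 4 chains × 7000 iterations, burn-in
5000, thin 2 (4000 retained); convergence flag requires Gelman–Rubin
R̂ < 1.1 for all top-level parameters (a threshold the package fixes;
the diagnostic itself is standard). Non-converged fits are returned with
`converged=False`, never silently.

## Mean gradient position

The grid is M equidistant points spanning the observed predictor range
(default M = 2001). For each retained draw and grid point one integer
count is simulated from the full mixture (structural-zero Bernoulli, then
NB), using that draw's parameters. How lake effects and the trend surface
enter grid predictions is a genuine choice: here a fresh lake effect is
drawn per (draw, grid point) from the fitted lake-effect distribution and
the surface is fixed at its average over observed lakes, so B isolates
the browning gradient. B = Σc·x/Σc per draw; all-zero rows (possible for
rare species) are dropped with a logged count, and the summary is the
mean with an equal-tailed 2.5/97.5% interval (the most common reading of
a "95% credible interval"; not HPD). B is invariant to count rescaling
and monotone under rightward mass shifts.

## Reduced JSDM

Occurrence is probit-Bernoulli with species intercepts, species browning
slopes and a lake-level spatial effect. Slopes follow a trait regression
(intercept + three standardized morphological ratios) with residual
covariance σ²[ρ·C + (1−ρ)I], C the Brownian phylogenetic correlation from
the newick tree (shared root-path length to the MRCA, scaled to unit
diagonal); ρ has a uniform prior on a 21-point [0, 1] grid. The spatial
effect is a zero-mean Gaussian process with correlation exp(−d/range)
(great-circle distance for lat/lon, Euclidean for planar synthetic
coordinates); the decay range has a uniform prior on a 15-point log-spaced
grid between 5% and 100% of the maximum inter-lake distance, and the GP
variance an inverse-gamma(2, 1) prior. This replaces the latent-factor
spatial machinery of general JSDM software with an explicit GP random
effect — a deliberate, documented reduction, not an emulation.

Sampling is Gibbs throughout: truncated-normal data augmentation for the
probit, a joint Gaussian update of all intercepts and slopes (2S-dim,
with the phylogeny coupling the slope block), conjugate updates for trait
coefficients and both variances, griddy-Gibbs for ρ and the range, and a
level-swap move redistributing the common level between intercepts and
the GP (likelihood-invariant; priors decide), which decorrelates the two
weakly separated levels. Default schedule 3 chains × 10,000, burn-in
5000, thin 5 (3000 retained).

Species with zero or full prevalence are flagged and retained with a
warning (their intercepts are prior-dominated). A configurable
contiguous-region filter (bounding box or region tags) drops
geographically sparse lakes before fitting, since isolated points
destabilize the range estimate.

**Variance partitioning.** Per species and draw, Var_l(b_s·x) and
Var_l(w) are each divided by their sum, so the two shares add to 1 by
construction; posterior means are reported per species and averaged. This
construction-based definition is an interpretation of partition output
from general JSDM software, and is labelled as such. Tjur R² (mean fitted
probability among presences minus absences) is computed from
posterior-mean probabilities.

## Evidence tallies

Effect classes {none, ±linear, ±quadratic} are recoded by the product of
the metric polarity (−1 for Secchi, which decreases with darkness) and the
response polarity (−1 for mortality recoded to survival): a product of −1
flips neg↔pos, for linear and quadratic classes alike (the quadratic
convention is a package decision; sources address only "directionality").
The flip is an involution and the normalization idempotent. Multiple
metrics or responses within one study count as separate datasets
(inclusive counting). The packaged fixture is synthetic — built
deterministically to reproduce only the published marginal counts
(59 papers, 305 datasets, 1–16 per paper; 38/20 foraging, 35/16 growth,
12/10 survival) — because per-cell counts are not printed in text; users
substitute their own evidence export for real analyses.

## Synthetic-data generator

One master seed feeds named `SeedSequence` child streams (browning,
spatial, counts, phylo, community, evidence), so generators are pure
functions of their configuration and independently reproducible.

- **Browning metrics:** one latent N(0,1) factor per lake; transformed
  metrics are centre + scale·(loading·z + noise) with loadings (1, −1, 1)
  and noise SD 0.52, chosen so the first component carries ≈86% of the
  standardized variance — the share the pooled real compilation exhibits.
  Default missingness (10.2%, 10.8%, 1.3%) is completely at random
  (matching the imputation model's assumption; the true mechanism is
  unknown), with all-missing rows re-masked. Centres/scales put raw values
  in realistic survey ranges (DOC ~1–30 mg l⁻¹, Secchi ~0.5–8 m, colour
  ~5–150 mg Pt l⁻¹). Rows whose inverse transform leaves the positive
  domain are redrawn; a rejection rate above 50% is an error.
- **Spatial trend:** a deterministic standardized quadratic bowl scaled by
  `trend_amplitude` — deterministic so the spline term has an exact known
  target (a GP draw would not).
- **Counts:** the exact ZINB forward model, all latent draws stored.
  Default truth: 8 species with intercepts ≈ e⁰·⁶–e¹·⁵ counts, slopes
  ±0.3–0.8, weak negative quadratics, structural-zero probabilities
  0.1–0.6, φ = 1.5 — zero fractions near 50% and strong overdispersion,
  the regime the model was built for.
- **Phylogeny/traits:** a Yule (pure-birth) tree normalized to unit depth;
  traits evolve by Brownian motion and are squashed to (0,1) by a logistic
  map (morphological ratios are bounded). A star tree can be injected for
  null checks.
- **Communities:** slopes = trait regression (eye effect +0.5 per SD,
  mouth size 0, mouth position −0.15) + phylogenetically correlated
  residual; occurrence via the probit model with a GP spatial effect
  (range 20 on a 100-unit domain).
- **Evidence:** 59 papers, 1 + Poisson(4.17) datasets each (capped at 16),
  hitting ≈305 datasets in expectation.

**What passing tests show — and don't.** Recovery tests demonstrate that
the estimators recover the parameters of their own generating model at
realistic sizes (300 lakes × 6 species; 150 lakes × 30 species). Real
surveys violate these assumptions in ways the generator does not emulate:
missingness correlated with lake type, gear- and effort-structured
detection, regional chemistry differences (e.g. iron-driven browning),
non-Brownian trait evolution, and abundance-to-presence conversions of
heterogeneous monitoring programs. Test scales were chosen to exercise
the estimators at survey-like sizes while keeping the full suite and the
acceptance script fast on a single CPU; posterior uncertainty at these
scales is wider than a 10,000-iteration production run would give.

## Numerical details

- ZINB log-pmf guards all parameter domains explicitly (errors, not NaN);
  log-means are clipped at ±30 inside the sampler so extreme proposals are
  rejected by likelihood rather than overflow.
- The spatial correlation matrix gets a multiplicative jitter (with a
  warning) when duplicate coordinates make it singular; the bending-energy
  penalty clips negative eigenvalues at 0 (numerical noise).
- Box-Cox inversion returns NaN outside its domain; the nomogram clips
  such values with a warning, the generator redraws them.
- Equal-tailed percentile intervals everywhere; no HPD.
- Retained-draw bookkeeping is exact: chains × floor((iters − burn)/thin),
  with a warning when thinning does not divide evenly.

## Known limitations

- The two samplers are single-threaded; chains run sequentially.
- φ is shared across species, as the likelihood is written; species-
  specific dispersion would need a small extension.
- The JSDM couples traits/phylogeny to browning slopes only (intercepts
  get an exchangeable prior); full trait-by-intercept coupling as in
  latent-factor JSDM software is out of scope.
- Catch-equation quantities (catchability q, effort E) are documentation
  of why lake/species random effects absorb effort; they are deliberately
  not implemented as code.
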