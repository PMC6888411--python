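# Methods

This note documents the models, priors, numerical choices and known
limitations of `stprev` in one place.  The README gives the model
equations; here the emphasis is on what was decided where the design was
genuinely open, and on what the synthetic experiments do and do not show.

## Data model and containers

Observations are binomial counts `O` out of totals `n` on a region × wave
grid, one layer per outcome (one for a single-sex analysis, two for the
joint sex-specific analysis).  Totals must be positive: a region–wave cell
with nobody surveyed is not representable, and the loaders reject it
rather than carrying a zero-information cell through the likelihood.
Panels are validated strictly against the region graph and wave list on
load; the CSV schema is long format (`region, year, sex, cases, total`,
plus optional covariate proportion columns).

The areal structure is a symmetric binary contiguity matrix `W` with
neighbour counts `D`; intrinsic CAR computations use the combinatorial
Laplacian `D − W`.  The bundled seven-province preset encodes land borders
among the surveyed provinces only (Shandong–Jiangsu, Shandong–Henan,
Henan–Hubei, Hubei–Hunan, Hunan–Guangxi, Hunan–Guizhou, Guangxi–Guizhou);
borders with unsurveyed provinces are not represented.  Any other
adjacency can be supplied as a plain edge list, and a BUGS-style
`(num, adj, sumNumNeigh)` export is available for cross-checking against
older tooling.

## Temporal basis

Calendar years are centred at 2004 and the trend is a cubic regression
B-spline with clamped boundary knots at the centred extremes (−13, 11 for
the 1991–2015 waves).  The full clamped basis has L + 4 columns whose rows
sum to one; the **first** column is dropped so a free intercept remains
identifiable, leaving K = L + 3.  Any single column drop restores
identifiability — dropping the first is fixed here for reproducibility.
One consequence worth knowing: at the first wave the retained columns all
vanish (the dropped boundary column is the only one alive there), so
fixed-trend contrasts are reported from the second wave onwards.

Interior knots are chosen by greedy forward selection starting from the
mandatory knot at 0 (the centre year): each remaining candidate is added
in turn, the model refitted, and the candidate with the largest DIC drop
accepted until the best drop falls below 2 — the conventional materiality
threshold for DIC differences.  Candidate positions default to the centred
interior waves.  The fit function is injectable so the search logic can be
exercised with a cheap penalised-GLM criterion in tests; the production
path refits by MCMC.

## Priors

- Fixed effects (intercepts, fixed spline coefficients, covariate
  coefficients): Normal(0, variance 10⁴).
- Exchangeable spatial blocks (`u` in the convolution model; shared `b_0i`
  and sex-specific `b_ji` in the shared-component model): Normal(0,
  variance 10⁴).  The variance reading of "N(a, b)" was validated against
  the shared-weight statement below.
- Structured blocks: intrinsic CAR for `s` and for the space–time
  interaction `β_it` (independent across waves — the minimal structure
  consistent with "a CAR prior"); intrinsic MCAR with precision
  `(D − W) ⊗ Γ` for random spline coefficient matrices; independent ICAR
  per column for the sex-specific spline coefficients.
- Precisions: gamma(5, 5·10⁻⁴), shape–rate.  `Γ`: Wishart with identity
  scale and df = K (the weakest proper choice).
- log δ_t: Normal(0, variance 0.169), independent across waves.  With this
  variance P(δ² ∈ [1/5, 5]) = 0.9497, matching the stated 95% design; the
  precision reading of 0.169 would not, which is how the variance
  convention was fixed.  A temporal smoothness prior on δ_t would be a
  reasonable alternative; independence was chosen as the minimal reading.

A dimensional note on the MCAR: this prior is sometimes written with an
identity matrix in place of `D` in `(D − W) ⊗ Γ`, which cannot be
conformable with the N × N adjacency `W` when the identity is sized K × K;
the standard intrinsic MCAR with `D` the neighbour-count diagonal is what
is implemented.

## Covariate extension

Regional covariates (proportions aged ≥ 60, overweight, ever-smokers,
drinkers) enter the linear predictor linearly with vague normal priors;
coefficients are per sex in the joint model.  A time-varying mode expands
each coefficient in the fixed spline basis, `b_c(t) = Σ_k β_ck B_k(t)`,
to let covariate effects drift over the study period.  Constant effects
are the default; reports are on the odds-ratio scale (exp of the
coefficient).

## Sampler

Inference is an own adaptive Metropolis-within-Gibbs sampler:

- Latent effects update by single-site Gaussian random-walk Metropolis,
  vectorised via graph colouring: regions are partitioned into independent
  sets, and all sites of one colour are proposed and accepted in parallel
  (no two are Markov-blanket neighbours).  Rows of spline-coefficient
  matrices update as small blocks the same way.
- Precisions with gamma priors and the Wishart-prior `Γ` are conjugate
  given the quadratic forms of their blocks and update by Gibbs (the
  intrinsic ranks, N − 1 per column, enter the shape/df updates).  The
  sensitivity variants (uniform on the sd, half-normal on the variance)
  are non-conjugate and update by Metropolis on log τ with the exact
  transformed densities.
- Proposal scales adapt per site during burn-in only (Robbins–Monro
  toward 0.44 acceptance for scalars, 0.24 for row blocks) and freeze at
  the end of burn-in, so kept draws come from a fixed Markov kernel.
- Intrinsic blocks are recentred every sweep.  Where an exact absorber
  exists the level moves there (`s` level into α₀; spline-column means
  into the fixed spline coefficients), which leaves both likelihood and
  intrinsic prior unchanged.  The shared spline columns and `β_it` in the
  joint model have no exact absorber — the shared term is scaled by δ_t —
  and are plainly recentred, the classic GeoBUGS-style treatment of
  intrinsic blocks; the recovery experiments below are the empirical check
  that this approximation is benign at study scale.
- The vague exchangeable blocks create a near-flat direction against the
  intercepts (only their sum is likelihood-identified).  Two extra moves
  keep that direction mixing: an exact directional Gibbs step
  redistributing the level between an intercept and its iid block, and a
  Metropolis level move between the shared spatial block and the two
  intercepts.  A corollary users should expect: the *marginal* posterior
  of an intercept alone is very wide by construction; identified
  quantities (prevalence surfaces, fixed-trend contrasts, centred spatial
  contrasts, δ_t, η_j(t)) are what the reports summarise, and the
  convergence gate (R̂ < 1.1) monitors those surfaces plus the deviance
  rather than raw blocks.

Initialisation defaults to "jitter": intercepts at the empirical pooled
logit, everything else small Normal(0, 0.1²) noise (restricted to blocks
the model variant actually includes).  Honest prior draws are available
(`init="prior_draw"`) but start fixed effects at |logit| ≈ 100 and burn in
very slowly, so they are not the default.  Zero-initialisation is also
available.

The documented full-run protocol is 2 chains × 100,000 iterations, 50,000
burn-in, thinning 10.  Tests, the bundled analyses and the acceptance
script use the desk-scale protocol (2 × 4,000, 2,000 burn-in, thin 2 —
2,000 kept draws), which the recovery experiments show is adequate for
panels of this size (7 regions × 9 waves).  Kept-draw accounting is
`chains × ceil((n_iter − burn_in)/thin)` exactly.  Runs are bit-reproducible
from the seed; chains derive independent streams from a seed sequence.

## DIC

`Dbar` is the mean of the per-draw deviance (−2 log-likelihood including
binomial coefficients); `D(θ̄)` plugs the posterior mean of every
parameter block into the linear predictor (the classic plug-in on the
natural parameterisation); `pD = Dbar − D(θ̄)`; `DIC = Dbar + pD`.  A
fully frozen model yields pD = 0 exactly.  Model comparison tables refuse
to mix fits whose data fingerprints differ.

## Synthetic data generator

The generator runs the models forwards: fixed effects plus
spatial/spline/interaction blocks (either frozen at supplied values or
drawn from their priors), binomial sampling of cases, totals drawn
uniformly from 200–1,500 per cell, optional covariates with regional
baselines, linear drifts and small wave-to-wave wiggle (clipped to
[0.01, 0.99]).  The survey-like preset mimics the published panel's
*shape*: seven contiguous provinces, nine waves 1991–2015, male
prevalence rising ≈ 0.13 → 0.38 and female ≈ 0.11 → 0.31 (logit-linear
with mild late-period steepening), δ_t = 1, and moderate invented
random-effect scales (shared spatial sd 0.15, sex-specific spatial sd
0.10, interaction sd 0.1).  All latent parameter values are synthetic
inventions tuned only to those pooled anchors; nothing else about the
restricted survey is emulated — no survey design, no individual-level
covariate structure, no measurement error.  Passing tests therefore
demonstrate self-consistency of the machinery on model-generated data,
not validity for any particular real survey.

Recovery/coverage experiments draw the random-effect *hyperparameters*
from their own priors (prior-predictive simulation), which is the regime
in which 95% credible intervals have exactly nominal coverage.  Simulating
instead with a fixed invented random-effect scale that conflicts with the
informative gamma(5, 5·10⁻⁴) precision prior produces intercept coverage
around 75–85% — a prior-mismatch effect, not a sampler defect — which is
why the calibration checks use the prior-predictive design and the
realistic-looking preset is reserved for the pipeline demonstrations.

## Moran screening

Global Moran's I uses binary (unstandardised) weights; the scale is
absorbed by S₀.  Significance is a one-sided (greater) Monte-Carlo
permutation test, `p = (1 + #{I* ≥ I})/(1 + n_perm)`, default 9,999
permutations — exact under exchangeability and assumption-free at N = 7.
Note the discreteness at small N: a binary ±1 pattern on seven regions
has only 35 distinguishable relabellings, so its smallest attainable
one-sided p is 1/35 and a 3-vs-4 split of a clustered pattern bottoms out
at 2/35 ≈ 0.057; graded values do not have this floor.

## Numerical choices

- Binomial log-likelihood as `O·η − n·log(1 + e^η)` with `logaddexp` —
  exact and overflow-safe for any finite logit.
- Intrinsic kernels carry their rank-deficient normalisers
  (`(N − 1)/2 · log τ` per column) so precision updates see the correct
  exponents.
- CSV exports round floats to 12 significant digits and round-trip
  exactly at that precision; summary JSONs are key-sorted so reruns are
  byte-comparable.
- Quantiles are central 95% intervals from the empirical draw quantiles.

## Limitations

- The proper-CAR variant (with an autocorrelation parameter), Poisson/log
  link variants, WAIC/LOO, and choropleth rendering are out of scope.
- The plain recentring of the shared spline columns and β_it is an
  approximation (exact only when an absorber exists); at study scale the
  coverage experiments show no measurable distortion, but users fitting
  much larger graphs with strongly time-varying δ_t should revalidate.
- δ_t has independent priors per wave; a smoothness prior might be
  preferable when T is large.
- The sensitivity harness refits only the structured-interaction
  precision's prior (τ_β in the joint model, τ_s in the single-outcome
  model), mirroring the usual robustness table; other hyperpriors are held
  fixed.
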