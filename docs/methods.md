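# Methods

This note documents the model, the sampler, the synthetic-data generator,
and the numerical and design choices behind `msom`, in the spirit of a
statistical-software methods appendix.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and assumptions

The package implements the community (multispecies) site-occupancy model
with data augmentation.  Binary indicators form three linked Bernoulli
layers: supercommunity membership `w_i ~ Bern(Ω)`, site occupancy
`z_ij | w_i ~ Bern(w_i ψ_ij)`, and detection
`y_ijk | z_ij ~ Bern(z_ij p_ijk)`.  Occupancy and detection probabilities
are logit-linear in standardized covariates with species-specific
coefficients drawn from community-level normal distributions.  Assumptions
inherited from this model family:

- **Closure.** A site's occupancy state `z_ij` is constant across all its
  replicate surveys (including the two host-plant visits at "both" sites,
  which occur on different days within one season).
- **Independence across sites and replicates** conditional on the latent
  states and covariates.
- **Exchangeability of species** given the community hyperparameters; all
  completely undetected taxa are statistically identical, which is why
  summaries report a single representative augmented taxon.
- **No false positives**: a detection implies presence (`z = 1` is forced
  wherever `y = 1`).

The survey layout is the two-host-plant design: each site offers
*Pycnanthemum muticum*, *Liatris spicata*, or both; each available plant
contributes a fixed number of replicate inflorescence surveys (default 5).
Slots for an unavailable plant are missing cells; the missing pattern is
identical across taxa and propagates unchanged into augmented slices.
Missing cells contribute exactly zero to every likelihood; on the
standardized scale missing survey covariates are stored as 0 (the
covariate mean), an inert fill value.

## Priors

Defaults follow the minimally informative set standard for this model
family (`msom.priors`): `Ω ~ Beta(0.001, 1)` (anchors the estimated pool
near the observed taxon count unless the data insist otherwise); community
mean intercepts are inverse-logit of Uniform(0, 1) draws — a standard
logistic prior on the logit scale, flat on the probability scale; community
mean coefficients are Normal(0, variance 10); community SDs are
Uniform(0, 4), with Uniform(0, 5) for the categorical host-plant
coefficient.  `sample_induced_prior` reproduces the induced-prior
calibration behind those choices (coefficient-mean central 95% interval
≈ ±6.2 on the logit scale, covering −5..5; intercepts flat on (0, 1)); the
empty-dataset prior-recovery test in the suite verifies that the sampler
reproduces these distributions when every observation is missing.

## Sampler

`run_chain` (numba) is Metropolis-within-Gibbs:

- **(w, z) blocked Gibbs.** For detected taxa `w = 1` and each `z_ij`
  follows its exact full conditional
  (`Pr(z=1) = ψ q / (ψ q + 1 − ψ)` with `q` the probability of zero
  detections).  For undetected taxa, `w` is drawn from its *marginal*
  conditional with `z` integrated out, then `z | w`.  One-at-a-time
  updates mix very slowly here (an augmented taxon with occupied sites
  must first lose all of them before `w` can flip), and the blocked update
  removes that bottleneck; it raised the effective sample size of `Ω` by
  roughly two orders of magnitude on weak-data fits.
- **Ω** by Beta conjugacy.
- **Species effects** by adaptive Gaussian random-walk Metropolis, one
  (species, column) at a time; adaptation targets 0.44 acceptance via
  Robbins–Monro on the log proposal scale and freezes at the end of
  burn-in, so retained draws come from a fixed Markov kernel.  Species
  contributing no likelihood (no occupied site for detection terms,
  `w = 0` for occupancy terms) are Gibbs-drawn exactly from the community
  prior.
- **Community means and SDs** by slice sampling (stepping-out/shrinkage) on
  their one-dimensional conditionals; SDs on the log scale with rejection
  outside the uniform support.  Slice updates are tuning-free and removed
  the convergence stragglers that random-walk hyper updates produced on
  20k-iteration schedules.

Likelihood evaluation collapses replicate slots that share one
detection-covariate row (the five inflorescences of a visit) into a
binomial success/trial count — algebraically identical to the Bernoulli
product and about 5× cheaper; a test cross-checks the kernel's deviance
against the standalone cell-wise statistic.  Initialization: `z = 1`
wherever detected else Bernoulli(0.5) given membership; `w = 1` for
observed taxa, Bernoulli(0.5) for augmented; intercepts at the logit of
naive rates clamped to ±3; coefficients at 0; SDs at 1.  Chains are
bit-reproducible given the run seed; chain `c` uses a fixed derived seed.

**Validation oracle.** `exact_posterior_tiny` enumerates every `(w, z)`
configuration of instances up to 3 taxa × 4 sites × 3 slots, integrating
Ω and the species intercepts over quadrature grids.  It shares no code
with the kernel.  The acceptance suite requires MCMC posterior quantities
(latent marginals, Ω, species intercept means) to agree with the oracle
within 3 Monte-Carlo standard errors (MCSE from a Geyer initial-monotone
effective-sample-size estimate).

**Convergence** uses the classic Gelman–Rubin potential scale reduction
factor (not rank-normalized split-R-hat; the suite cross-checks against
arviz on well-mixed chains), with the conservative < 1.05 rule.

## Goodness of fit

The discrepancy is the deviance conditional on the current occupancy draw:
`D = −2 Σ log Bern(y | p)` over observed cells with `z = 1` (cells with
`z = 0` contribute 0; a detection with `z = 0` is an invalid state).  At
every retained draw the kernel records `D_obs` and `D_rep` for one
replicate drawn from the same `(z, p)` (one replicate per retained draw
keeps cost linear).  The Bayesian p-value is the fraction of draws with
`D_rep ≥ D_obs` — ties count toward the p-value — and values outside
(0.1, 0.9) flag unacceptable fit.  Mean per-site and per-taxon observed
deviance contributions are exported for diagnostic plots; their sum equals
the total at every draw (tested).

## Covariate selection

Forward-stepwise screening by influence counts (`msom.selection`): a
coefficient is *influential* for a taxon when its central 95% CrI excludes
0, and a covariate is retained when influential for at least 2 taxa (the
"multiple species" rule; covariates worth dropping in practice show 0–1).
Candidates are fitted one at a time on the current base; the candidate with
the most influential coefficients advances; ties prefer main effects over
interactions, then pool order, making the procedure a deterministic pure
function of fit summaries (tested with stubbed fitters).  Site covariates
are stepped on the occupancy side first; the host-plant term stays in every
detection model; interactions become eligible once both mains are present;
retained mains are re-checked after each advance and dropped when other
covariates absorb their signal.  Pairs with |Pearson r| ≥ 0.6 (boundary
inclusive, pairwise-complete) never co-occur.  Candidate fits may use a
reduced MCMC schedule since only CrI-versus-zero decisions are consumed;
fits with any hyperparameter R-hat ≥ 1.05 are refitted once with a doubled
schedule.

## Synthetic data

`msom.simulate` runs the generative model forward on the survey layout.
Covariate marginals are independent truncated-at-zero normals with the
reference moments of the emulated urban-garden study (distance to urban
center 15 124 ± 12 356 m, garden area 465 ± 431 m², Julian date 193 ± 9,
temperature 32.4 ± 5 °C, light 42 161 ± 25 341 lux, bloom richness
19.6 ± 8.5); survey start time is uniform over the ~09:20–16:45
observation window.  Survey covariates are drawn once per visit and
broadcast to that visit's replicate slots, mirroring once-per-visit field
measurement.  Standardization uses sample moments by default (fixed
reference moments can be injected for exact replication).  What the
generator does **not** emulate: covariate dependence (available only
through an explicit `correlate` injection for screen tests), phenology or
weather structure in the survey covariates, spatial autocorrelation
between gardens, and taxonomy — so passing recovery tests demonstrate
statistical correctness of the estimator under the model's own
assumptions, not robustness to real-data violations of them.

Two presets:

- `reference` — community truth at the posterior centre of the emulated
  study (Ω 0.45; logit-scale occupancy intercept −1.37 ± 2.47; detection
  intercept −3.12 ± 2.73; *L. spicata* shift −1.37 ± 2.85), 49-taxon pool.
  Typically yields 10–20 observed taxa, broadly comparable to 14 of 49.
- `selection_demo` — known detection effects and null occupancy
  covariates for selection-consistency experiments: plant −1.37 ± 2.0 and
  start time 1.0 ± 0.5 on the logit scale; Ω 0.6, occupancy −0.5 ± 1.5,
  detection intercept −2.8 ± 2.0, 15-taxon pool.  These values were chosen
  to match the *data richness* of the emulated system (5–11 observed taxa,
  detection totals of order a few hundred): communities much more
  detectable than that make latent occupancy nearly observed, and chance
  in-sample correlations between site covariates and occupancy patterns at
  50 sites then genuinely clear the two-taxon influence bar — a property
  of the heuristic itself, not an estimation error.

## Problem sizes and checks in the shipped experiments

The validation experiments run at desk scale: oracle comparison on a
2 × 3 × 2 instance with 3 × 40k chains; self-simulation calibration with a
15-taxon pool, 50 sites and 20 replicates of 3 × 20k chains (burn-in 5k,
thin 5); selection consistency over 10 replicates with 2 × 4k candidate
fits.  Statistical assertions use 3σ Monte-Carlo or binomial bands around
the checked quantity.  Coverage of hyperparameter CrIs is assessed pooled
across hyperparameters and replicates: at 20 replicates a per-parameter
binomial check has essentially no power, and at a fixed generative truth
frequentist CrI coverage is not exactly 0.95 parameter-by-parameter —
weakly identified SDs overcover, while the detection-intercept mean (true
value −3.12, in the tail of its standard-logistic prior) undercovers
mildly; the pooled rate is the meaningful calibration summary.

## Numerical choices

- Quantiles (all CrIs): linear interpolation between order statistics
  (`numpy.quantile` default), so intervals are bit-reproducible.
- Probability- and logit-scale values are reported to 2 decimals in output
  tables; medians for integer-valued derived parameters, means for
  continuous ones.
- Stable identities `log σ(L) = L − softplus(L)` and
  `log(1 − σ(L)) = −softplus(L)` throughout the kernel; softplus switches
  to its asymptotes beyond |35|.
- Interactions are products of standardized mains (not re-standardized), so
  covariate value 0 remains "at the mean"; quadratics are squares of
  standardized values, uncentered.
- Duplicate detection records collapse to one detection with a warning (the
  model is detection/non-detection).
- Degenerate traces get R-hat 1 with a warning; constant covariates yield
  an undefined-correlation warning in the screen and are never excluded.
- Ω draws are clamped to [1e−12, 1 − 1e−12] after the conjugate update.

## Known limitations

- The plant effect enters as an indicator product, not a two-level indexed
  coefficient — mathematically equivalent parameterizations.
- No WAIC/DIC model comparison (deliberately; the selection heuristic is
  the supported procedure) and no spatial dependence between sites.
- `PosteriorSamples.save` writes per-chain parameter CSVs with a registry
  sidecar; full mid-chain checkpointing is not implemented — desk-scale
  chains re-run from seed in seconds, which is the supported reproduction
  path.
- The R-hat implementation is the classic PSRF; very short chains can pass
  it while still biased — the oracle-equivalence and prior-recovery tests
  are the substantive correctness checks.
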