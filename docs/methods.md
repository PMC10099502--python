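# Methods

## Setting and data model

The package analyses linked household–outlet family-planning surveys. Three
tables describe a study site:

- **respondents** — one surveyed woman: home coordinates (planar km, site
  centre at the origin), age group, education, marital status, parity, wealth
  indicator, a six-category method-use/linkage outcome, and (for linked users)
  the identifier of the outlet where she obtained her method;
- **outlets** — one service-delivery point: type (public clinic, private
  clinic, pharmacy), coordinates, and structural-quality attributes (number of
  methods offered, stockout of injectables at audit, recently trained
  provider, visible FP signage, open seven days a week, outreach, counselling,
  job aids, prices);
- **links** — respondent → chosen outlet.

All distances are Euclidean, computed from home coordinates. Coordinates are
kept planar by construction, so straight-line distance is exact; geographic
projections, road networks and travel-time models are out of scope.

## Estimation pipeline

1. **Choice sets.** A respondent's choice set is every outlet within a fixed
   radius of her residence (3 km Kenya-like, 2 km Uganda-like). A chosen
   outlet beyond the radius is retained and flagged `out_of_radius` rather
   than dropped — dropping would discard the dependent variable; the flag
   keeps the decision auditable. Respondents with empty sets, or whose set
   collapses to the chosen outlet alone, are excluded from choice modelling
   and reported. Supply-environment covariates (counts of outlets by type,
   outlets with outreach, mean methods offered within the radius) are computed
   for all respondents; a respondent with no in-radius outlet gets zero counts
   and a missing mean.

2. **Selection model and weights.** A multinomial logit over the six
   method-use/linkage categories (reference: no method) on demographics plus
   supply-environment covariates. The fit standardizes covariates internally
   for a stable Newton solve and maps estimates back (the likelihood is
   globally concave, so this affects only the iteration path); the gradient at
   the optimum must be below 1e-5 per observation. Each linked respondent's
   inverse-probability weight is the reciprocal of her fitted probability of
   her *own observed* linked category (5 or 6), rescaled to mean one over the
   estimation sample — normalization stabilizes the weighted likelihood
   without changing relative weighting. Fitted probabilities below 1e-6
   raise an error (the selection model badly misfits those observations).

3. **Screening.** The conditional logit is deliberately overfitted with all
   candidate attributes, then backward elimination removes the attribute with
   the largest Wald p-value above `p_drop` (default 0.3) and refits until all
   retained attributes pass; distance is never dropped, and within-set
   collinear attributes are removed up front and logged. Note the stopping
   rule's arithmetic: an irrelevant attribute's p-value is approximately
   Uniform(0,1), so at `p_drop = 0.3` it survives a given run with
   probability ≈ 0.3.

4. **Choice models.** The conditional logit maximizes the IPW-weighted
   log-likelihood by damped Newton with analytic Hessian (gradient max-norm
   < 1e-5). The mixed logit draws `beta_i ~ N(beta, diag(s^2))` and maximizes
   the weighted *simulated* log-likelihood: per chooser, the probability of
   the chosen alternative is averaged over R Halton draws before taking logs.
   Halton points (bases 2, 3, 5, …; the leading zero point plus a burn of 10
   discarded; one permutation seed) are mapped through the standard-normal
   quantile function; respondents take consecutive shuffled blocks. Defaults
   R = 500, configurable. SD parameters enter unconstrained as `s_k * eta`
   and are reported as `|s_k|`, avoiding boundary failures at zero. BFGS
   optimizes the *average* log-likelihood (scale-free steps) from the
   conditional-logit estimates with SDs started at 0.1; if the solve ends
   below the nested conditional-logit likelihood (a bad basin) it restarts
   from the nest, and a line-search precision stall triggers one fresh-Hessian
   restart. With an empty random set the objective reduces exactly to the
   conditional logit.

5. **Inference.** Standard errors are sandwich (robust) by default: IPW
   weighting breaks the information equality. The mixed-logit bread is a
   central-difference Hessian of the analytic gradient with eigenvalues
   floored at 1e-6 of the largest — an SD estimate at zero leaves the
   objective locally flat, and the floor turns that direction into a
   large-but-finite variance instead of an indefinite matrix. Coefficients
   whose magnitude exceeds 10 raise a separation error: on these utility
   scales (distance weights near −1) such values only arise when an attribute
   level is never (or always) chosen and the likelihood is unbounded.

6. **Likelihood-ratio test.** `2(LL_mixed − LL_clogit)` floored at zero,
   df = number of random coefficients, chi-square upper tail. Under the null
   the SD parameters lie on the boundary of the parameter space, so the
   standard chi-square reference is conservative (simulated size ≈ 2% at
   nominal 5%); a chi-bar-square mixture is deliberately not implemented.

7. **Willingness to travel.** `wtt_k = −beta_k / beta_d` uses the estimated
   coefficient *means* only (one value per attribute, not an individual-level
   distribution). Confidence intervals: delta method by default —
   `var(r) = var(b_k)/b_d² + b_k² var(b_d)/b_d⁴ − 2 b_k cov(b_k,b_d)/b_d³` —
   because it is deterministic and auditable; a simulation method (draw the
   estimates' normal approximation, form ratios, take quantiles) is available
   where the ratio's nonlinearity matters. A distance coefficient below 1e-8
   in magnitude is an identification error, not a huge ratio.

## Synthetic-study generator

The generator emulates the linked-survey design under known truth so every
stage is testable:

- **Geometry.** Outlets uniform in an outer disc (radius 5 km), households
  uniform in a nested inner disc (radius 2 km).
- **Supply.** Two presets mirror the two study settings: Kenya-like
  (pharmacy-heavy mix 921:614:233 scaled to ~59 outlets, 3 km radius) and
  Uganda-like (private-heavy 826:56:18, 2 km radius). Attribute prevalences,
  mean method counts and median prices per outlet type follow the audit-table
  profile of each setting (e.g. public outlets: cheap, most methods, most
  outreach/signage, rarely open 7 days). Method counts are a truncated
  shifted-Poisson on {1..12} targeting the type mean; prices are log-normal
  around the type median (sigma 0.5) since only medians are reported.
- **Selection.** Categories 1–6 are drawn from a multinomial logit on the
  demographics; the default coefficients make linkage more likely for
  married, higher-parity, less-than-college-educated women, mirroring the
  matched/unmatched contrasts of such surveys. Linked respondents with no
  in-radius outlet are demoted to the unlinked twin category (they could not
  have been linked) and reported.
- **Choices.** Each linked woman draws `beta_i ~ N(mean_i, diag(sd²))` — with
  `mean_i` optionally shifted by her covariates — adds independent standard
  Gumbel errors (the conventional additive form of the type-1 extreme-value
  assumption) and picks the argmax. Realized draws are stored for oracle
  tests. Default truth: distance −1.0 (SD 0.5), methods 0.15 (SD 0.1),
  public 2.0 (SD 1.0), signage 0.45, pharmacy 0.5, trained 0.3, open7 0.2,
  stockout −0.3 — chosen so the implied willingness-to-travel ratios sit in
  the plausible 0.1–2 km range for this setting.
- **Informative selection.** Selection on observables only biases the choice
  model if preferences co-vary with those observables. `TruthParams` therefore
  carries optional `preference_shifts`; the `observable_linkage` preset makes
  college-educated women value public outlets much less (−2.0) and top-wealth
  women much less distance-averse (+0.4) while both strongly affect linkage.
  The estimand is the population-average coefficient vector
  (`beta_mean` + shifts × population covariate means); IPW recovers it, the
  unweighted fit does not.

What the generator does **not** emulate: spatial clustering of outlets and
households, repeated survey rounds, measurement error in coordinates or
attributes, outlet-side causes of failed matching (missingness is at random
given observables — exactly the assumption IPW needs), and any dependence of
the choice radius on respondent behaviour. Passing tests therefore demonstrate
the estimators' correctness under the stated assumptions, not robustness to
their violation in field data.

## Simulation designs used in the validation suite

Problem sizes were fixed at design time to balance statistical resolution
against desk-scale runtimes:

- **Parameter recovery:** 20 replicates of the Kenya-like preset with 1,500
  choosers over a 30-outlet supply, R = 200; means and SDs within 3 reported
  SEs of truth for ≥ 80% of parameters.
- **WTT recovery / CI coverage:** the same 20 fits for point recovery (within
  3 delta SEs for ≥ 90%); coverage over 300 reduced replicates (400 choosers,
  same 30-outlet supply, R = 100), pooled across the seven non-distance
  attributes, required in [93%, 97%]. Replicates raising separation or
  identification errors are excluded — coverage is a property of identified
  fits; sparser supplies (e.g. 16 outlets) make a single never-chosen
  attribute level and hence separation common, which is why the 30-outlet
  supply is kept.
- **IPW correction:** 50 replicates of the observable-linkage preset at 5,000
  respondents (~1,300 linked); the weighted fit must beat the unweighted on
  summed absolute willingness-to-travel error in ≥ 70%. The sample size makes
  the consistent estimator's bias advantage dominate sampling noise.
- **LR calibration:** 200 replicates with homogeneous truth (150 choosers,
  R = 50, two random coefficients); rejection rate at 5% must not exceed 5%.

## Numerical choices and edge cases

- Determinism: every stochastic step takes an explicit integer seed; the
  pipeline derives per-stage seeds from the master seed via `SeedSequence`,
  so identical configuration and seed reproduce artifacts byte-for-byte.
- Percentages (linkage rates) are rounded half-up to one decimal, matching
  descriptive-table convention rather than banker's rounding.
- Ties in simulated utilities are broken by stable sort order; they have
  probability zero under continuous Gumbel noise.
- `n_draws < 25` with a nonempty random set triggers a warning (simulation
  noise), not an error.

## Known limitations

- Diagonal `Sigma_beta` only; no correlated random coefficients, no
  non-normal mixing distributions, no panel structure (one choice per woman).
- The willingness-to-travel CIs treat the estimates as asymptotically normal;
  with a weakly identified distance coefficient the delta method is
  unreliable (hence the hard floor and the simulation-based alternative).
- The LR test is conservative at the boundary; a significant result is
  trustworthy, a marginal non-rejection may reflect low power rather than
  homogeneity.
- IPW corrects selection on *observables* only; preference differences
  between linked and unlinked users that are not captured by the covariates
  remain uncorrected.
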