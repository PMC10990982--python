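# Methods

## The problem

In a longitudinal study, inference from a random-effects growth model is
valid under ignorable missingness (MCAR/MAR), but when the probability that
a response is missing depends on the unobserved values themselves (MNAR),
estimates can be biased — and no test on the observed data can establish
which regime holds.  The accepted practice is therefore a *sensitivity
analysis*: fit several models that encode different plausible missing-data
mechanisms and compare the substantive estimates across them.  `patternmix`
implements that workflow for two-level growth curves, with the missing-data
machinery organised around the *pattern* of observed/missing occasions.

## Data model

Long-format records (subject, week, response) with subject-level covariates.
A missing response is the absence of a row.  Patterns are defined over a
configurable subset of *key* occasions (default weeks {0, 1, 3, 6} of a
7-week design); occasions outside this set are treated as valid data when
present but are assumed missing by design (hence MCAR) and excluded from the
pattern definition.  Masks are classified as

* `complete` — all key occasions observed;
* `monotone_dropout` — a prefix of observed occasions, then only missing
  ones;
* `intermittent` — interior gaps, final key occasion observed;
* `mixed` — interior gaps and trailing missingness.

The subject-level dropout indicator is 1 exactly when the final key occasion
is unobserved (monotone and mixed patterns).  Pattern ids are assigned by
descending frequency with ties broken by ascending mask value, which makes
the catalogue deterministic.

**The dropout-time proxy.**  The joint models regress the log of the last
observed week on covariates.  Weeks are renumbered from 1 (i.e.
`ln(max_week + 1)` with 0-based weeks) so the log is defined for subjects
observed only at baseline.  This renumbering is not cosmetic: on the
reference pattern table it reproduces the published dropout-time regression
(intercept 1.63, group effect 0.13, log-variance intercept −1.49 and group
effect −0.31) by closed-form arithmetic, so it is evidently the convention
of the reference analysis.  The offset is configurable (`week_offset`).

**Exact test.**  Independence of pattern and treatment group is tested by a
Monte-Carlo Fisher-type test: tables are sampled from the fixed-margins
hypergeometric null (`scipy.stats.random_table`, Patefield's algorithm) and
the p-value is the fraction with null probability at most that of the
observed table, with the (s+1)/(reps+1) continuity correction.  A network
algorithm would be exact but is unnecessary for a 9×2 table; the MC version
is simple and seed-reproducible.  Cross-checked against R's
`fisher.test(simulate.p.value = TRUE)` during development.

## Growth models

Level 1: `y_ti = f(beta_i, week_ti) + e_ti` with four forms `f`: linear,
linear in `sqrt(week)`, quadratic, and exponential
`b1 − (b1 − b0) exp(−b2 week)` (baseline b0, asymptote b1, rate b2 > 0).
Level 2: each of b0, b1 regressed on an intercept plus subject-level
covariates, with bivariate-normal residuals (u0, u1) ~ N(0, Phi_u).  The
third coefficient of the quadratic/exponential forms is non-randomly varying
(fixed-effect regression, no residual); for the exponential form its linear
predictor is exponentiated so the rate is positive for every covariate
value.  Residual variance is log-linear in covariates,
`sigma2_e(i) = exp(tau' x_i)`, allowing group heteroscedasticity.

Missingness treatments share this core:

* **ignorable** — the growth model alone.
* **fixed pattern-mixture** — the dropout indicator and its covariate
  interaction enter every level-2 regression.  The stratum-specific
  coefficients are averaged over strata per posterior draw,
  `gamma_avg = gamma + pi_drop * Delta`, so the population-averaged effects
  come with exact posterior intervals.
* **random pattern-mixture** — incomplete subjects are clustered by
  pattern; clusters contribute random intercept/slope deviations
  (v0k, v1k) ~ N(0, Phi_v): a three-level hierarchy.  Two cluster sets are
  supported: all incomplete patterns, or the attrition patterns only
  (monotone + mixed); a flag adds the completer pattern as a reference
  cluster.
* **joint dropout-time** — the growth model estimated jointly with the
  normal regression of ln(MaxWeek) on the group covariate, with its own
  log-linear residual variance; the two processes are independent.
* **shared-parameter** — the dropout-time regression additionally loads on
  the subject's growth coefficients (alpha_2 b0i + alpha_3 b1i), making
  dropout time depend on the observed *and unobserved* trajectory through
  the shared random coefficients; setting alpha_2 = alpha_3 = 0 reduces the
  likelihood to the joint model exactly (a unit-tested identity).

**Priors.**  Fixed effects, variance-model and dropout-time coefficients:
N(0, 1000).  The growth intercept may be truncated to the response scale
(default [1, 7], the illness-rating range; disable for unbounded outcomes —
the simulation experiment does).  Phi_u and Phi_v: inverse-Wishart with
dimension + 1 degrees of freedom and identity scale.  With very few pattern
clusters the IW scale is influential — the pattern-level variances on the
reference-size fixture come out larger than a half-t alternative would give;
`PriorSpec.pattern_sd_half_t_df` is carried as a configuration stub for that
variant but the sampler does not implement it.

**Parameter count q** (used for the minimum-ESS bound) counts the scalar
level-2 fixed effects and variance-model coefficients individually, and each
covariance matrix and each auxiliary coefficient block (curvature
regression, dropout-time regression) once — the convention under which the
linear and sqrt-week models have q = 7 and the quadratic and exponential
models q = 8.

## Estimation

A self-tuned random-walk Metropolis-within-Gibbs sampler:

* scalar fixed effects, tau, kappa, alpha: adaptive random-walk Metropolis,
  proposal scales tuned toward 0.44 acceptance during burn-in
  (Robbins–Monro on the log scale, step ∝ t^-0.6) and frozen afterwards so
  the post-burn-in chain satisfies detailed balance;
* subject effects u_i: per-subject bivariate Metropolis steps, vectorized
  across subjects, per-subject scales tuned toward 0.234; pattern effects
  v_k likewise;
* **translation moves**: after the u-update, each level-2 coefficient is
  proposed jointly with an offsetting shift of the random effects
  (gamma_jm += delta, u_j −= delta·x_m), leaving every subject coefficient —
  hence the whole likelihood — invariant, so acceptance depends on the
  priors only.  Scalar conditional updates alone crawl along the
  fixed-effect/random-effect ridge (we measured ESS ≈ 0.5% of draws and
  visible underdispersion against REML standard errors); with the
  translation moves ESS rises roughly eightfold and posterior spreads match
  `statsmodels` MixedLM on the same data.
* Phi_u (and Phi_v): exact inverse-Wishart full conditionals given the
  current random effects (conjugate Gibbs).  This deviates from a pure
  all-Metropolis scheme but targets the same posterior and mixes better.

Initial values come from a pooled least-squares fit (growth coefficients and
residual variance) and the analogous regression for the dropout-time block;
random effects start at zero.

Default chain settings are desk-scale: 200,000 iterations, 10,000 burn-in,
thinning 20.  Reference-quality settings (10M iterations, 50k burn-in, thin
1000) are reachable through `McmcConfig`.  The tests and the acceptance
script use shorter chains (stated per experiment below) chosen so posterior
means are stable to a few hundredths, which is the precision the checks
need.

**Summaries.**  Posterior mean and median; mode as the argmax of a Gaussian
KDE with Silverman bandwidth over the retained draws (the noisiest of the
three — flat-topped densities move the argmax by a few tenths of a posterior
sd); 95% HPDI as the shortest contiguous window containing ceil(0.95 n)
sorted draws (leftmost on ties); ESS by batch means with batch size
floor(sqrt(n)); the minimum-ESS bound
`2^(2/p) π / (p Γ(p/2))^(2/p) · chi2(1−alpha, p) / eps^2` (defaults
alpha = eps = 0.05).  Note the bound is *not* monotone in p everywhere: it
peaks near p = 11 and declines very slowly after; it rises steeply over the
model sizes used here.  DIC is the conditional-likelihood variant (random
effects in focus): p_D = mean deviance − deviance at the posterior means of
every quantity in the likelihood, random effects included.  The marginal
DIC is out of scope.  Reports disclose both conventions in their headers.

## Synthetic data

**Bias-experiment DGM.**  Linear growth for 400 subjects over waves 1–6
(time = wave − 1): gamma = (1, 0.5, 1) for the intercept regression on
(1, X1, X2) and (2, 0.2, 0.5) for the slope; sigma2_e = 0.3;
Phi_u = [[1, .1], [.1, .5]].  X2 ~ N(0,1) is withheld from all fitted
models (an unmeasured confounder).  X1 is binary: a unit-variance latent
0.5·X2 + e_x (Var e_x = 0.75) cut at zero, satisfying simultaneously the
"standard normal latent with cutpoint at 0" and "0.5·X2 + e_x" definitions.
Missingness at waves 2–6 is logistic in (X1, X2) with intercept −1 and
slopes doubling each wave from (0.2, 0.3) to (3.2, 4.8); wave 1 is always
observed.  This produces monotone and intermittent missingness whose
probability rises with the same unobserved quantity that raises the
response — MNAR once X2 is withheld.

Four models are fitted per replicate, each with X1 on both level-2
regressions, homoscedastic residuals, unbounded intercept prior:
(a) ignorable; (b) + a monotone-dropout indicator; (c) + a dropout-timing
covariate counting the trailing missing waves (0 for completers, who are
the reference stratum in both (b) and (c)); (d) a random pattern-mixture
clustering *every* subject by its observation mask, completers forming
their own pattern — under which the fixed intercept is a
population-of-patterns mean rather than being anchored by the completer
stratum.  The bias table reports, per model and parameter, the average
posterior mean across replicates, bias = average − generating value
(an exact identity in the output), and the average 95% HPDI width
(reported, not acceptance-tested: with the binary X1 the omitted-confounder
bias on the X1 coefficients is gamma_x2 · cov(X1, X2)/Var(X1) ≈ 0.8 before
attenuation, larger than the latent-covariate value ≈ 0.5, so interval
widths and those two bias magnitudes are convention-dependent).  Replicate
seeds are base seed + replicate index and are recorded in the output.

What passing shows: under this confounded-missingness DGM the random
pattern-mixture fit has the smallest |bias| of the four models for every
generating fixed effect, and the ignorable fit's intercept bias is clearly
negative while the random pattern-mixture's is near zero.  What it does not
show: performance at the full published scale (100 replicates; we run 6
replicates with 3,500-iteration chains in the routine checks), or behaviour
when the confounder is observed.

**Illness-severity-like fixture.**  A stand-in for the motivating
schizophrenia-trial dataset (square-root-of-week decline of a 1–7 severity
rating, two treatment groups, n = 437).  Treatment groups and missing-data
patterns are assigned by largest-remainder quotas on the reference
pattern-frequency table, so at n = 437 the 9×2 pattern-by-group table is
reproduced *exactly* — every quantity that is a function of that table
(completer count 312, dropout count 102 = 23.34%, expected cell counts, the
exact-test p ≈ .016, and the whole dropout-time regression) is then genuine
computation, not imitation.  Responses follow the reference point estimates
(intercepts 5.34/+0.05, sqrt-week slopes −0.33/−0.65, log residual variance
−0.81/+0.28, Phi_u = [[.47, −.03], [−.03, .32]]) and are clipped to [1, 7].
Mid-weeks 2/4/5 appear with probability 0.03, only before a subject's last
key-week observation, so the last-observed week stays pattern-determined.
Pattern assignment is independent of the responses: the fixture is MCAR by
construction, which matches the reference analysis' own conclusion
(mechanism-insensitive estimates) and makes cross-mechanism agreement a
testable property.  What the fixture does not emulate: any true MNAR signal
in the real data, ordinal measurement, and the mild estimate attenuation
from clipping (the realized slope effect averages ≈ −0.62 against the
generating −0.65, with a per-realization sd of ≈ 0.06 — fit checks
therefore use HPDI coverage and a MixedLM cross-fit on the same realized
data rather than equality with the generating values).

## Numerical choices and degenerate inputs

* Truncated intercept prior: proposals outside the bounds are rejected
  (prior support), including in the translation moves.
* Non-finite proposals are rejected; non-finite retained draws abort the
  run.  A constant chain reports ESS = n with a warning.
* HPDI and ESS require ≥ 100 draws by contract.
* Subjects observed at no key week get the all-zero mask and a warning;
  classification calls them monotone dropouts.
* A single-level grouping variable makes expected counts equal observed,
  with a warning rather than an error.
* Covariance sampling guards: the inverse-Wishart scale is the prior scale
  plus the random-effect cross-product, always positive definite.

## Known limitations

* The sampler is single-machine, single-chain by default (multiple chains
  are run sequentially when requested); no NUTS/HMC, no marginal-likelihood
  machinery.
* The pattern-level variance posterior is prior-sensitive when the number
  of clusters is small (see Priors); the half-t alternative is stubbed, not
  implemented.
* Selection models in which missingness depends directly on the unobserved
  response values (Diggle–Kenward style), multiple imputation, ordinal
  response models and time-varying covariates are out of scope.
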