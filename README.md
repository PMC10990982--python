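# patternmix

Bayesian random-effects growth models for longitudinal data under competing
missing-data mechanisms.

## Who this is for

Analysts of longitudinal outcomes — clinical ratings, behavioural scores,
any repeated continuous measure — who face dropout and intermittently
missing responses and need to know whether their growth-model inference
depends on untestable assumptions about why the data are missing.  Because
no analysis of the observed data can verify that missingness is ignorable,
the defensible practice is to fit a *suite* of models encoding different
plausible mechanisms and compare the substantive estimates across them.
`patternmix` implements that sensitivity-analysis workflow end to end, with
its own Metropolis-within-Gibbs engine, plus a simulation experiment that
quantifies the bias each treatment incurs under a confounded (MNAR)
missingness process.

## The models

The core is a two-level growth curve for response y_ti of subject i at
week t,

    level 1:  y_ti  = f(β_i, week_ti) + e_ti,       e_ti ~ N(0, σ²_e(i))
    level 2:  β_ji  = γ_j0 + γ_j1 x_i + u_ji,       (u_0i, u_1i) ~ N₂(0, Φ_u)

with growth forms f ∈ {linear, √week, quadratic, exponential-to-asymptote}
and log-linear residual variance σ²_e(i) = exp{τ₀ + τ₁ x_i}.  Missing-data
patterns over the key occasions drive five treatments of the mechanism:

| treatment | extension |
|---|---|
| ignorable | growth model alone |
| fixed pattern-mixture | dropout indicator (+ interaction) in every level-2 regression; population effects recovered per draw as γ̄ = γ + π·Δ |
| random pattern-mixture | pattern clusters contribute (v_0k, v_1k) ~ N₂(0, Φ_v): a three-level hierarchy |
| joint dropout-time | growth model fitted jointly with ln(MaxWeek)_i = α₀ + α₁ x_i + ε_i, Var ε_i = exp{κ₀ + κ₁ x_i} |
| shared-parameter | the dropout-time regression additionally loads on the subject's growth coefficients: + α₂ β_0i + α₃ β_1i |

Inference is by a self-tuned random-walk Metropolis-within-Gibbs sampler
(conjugate inverse-Wishart steps for the covariance matrices,
likelihood-invariant translation moves to decorrelate fixed and random
effects), reporting posterior mean/median/KDE-mode, 95% highest posterior
density intervals, batch-means effective sample sizes against the published
minimum-ESS bound, and the conditional-likelihood DIC.  See
`docs/methods.md` for every modelling and numerical choice.

## Worked example

Generate the bundled illness-severity-like dataset (437 subjects, two
treatment arms, √week decline on a 1–7 scale, the reference catalogue of
nine missing-data patterns) and inspect its patterns:

```
python -c "import patternmix as pm; pm.generate_empirical_like(437, seed=1).to_csv('imps_like.csv')"
patternmix patterns imps_like.csv --reps 100000 --seed 7
```

```
            mask             class  count  observed_0  expected_0  observed_1  expected_1
pattern_id
1           1111          complete    312          64        77.1         248       234.9
2           1110  monotone_dropout     53          19        13.1          34        39.9
3           1100  monotone_dropout     45          18        11.1          27        33.9
...
dropout: n=102 (23.3%)
MC exact test of pattern-group independence: p = 0.0154 (100000 tables)
```

312 of 437 subjects are completers; the 102 subjects (23.3%) whose final
key week is unobserved form the dropout stratum.  The expected counts show
the placebo arm (group 0) under-represented among completers, and the exact
test (p ≈ .015) says pattern and treatment arm are not independent — reason
to take the missingness seriously.  Then fit the √week growth model under
ignorable missingness:

```
patternmix fit imps_like.csv --model ignorable --growth sqrt_linear \
    --iterations 20000 --burnin 4000 --thin 8 --seed 1
```

```
           mean  median   mode  hpdi_low  hpdi_high      ess
gamma_00  5.330   5.332  5.335     5.156      5.494  284.208
gamma_01  0.046   0.042  0.019    -0.153      0.245  287.722
gamma_10 -0.280  -0.280 -0.277    -0.413     -0.150  330.619
gamma_11 -0.603  -0.604 -0.611    -0.755     -0.448  305.634
tau_0    -0.818  -0.819 -0.823    -1.022     -0.640  388.269
tau_1     0.192   0.192  0.203    -0.017      0.422  323.596
phi_u0    0.432   0.429  0.424     0.315      0.550  305.992
phi_u1u0 -0.071  -0.070 -0.069    -0.147     -0.003  355.896
phi_u1    0.301   0.299  0.292     0.229      0.365  493.174
q = 7; min ESS bound = 8769; observed min ESS = 284; DIC = 4027.5
```

Both arms start near "markedly ill" (γ₀₀ ≈ 5.33, arm difference γ₀₁ ≈ 0.05
with an HPDI straddling zero) and the treated arm improves faster: the
drug × √week effect γ₁₁ ≈ −0.60 (HPDI (−0.76, −0.45)) on top of the placebo
slope γ₁₀ ≈ −0.28 per √week.  The residual variance is larger in the
treated arm (τ₁ ≈ 0.19).  At these desk-scale chain settings the observed
ESS (~280) is far below the q = 7 minimum-ESS bound (8769) that
reference-quality runs should meet — the diagnostics line makes that
explicit rather than hiding it.  `patternmix sensitivity` fits the full
seven-column suite (ignorable, fixed pattern-mixture raw and averaged, two
random pattern-mixture cluster sets, joint, shared-parameter) and writes an
aligned comparison table; `patternmix simstudy` runs the bias experiment.

The same machinery is available as a library (`read_long_csv`,
`classify_patterns`, `build_model`, `sample_posterior`, `run_sensitivity`,
`run_simulation_study`, ...).

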