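# illnessdeath

Semi-Markov three-state illness–death modelling with piecewise-constant
hazards under left, right and interval censoring and left truncation.

## The problem

Panel studies of chronic disease observe each participant's state — healthy
(1), history of illness (2), or dead (3) — only at scheduled visits, while
death ages are exact. The age `W` at which a participant enters the illness
state is therefore never observed directly: it is *interval-censored*
between the last healthy visit and the first ill visit, or *left-censored*
before study entry for participants recruited already ill. Participants who
died before recruitment never enter the data at all (*left truncation*).
This matters when the death hazard after illness depends on the time already
spent ill — a semi-Markov effect that requires knowing `W`.

`illnessdeath` fits the transition-intensity model

    q_1j(A)     = exp( Z(A)·β_1j ),                j ∈ {2, 3}
    q_23(A | W) = exp( Z(A)·β_23 + γ (A − W) ),

with age `A` as the time scale, `Z(A) = (1, A, X_1, …, X_r)` and sojourn
time `A − W` as a time-varying covariate. Intensities are held piecewise
constant on a grid of resolution `h` (evaluated at left subinterval limits),
making the 1→j baselines Gompertz in age and the 2→3 baseline Gompertz in
sojourn time, with rate `α_23 = exp(β_0.23 + β_A.23 W)` and shape
`ξ_23 = γ + β_A.23`; when `ξ_23 < 0` a fraction `exp(α_23/ξ_23)` of the ill
never experiences the modelled death hazard.

The toolkit provides:

- interval-censored likelihood contributions that integrate the unobserved
  onset age out by composite Simpson quadrature (`likelihood`);
- an EM-inspired fit–impute algorithm for left-censored onsets, alternating
  maximum-likelihood fits with posterior-expected onset imputation on the
  `[A_0, A_b]` grid, where `A_0` is the age at which everyone is assumed to
  have been healthy (`em`);
- a study-design trajectory simulator with exact piecewise-exponential event
  times, interval-censored observation, left truncation and the two
  benchmark scenario designs (`simulate`);
- stratified (patterns A–D vs E–F) studentised bootstrap intervals with
  Box–Cox variance stabilisation (`bootstrap`);
- microsimulation goodness-of-fit: Kaplan–Meier and state-prevalence
  envelopes from fitted-model replicates cloned at the observed baseline
  (`gof`);
- a CLI (`illnessdeath simulate | fit | bootstrap | gof`) over a CSV panel
  format (`io`, `cli`).

## Worked example

Simulate a moderate-left-censoring cohort (trajectories healthy from age 60,
baseline ages ~ N(65, 2²) truncated at 64, visits every 2 years for 12
years), then fit with the onset-age assumption matched to the design:

```python
import illnessdeath as idm

records, stats = idm.generate_scenario(
    idm.scenario_I(seed=1, n_pool=1000, n_keep=600))
print(f"{100*stats.frac_truncated:.1f}% left-truncated, "
      f"{100*stats.frac_ill_at_baseline:.1f}% ill at baseline")

settings = idm.LikelihoodSettings(h=0.25, integ_res=0.1, A_0=60.0)
fit = idm.em_fit(records, settings=settings)
for name, est in zip(fit.theta.param_names(), fit.theta.to_vector()):
    print(f"{name:>10s} {est:+8.4f}")
```

prints

```
8.3% left-truncated, 7.0% ill at baseline
 beta_0.12  -7.9265
 beta_A.12  +0.0535
 beta_0.13 -10.3661
 beta_A.13  +0.0943
 beta_0.23  -5.2294
 beta_A.23  +0.0398
     gamma  -0.1018
```

The generating values were β_12 = (−8.78, 0.065), β_13 = (−10.31, 0.093),
β_23 = (−5.92, 0.052), γ = −0.11: the 1→2 and 1→3 coefficients are
recovered to within sampling error at n = 600; the 2→3 block sits on a flat
ridge (age and sojourn slopes are nearly collinear when onset ages vary
little), yet the identified combination β_A.23 + γ = −0.062 (truth −0.058)
and γ itself (−0.102 vs −0.11) land close to truth. `fit.imputed_onsets`
holds the imputed onset ages of the left-censored participants and
`fit.em_trace` the fit–impute iteration history.

The same pipeline from the shell:

```sh
illnessdeath simulate --scenario I --seed 1 --out runs/sim
illnessdeath fit runs/sim/panel.csv --a0 60 --out runs/fit
illnessdeath bootstrap runs/sim/panel.csv -B 450 --a0 60 --out runs/ci
illnessdeath gof runs/sim/panel.csv -R 100 --a0 60 --out runs/gof
```

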