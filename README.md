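# dynconn

Seed-based **dyn**amic-**conn**ectivity predictive modeling: estimate
time-varying correlations between a seed region and many target regions
with a two-stage GARCH(1,1)/DCC model, use the *temporal variance* of each
correlation path as a per-edge feature, fit sparse linear trait models with
a max-features Lasso rule, and select generalizable models through a
train → validate → test cascade with permutation tests, BH-FDR and
virtual-lesion refinement.

The package is aimed at researchers studying trait prediction from
resting-state functional connectivity — in particular the hypothesis that
*variability* of seed connectivity (e.g. with the dorsomedial prefrontal
cortex), rather than its average strength, tracks trait rumination. Because
raw fMRI cohorts of this kind are access-restricted, the package ships a
synthetic cohort generator with full ground truth (known time-varying
correlation paths, known sparse support, known trait coupling) so that
every stage of the pipeline is testable end to end.

## The model in brief

For one edge with series x (seed) and y (target):

1. GARCH(1,1) per series, quasi-ML, constant mean:
   σ²ₜ = ω + α ε²ₜ₋₁ + β σ²ₜ₋₁, residuals zₜ = (xₜ − μ)/σₜ.
2. DCC correlation stage on the residual pair:
   Qₜ = (1 − θ₁ − θ₂) S̄ + θ₁ zₜ₋₁ zₜ₋₁′ + θ₂ Qₜ₋₁,
   ρₜ = q₁₂,ₜ / √(q₁₁,ₜ q₂₂,ₜ).

Edge features: mean ρₜ ("DCC mean", the analogue of static connectivity)
and Var(ρₜ) (the predictive feature). Trait model: Lasso with the penalty
chosen as the least-regularized point whose active set does not exceed the
training sample size ("as many features as subjects"), features z-scored
within each training fit, evaluated by leave-one-participant-out CV and
one-sided permutation tests, with BH-FDR (q < 0.05) across the seed ×
outcome model family. Virtual lesion: Δcorr = r_full − r_reduced per
zeroed weight; features with Δcorr > 0 on every evaluation cohort form the
refined model. Details and all numerical conventions: `docs/methods.md`.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study and
write tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py    # train/validation/test cohorts
python analysis/02_estimate_features.py   # DCC variance / mean / static tables
python analysis/03_train_and_cascade.py   # sparse models + selection cascade
python analysis/04_lesion_and_refine.py   # virtual lesion + refined model
```

Script 03 prints, for the dynamic-variance features:

```
[dcc_variance] stage 1 (training LOOCV):
  seed    outcome        r        p  fdr_pass
seed_1      trait 0.520511 0.000100      True
seed_1 nuisance_1 0.193511 0.067093     False
seed_1 nuisance_2 0.243642 0.030997      True
[dcc_variance] final test:   seed outcome        r      p   ci_low  ci_high
seed_1   trait 0.464388 0.0022 0.231808 0.646248
```

The model for the coupled trait predicts in training (cross-validated
r = 0.52, permutation p = 1e-4), survives FDR and independent validation
(r = 0.56), and generalizes to the held-out test cohort (r = 0.46, 95% CI
[0.23, 0.65]). A nuisance outcome that slipped through stage-1 FDR dies at
validation — the cascade doing its job. The same cascade on *static*
connectivity features selects nothing (`[static] survivors -> validation:
none`): the trait signal lives in the variance of the dynamic correlations,
not in their average. Script 04 then reports

```
full model: 59 nonzero weights; 14 important on both cohorts
cross-cohort delta consistency validation-test: r = 0.880
test: r_full = 0.464, r_refined = 0.873
```

i.e. lesion importance is consistent across the two evaluation cohorts, and
the refined model — restricted to the 14 edges whose removal hurts on both
— sheds the overfit weights and predicts the held-out cohort better than
the full model.

There is also a CLI for running individual stages on your own delimited
series files (`dynconn simulate|score-rrs|features|train|evaluate|cascade|
lesion|refine|apply`; see `dynconn --help`).

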