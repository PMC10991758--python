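# trialemu

Competing risks, immortal-time bias, and baseline confounding routinely
distort treatment-effect estimates in observational hospital studies: when
in-hospital death is the outcome, discharge is a competing event that the
naive Kaplan-Meier estimator mishandles; when treatment starts days after
admission, classifying ever-treated patients as treated from baseline
manufactures "immortal" person-time; and when sicker patients are likelier
to be treated, crude comparisons confound indication with effect.

`trialemu` is a toolkit for studying — and correcting — all three on
synthetic COVID-19-like inpatient cohorts with known ground truth. It is
aimed at biostatisticians and epidemiologists who want a controlled
sandbox for these biases, and it bundles:

- a calibrated **synthetic cohort generator**: three competing endpoints
  (death, discharge home, transfer), administrative censoring at day 45, a
  confounded time-dependent single-dose treatment, correlated inflammatory
  markers with MCAR/MAR missingness, and configurable true cause-specific
  treatment hazard ratios;
- weighted **Kaplan-Meier / Aalen-Johansen** estimators (ΔCIF_k(t) =
  Ŝ(t−)·d_k(t)/n(t)), the deliberately biased 1−KM comparator, and
  **Fine-Gray** subdistribution analysis via censoring-distribution-weighted
  expansion;
- a start-stop **Cox partial-likelihood engine** (Efron/Breslow ties, case
  weights, cluster-robust sandwich variance) verified against
  `survival::coxph` and brute-force likelihood grids;
- **IPTW** propensity weighting, **IPCW** for artificial censoring, and
  standardized-mean-difference balance diagnostics;
- a **clone-censor-weight target-trial emulation**: two clones per patient,
  artificial censoring at protocol deviation within a 2-day grace window,
  inverse-probability-of-censoring weights, per-arm weighted Aalen-Johansen
  curves, weighted cause-specific Cox hazard ratios, and patient-level
  bootstrap confidence intervals;
- **multiple imputation** (chained equations, Bayesian regression draws)
  with Rubin's-rules pooling;
- a **five-model comparison** from fully biased to fully corrected, with a
  report mirroring the bias-accounting table of such studies.

## Worked example

```python
import trialemu as te

cohort = te.generate_cohort(te.default_config(n=478, seed=7))
print(te.run_motivating_example(cohort).at_horizon())
```

The motivating competing-risks contrast on this cohort prints

```
naive_1mkm   54.7%
finegray_2   41.7%
finegray_3   35.1%
```

— the naive 1−KM estimate of 45-day in-hospital death (54.7%) shrinks to
41.7% once discharge home is treated as a competing event, and to 35.1%
once transfers are kept in the risk set too: censoring discharged patients
pretends they could still die in hospital, inflating the estimate.

The five-model treatment-effect comparison:

```python
report = te.run_five_models(cohort, te.Protocol(n_boot=200, seed=7), seed=7)
print(report.pivot())
```

```
model  method                                                      death             home              transfer
1      Univariable Cox, treatment misclassified at baseline        0.81 [0.57-1.15]  0.58 [0.39-0.88]  0.48 [0.29-0.79]
2      Univariable time-dependent Cox, start-stop treatment        1.39 [0.97-1.98]  0.81 [0.52-1.26]  0.70 [0.42-1.19]
3      Multivariable time-dependent Cox with baseline covariates   0.72 [0.49-1.07]  1.12 [0.69-1.81]  0.76 [0.43-1.33]
4      IPTW-weighted time-dependent Cox (robust SE)                1.03 [0.67-1.58]  0.84 [0.49-1.44]  1.09 [0.62-1.91]
5      Target-trial emulation, clone-censor-weight                 1.10 [0.61-1.98]  0.89 [0.48-1.64]  0.77 [0.32-1.88]
```

Model 1's death hazard ratio (0.81) sits below Model 2's (1.39): crediting
pre-treatment survival time to the treated group makes the treatment look
spuriously protective. Adjusting for baseline covariates (Model 3) moves
the estimate to 0.72, close to the generator's true death HR of 0.70; at
n = 478 the weighting-based Models 4-5 are noisy, which is exactly the
sample-size lesson the sandbox makes visible (rerun with `n=10000` to watch
them tighten around the truth). The report also contrasts the crude
per-group 1−KM death probabilities (48.3% treated / 57.7% untreated here)
with the emulated arms' weighted Aalen-Johansen probabilities (38.3% /
34.9%), reproducing the characteristic overestimation of the naive curves.

The same pipeline is scriptable from a shell:

```bash
trialemu --seed 7 simulate --n 478 --out cohort.csv
trialemu motivate --cohort cohort.csv
trialemu --seed 7 analyze --cohort cohort.csv --boot 200 --out report/
trialemu recover --reps 100 --n 2000
```

See `docs/methods.md` for the generating model, estimator conventions
(tie-breaking, weight timing, grace-window estimand caveats) and known
limitations.

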