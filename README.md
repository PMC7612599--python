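# blrm2

Bayesian dose-finding for dual-agent trials in which one compound's dose is
prescribed externally, per patient, and the other is escalated.

The motivating setting is an opiate-detoxification trial combining
methadone (continuous dose, 10–150 mg, fixed for each patient by the
treating clinician) with baclofen (escalated over the grid 10/30/60/90 mg).
Because every patient arrives with their own methadone dose, the trial's
output is not a single maximum tolerated combination but a **dosing
function**: for each methadone dose, the baclofen dose whose risk of a
dose-limiting toxicity (DLT) lies in the target band
[γ−δ, γ+δ] = [0.15, 0.25].

## Model

Monotherapy risks follow two-parameter logistic curves on the log-dose
scale,

    logit p(M) = α01 + α11 · log(M / M*),      M* = 60 mg
    logit p(B) = α02 + α12 · log(B / B*),      B* = 30 mg

combined under independence, p0 = 1 − (1 − p(M))(1 − p(B)), with a
synergy term acting multiplicatively on the odds:

    odds p(M, B) = odds p0 · exp(η · (M/M*) · (B/B_top)),   B_top = 90 mg

θ = (α01, α11, α02, α12, η) carries the calibrated prior: normal
intercepts (means −3.75 and −3.25, SD 0.50), log-normal slopes (medians
0.40 and 0.05, log-SD 0.35) and a half-normal interaction
η ~ N(0, 1.25²) truncated to η ≥ 0. The posterior is updated after every
cohort of 3 patients (emcee ensemble MCMC; a deterministic 5-D quadrature
oracle cross-checks every functional on small datasets).

Escalation follows four rules per patient with methadone dose M′:
no skipping of untried baclofen levels; coherency after a DLT cohort;
overdose control, keeping doses with P(p(M′, B) > 0.25) < 0.25; and
assignment of the dose maximising P(p(M′, B) ∈ (0.15, 0.25)). Two
trial-level rules can stop early: stop-unsafe if
P(p(60, 30) > 0.25) > 0.25, and stop-safe if P(p(120, 90) < 0.25) > 0.925.

## Worked example

Replay the recorded no-DLT escalation path and recompute every decision
quantity:

```
$ blrm2 replay examples/clean_path_cohorts.yaml --seed 1 --out replay_out
 Group    M doses    B doses    DLTs P(unsafe) P(safe) B = 10mg  B = 30mg  B = 60mg B = 90mg
     1 31, 47, 86 10, 10, 10 0, 0, 0        0%     46%        -  (97,150)   (67,96)  (10,66)
     2 66, 29, 44 30, 30, 30 0, 0, 0        0%     45%        -  (98,150)   (68,97)  (10,67)
     3 28, 56, 66 60, 60, 60 0, 0, 0        0%     54%        - (113,150)  (78,112)  (10,77)
     4 18, 84, 83 90, 90, 90 0, 0, 0        0%     69%        -         - (107,150) (10,106)
     5 74, 30, 75 90, 90, 90 0, 0, 0        0%     75%        -         - (121,150) (10,120)
     6 82, 90, 10 90, 90, 90 0, 0, 0        0%     84%        -         - (145,150) (10,144)
     7 64, 60, 91 90, 90, 90 0, 0, 0        0%     87%        -         - (10,150)
final status: completed
```

Each row shows one cohort: the externally prescribed methadone doses, the
baclofen doses the design assigned, the DLT outcomes, the two stopping
probabilities — `P(unsafe)` is the posterior probability that the
safety-check combination (60 mg methadone + 30 mg baclofen) is too toxic,
`P(safe)` the probability that even the high combination (120 mg + 90 mg)
is safe — and the current dosing function as methadone intervals per
baclofen dose. With seven clean cohorts the confidence that all baclofen
doses are safe rises from 46% to 87%, and by cohort 7 the whole methadone
range (10, 150) is assigned the top 90 mg dose.

Other entry points: `blrm2 simulate` (operating characteristics under a
true scenario), `blrm2 random-robustness` (random logistic/Bliss scenario
sweeps), `blrm2 calibrate` (prior grid search), `blrm2 posterior-check`
(sampler vs quadrature oracle). The same functionality is available as a
library; see `blrm2.run_trial`, `blrm2.run_many`, `blrm2.summarize` and
`blrm2.calibrate_priors`.

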