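# Methods

## Setting and objective

One agent (methadone, `M`) is dosed externally and continuously per
patient on [10, 150] mg; the other (baclofen, `B`) is escalated over the
grid {10, 30, 60, 90} mg in cohorts of 3, up to 48 patients. The
deliverable of the trial is the dosing function mapping a patient's
methadone dose to the baclofen dose whose DLT risk lies in
[γ−δ, γ+δ] = [0.15, 0.25].

## Combination–toxicity model

Monotherapy risks are two-parameter logistic in log-dose with reference
doses M\* = 60 mg and B\* = 30 mg; the combination risk is the
independence combination of the monotherapy risks with the odds multiplied
by `exp(η·(M/M*)·(B/B_top))`, `B_top` = 90 mg. Doses of zero bypass the
log-dose arithmetic and contribute risk zero. The odds transform is
applied on the log-odds scale with probabilities clipped to
[1e−12, 1−1e−12], so tail parameter draws cannot overflow.

Model conventions. Three aspects of this parameterisation were genuinely
open and were fixed as follows; all three are deliberate design choices of
this package, made once and documented here:

1. **Slope prior scale.** The calibrated slope values (0.40 for methadone,
   0.05 for baclofen) are interpreted as the prior *medians* of the
   log-normally distributed slopes (log-slope means log 0.40 and
   log 0.05, log-SD 0.35). The alternative reading — 0.40 as the mean of
   the log-slope, implying a median slope of e^0.40 ≈ 1.49 — produces
   dosing-function boundaries and escalation behaviour sharply at odds
   with the published worked examples (for instance, it would already cut
   the 90 mg dose at methadone ≈ 20 mg under the prior, where the
   published path recommends it up to ≈ 72 mg), and is incompatible with
   a calibration grid for this hyper-parameter that includes the value 0.
2. **Interaction truncation.** η ~ N(0, 1.25²) truncated to η ≥ 0: the
   design works under the assumption that co-administering the escalated
   agent cannot reduce toxicity (synergistic or additive, never
   antagonistic). This matches the random-scenario generator, which draws
   η from U(0, 1.1), and reproduces the marked asymmetry of the published
   escalation paths, where the confidence in safety collapses after a DLT
   but recovers only slowly from clean cohorts.
3. **Interaction standardisation.** The odds multiplier uses
   `(M/M*)·(B/B_top)` with `B_top` the highest planned baclofen dose.
   Standardising the escalated agent by B\* = 30 mg instead makes the
   interaction term at the safety-check combination (60, 30) large enough
   that the stop-unsafe probability under the prior is ≈ 9%, whereas the
   published paths print 0% throughout; the `B_top` scaling keeps it
   below 0.5% while preserving the published behaviour at the high
   combination.

σ0i and σ1i are standard deviations (Σi = [[σ0i², σ01,i], [σ01,i, σ1i²]]);
σ01,i defaults to 0 and σ_η = 1.25.

Known limitation. Even under these conventions the package does not
reproduce the published per-cohort decision probabilities exactly: the
replayed stop-safe probability runs ≈ 6–10 points below the published
column on the clean path and ≈ 5–16 points above it on the DLT path, with
the stop-unsafe column (≤ 0.5% vs printed 0%) and most dosing-interval
cut-points (within 4 mg) agreeing. A systematic inversion over prior
scales, covariate shapes and truncation choices could not close this gap:
the published posterior is sharper, in both directions, than this model
family allows. Users comparing against the published tables should expect
qualitative agreement (escalation decisions, interval movements,
de-escalation after DLTs) rather than probability-level agreement.

## Posterior computation

Sampling is on the unconstrained scale (intercepts, log-slopes, η) with
the affine-invariant ensemble sampler (emcee), chosen as the
general-purpose MCMC engine for this 5-dimensional, cheap-likelihood
posterior. Default settings: 40 walkers × 1500 steps, first 400 discarded
(44,000 retained dependent draws; integrated autocorrelation ≈ 30–50
steps, so ≈ 1,000–2,000 effective draws, Monte-Carlo SE of decision
probabilities ≈ 0.01–0.015). Every sampling call takes an explicit seed
and is bit-reproducible. Convergence is monitored through the integrated
autocorrelation time; estimates above 80 steps raise a warning and are
recorded in the draws' metadata. Simulation studies use a lighter profile
(64 walkers × 220 steps, 100 discarded, ≈ 7,700 draws) that trades ≈ 3×
wall time for decision-probability noise of ≈ 0.02–0.03; replay and
acceptance computations use 64 × 2000–3000.

An independent deterministic check is provided by a tensor-product
quadrature over the five parameters. Because the likelihood concentrates
the posterior well inside the prior's span, the oracle runs two passes:
a prior-spanning grid, then a grid recentred on the posterior moments of
pass one (±5 posterior SDs, 13–15 nodes per axis, trapezoid end weights).
Against a 400,000-draw importance-sampling gold standard the two-pass
oracle is accurate to < 0.01 on datasets up to n ≈ 10; it is quadratic in
nodes-per-axis to the fifth power and not intended beyond n ≈ 15 nodes.

## Escalation and stopping

Admissibility: the first cohort receives 10 mg; afterwards at most one
level above the highest level tried (no skipping), and after a cohort
with a DLT no more than the lowest baclofen dose at which a DLT occurred
in that cohort (coherency; the minimum over multiple DLTs is the
strictest reading). Overdose control keeps admissible doses with
P(risk > 0.25) < 0.25; among those the dose maximising
P(risk ∈ (0.15, 0.25)) is assigned, ties to the lowest dose. If no
admissible dose passes the overdose rule the lowest dose is assigned —
the trial-level stop-unsafe rule, checked once per cohort, owns the
decision to halt enrolment. Stop-safe
(P(p(120, 90) < 0.25) > 0.925) is evaluated after stop-unsafe when both
would fire. The dosing function evaluates the same safe-set/argmax rule
on the 1 mg methadone grid without the intra-trial admissibility
restrictions (those belong to the escalation, not the end product);
non-contiguous recommendation runs, possible under posterior uncertainty,
are reported as multiple intervals with a logged warning.

## Synthetic data

The methadone-dose generator mirrors the study population: truncated
normal, mean 51.4 mg, SD 23.3 mg on [10, 150], rounded to integer mg.
Robustness variants: a truncated Student-t with 10 degrees of freedom
(same location/scale, same bounds) and a uniform on [1, 150]. DLT
outcomes are Bernoulli draws from a true scenario surface of one of three
families: the five-parameter logistic working model, the binary-covariate
(Bailey-style) comparator, and a seven-parameter Bliss surface used for
model misspecification. Random scenario generators draw logistic
parameters from U(−5, −0.75) × U(0.40, 3.00) × U(−6, −0.75) ×
U(0.10, 2.00) × U(0, 1.1) and Bliss parameters from U(0, 0.4), U(0, 0.25),
four U(0.5, 1.5) and U(0.75, 1.5); Bliss draws with β1 ≤ β2 (risk
decreasing in dose) are retained as legitimate, if unusual, surfaces.

What the generator does not emulate: within-patient dose adjustment,
staggered enrolment, non-binary toxicity grades, and any dependence of
the methadone dose on patient covariates. Passing simulation tests
therefore says nothing about those aspects of real trials.

The eight named fixed scenarios of the original simulation study are
accepted as user-supplied configuration (their exact parameter vectors
are not in the public main text); `examples/fixed_scenarios_template.yaml`
ships with placeholders that the loader refuses to consume. The test
suite instead uses synthetic stand-ins constructed from the scenarios'
*definitions*: a safe surface whose top baclofen dose is the target dose
(risk ≈ 0.20) at methadone 120 mg, and a uniformly toxic surface with
risk ≈ 0.22 even at the lowest combination. Operating characteristics
measured on these stand-ins approximate, but cannot replicate, the
published Table-3 rows.

## Evaluation metrics

Predictive accuracy scores the end-of-trial dosing function on 112 future
patients drawn from the (configurable) methadone distribution, re-drawn
per trial: `pct_correct` is the share recommended a dose whose true risk
is in the target band — when no dose reaches the band for a given
methadone dose, the highest dose with risk below the band counts as the
correct choice — and `pct_safe` the share whose recommended dose's true
risk is at most 0.25. By construction `pct_correct ≤ pct_safe`. Both are
averaged over trials not stopped unsafe; DLT burden and sample size cover
all trials. Binned random-scenario curves aggregate per-scenario results
by the true risk at the safety-check combination (below x for accuracy,
at or above x for termination), with empty bins reported as missing.

Prior calibration is a grid search maximising the geometric mean of
`pct_correct` over three calibration scenarios; cells containing a zero
accuracy are annihilated by the geometric mean and logged. The simulation
budget per cell is injected by the caller (CLI default: 200 trials per
scenario per cell, with cell-level resume).

## Problem sizes used in the test suite

Unit and property tests run at n ≤ 200 observations with 5–50 replicates.
The end-to-end checks use: replay of both recorded escalation paths at
64 × 2000 sampler steps; sampler-vs-oracle comparison on 5 random small
datasets at 64 × 3000; robustness smoke runs of 10 unsafe logistic
scenarios × 10 trials and 6 safe-bin Bliss scenarios × 6 trials; scaled
operating characteristics with 16 (safe) and 24 (unsafe) trials; and
40-replicate credible-interval coverage. These sizes are the package's
chosen desk-scale defaults; all of them widen Monte-Carlo tolerances
accordingly.
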