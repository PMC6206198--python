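# Methods

## Model

The joint likelihood multiplies three independent blocks, which share no
parameters and therefore factorize in the posterior:

**Dead recoveries.** Each banded cohort (age class × banding year *t*) is a
multinomial over "first recovered dead at occasion *k*" cells plus a
never-recovered cell, conditional on the number released. Under the Seber
survival/reporting parameterization the adult cell probability is
`∏_{y=t}^{k−1} S_a[y] · (1−S_a[k]) · r_a[k]`; a juvenile cohort uses
`(1−S_j)·r_j` for its banding-year cell and switches to adult survival and
adult recovery rates after the first interval (the standard two-age-class
band-recovery structure). Recovery occasions are labelled by the calendar
year in which the recovery season begins, and years are 1-based within a
dataset. Cell vectors sum to one by construction; a zero-probability cell
holding a nonzero count makes the log-likelihood −∞ (returned, not raised).

**Within-season recaptures.** `f2_j ~ Bin(M_j, p_j)` and
`f2_a ~ Bin(M_a, p_a)`: of `M` newly banded birds, `f2` were handled a
second time during the initial season. Capture probabilities are
age-specific constants in all model variants, and recapture counts are
pooled over years; birds handled three or more times are folded into `f2`
(the estimator conditions on 1 vs 2 captures) and flagged by validation.

**Age composition.** `M_j ~ Bin(M_j + M_a, c_j)`, per year when `c_j` is
temporal.

Derived parameters per posterior draw: `V = p_j/p_a`,
`F_t = [c_t/(1−c_t)]/V`, `λ_t = S_{a,t} + F_t S_{j,t}`. The identity
`λ − S_a − F·S_j = 0` holds draw-by-draw exactly.

Key assumptions: the population is closed during the banding season; all
individuals within an age class share one capture probability; marks are
neither lost nor unreported; recoveries are reported from the population's
whole range (so `S` is true, not apparent, survival); and one-year-olds
breed, so a one-stage projection suffices for `λ`.

## Collapsed m-arrays

Sparse datasets are summarized by years-since-banding (lag 1 = the banding
year's season). Under time-constant rates the adult lag-*d* cell is
`S_a^{d−1}(1−S_a)r_a` and the juvenile lag-1 cell `(1−S_j)r_j` (then
`S_j S_a^{d−2}(1−S_a)r_a`). Collapsing discards which cohort produced each
lagged recovery, which matters because late cohorts cannot produce long
lags. When the collapsed array is built in-memory from a full m-array the
per-cohort lag rows are retained and the likelihood is the exact sum of
per-cohort multinomials, each truncated at its own horizon. A file that
carries only pooled lag counts gets the single pooled multinomial instead
(the textbook template form, exact only when every cohort's horizon reaches
the maximum lag); `pooled_collapsed=True` forces that form for strict
replication. Both agree with the full-m-array likelihood on single-cohort
data.

## Priors and sampling

Time-constant probabilities carry Uniform(0,1) priors. Temporal parameters
are non-centered logit-normal year effects, `logit x_t = μ + σ z_t` with
`μ ~ Uniform(−2, 2)`, `σ ~ Uniform(0, 2)`, `z_t ~ N(0,1)`; the non-centered
form only changes the sampling geometry, not the posterior. Note the μ
bounds confine a temporal parameter's typical scale to roughly
expit(±2) = [0.12, 0.88] unless σ stretches it — adequate for survival and
age composition, restrictive for very small recovery rates, which is one
reason capture probabilities stay constant.

Sampling is an adaptive random-walk Metropolis-within-Gibbs on transformed
scales (logit for unit-interval parameters, identity for bounded
hyper-parameters and year effects). Each scalar update recomputes only the
likelihood blocks that read that parameter. Per-parameter step sizes adapt
toward a 0.44 acceptance rate in 50-iteration batches during the first
`n_adapt` iterations only, so the post-adaptation chain is a valid Markov
chain; all randomness derives from the settings seed via
`numpy.random.SeedSequence`, making runs bit-reproducible. Starting values
are crude data-driven moments (e.g., `(f2+1)/(M+2)` for capture
probabilities) jittered per chain.

Schedules: the default is 3 chains × 25,000 iterations (5,000 burn-in,
thin 10, 1,000 adaptation) — adequate for data-rich fits;
`MCMCSettings.sparse()` multiplies all counts ten-fold for sparse-data fits
such as the junco example; `MCMCSettings.reduced()` (3 × 5,000, thin 5) is
for per-replicate fits inside simulation studies. Convergence is judged by
the classic Gelman–Rubin potential scale reduction factor (between/within
chain variance ratio, no rank normalization), flagged rather than raised at
R-hat ≥ 1.01. Known slow direction: `S_j` and `r_j` are strongly correlated
through the first-interval cell product `(1−S_j)r_j` when later juvenile
recoveries are few; scalar updates then need the longer schedules (the
parameter-recovery test uses 3 × 12,000).

Posterior summaries report mean, SD, CV = SD/mean and the 5%/95% empirical
quantiles of pooled post-burn-in draws (a 90% credible interval). For
temporal fits, the across-year variation `sd_t` is the SD across years of
the annual posterior means; the alternative definition (posterior mean of
the logit-scale hyper-SD) is available via `sd_t(..., method="hyper")`
since the two measure different things and reported values are sensitive to
the choice.

## Closed-form estimators

`chao_abundance` implements `N̂ = M + f1²/(2 f2)` per age class; `f2 = 0`
is an error rather than silently switching to the bias-corrected form
`f1(f1−1)/(2(f2+1))`, which is available behind an explicit flag. The three
estimators are mutually consistent by construction:
`F̂ · V̂ = M_j/M_a` exactly, and `V̂` equals the ratio of Chao-implied
capture rates `(M_j/N̂_j)/(M_a/N̂_a)`. Estimators operate on pooled
all-years counts, matching how the recapture binomials pool years.

## Synthetic-data generator

Each replicate emulates a 24-year banding program on a stationary
population. Truths are fixed at `S_a = 0.60`, `S_j = 0.50`, `F = 0.80`
(hence `λ = 1`) with `N_j = 240,000` and `N_a = 300,000` birds available
for capture each year (their ratio *is* `F`, enforced by a consistency
check). Encounter rates vary between replicates:
`r_j ~ U[0.0001, 0.4]`, `r_a ~ U[0.0001, 0.2]`, `p_a ~ U[0.0001, 0.02]`
and `V ~ U[0.5, 1.5]` with `p_j = V·p_a`; a flag redraws them per year
instead. Per-replicate seeds derive from `SeedSequence(master, index)`, so
any subset of replicates is reproducible independently — partial studies
resume by index.

How banding totals arise from `p` is a modelling choice here: each year
`M_t ~ Bin(N, p)` birds are newly banded and `f2_t ~ Bin(M_t, p)` of them
recaptured once more, mirroring the fitted model's conditional structure so
that bandings and recaptures co-vary with the drawn capture probability.
The population is treated as reconstituted annually (fixed `N`, `λ = 1`),
so banded birds simply leave the "new-banding" pool. Dead recoveries per
cohort are drawn from the same Seber cell probabilities the likelihood
uses; a property test confirms the score of the likelihood averages to zero
at the generating values.

What the generator does *not* emulate: capture heterogeneity within age
class, behavioral trap response, band loss, emigration, density dependence,
temporal trends in vital rates, or sex structure. Passing tests therefore
show estimator correctness under the model's own assumptions, not
robustness to their violation in field data.

## Estimator evaluation

Across replicates: `bias = mean(est) − truth`, `SD` with n−1, `RMSE =
√(bias² + SD²)` (the identity `RMSE² = bias² + SD²` is enforced to 1e−9),
and `CV = SD/truth` — the truth is known in simulation; `SD/mean` is
available and agrees to reported precision at the near-unbiased study
settings. Point estimates are posterior means (Bayesian route) or the
closed-form/MLE values; draws are never pooled across replicates.
Binning uses right-closed intervals with default edges at 300 and 1,000
total within-season recaptures; bins with fewer than 10 replicates are
flagged. Replicates where the closed-form estimator is undefined
(`f2 = 0`) are recorded as failures and excluded from summaries — they
concentrate in the lowest-recapture bin.

## Problem sizes used

The bundled study runs 150 replicates of 24 years with the closed-form
estimator (the full 1,000-replicate design is a `SimConfig` field away);
the Bayesian per-replicate route is exercised at smoke scale with the
reduced schedule. The junco fit uses the full ten-fold sparse schedule.
Parameter recovery uses one 24-cohort replicate at waterfowl-like encounter
rates (`r_j ≈ 0.1`, `r_a ≈ 0.04`, `p_a ≈ 0.0007`, `V = 2`).

## Limitations

- Recapture data enter only as 1-vs-2 capture frequencies; richer
  within-season capture histories (model M_t, M_h variants) are out of
  scope, though any closed-population estimator could replace Chao's in
  principle.
- The MLE route covers time-constant models only.
- Temporal models require full (uncollapsed) m-arrays with at least two
  cohorts, and the `U(−2, 2)` hyper-mean bound makes them unsuitable for
  parameters whose scale is far below ~0.12.
- `V` and `F` posteriors are heavy-tailed when `f2` is small (they involve
  `1/p`); posterior means then exceed posterior medians noticeably, as in
  the junco example.
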