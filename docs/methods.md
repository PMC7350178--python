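# Methods

`survselect` benchmarks variable-selection strategies for right-censored
survival outcomes when the number of gene-expression covariates far
exceeds the number of patients. This note records the statistical model,
the defaults and why they were chosen, the numerical conventions, and what
the simulated benchmark can and cannot say about real cohorts.

## Data model

A simulated cohort has `N` subjects and `p = 1500` mean-zero Gaussian
covariates ("genes"). Genes are organised in contiguous blocks
(default 10 genes per block) with a within-block autoregressive
correlation `corr(z_i, z_j) = rho^|i-j|` (`rho = 0.6`) and independence
across blocks — a stylised picture of co-regulated gene modules. Event
times follow an exponential relative-risk model with unit baseline hazard,

    T_i ~ Exp( exp(beta' z_i) ),      via  T_i = -log(U_i) / exp(beta' z_i),

and censoring times are uniform `C ~ U(3, 5)`, independent of everything;
the observed data are `(min(T,C), 1{T<=C}, z)`. A subset of `q` genes is
truly prognostic with protective log-hazard ratios fixed at −0.11 or −0.22
(hazard ratios ≈ 0.9 and 0.8 per unit of expression). The nine scenario
presets cross `N ∈ {500, 750, 1000}` with `q ∈ {0, 12, 50}`.

Design choices that the problem statement leaves open, fixed once here:

* **Block size 10.** Small blocks keep the covariance sparse and match the
  convention of modest co-expression modules in the simulation literature.
* **Placement of active genes**: consecutively from gene 0, so each active
  gene has correlated inactive neighbours — the mechanism that produces
  false discoveries. A "spread" mode (one active gene per block) is
  available for sensitivity analyses.
* **Effect allocation**: the two magnitudes (−0.11, −0.22) alternate along
  the active set, so both appear in every non-null scenario.
* **Ties**: event times are continuous, so ties have probability zero and
  observed times are not rounded; fitting code nevertheless handles ties
  (Breslow) for real data.

**Censoring-rate caveat.** With Exp(1)-scale event times, `U(3, 5)`
censoring removes only ≈ 2% of a null cohort (closed form
`(e^-3 − e^-5)/2`) and ≈ 10% of a q = 12 cohort — well below the 10–30%
the design narrative aims for. The bounds are kept as stated; because the
discrepancy changes the effective information per cohort (more observed
events, hence stronger selection signal), `calibrate_censoring_bound`
performs a bisection on an administrative censoring bound for users who
want to hit a target censoring rate instead.

## The six selectors

All penalized fits standardise covariates internally and report
coefficients on the original scale. The penalty mixing convention is
`alpha * |b|_1 + (1-alpha)/2 * |b|_2^2`: `alpha = 1` is the LASSO,
`alpha = 0.5` the Elastic Net. Path fitting is delegated to the
coordinate-descent Cox path solver of scikit-survival (the glmnet
algorithm); note its penalty grid lives on a unit-L2-norm covariate scale.

1. **LASSO-cvl.** 100 log-spaced penalties from the data's `lambda_max`
   down to `0.01 * lambda_max`; the penalty maximises the 10-fold
   cross-validated partial log-likelihood (cvl) of Verweij and van
   Houwelingen, `cvl(λ) = Σ_k [ l(β̂_{-k}; all) − l(β̂_{-k}; minus fold k) ]`.
   Folds are stratified by event status so every fold carries events.
2. **LASSO-pcvl.** The cvl is penalized for model size:
   `pcvl(λ) = cvl(λ) − c · df(λ)` with
   `c = [cvl(λ_cvl) − cvl(λ_max)] / df(λ_cvl)` — the average cvl gain per
   selected gene of the cvl-optimal model over the null end of the path.
   The criterion is maximised over `λ ≥ λ_cvl` with ties resolved to the
   largest penalty, so the pcvl model never selects more genes than the
   cvl model.
3. **Elastic Net** (`alpha = 0.5`), penalty again by 10-fold cvl.
4. **BSS Enet** — bootstrap stability selection: the Elastic Net (penalty
   by cvl) is refit on `B = 100` bootstrap resamples of the training set;
   genes selected in at least `sigma = 0.5` of the resamples form the
   signature. The final risk model refits a Cox model on the signature:
   unpenalized when `|signature| < n/5`, otherwise ridge with the penalty
   chosen by a coarse cvl grid — a "final model" implies a refit, and the
   guard keeps it identifiable.
5. **CoxBoost** — component-wise likelihood boosting. From `β = 0`, each
   step applies the single best penalized one-dimensional Newton update
   (score `U_j`, information `I_j`, step `U_j/(I_j + penalty)`, chosen by
   the penalized score statistic `U_j²/(I_j + penalty)`), with the current
   linear predictor as an offset. The step count is tuned by 10-fold cvl;
   the boosting penalty starts at `9 × (number of events)` and is
   coarsely doubled/halved (at most 3 rounds) until the CV-optimal step
   count falls in [50, 200].
6. **RSF** — random survival forest with log-rank splitting, `sqrt(p)`
   candidate variables per node, minimum terminal node size 15, 1000
   trees by default. Selection uses minimal-depth *variable hunting*: 50
   repetitions each draw a 63.2% subject subsample and up to 250 candidate
   variables, grow a 100-tree forest, and flag variables whose
   forest-averaged minimal depth (first split depth; unused trees
   contribute their maximal depth) is below the mean minimal depth a
   noise variable would attain given the observed per-depth node counts.
   The final signature keeps the most frequently flagged variables, with
   size equal to the average per-repetition model size (at least 1 — the
   hunt always returns a signature, which is precisely why it cannot
   control false discoveries under the null). The risk score is the
   ensemble mortality (sum of the ensemble cumulative hazard over the
   training event-time grid); training subjects average only the trees
   whose bootstrap excluded them (out-of-bag), validation subjects use
   all trees.

## Resampling design and metrics

Each cohort is split at random into a training fraction (1/2 or 2/3,
round-half-up) and a validation remainder, 100 times by default; all
methods share the same splits so between-method intersections compare
selections made on identical samples. Selection quality is summarised by
the FDR and FNR against the simulation truth, per-gene occurrence
frequencies over splits (never-selected genes are excluded from the
med(min–max) summaries, and the TP/FP split is reported separately), and
pairwise intersection sizes with the TP rate among common genes.
Undefined ratios (FDR of an empty selection, FNR under the null, TP rate
of an empty intersection) are NaN and are dropped from aggregation —
never coerced to 0. FDR/FNR are aggregated across splits by the median,
consistent with the med-based envelopes of the other summaries (the
alternative mean aggregation is a one-line change).

Prognostic performance on the validation half uses Harrell's concordance
index (ties in the risk score get half credit) and the IPCW integrated
Brier score: the censoring distribution `G` is estimated by Kaplan–Meier
on the validation set, subjects with an observed event before `t` are
weighted by `1/G(T_i^-)` and subjects still at risk by `1/G(t)`, and the
prediction-error curve is integrated by the trapezoid rule over the event
time grid up to `tau` = the 80th percentile of observed validation times
(a logged, per-split choice that avoids the unstable IPCW tail). If `G`
hits zero before `tau`, the horizon is truncated with a warning.

## Numerical choices

* Path-solver convergence tolerance `1e-5` (measured to leave selection
  paths identical to `1e-7` on this design while an order of magnitude
  faster); oracle-equivalence tests tighten it locally where they need
  `1e-6` agreement.
* `lambda = 0` or `alpha = 0` requests are routed to a Newton–Raphson
  (optionally ridge) fit, since the path solver needs a positive L1 term.
* Survival prediction for Cox-type models uses the Breslow baseline
  cumulative hazard `H0(t) = Σ_{s≤t} d_s / Σ_{j at risk} exp(β̂'z_j)`.
* Cross-validation folds: stratified by event status; a degenerate fold
  draw is retried once, then the run fails loudly. Splits likewise
  guard events into both halves with a single redraw.
* All randomness flows through integer seeds into `numpy` Generators;
  every benchmark cell (split × method) derives an independent seed from
  (master seed, split id, method index), so cells can run in any order
  with byte-identical results.

## Problem sizes in the shipped checks

The full 9-scenario × 2-fraction × 100-split × 6-method experiment is a
cluster-scale computation. The shipped test-suite and acceptance script
reproduce targeted slices at desk scale, chosen as the package's own
defaults for a quick-but-stable reproduction: 20 random half-splits of one
N = 500 cohort for the penalized methods (medians over 20 splits are
stable to ±1–2 genes across master seeds); bootstrap stability selection
with B = 20 resamples and 5-fold inner tuning on 8 splits; variable
hunting with 5 repetitions × 40-tree forests and a 200-tree scoring
forest. The qualitative findings these checks verify (null-scenario
behaviour, method ordering, FDR levels) are insensitive to these depths;
the printed envelopes (min–max) of course tighten or widen with the
number of splits.

## What the simulator does not emulate

Real expression cohorts violate this generator in known ways: effects are
not exactly linear in log-expression, correlation is long-range and not
block-diagonal, censoring is usually administrative-plus-dropout rather
than uniform on a fixed window (and, per the caveat above, the stated
uniform window censors far less than a clinical cohort would), and the
proportional-hazards assumption itself is an idealisation. Passing the
shipped checks therefore demonstrates correctness of the algorithms and
reproduction of the benchmark's qualitative conclusions under the stated
generative model — not performance guarantees on any particular clinical
dataset. The real-data path (`load_expression_survival` + the IQR > 1
prefilter) applies the identical resampling machinery to a user-supplied
cohort.

## Known limitations

* The exact variable-hunting routine of the original random-forest
  authors has unpublished details; the implementation here is the
  minimal-depth forward variant described above with every knob recorded
  in diagnostics. Its absolute signature sizes should not be compared
  gene-for-gene against other implementations.
* The boosting penalty search is coarse by design; it targets a step-count
  window, not a unique optimum.
* Unpenalized refits (BSS final models) require the selected set to be
  comfortably identifiable; the `n/5` guard switches to ridge rather than
  failing, which slightly shrinks the refit coefficients.
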