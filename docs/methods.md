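# Methods

## Observation model

One animal's telemetry is a uniform 15-minute grid of movement counts
(summed within the window) and median core body temperature, with daily body
weight broadcast to every step of its day. The modelled observation is the
pair (M, T) with M = ln(movement count + 1); the natural log is used
throughout (the base only rescales parameters). A window is either observed
or missing (NA) per channel; missing channels are marginalised out of the
likelihood — the emission term contributes 1 — never imputed.

Given the latent activity state, M and T are independent normals, so each
state carries two means and two variances and no cross-channel covariance.
This diagonal structure is an assumption of the model class, and it is what
makes per-channel pseudo-residuals a complete residual description.

## Covariate structure

A single standardised covariate z — elapsed time in 15-minute steps (t) or
daily body weight (BW), centred and scaled to sample SD 1 (n−1 denominator)
per animal and period — can enter:

- the emission means, linearly: mu_i(z) = alpha_i + beta_i z (variances stay
  time-invariant);
- the transition matrix, additively on row-wise multinomial logits with the
  self-transition (diagonal) as the reference category, so every row sums to
  one at every z by construction.

t and BW are never mixed within one model. The transition matrix indexed at
step t governs the move from step t−1 to t; the generator uses the same
convention, so inference and simulation agree exactly. The candidate grid
crosses 2 and 3 states with 15 covariate placements (none; t or BW on the
movement mean, temperature mean, or both; t or BW on the transition matrix;
and transition-plus-emission combinations), 30 models in all, named HMM2.1
… HMM3.15.

Exact functional forms for the covariate effects were an open design point;
linear-on-means and additive-on-logits is the generalised-linear choice
consistent with the EM fitting scheme (weighted least squares and weighted
multinomial-logit regression are then exact M-steps), and it keeps mean
drift — the phenomenon of interest — identifiable without touching the
variances.

## Fitting

Maximum likelihood by EM with random restarts (default 10; grid studies in
the tests use 2–5, which the restart-dominance property shows is already
stable for well-separated states):

- E-step: scaled forward–backward with per-step normalisation; safe for
  ~10,000-step series. Kernels are numba-compiled.
- M-step, separately for prior, transition and response parameters:
  initial distribution ← gamma_1; transitions ← row-normalised expected
  counts (no covariate) or a per-row damped-Newton weighted multinomial
  logit on expected transition counts (tolerance 1e-9, ≤ 50 inner
  iterations); emission means ← gamma-weighted least squares on [1, z] per
  state and channel; variances ← gamma-weighted mean squared residuals.
- Convergence: relative log-likelihood change ≤ 1e-8 (default), max 500
  iterations. The log-likelihood trace is retained and is monotone.
- Guards: variances floored at 1e-6 (unpenalised Gaussian mixtures have
  unbounded likelihood; this is a numerical guard, not a model constraint —
  estimation is otherwise unconstrained). A restart whose state loses
  essentially all posterior mass (< 1e-6) is flagged failed; if all
  restarts fail the fit errors and model selection records the candidate as
  failed (two fresh restart batches are attempted first).
- Initialisation: emission intercepts at randomised channel quantiles
  spread across states (symmetry breaking), slopes 0, variances at channel
  sample variance, small random transition logits, uniform initial
  distribution. The initial distribution is then estimated (as gamma_1),
  not fixed.

After fitting, states are relabelled canonically by movement-mean intercept
descending (state 1 = most active; ties break by temperature intercept).
Because transition logits are referenced to each row's own diagonal, a
symmetric permutation maps diagonal to diagonal and the logits permute
without re-referencing.

Model selection is minimum AIC (= −2 loglik + 2k) per animal per period,
with ties broken toward fewer parameters, then lower grid index. The free
parameter count is (n−1) for the initial distribution, n(n−1) transition
intercepts (doubled when the transition covariate is present), and per
state two intercepts, two variances, and one slope per covariate-bearing
channel — e.g. 20 for the covariate-free 3-state model.

## Validation

Pseudo-residuals are one-step-ahead forecast residuals: for each observed
channel value x_t, u_t = Phi^{-1}(F_t(x_t)) where F_t is the mixture of
that channel's state-conditional normal CDFs weighted by the *filtered*
(past-only) state probabilities propagated one step through the transition
matrix. Under a correct model the u_t are iid standard normal; QQ pairings
use plotting positions (k−0.5)/n and report the QQ correlation. CDF values
at machine 0/1 are clamped to [1e-12, 1−1e-12] and counted. Movement counts
are discrete; the CDF is evaluated at the continuous log(count+1) value
with no randomisation — reproducibility is preferred over exact uniformity
for that channel, and the temperature channel is the cleaner calibration
check.

The second check is emergent diurnality: fitted models are light-phase
blind, so we decode the path (Viterbi, ties toward the lower state index),
compute state budgets separately for light and dark phases, and summarise
with total-variation distance. Under a phase-modulated generator this
distance is large (≈ 0.3 at the default settings); under a phase-constant
generator it is near 0.

## Interpretation statistics

State characteristics are summarised by 1000 seeded bivariate-normal draws
per state per animal (means evaluated at the start, halfway or end
covariate value). Paired BL-vs-CR contrasts evaluate each fit's means at
its own covariate endpoint — first/last observed step — and difference
them; transition matrices are differenced the same way on the probability
scale. Treatment effects are tested with one-way multivariate linear models
per state (responses: change in movement mean and temperature mean) and per
transition row (responses: that row's off-diagonal changes; the
self-transition column is dropped because rows sum to zero, and p-values
are Bonferroni-multiplied by the number of rows, capped at 1). Pillai's
trace V = tr(H(H+E)^{-1}) uses the standard F approximation; the reported
adjusted R² is the mean of the per-response univariate adjusted R² (a
multivariate fit has no canonical single R²). The implementation is checked
against statsmodels' MANOVA in the tests, and its null type-I error is
calibrated empirically.

Torpor is called when the fitted state-3 temperature mean, evaluated at the
end-of-treatment covariate value, is strictly below 31.0 °C ("dropping
below" is read as strict). A two-state fit is evaluated on its
lowest-temperature state with a warning.

## Synthetic cohort

The generator realises exactly the structure the model class assumes, plus
the features the fitted models deliberately omit:

- latent 3-state chain with distinct dark-phase and light-phase transition
  matrices (lights on 06:30–18:30); the fitted models are phase-blind;
- baseline emission parameters: movement-log means (2.5, 1.2, 0.2),
  variances (0.30, 0.25, 0.10); temperature means (37.0, 36.0, 35.5) °C,
  variances 0.25. Movement is drawn on the log scale and discretised to
  counts via round(exp(g) − 1) truncated at 0, so the Gaussian model on
  log(count+1) is approximately well-specified (the rounding bias is ≲ 0.02
  log-units at the lowest state, which parameter-recovery tolerances
  absorb);
- body weight: daily linear decline from bw_start to bw_end with 0.15 g
  daily noise, flat during baseline;
- drift: per-state total change in means across the treatment period,
  driven by t (linear in step) or by BW (linear in realised weight loss);
- missing windows at rate 0.02 (both channels, emulating tag failures);
- group sizes default to 8 animals, 14 baseline days, 90 treatment days.

The six bundled templates: 12AL and 24AL controls (no drift), 10CR and 20CR
(mild state-3 temperature drift, −0.5/−0.8 °C), 30CR (half the animals
drift, state-3 ending at 30.7 °C), 40CR (all animals drift, state-3
temperature 35.5 → 30.0 °C, time-driven). The 30CR drifting subset is the
lowest animal indices — deterministic, so the expected torpor pattern is
reproducible. What the generator does *not* emulate: food-anticipatory
activity, autocorrelated within-state noise, thermoregulatory dynamics, or
any feedback of behaviour on body weight. Passing tests therefore
demonstrate correctness of the estimation and testing machinery under the
assumed data-generating process, not physiological realism.

## Numerical and scale choices

- Forward/backward/Viterbi run on precomputed (T, n) emission log-densities
  and (T, n, n) transition stacks; per-step normalisation constants
  accumulate into the log-likelihood.
- Viterbi ties resolve toward the lower state index (strict-greater
  comparisons).
- Enumeration oracles (all n^T paths, T ≤ 8) verify the recursions to 1e-8.
- Test problem sizes: recovery studies use ~10,000-step series and 20
  seeds; the state-count study uses 8 animals × 5,000 steps with the
  covariate-free 2- vs 3-state pair; cohort-level property tests scale to 2
  animals per group and 20 treatment days (drift endpoints unchanged by
  scaling). These sizes were chosen so the full suite runs in a few minutes
  on one core while keeping Monte-Carlo error far below every tolerance.
- Pillai null calibration: 1000 replicates of 48 animals in 6 groups;
  empirical size at alpha = 0.05 is required to be in [0.03, 0.07].

## Known limitations

- Emission covariance is diagonal; a state with correlated movement and
  temperature noise would be mis-specified.
- At most 3 states and one covariate; no covariate effects on variances.
- AIC comparisons assume the per-animal series are long enough that the
  penalty scale is appropriate; no small-sample correction is applied.
- Standard errors for HMM parameters are not computed; inference about
  treatment effects runs through the cohort-level multivariate linear
  models instead.
- The discrete movement channel makes its pseudo-residuals slightly
  granular at low activity; calibration tests lean on the continuous
  temperature channel.
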