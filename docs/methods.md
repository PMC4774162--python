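# Methods

## Models

**Cox proportional hazards.** Hazard λ(t|x) = λ₀(t)·exp(β′x) with an
unspecified baseline λ₀. Fitting maximizes the Breslow log partial likelihood

l(β) = (1/n) Σ_{r∈D} [β′x₍ᵣ₎ − log Σ_{j∈R_r} exp(β′xⱼ)],

where D indexes observed events and R_r = {j : tⱼ ≥ t₍ᵣ₎} is the risk set.
Ties are handled by the Breslow convention throughout (tied events share a
risk set), matching the Breslow estimator used for the baseline cumulative
hazard Ĥ₀(t) = Σ_{t₍ᵣ₎≤t} d_r / Σ_{j∈R_r} exp(β′xⱼ) and the predicted
survival curves Ŝ(t|x) = exp(−Ĥ₀(t)·exp(β′x)).

**Accelerated failure time (AFT).** h(tᵢ) = β₀ + xᵢ′β + εᵢ with h = log
(the conventional choice for positive times; any monotone transform could be
substituted). Censored responses are replaced by Kaplan–Meier conditional
means before least squares:

h(t*ᵢ) = δᵢ·h(tᵢ) + (1−δᵢ)·Ŝ(tᵢ)⁻¹ Σ_{t₍ᵣ₎>tᵢ} h(t₍ᵣ₎) ΔŜ(t₍ᵣ₎),

with ΔŜ the drop of the product-limit curve at each event time. The sum runs
over *strictly* later event times; a censored time tied with an event uses
later events only. A censored sample with no later event has an empty sum:
it receives the last event time as a redistribute-to-the-right fallback and
is flagged `undefined_tail` so downstream steps can exclude it.

**L<sub>1/2</sub> penalty.** Both models minimize loss + λ·Σⱼ|βⱼ|^{1/2}.
With features standardized to mean 0 and Σx² = n, and the quadratic loss
written (1/n)‖y − Xβ‖², each coordinate subproblem is
(β − ωⱼ)² + λ|β|^{1/2} with ωⱼ the partial-residual regression weight, whose
*exact* global minimizer is the half-thresholding operator: 0 when
|ωⱼ| ≤ (∛54/4)·λ^{2/3}, else (2/3)ωⱼ(1 + cos(2(π − φ_λ(ωⱼ))/3)) with
φ_λ(ω) = arccos((λ/8)(|ω|/3)^{−3/2}). At the boundary the operator returns 0
(the strict-inequality tie-break; at that point the zero and interior
solutions have equal objective). Because each update is an exact scalar
minimization, the penalized objective is non-increasing along the cyclic
sweep, which is the solver's contract — the objective is nonconvex, so
fixed conventions (cyclic order, zero initialization, warm starts down a
log-spaced λ path) define *which* local minimum is reported, and global
optimality is not claimed.

Some texts state the same operator for the loss ½(β−ω)² + μ|β|^{1/2}; the two
normalizations coincide under μ = 2λ, with zeroing threshold (3/2)·μ^{2/3}.

**Cox inner loop.** The partial likelihood is reduced to the penalized
least-squares form by iteratively reweighted least squares: at the current
η = Xβ the gradient g and diagonal Hessian w of the log partial likelihood
with respect to η define the working response z = η + g/w and observation
weights w/2. Weights are floored at 1e−8; the weighted coordinate subproblem
is rescaled exactly (operator applied to cⱼ/aⱼ with penalty λ/aⱼ, where aⱼ is
the weighted column scale). A step-halving safeguard rejects IRLS steps that
increase the true penalized objective — the quadratic model of a nonconvex
objective can overshoot — and a diverging inner problem (possible at very
small λ when p ≫ n allows the partial likelihood to be driven to infinity)
terminates the fit at the last finite iterate.

## Penalty tuning

Stratified K-fold cross-validation (K = 5), stratified on the event indicator
only — censoring imbalance across folds is what destabilizes the CV criteria.
Cox uses the Verweij–van Houwelingen cross-validated partial likelihood
cvl_k = l_full(β₋ₖ) − l₋ₖ(β₋ₖ); the AFT uses held-out mean squared error on
the h scale, scored only against trustworthy responses (observed events or
previously validated imputations — never against fabricated targets). Ties
prefer the larger (sparser) λ. The path has 15 log-spaced values from λ_max
(the smallest λ that zeroes every coefficient from a zero start, solved in
closed form from the threshold condition) down to 0.05·λ_max.

## The semi-supervised loop

Per iteration, with the current training set = complete samples ∪ previously
accepted imputations (the latter as events at their imputed times):

1. CV-tune and fit the Cox model on the training set. If the tuned model is
   empty (possible on weak signal), descend the λ path to the largest λ with
   a nonempty support — an empty model cannot classify, and the loop's
   purpose requires a split; the descent is logged.
2. Score **all** samples; threshold at the median training score;
   label high risk above the threshold.
3. Within each risk class, impute every censored sample's log-time by the
   conditional-mean formula using the Kaplan–Meier curve of the class's
   **original complete samples**. Using only completed data keeps the
   imputation from feeding on its own previous output (accepted imputations
   would otherwise extend the class curve each round and eventually validate
   everything); a censored time beyond the class's last complete event
   remains unimputable no matter how the training set grows.
4. CV-tune and fit the AFT model on the training samples plus the
   class-imputed censored samples, then re-evaluate every censored sample's
   survival time from its covariates.
5. The accepted imputation is the AFT re-evaluation when that prediction is
   itself consistent with the censoring (strictly exceeds the censored
   time) — the re-evaluation is authoritative, with the class conditional
   mean (which exceeds the censored time by construction whenever defined)
   standing otherwise. A sample with neither — its class imputation is
   degenerate and the AFT prediction falls at or below the censored time —
   is an "error estimation", excluded from training this round. Equality
   carries no information beyond the censoring itself, hence the strict
   inequality.
6. Stop when the accepted set is unchanged between iterations, or after
   `max_iters` (default 5) iterations; final models are refit on the
   terminal augmented set if it changed after the last fit.

Typical behaviour on the reference design: the loop stabilizes in 2–4
iterations and ~97–100 % of censored samples are recovered at n = 300
(fewer at n = 100 or under correlation, where risk classes are estimated
less accurately and class tails are shorter).

## Synthetic data

The generator emulates a high-dimensional expression study with a sparse
proportional-hazards signal:

- covariates X_ij = γ_ij·√(1−ρ) + γ_i0·√ρ with γ ~ N(0,1): every column is
  standard normal and every pair of columns has correlation ρ;
- event times by inverse-transform sampling from a Gompertz hazard,
  y = (1/α)·log(1 − α·log(U)/(ω·exp(β′x))), U ~ Uniform(0,1);
- independent exponential censoring; the rate θ is found by root bracketing
  on the expected censored fraction given the realized latent times, then
  observed time = min(y, c) and δ = 1(y < c) (ties censor);
- defaults: p = 1000 features, the first 10 carrying coefficient 1.0,
  α = ω = 1, target censoring 40 %, n ∈ {100, 200, 300}, ρ ∈ {0, 0.3}.

The defaults fix the study conditions; the nonzero-coefficient magnitude and
Gompertz parameters are configurable because absolute selection difficulty
depends strongly on them. With unit coefficients the linear predictor has
standard deviation √10 — a strong signal under which CV-tuned
L<sub>1/2</sub> selection is nearly exact at n = 300 (precision close to 1
for all pipelines, with the semi-supervised variants at or above the single
models). Weaker, unequal coefficients would push all precisions down and
widen the semi-vs-single gap; the package's comparative claims (semi ≥
single on correct selections, classification accuracy improving with the
recovered samples, precision increasing with n and decreasing with ρ) are
the generator-robust content of the simulation study. What the generator
does **not** emulate: heavy-tailed expression distributions, block
correlation structure, batch effects, or informative censoring — passing
tests on this generator says nothing about those.

## Evaluation statistics

- **Brier score / IBS:** BS(t) averages the squared error of predicted
  survival probabilities with inverse-probability-of-censoring weights from
  the Kaplan–Meier curve Ĝ of the censoring distribution, evaluated at left
  limits Ĝ(t⁻) so an event is never weighted by a drop at its own time;
  zero-weight samples are excluded with the denominator adjusted. The
  integrated score averages BS over [0, max tᵢ]; for the step-function
  predictors used here BS is piecewise constant between observed times and
  the integral is an exact sum (evaluated at interval midpoints — an
  endpoint would straddle a drop of Ĝ).
- **Concordance index:** fraction of comparable pairs (tᵢ < tⱼ with δᵢ = 1)
  whose predictions are strictly concordant; tied predictions never count;
  Cox risk scores are negated so that larger always means longer predicted
  survival.
- **Selection precision:** correctly selected features / all selected
  features; a replicate that selects nothing is flagged undefined and
  excluded from averages.

## Numerical conventions and defaults

| parameter | default | meaning |
|---|---|---|
| `tol_cd` | 1e-5 | max coefficient change ending a CD sweep cycle |
| `max_sweeps` | 10⁴ | CD sweep cap |
| `tol_irls` | 1e-4 | max change of η between IRLS cycles |
| `max_irls` | 100 | IRLS cycle cap |
| `n_lambdas`, `lambda_min_ratio` | 15, 0.05 | λ-path geometry |
| `cv` / `folds` | 5 | stratified folds |
| `max_iters` | 5 | semi-supervised iterations |
| `threshold_rule` | median | risk-class boundary |

Features are standardized internally (mean 0, Σx² = n) and coefficients are
returned on the original scale together with the intercept shift that makes
X·β_raw + shift equal the standardized-scale linear predictor. Constant
columns are dropped with a warning. Input tables must have strictly positive
times and {0,1} status; offending rows are named, never silently dropped,
since silent loss corrupts censoring rates.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` runs 10 replicates at (n=300, ρ=0) and (n=100,
ρ=0.3), and 5 replicates at each of (100, 0), (200, 0), (200, 0.3) and
(300, 0.3); the full-size study would use 50 replicates per setting. All
seeds derive deterministically from `--seed`.

## Known limitations

- The nonconvex objective makes every fit initialization-dependent; the
  package fixes and documents its conventions rather than claiming global
  optima.
- Both models see all p features each iteration (independent selection); the
  variant restricting the AFT design to Cox-selected genes is available as
  `restrict_aft_to_cox_genes=True` but is not the default, since the two
  models legitimately select different feature sets.
- No Efron ties, time-varying covariates, stratified baselines, or
  alternative AFT estimators (Buckley–James, rank-based, IPW).
- The imputation loop assumes non-informative censoring within risk classes;
  informative censoring would bias the conditional means upward or downward
  undetectably.
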