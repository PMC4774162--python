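# semisurv

Semi-supervised survival analysis for high-dimensional censored data, built
around L<sub>1/2</sub>-regularized Cox and accelerated failure time (AFT)
models.

## The problem

Gene-expression survival studies typically have a few hundred samples, a
thousand or more features, and 30–60 % right censoring. A Cox proportional
hazards classifier trained only on the complete (uncensored) samples wastes
much of the cohort; an AFT regression needs a full response vector, which
censoring denies it. `semisurv` couples the two models in a semi-supervised
loop that turns most censored samples into usable training data:

1. fit an L<sub>1/2</sub>-penalized Cox model λ(t|x) = λ₀(t)·exp(β′x) on the
   complete samples (plus any previously accepted imputations) and split all
   samples into low/high prognostic classes at the median linear predictor;
2. inside each risk class, impute every censored log-time by its Kaplan–Meier
   conditional mean
   h(t*ᵢ) = Ŝ(tᵢ)⁻¹ · Σ_{t₍ᵣ₎ > tᵢ} h(t₍ᵣ₎) ΔŜ(t₍ᵣ₎),
   the survivor-weighted average of the class's later event times;
3. fit an L<sub>1/2</sub>-penalized AFT model h(tᵢ) = β₀ + xᵢ′β + εᵢ on the
   augmented data and re-evaluate each censored sample's survival time;
4. accept an imputation only if it strictly exceeds the observed censored
   time ("error estimations" are discarded), add the accepted samples to the
   training set as events, and repeat until the accepted set stabilizes.

Both models use the nonconvex penalty λ·Σⱼ|βⱼ|^{1/2}, solved by cyclic
coordinate descent with the analytic half-thresholding operator: a
coefficient with univariate regression weight ω is set to 0 when
|ω| ≤ (∛54/4)·λ^{2/3} and otherwise shrunk through a closed-form cosine
expression — markedly sparser than the lasso. λ is tuned by stratified
5-fold cross-validation (cross-validated partial likelihood for Cox,
held-out squared error for the AFT).

## Worked example

```python
import numpy as np
from semisurv import (SimulationConfig, simulate_dataset,
                      SemiSupervisedCoxAFT, CoxL12, selection_precision)

truth = simulate_dataset(SimulationConfig(n=300, p=1000, n_informative=10,
                                          rho=0.0, censor_rate=0.4, seed=7))
ds = truth.dataset

single = CoxL12(lam="auto", random_state=0).fit(
    ds.X[ds.status == 1], time=ds.time[ds.status == 1],
    status=ds.status[ds.status == 1])
semi = SemiSupervisedCoxAFT(random_state=0).fit(ds.X, time=ds.time,
                                                status=ds.status)

for name, sel in [("single Cox", single.selected_),
                  ("semi Cox", semi.cox_.selected_),
                  ("semi AFT", semi.aft_.selected_)]:
    r = selection_precision(sel, truth.true_support)
    print(f"{name}: {r.n_correct}/{r.n_selected} correct, "
          f"precision {r.precision:.3f}")
print(f"censored samples recovered: {len(semi.validated_)} of "
      f"{int((ds.status == 0).sum())}")
```

prints

```
single Cox: 10/13 correct, precision 0.769
semi Cox: 10/10 correct, precision 1.000
semi AFT: 10/10 correct, precision 1.000
censored samples recovered: 126 of 126
```

The single Cox model, fitted on the 174 complete samples alone, already finds
all 10 informative genes but carries 3 false positives; the semi-supervised
loop recovers the censored samples (here all 126) and cleans the selection to
exactly the true support for both models.

A command-line interface mirrors the library:
`semisurv simulate|fit-cox|fit-aft|impute|semisup|evaluate|experiment`
(see `semisurv --help`).

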