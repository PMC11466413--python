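# numbci

Bayesian causal-inference observer models for audiovisual **number
estimation** (the flash-beep / sound-induced-flash-illusion paradigm):
simulation, maximum-likelihood fitting, group-level Bayesian model
selection, behavioral weighting indices, sequential-prior analyses, and
sliding-window EEG decoding — all runnable end to end on synthetic data.

## Who this is for

Computational psychophysicists and cognitive-modelling researchers who want
a tested, reproducible implementation of the standard *Bayesian causal
inference* (BCI) observer for discrete numerosity tasks, together with the
analysis stack that typically surrounds it: factorial model comparison with
protected exceedance probabilities, crossmodal-bias indices,
randomization/cluster statistics, and multivariate EEG decoding of
model-internal estimates.

## The model

On each trial an observer receives `n_A ∈ {1..4}` beeps and `n_V ∈ {1..4}`
flashes and reports the count in the task-relevant modality with one of 4
buttons. Internally the observer draws noisy sensory inputs

    x_A ~ N(n_A, σ'_A),   x_V ~ N(n_V, σ'_V),
    σ'_M = σ_M + Δσ_M (n_M − 1)        (scalar variability; Δσ ≡ 0 in
                                        constant-variance models)

and holds a Gaussian numeric prior `N(μ_P, σ_P)` plus a causal prior
`p_common` that both streams share one cause. The posterior probability of a
common cause follows from Bayes' rule with closed-form Gaussian marginal
likelihoods. Under a common cause the optimal estimate fuses both inputs and
the prior by their precisions,

    N̂_AV,C=1 = (x_A/σ'²_A + x_V/σ'²_V + μ_P/σ_P²) /
               (1/σ'²_A + 1/σ'²_V + 1/σ_P²),

while under independent causes each modality is combined with the prior
alone (segregation estimates). Five decision strategies turn these into a
final estimate: **model averaging** (posterior-weighted mix), **model
selection** (posterior > 0.5), **probability matching** (fusion with
probability equal to the posterior), **fixed criterion** (fusion iff
`|x_A − x_V| < k`), and **stochastic fusion** (fusion with fixed probability
η). Crossed with the two sensory-variance modes this spans a 5 × 2 factorial
model space of 10 candidate observers, each with a lapse rate `L`.

Fitting is per subject by simulation-based maximum likelihood (common random
numbers make the surface deterministic; multi-start bounded Powell).
Group-level inference uses −BIC/2 as log model evidence in random-effects
Bayesian model selection with protected exceedance probabilities (PXP) and
the Bayesian omnibus risk (BOR), including family-level inference over the
two factors and a between-group frequency comparison.

## Worked example

```python
import numpy as np
from numbci import (ModelSpec, SimulationState, av_conditions,
                    unisensory_conditions, simulate_trials,
                    ObserverParams, fit_mle)

truth = ObserverParams(p_common=0.5, mu_p=2.5, sigma_p=1.5,
                       sigma_a=0.4, sigma_v=1.0,
                       dsigma_a=0.2, dsigma_v=0.5, lapse=0.05)
spec = ModelSpec("MA", "scalar")
conds = av_conditions() + unisensory_conditions()
table = simulate_trials(conds, truth, spec, SimulationState(1, n_sim=160), 160)

fit = fit_mle(table, spec, n_inits=8, state=SimulationState(7, n_sim=2000),
              maxfev=700)
print(f"logL = {fit.loglik:.1f}, BIC = {fit.bic:.1f}")
print(f"p_common = {fit.params.p_common:.3f}  (truth 0.5)")
print(f"sigma_p  = {fit.params.sigma_p:.3f}  (truth 1.5)")
```

Output from this exact script:

```
logL = -6243.1, BIC = 12556.2
p_common = 0.500  (truth 0.5)
sigma_p  = 1.511  (truth 1.5)
```

`logL` is the summed log-likelihood of the 6,400 simulated button reports
under the best of 8 optimizer starts; the recovered causal prior and
numeric-prior width sit close to the generating values, which is the basic
sanity check before interpreting fitted parameters on real data.

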