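# Methods

This note documents the models and procedures implemented in `numbci`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## The generative observer

A trial presents `n_A` beeps and `n_V` flashes (each 0–4; 0 = absent) and
asks for the count in one modality. The observer model has up to eight
parameters:

| parameter | meaning | units | bounds used in fitting |
|---|---|---|---|
| `p_common` / `k` / `η` | causal prior (MA/MS/PM) / disparity criterion (FC) / fusion probability (SF) | prob. / counts / prob. | [0,1] / [0,6] / [0,1] |
| `μ_P` | numeric-prior mean | counts | [0, 6] |
| `σ_P` | numeric-prior std | counts | [0.05, 6] |
| `σ_A`, `σ_V` | baseline sensory std | counts | [0.05, 6] |
| `Δσ_A`, `Δσ_V` | std increment per extra event (scalar variability) | counts | [0, 3]; fixed 0 in constant-variance models |
| `L` | lapse rate (uniform random report) | prob. | [0, 1] |

Sensory inputs are `x_M ~ N(n_M, σ'_M)` with `σ'_M = σ_M + Δσ_M (n_M − 1)`.
The same effective σ' enters both the generative draw and the observer's
inference weights: the observer is assumed to know its own noise level, and
no separate belief-noise model is introduced. The causal posterior uses the
closed-form Gaussian marginals

    p(x_A, x_V | C=1) = ∫ N(x_A; N, σ'_A) N(x_V; N, σ'_V) N(N; μ_P, σ_P) dN
    p(x_A, x_V | C=2) = N(x_A; μ_P, √(σ'²_A+σ_P²)) · N(x_V; μ_P, √(σ'²_V+σ_P²))

validated in the tests against numerical quadrature to ≤ 1e-6. The model
selection strategy (MS) reports the fusion estimate whenever
`p(C=1|x) > 0.5`; the fusion estimate in all strategies is the audiovisual
`N̂_AV,C=1`, and unisensory trials bypass causal inference entirely and use
the segregation estimate of the present modality (so unisensory runs inform
σ, μ_P, σ_P and L jointly with the audiovisual runs during fitting).

Stochastic strategies (PM, SF) consume one uniform draw `α` per trial from
the simulation state's RNG stream, after the sensory draws, so that a seed
fully determines every trial.

## Likelihood and fitting

Button-report probabilities are simulation-based: per condition, `n_sim`
final estimates are discretized (nearest integer, ties half-up, clipped to
1–4) and the resulting pmf is mixed with the lapse,
`pmf' = (1−L)·pmf + L/4`, then floored at 1e-6 before taking logs. The
standard-normal and uniform draws are keyed by (seed, condition) and reused
across parameter evaluations (common random numbers), so the likelihood
surface is deterministic and two evaluations at the same parameters are
bit-identical. The default `n_sim` is 5,000 per condition.

Optimization is multi-start bounded Powell (derivative-free) with uniform
random starts inside the box bounds above; 50 starts is the production
default, and the recovery analyses in this repository use 3–8 starts with a
capped number of objective evaluations to stay within a desk-scale compute
budget. The bounds are generous physical ranges for counts 1–4 and are not
themselves data-derived. Constant-variance models fit 6 free parameters,
scalar-variance models 8; `BIC = d·ln(n_trials) − 2·logL`.

A caution from the recovery experiments: with few optimizer starts the
sensory-noise parameters acquire occasional poor local optima that inflate
the recovered-vs-generating regression slope; at 8 starts with ≥ 2,000
simulated trials per condition all slopes fall within [0.8, 1.2]. Fit
quality therefore matters more than data quantity for σ_V in this design.

## Group-level model selection

Log model evidence per subject and model is −BIC/2. Random-effects BMS uses
the variational Dirichlet scheme (uniform prior α₀ = 1): responsibilities
`u_nm ∝ exp(lme_nm + ψ(α_m) − ψ(Σα))`, `α = α₀ + Σ_n u_n`. Exceedance
probabilities come from 10⁵ seeded Dirichlet draws. The Bayesian omnibus
risk compares the variational free energy of this model against the
equal-frequency null, `F₀ = Σ_n (logsumexp_m lme_nm − ln M)`, via
`BOR = 1/(1+exp(F₁−F₀))`, and `PXP = (1−BOR)·EP + BOR/M`.

Two properties of this standard scheme are worth knowing and are asserted in
the tests rather than hidden: (i) the mean-field factorization makes the
expected frequencies mildly over-confident relative to the exact posterior
at very small n (deviations up to ~0.07 on 3-subject problems, verified
against an exact assignment-enumeration oracle) — direction and ranking are
preserved; (ii) for perfectly exchangeable evidences BOR is not 1 but
~0.81 at 8 subjects, approaching 1 as n grows, because the free energy is a
lower bound while the exact null-vs-alternative Bayes factor is 1.

Family inference aggregates per-subject member evidences by log-mean-exp
(uniform within-family prior) and reruns the BMS over families. The
between-group test compares free energies: `F_same` from pooling both
groups, `F_diff` from fitting each separately; `BF₁₀ = exp(F_diff −
F_same)` with equal prior odds.

## Behavioral indices

*Accuracy* is the Fisher-z Pearson correlation between report and the true
task-relevant count, computed per subject for unisensory and congruent
audiovisual trials; r is clipped to ±(1−1e-8) before atanh because perfect
correlations do occur in synthetic data.

*Crossmodal bias* (CMB) is computed on incongruent audiovisual cells as
`(mean report − ñ_A)/(ñ_V − ñ_A)`, where ñ are the true counts passed
through a per-subject, per-task OLS regression of congruent-trial reports on
the true count (bias adjustment). The regression is fitted separately per
task modality because auditory- and visual-report trials have different
response mappings. Cells are averaged into disparity levels after the CMB
is formed per cell; cells whose adjusted denominator is < 1e-9 are flagged
invalid.

*Illusion strength* is the d′ difference between the unisensory baseline
(1 vs 2 flashes, no sound) and the illusion conditions, with response "2"
(fission) or "1" (fusion) as the signal, visual-report trials with reports
≤ 2 only, and hit/false-alarm rates clipped at 1/(2N).

*Randomization tests* permute group labels (two-sample) or flip signs
(one-sample/paired), use the t statistic, and include the observed value in
the p-value: `p = (1 + #extreme)/(1 + n_perm)`; 5,000 permutations is the
production default, reduced in the calibration simulations.

## Sequential priors

History tags are computed within subject and run only (runs break history);
the first trial of a run, and disparity after a unisensory trial, are
undefined. Conditional refits re-optimize only `p_common` (by previous
disparity 0–3) or only `(μ_P, σ_P)` (by previous task-relevant count 1–4)
with all other parameters frozen at the subject's full-data fit; bins under
20 trials are flagged low-power. A null-simulation point: with the design's
bin sizes (~160–480 trials) the per-bin MLE of `p_common` has sampling sd
near 0.1, so bin-to-bin scatter of that order is expected under a constant
prior; the meaningful null check is the absence of a systematic monotone
trend, and the meaningful positive check is recovery of an imposed monotone
schedule.

## EEG pipeline

Epochs are trials × 64 channels × samples at 200 Hz over −100..750 ms.
Sliding windows are 60 ms advancing by 20 ms; the twelve 64-channel sample
vectors in a window are concatenated (sample-major) into 768 features, and
each window is labelled by its first sample's time. Features are z-scored
with training-fold statistics only — fold-wise rather than global scoring is
the conservative choice against leakage. Decoding is linear ν-SVR under
leave-one-run-out cross-validation with a nested leave-one-run-out grid
search over C (decade grid 10⁻³..10³) and ν (0.1..0.8 in steps of 0.1);
the tests use reduced grids. Accuracy is the Fisher-z correlation between
pooled held-out predictions and the labels. Labels are the per-condition
modes (Gaussian KDE, Silverman bandwidth, 512-point grid) of the four model
estimates — visual segregation, auditory segregation, fusion, final — over
10,000 simulated trials per condition.

The ERP contrast averages occipital channels (O1, O2, Oz, PO3, POz, PO4)
and computes `AV_congruent − (A + V)` after prestimulus baseline
correction. Cluster statistics threshold the pointwise t series at |t| > 2,
define clusters as contiguous same-sign runs, score them by the summed t,
and compare against the permutation null of the maximum cluster mass
(sign flips or label permutations); one-sided tests are used for
accuracy-above-zero, two-sided for group differences.

## Synthetic data

The design generator reproduces the standard flash-beep session layout: audiovisual runs of 160
trials (16 count combinations × 10 repeats, shuffled), half auditory- and
half visual-report, plus unisensory runs of 4 × 40 trials; button order
alternates ascending/descending across runs; stimulus slots at 0, 66.7,
133, 200 ms with a 66.6-ms SOA are carried as metadata.

Cohort presets centre the parameters on mid-range values (p_common 0.5,
μ_P 2.5, σ_P 1.5, σ_A 0.4, σ_V 1.0, Δσ 0.2/0.5, L 0.05) with modest
between-subject spread; these are declared presets, not published
estimates. The patient-like preset differs only in a smaller σ_P (1.0),
the direction expected for a group that over-relies on prior knowledge
relative to incoming sensory evidence. Sequential-prior updating
can be imposed by mapping the previous trial's disparity (or count) to a
per-trial `p_common` (or `μ_P`).

Forward-modeled EEG embeds each chosen estimate as
`pattern ⊗ Gaussian-bump(t) · (condition-mode value − grand mean)` plus
white/1-f channel noise. This is exactly the linear structure the decoding
analysis assumes — passing the decoding tests on these data shows the
pipeline is correct and leak-free, not that real EEG contains such signals;
nonlinear mixing, trial-varying latencies, artifacts, and correlated noise
are all absent by construction. Likewise the behavioral generator draws
i.i.d. trials from the fitted model family, so model-recovery results
certify identifiability within the family, not the adequacy of the family
for real observers.

## Problem sizes used in this repository

The test-suite and acceptance-script runs use deliberately reduced scales
chosen as desk-scale defaults: model recovery with 6 subjects per
generating model, 160 trials per condition, 4 optimizer starts; parameter
recovery with 20 subjects at 8 starts; end-to-end family inference with 15
(tests) or 12 (script) subjects at 3 starts; decoding on thinned 4-run
designs with single-point hyperparameter grids. Production analyses should
restore 50 starts, 5,000-trial pmfs, and the full grids.

## Known limitations

- The simulation-based likelihood has resolution 1/n_sim per cell; the 1e-6
  pmf floor bounds the log-likelihood contribution of unresolvable cells.
- Powell with box bounds can stall on ridges (σ vs Δσ trade-off); the
  multi-start scheme mitigates but does not eliminate this at small start
  counts.
- The VB-BMS biases documented above are properties of the standard
  algorithm, inherited deliberately.
- No hierarchical (group-level) parameter estimation; fits are per subject.
- The EEG module assumes preprocessed, baseline-corrected epochs; no
  filtering or artifact handling is provided.
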