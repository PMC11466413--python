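"""Generative Bayesian-causal-inference (BCI) observer for audiovisual number
estimation.

The observer receives a sequence of 1-4 beeps and 1-4 flashes and reports the
number of events in the task-relevant modality.  Internally it draws noisy
sensory inputs ``x_A ~ N(n_A, sigma'_A)`` and ``x_V ~ N(n_V, sigma'_V)``,
infers the posterior probability that both streams share a single cause, and
combines the forced-fusion estimate (reliability-weighted average of both
inputs and a Gaussian numeric prior) with the task-relevant segregation
estimate according to one of five decision strategies:

``MA``  model averaging      -- posterior-weighted average of the estimates
``MS``  model selection      -- whichever causal structure is more probable
``PM``  probability matching -- fusion with probability equal to the posterior
``FC``  fixed criterion      -- fusion iff ``|x_A - x_V| < k``
``SF``  stochastic fusion    -- fusion with a fixed probability ``eta``

A second model factor lets the sensory standard deviation grow linearly with
the presented count (scalar variability): ``sigma' = sigma + dsigma*(n - 1)``.
All marginal likelihoods needed for the causal posterior are Gaussian
integrals with closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "STRATEGIES",
    "VARIANCE_MODES",
    "ModelSpec",
    "ObserverParams",
    "Condition",
    "SimulationState",
    "InternalSamples",
    "effective_sigma",
    "sample_sensory_inputs",
    "fusion_estimate",
    "segregation_estimate",
    "causal_posterior",
    "final_estimate",
    "simulate_trials",
    "av_conditions",
    "unisensory_conditions",
]

STRATEGIES = ("MA", "MS", "PM", "FC", "SF")
VARIANCE_MODES = ("constant", "scalar")

# strategies whose causal parameter is p_common (a posterior is computed)
_POSTERIOR_STRATEGIES = ("MA", "MS", "PM")


@dataclass(frozen=True)
class ModelSpec:
    """One point in the 5 (decision strategy) x 2 (sensory variance) space."""

    strategy: str = "MA"
    variance_mode: str = "scalar"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if self.variance_mode not in VARIANCE_MODES:
            raise ValueError(
                f"unknown variance_mode {self.variance_mode!r}; expected one of {VARIANCE_MODES}"
            )

    @property
    def uses_posterior(self) -> bool:
        return self.strategy in _POSTERIOR_STRATEGIES

    @property
    def causal_param_name(self) -> str:
        if self.strategy in _POSTERIOR_STRATEGIES:
            return "p_common"
        return "k" if self.strategy == "FC" else "eta"

    @property
    def label(self) -> str:
        return f"{self.strategy}-{self.variance_mode}"

    @staticmethod
    def all_specs() -> list["ModelSpec"]:
        return [ModelSpec(s, v) for v in VARIANCE_MODES for s in STRATEGIES]


@dataclass
class ObserverParams:
    """Parameters of one observer model.

    Exactly one of ``p_common`` (MA/MS/PM), ``k`` (FC, in count units) or
    ``eta`` (SF) plays the role of the causal parameter; the other two slots
    may stay ``None``.  ``dsigma_a``/``dsigma_v`` are the per-count increments
    of the sensory standard deviations and must be 0 under constant variance.
    """

    p_common: float | None = None
    k: float | None = None
    eta: float | None = None
    mu_p: float = 2.5
    sigma_p: float = 1.5
    sigma_a: float = 0.5
    sigma_v: float = 1.0
    dsigma_a: float = 0.0
    dsigma_v: float = 0.0
    lapse: float = 0.0

    def causal_value(self, spec: ModelSpec) -> float:
        name = spec.causal_param_name
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"strategy {spec.strategy} requires parameter {name!r}")
        return float(value)

    def validate(self, spec: ModelSpec) -> None:
        c = self.causal_value(spec)
        if spec.causal_param_name in ("p_common", "eta") and not 0.0 <= c <= 1.0:
            raise ValueError(f"{spec.causal_param_name} must lie in [0, 1], got {c}")
        if spec.causal_param_name == "k" and c < 0.0:
            raise ValueError(f"k must be non-negative, got {c}")
        for name in ("sigma_p", "sigma_a", "sigma_v"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("dsigma_a", "dsigma_v"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        if spec.variance_mode == "constant" and (self.dsigma_a != 0.0 or self.dsigma_v != 0.0):
            raise ValueError("constant-variance models require dsigma_a = dsigma_v = 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    def with_causal(self, spec: ModelSpec, value: float) -> "ObserverParams":
        return replace(self, **{spec.causal_param_name: value})


@dataclass(frozen=True)
class Condition:
    """One stimulus/task cell: counts ``n_a``/``n_v`` in 0..4 (0 = absent)."""

    n_a: int
    n_v: int
    task: str  # "A" or "V"

    def __post_init__(self) -> None:
        if not (0 <= self.n_a <= 4 and 0 <= self.n_v <= 4):
            raise ValueError("counts must lie in 0..4")
        if self.n_a == 0 and self.n_v == 0:
            raise ValueError("at least one modality must be present")
        if self.task not in ("A", "V"):
            raise ValueError("task must be 'A' or 'V'")

    @property
    def audiovisual(self) -> bool:
        return self.n_a > 0 and self.n_v > 0

    @property
    def disparity(self) -> int:
        if not self.audiovisual:
            raise ValueError("disparity is defined only for audiovisual conditions")
        return abs(self.n_a - self.n_v)


def av_conditions() -> list[Condition]:
    """The 32 audiovisual condition x task cells of the factorial design."""
    return [
        Condition(n_a, n_v, task)
        for task in ("A", "V")
        for n_a in range(1, 5)
        for n_v in range(1, 5)
    ]


def unisensory_conditions() -> list[Condition]:
    """The 8 unisensory cells (4 auditory-only + 4 visual-only)."""
    return [Condition(n, 0, "A") for n in range(1, 5)] + [
        Condition(0, n, "V") for n in range(1, 5)
    ]


class SimulationState:
    """Seeded RNG stream for observer simulations.

    One instance carries a persistent generator: sensory inputs are drawn
    first, then one uniform ``alpha`` per trial for the stochastic strategies
    (PM/SF), so the same seed reproduces the full trial stream bit for bit.
    """

    def __init__(self, seed: int, n_sim: int = 5000):
        if n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        self.seed = int(seed)
        self.n_sim = int(n_sim)
        self.rng = np.random.default_rng(self.seed)

    def reset(self) -> "SimulationState":
        self.rng = np.random.default_rng(self.seed)
        return self

    def condition_rng(self, cond: Condition) -> np.random.Generator:
        """Independent per-condition stream (common random numbers)."""
        task_code = 0 if cond.task == "A" else 1
        ss = np.random.SeedSequence((self.seed, cond.n_a, cond.n_v, task_code))
        return np.random.default_rng(ss)


@dataclass
class InternalSamples:
    """Latent variables of simulated trials for one condition."""

    x_a: np.ndarray | None
    x_v: np.ndarray | None
    n_hat_a_seg: np.ndarray | None = None
    n_hat_v_seg: np.ndarray | None = None
    n_hat_fus: np.ndarray | None = None
    n_hat_final: np.ndarray | None = None
    post_c1: np.ndarray | None = None


def effective_sigma(
    params: ObserverParams, spec: ModelSpec, count: int, modality: str
) -> float:
    """Sensory std for ``count`` presented events: ``sigma + dsigma*(count-1)``.

    Under constant variance the increment is fixed at zero and the baseline
    std is returned unchanged.
    """
    if count < 1:
        raise ValueError("count must be >= 1 for a present modality")
    if modality == "A":
        base, inc = params.sigma_a, params.dsigma_a
    elif modality == "V":
        base, inc = params.sigma_v, params.dsigma_v
    else:
        raise ValueError("modality must be 'A' or 'V'")
    if spec.variance_mode == "constant":
        return float(base)
    return float(base + inc * (count - 1))


def sample_sensory_inputs(
    cond: Condition,
    params: ObserverParams,
    spec: ModelSpec,
    state: SimulationState,
) -> InternalSamples:
    """Draw ``n_sim`` noisy sensory inputs for one condition.

    ``x_a ~ N(n_a, sigma'_A)`` and ``x_v ~ N(n_v, sigma'_V)`` independently;
    an absent modality yields ``None`` for its channel.
    """
    x_a = x_v = None
    if cond.n_a > 0:
        s = effective_sigma(params, spec, cond.n_a, "A")
        x_a = cond.n_a + s * state.rng.standard_normal(state.n_sim)
    if cond.n_v > 0:
        s = effective_sigma(params, spec, cond.n_v, "V")
        x_v = cond.n_v + s * state.rng.standard_normal(state.n_sim)
    return InternalSamples(x_a=x_a, x_v=x_v)


def fusion_estimate(x_a, x_v, params: ObserverParams, sigma_a: float, sigma_v: float):
    """Forced-fusion estimate: precision-weighted average of both inputs and
    the numeric prior."""
    if sigma_a <= 0 or sigma_v <= 0 or params.sigma_p <= 0:
        raise ValueError("standard deviations must be strictly positive")
    wa, wv, wp = sigma_a**-2, sigma_v**-2, params.sigma_p**-2
    return (np.asarray(x_a) * wa + np.asarray(x_v) * wv + params.mu_p * wp) / (wa + wv + wp)


def segregation_estimate(x, params: ObserverParams, sigma: float):
    """Unisensory estimate: precision-weighted average of the input and the
    numeric prior."""
    if sigma <= 0 or params.sigma_p <= 0:
        raise ValueError("standard deviations must be strictly positive")
    w, wp = sigma**-2, params.sigma_p**-2
    return (np.asarray(x) * w + params.mu_p * wp) / (w + wp)


def _log_lik_c1(x_a, x_v, mu_p, var_p, var_a, var_v):
    # p(x_a, x_v | C=1) = Int N(x_a; N, sa) N(x_v; N, sv) N(N; mu_p, sp) dN
    denom = var_a * var_v + var_a * var_p + var_v * var_p
    quad = (
        (x_a - x_v) ** 2 * var_p
        + (x_a - mu_p) ** 2 * var_v
        + (x_v - mu_p) ** 2 * var_a
    ) / denom
    return -0.5 * quad - np.log(2.0 * np.pi * np.sqrt(denom))


def _log_lik_c2(x_a, x_v, mu_p, var_p, var_a, var_v):
    # product of two independent marginals N(x; mu_p, sqrt(var + var_p))
    va, vv = var_a + var_p, var_v + var_p
    return (
        -0.5 * ((x_a - mu_p) ** 2 / va + (x_v - mu_p) ** 2 / vv)
        - 0.5 * np.log(4.0 * np.pi**2 * va * vv)
    )


def causal_posterior(x_a, x_v, params: ObserverParams, sigma_a: float, sigma_v: float):
    """Posterior probability of a common cause, ``p(C=1 | x_a, x_v)``.

    Both marginal likelihoods are closed-form Gaussian integrals; the
    posterior follows by Bayes rule with prior ``p_common``.
    """
    if sigma_a <= 0 or sigma_v <= 0 or params.sigma_p <= 0:
        raise ValueError("standard deviations must be strictly positive")
    if params.p_common is None:
        raise ValueError("causal_posterior requires p_common")
    pc = float(params.p_common)
    if pc == 0.0:
        return np.zeros_like(np.asarray(x_a, dtype=float))
    if pc == 1.0:
        return np.ones_like(np.asarray(x_a, dtype=float))
    x_a = np.asarray(x_a, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    var_p, var_a, var_v = params.sigma_p**2, sigma_a**2, sigma_v**2
    log1 = _log_lik_c1(x_a, x_v, params.mu_p, var_p, var_a, var_v) + np.log(pc)
    log2 = _log_lik_c2(x_a, x_v, params.mu_p, var_p, var_a, var_v) + np.log1p(-pc)
    return expit(log1 - log2)


def final_estimate(
    samples: InternalSamples,
    cond: Condition,
    params: ObserverParams,
    spec: ModelSpec,
    state: SimulationState,
) -> np.ndarray:
    """Task-relevant final estimate per simulated trial, filling the derived
    fields of ``samples`` in place.

    For PM and SF one uniform draw ``alpha`` per trial is consumed from
    ``state`` after the sensory draws.
    """
    if not cond.audiovisual:
        raise ValueError("final_estimate requires an audiovisual condition; "
                         "use segregation_estimate for unisensory trials")
    params.validate(spec)
    x_a, x_v = samples.x_a, samples.x_v
    sa = effective_sigma(params, spec, cond.n_a, "A")
    sv = effective_sigma(params, spec, cond.n_v, "V")
    fus = fusion_estimate(x_a, x_v, params, sa, sv)
    seg_a = segregation_estimate(x_a, params, sa)
    seg_v = segregation_estimate(x_v, params, sv)
    seg = seg_a if cond.task == "A" else seg_v
    samples.n_hat_fus = fus
    samples.n_hat_a_seg = seg_a
    samples.n_hat_v_seg = seg_v

    if spec.uses_posterior:
        post = causal_posterior(x_a, x_v, params, sa, sv)
        samples.post_c1 = post
    strategy = spec.strategy
    if strategy == "MA":
        final = samples.post_c1 * fus + (1.0 - samples.post_c1) * seg
    elif strategy == "MS":
        final = np.where(samples.post_c1 > 0.5, fus, seg)
    elif strategy == "PM":
        alpha = state.rng.uniform(size=np.shape(fus))
        final = np.where(samples.post_c1 > alpha, fus, seg)
    elif strategy == "SF":
        alpha = state.rng.uniform(size=np.shape(fus))
        final = np.where(params.causal_value(spec) > alpha, fus, seg)
    else:  # FC
        final = np.where(np.abs(x_a - x_v) < params.causal_value(spec), fus, seg)
    samples.n_hat_final = final
    return final


def _discretize(estimate: np.ndarray) -> np.ndarray:
    # nearest integer, ties half-up, clipped to the 4 response buttons
    return np.clip(np.floor(np.asarray(estimate) + 0.5), 1, 4).astype(int)


def simulate_trials(
    cond_list: Sequence[Condition],
    params: ObserverParams,
    spec: ModelSpec,
    state: SimulationState,
    n_per_cond: int,
) -> pd.DataFrame:
    """Simulate ``n_per_cond`` trials per condition and return a trial table.

    Unisensory conditions go through the segregation-only pathway.  With
    probability ``lapse`` a trial's report is replaced by a uniform draw from
    {1, 2, 3, 4}.
    """
    if len(cond_list) == 0:
        raise ValueError("condition list is empty")
    if n_per_cond < 1:
        raise ValueError("n_per_cond must be >= 1")
    rows = []
    for cond in cond_list:
        sub = SimulationState(seed=state.seed, n_sim=n_per_cond)
        sub.rng = state.rng  # share the parent stream
        samples = sample_sensory_inputs(cond, params, spec, sub)
        if cond.audiovisual:
            est = final_estimate(samples, cond, params, spec, sub)
        else:
            if cond.task == "A":
                s = effective_sigma(params, spec, cond.n_a, "A")
                est = segregation_estimate(samples.x_a, params, s)
            else:
                s = effective_sigma(params, spec, cond.n_v, "V")
                est = segregation_estimate(samples.x_v, params, s)
        report = _discretize(est)
        if params.lapse > 0:
            is_lapse = state.rng.uniform(size=n_per_cond) < params.lapse
            report = np.where(is_lapse, state.rng.integers(1, 5, size=n_per_cond), report)
        rows.append(
            pd.DataFrame(
                {
                    "n_aud": cond.n_a,
                    "n_vis": cond.n_v,
                    "task": cond.task,
                    "estimate": est,
                    "report": report,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
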