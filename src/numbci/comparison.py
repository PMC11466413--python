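"""Random-effects Bayesian model selection (BMS) over the observer-model
space, family-level inference across the two model factors, between-group
comparison, and the recovery harnesses.

Per-subject log model evidences are -BIC/2.  Group-level inference treats the
model identity of each subject as drawn from an unknown Dirichlet-distributed
frequency vector and estimates its posterior with the standard variational
scheme; exceedance probabilities come from seeded Monte-Carlo Dirichlet
sampling, and the protected exceedance probability corrects them by the
Bayesian omnibus risk (BOR) — the posterior probability that all model
frequencies are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .fitting import FitResult, ObserverModelMLE
from .observer import ModelSpec, ObserverParams, SimulationState, simulate_trials

__all__ = [
    "BMSResult",
    "bic_to_evidence",
    "rfx_bms",
    "RandomEffectsBMS",
    "family_bms",
    "between_group_bms",
    "model_recovery",
    "parameter_recovery",
    "conditional_prior_recovery",
]


def bic_to_evidence(fit: FitResult) -> float:
    """Approximate log model evidence, -BIC/2."""
    return -0.5 * fit.bic


@dataclass
class BMSResult:
    """Group-level model-selection output."""

    model_names: list[str]
    alpha: np.ndarray  # posterior Dirichlet parameters
    frequencies: np.ndarray  # expected model frequencies (simplex)
    ep: np.ndarray  # exceedance probabilities
    pxp: np.ndarray  # protected exceedance probabilities
    bor: float  # Bayesian omnibus risk
    free_energy: float  # of the random-effects (alternative) model
    free_energy_null: float  # of the equal-frequency null

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_names,
                "frequency": self.frequencies,
                "ep": self.ep,
                "pxp": self.pxp,
            }
        )


def _as_matrix(evidence) -> tuple[np.ndarray, list[str]]:
    if isinstance(evidence, pd.DataFrame):
        return evidence.to_numpy(dtype=float), [str(c) for c in evidence.columns]
    arr = np.asarray(evidence, dtype=float)
    return arr, [f"m{j}" for j in range(arr.shape[1])]


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray, tol=1e-8, max_iter=500):
    """Variational posterior Dirichlet(alpha) and responsibilities u."""
    n, m = lme.shape
    alpha = alpha0.copy()
    for _ in range(max_iter):
        w = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def _free_energy(lme, alpha0, alpha, u):
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_u = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    f = np.sum(u * lme)
    f += np.sum(u * e_ln_r[None, :])
    f += gammaln(alpha0.sum()) - np.sum(gammaln(alpha0)) + np.sum((alpha0 - 1) * e_ln_r)
    f -= gammaln(alpha.sum()) - np.sum(gammaln(alpha)) + np.sum((alpha - 1) * e_ln_r)
    f += ent_u
    return float(f)


def rfx_bms(
    evidence,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS over a subjects x models log-evidence matrix."""
    lme, names = _as_matrix(evidence)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be subjects x (>=2) models")
    if lme.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidences must be finite")
    n, m = lme.shape
    a0 = np.full(m, float(alpha0))
    alpha, u = _vb_dirichlet(lme, a0)
    freq = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=m) / n_samples

    f1 = _free_energy(lme, a0, alpha, u)
    # null: all frequencies fixed at 1/m
    f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(m)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / m
    return BMSResult(
        model_names=names,
        alpha=alpha,
        frequencies=freq,
        ep=ep,
        pxp=pxp,
        bor=bor,
        free_energy=f1,
        free_energy_null=f0,
    )


class RandomEffectsBMS:
    """Estimator-style wrapper: ``fit(evidence)`` exposes ``frequencies_``,
    ``ep_``, ``pxp_``, ``bor_`` and ``result_``."""

    def __init__(self, alpha0: float = 1.0, n_samples: int = 100_000, seed: int = 0):
        self.alpha0 = alpha0
        self.n_samples = n_samples
        self.seed = seed

    def fit(self, evidence, y=None) -> "RandomEffectsBMS":
        res = rfx_bms(evidence, self.alpha0, self.n_samples, self.seed)
        self.result_ = res
        self.frequencies_ = res.frequencies
        self.ep_ = res.ep
        self.pxp_ = res.pxp
        self.bor_ = res.bor
        return self

    def get_params(self, deep=True):
        return {"alpha0": self.alpha0, "n_samples": self.n_samples, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def family_bms(
    evidence: pd.DataFrame,
    families: Mapping[str, Sequence[str]],
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
) -> BMSResult:
    """Family-level BMS: per-subject family evidence is the log-mean-exp of
    member evidences (uniform within-family prior), then random-effects BMS
    over families."""
    cols = list(evidence.columns)
    seen: list[str] = []
    for members in families.values():
        for mname in members:
            if mname not in cols:
                raise ValueError(f"unknown model {mname!r}")
            if mname in seen:
                raise ValueError(f"model {mname!r} appears in more than one family")
            seen.append(mname)
    fam_lme = {}
    for fam, members in families.items():
        sub = evidence[list(members)].to_numpy(dtype=float)
        fam_lme[fam] = logsumexp(sub, axis=1) - np.log(len(members))
    return rfx_bms(pd.DataFrame(fam_lme, index=evidence.index), alpha0, n_samples, seed)


def factor_families(model_names: Sequence[str], factor: str) -> dict[str, list[str]]:
    """Partition ``strategy-variance`` labels by one of the two factors."""
    fams: dict[str, list[str]] = {}
    for name in model_names:
        strategy, variance = name.split("-")
        key = strategy if factor == "strategy" else variance
        fams.setdefault(key, []).append(name)
    return fams


def between_group_bms(e1, e2, alpha0: float = 1.0) -> float:
    """Bayes factor BF10 for different (H1) versus equal (H0) model
    frequencies in two groups, by free-energy comparison."""
    lme1, names1 = _as_matrix(e1)
    lme2, names2 = _as_matrix(e2)
    if names1 != names2 or lme1.shape[1] != lme2.shape[1]:
        raise ValueError("both groups must share the same model set")
    m = lme1.shape[1]
    a0 = np.full(m, float(alpha0))

    def f_of(lme):
        alpha, u = _vb_dirichlet(lme, a0)
        return _free_energy(lme, a0, alpha, u)

    f_same = f_of(np.vstack([lme1, lme2]))
    f_diff = f_of(lme1) + f_of(lme2)
    return float(np.exp(f_diff - f_same))


def model_recovery(
    generating_specs: Sequence[ModelSpec],
    n_subjects: int,
    params_sampler: Callable[[ModelSpec, np.random.Generator], ObserverParams],
    conditions,
    state: SimulationState,
    n_per_cond: int = 10,
    fitted_specs: Sequence[ModelSpec] | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Simulate subjects from each generating model, fit all candidate
    models, and tabulate per-row fractions of BIC winners (confusion
    matrix; rows sum to 1)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects per generating model")
    fitted_specs = list(fitted_specs or generating_specs)
    fit_kwargs = dict(fit_kwargs or {})
    rng = np.random.default_rng(np.random.SeedSequence((state.seed, 0xC0)))
    rows = {}
    for gi, gen_spec in enumerate(generating_specs):
        wins = np.zeros(len(fitted_specs))
        for si in range(n_subjects):
            params = params_sampler(gen_spec, rng)
            sim_state = SimulationState(
                int(rng.integers(2**31)), n_sim=n_per_cond
            )
            table = simulate_trials(conditions, params, gen_spec, sim_state, n_per_cond)
            bics = []
            for fj, fit_spec in enumerate(fitted_specs):
                est = ObserverModelMLE(
                    strategy=fit_spec.strategy,
                    variance_mode=fit_spec.variance_mode,
                    seed=int(rng.integers(2**31)),
                    **fit_kwargs,
                )
                est.fit(table)
                bics.append(est.bic_)
            wins[int(np.argmin(bics))] += 1
        rows[gen_spec.label] = wins / n_subjects
    return pd.DataFrame(rows, index=[s.label for s in fitted_specs]).T


def parameter_recovery(
    spec: ModelSpec,
    params_list: Sequence[ObserverParams],
    conditions,
    state: SimulationState,
    n_per_cond: int = 10,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Simulate -> refit each parameter set; returns a long table of
    generating vs recovered values."""
    from .fitting import _params_to_dict  # local to avoid cycle at import

    fit_kwargs = dict(fit_kwargs or {})
    rng = np.random.default_rng(np.random.SeedSequence((state.seed, 0xA7)))
    records = []
    for i, params in enumerate(params_list):
        sim_state = SimulationState(int(rng.integers(2**31)), n_sim=n_per_cond)
        table = simulate_trials(conditions, params, spec, sim_state, n_per_cond)
        est = ObserverModelMLE(
            strategy=spec.strategy,
            variance_mode=spec.variance_mode,
            seed=int(rng.integers(2**31)),
            **fit_kwargs,
        )
        est.fit(table)
        gen = _params_to_dict(params, spec)
        rec = _params_to_dict(est.params_, spec)
        for name in gen:
            records.append(
                {
                    "subject": i,
                    "parameter": name,
                    "generating": gen[name],
                    "recovered": rec[name],
                }
            )
    return pd.DataFrame(records)


def conditional_prior_recovery(
    base_params: ObserverParams,
    pcommon_by_prev_disparity: Mapping[int, float],
    state: SimulationState,
    n_av_runs: int = 6,
    refit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Recovery harness for the sequential-prior analysis: simulate one
    observer whose causal prior follows an imposed previous-disparity
    schedule, refit the prior per bin with everything else frozen, and
    report generating vs recovered values per bin."""
    from .history import refit_conditional
    from .synth import make_design, simulate_subject

    spec = ModelSpec("MA", "scalar")
    design = make_design(n_av_runs=n_av_runs, n_uni_runs=0, state=state)
    table = simulate_subject(
        design,
        base_params,
        spec,
        np.random.default_rng(np.random.SeedSequence((state.seed, 0x51))),
        pcommon_by_prev_disparity=dict(pcommon_by_prev_disparity),
    )
    table["subject"] = "SYN"
    base_fit = FitResult(
        params=base_params, spec=spec, loglik=0.0, n_trials=len(table),
        n_free_params=8, bic=0.0, n_inits=1, best_init_index=0,
    )
    refit = refit_conditional(
        table, base_fit, "causal", state, **(refit_kwargs or {})
    )
    refit["generating"] = refit["bin"].map(pcommon_by_prev_disparity)
    refit = refit.rename(columns={"causal": "recovered"})
    return refit[["bin", "generating", "recovered", "n_trials", "low_power"]]
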