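"""Maximum-likelihood fitting of observer models to button-report tables.

Predicted response distributions are simulation-based: for every condition a
fixed set of standard-normal and uniform draws (common random numbers, seeded
per condition) is transformed by the candidate parameters into final
estimates, discretized to the 4 response buttons, and mixed with the lapse
rate.  The likelihood surface is therefore deterministic, which lets a
multi-start bounded derivative-free optimizer (Powell) do the work that a
Bayesian-optimization toolbox would otherwise do.

Models are fitted jointly to unisensory and audiovisual conditions, so the
sensory noise, numeric prior and lapse parameters are informed by both.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .observer import (
    Condition,
    InternalSamples,
    ModelSpec,
    ObserverParams,
    SimulationState,
    _log_lik_c1,
    _log_lik_c2,
)

__all__ = [
    "PMF_FLOOR",
    "FitResult",
    "LikelihoodEngine",
    "ObserverModelMLE",
    "default_bounds",
    "discretize",
    "predict_response_pmf",
    "log_likelihood",
    "fit_mle",
    "fit_subset",
]

PMF_FLOOR = 1e-6

try:  # numba accelerates the inner pmf evaluation; numpy path is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco


_STRATEGY_CODE = {"MA": 0, "MS": 1, "PM": 2, "SF": 3, "FC": 4}


@_njit(cache=True, fastmath=True)
def _av_counts(za, zv, alpha, na, nv, sa, sv, task_a, strat, causal, mu_p, var_p, out):
    m, n = za.shape
    wp = 1.0 / var_p
    for i in range(m):
        va = sa[i] * sa[i]
        vv = sv[i] * sv[i]
        wa = 1.0 / va
        wv = 1.0 / vv
        inv_wsum = 1.0 / (wa + wv + wp)
        inv_wa_p = 1.0 / (wa + wp)
        inv_wv_p = 1.0 / (wv + wp)
        denom1 = va * vv + va * var_p + vv * var_p
        va2 = va + var_p
        vv2 = vv + var_p
        cconst = -0.5 * np.log(denom1) + 0.5 * np.log(va2 * vv2)
        forced = -1
        lpo = 0.0
        if strat <= 2:
            if causal <= 0.0:
                forced = 0
            elif causal >= 1.0:
                forced = 1
            else:
                lpo = np.log(causal) - np.log(1.0 - causal)
        for j in range(n):
            xa = na[i] + sa[i] * za[i, j]
            xv = nv[i] + sv[i] * zv[i, j]
            fus = (xa * wa + xv * wv + mu_p * wp) * inv_wsum
            if task_a[i]:
                seg = (xa * wa + mu_p * wp) * inv_wa_p
            else:
                seg = (xv * wv + mu_p * wp) * inv_wv_p
            if strat <= 2:
                if forced == 0:
                    post = 0.0
                elif forced == 1:
                    post = 1.0
                else:
                    q1 = (
                        (xa - xv) ** 2 * var_p
                        + (xa - mu_p) ** 2 * vv
                        + (xv - mu_p) ** 2 * va
                    ) / denom1
                    q2 = (xa - mu_p) ** 2 / va2 + (xv - mu_p) ** 2 / vv2
                    d = -0.5 * q1 + 0.5 * q2 + cconst + lpo
                    if d > 35.0:
                        post = 1.0
                    elif d < -35.0:
                        post = 0.0
                    elif d >= 0.0:
                        post = 1.0 / (1.0 + np.exp(-d))
                    else:
                        e = np.exp(d)
                        post = e / (1.0 + e)
                if strat == 0:
                    est = post * fus + (1.0 - post) * seg
                elif strat == 1:
                    est = fus if post > 0.5 else seg
                else:
                    est = fus if post > alpha[i, j] else seg
            elif strat == 3:
                est = fus if causal > alpha[i, j] else seg
            else:
                est = fus if abs(xa - xv) < causal else seg
            r = int(np.floor(est + 0.5))
            if r < 1:
                r = 1
            elif r > 4:
                r = 4
            out[i, r - 1] += 1.0


@_njit(cache=True, fastmath=True)
def _uni_counts(z, count, s, mu_p, var_p, out):
    m, n = z.shape
    wp = 1.0 / var_p
    for i in range(m):
        w = 1.0 / (s[i] * s[i])
        inv = 1.0 / (w + wp)
        for j in range(n):
            x = count[i] + s[i] * z[i, j]
            est = (x * w + mu_p * wp) * inv
            r = int(np.floor(est + 0.5))
            if r < 1:
                r = 1
            elif r > 4:
                r = 4
            out[i, r - 1] += 1.0

_ORDER_SCALAR = ("causal", "mu_p", "sigma_p", "sigma_a", "sigma_v", "dsigma_a", "dsigma_v", "lapse")
_ORDER_CONSTANT = ("causal", "mu_p", "sigma_p", "sigma_a", "sigma_v", "lapse")


def free_param_names(spec: ModelSpec) -> tuple[str, ...]:
    return _ORDER_SCALAR if spec.variance_mode == "scalar" else _ORDER_CONSTANT


def default_bounds(spec: ModelSpec) -> dict[str, tuple[float, float]]:
    """Generous physical bounds for counts 1-4."""
    causal_hi = 6.0 if spec.strategy == "FC" else 1.0
    b = {
        "causal": (0.0, causal_hi),
        "mu_p": (0.0, 6.0),
        "sigma_p": (0.05, 6.0),
        "sigma_a": (0.05, 6.0),
        "sigma_v": (0.05, 6.0),
        "lapse": (0.0, 1.0),
    }
    if spec.variance_mode == "scalar":
        b["dsigma_a"] = (0.0, 3.0)
        b["dsigma_v"] = (0.0, 3.0)
    return b


def discretize(estimate) -> np.ndarray:
    """Map a continuous estimate to a button report: nearest integer, ties
    rounded half up, clipped to [1, 4]."""
    est = np.asarray(estimate, dtype=float)
    if np.any(~np.isfinite(est)):
        raise ValueError("estimate must be finite")
    return np.clip(np.floor(est + 0.5), 1, 4).astype(int)


def _params_to_dict(params: ObserverParams, spec: ModelSpec) -> dict[str, float]:
    d = {
        "causal": params.causal_value(spec),
        "mu_p": params.mu_p,
        "sigma_p": params.sigma_p,
        "sigma_a": params.sigma_a,
        "sigma_v": params.sigma_v,
        "dsigma_a": params.dsigma_a,
        "dsigma_v": params.dsigma_v,
        "lapse": params.lapse,
    }
    if spec.variance_mode == "constant":
        d["dsigma_a"] = d["dsigma_v"] = 0.0
    return d


def params_from_values(values: Mapping[str, float], spec: ModelSpec) -> ObserverParams:
    kwargs = {
        "mu_p": values["mu_p"],
        "sigma_p": values["sigma_p"],
        "sigma_a": values["sigma_a"],
        "sigma_v": values["sigma_v"],
        "dsigma_a": values.get("dsigma_a", 0.0),
        "dsigma_v": values.get("dsigma_v", 0.0),
        "lapse": values["lapse"],
        spec.causal_param_name: values["causal"],
    }
    return ObserverParams(**kwargs)


class LikelihoodEngine:
    """Vectorized predicted-pmf evaluator over a fixed set of conditions.

    Draws are made once per condition from a condition-keyed seed; every
    parameter evaluation reuses them, so two evaluations at the same
    parameters return bit-identical results.
    """

    def __init__(
        self,
        conditions: Sequence[Condition],
        spec: ModelSpec,
        state: SimulationState,
    ):
        if len(conditions) == 0:
            raise ValueError("no conditions")
        self.conditions = list(conditions)
        self.spec = spec
        self.n_sim = state.n_sim
        av_idx, uni_idx = [], []
        for i, c in enumerate(self.conditions):
            (av_idx if c.audiovisual else uni_idx).append(i)
        self._av_idx = np.array(av_idx, dtype=int)
        self._uni_idx = np.array(uni_idx, dtype=int)

        n = state.n_sim
        if av_idx:
            conds = [self.conditions[i] for i in av_idx]
            self._av_na = np.array([c.n_a for c in conds], dtype=float)
            self._av_nv = np.array([c.n_v for c in conds], dtype=float)
            self._av_task_a = np.array([c.task == "A" for c in conds])
            za, zv, al = [], [], []
            for c in conds:
                rng = state.condition_rng(c)
                za.append(rng.standard_normal(n))
                zv.append(rng.standard_normal(n))
                al.append(rng.uniform(size=n))
            self._av_za = np.array(za)
            self._av_zv = np.array(zv)
            self._av_alpha = np.array(al)
        if uni_idx:
            conds = [self.conditions[i] for i in uni_idx]
            self._uni_count = np.array(
                [c.n_a if c.n_a > 0 else c.n_v for c in conds], dtype=float
            )
            self._uni_is_a = np.array([c.n_a > 0 for c in conds])
            self._uni_z = np.array(
                [state.condition_rng(c).standard_normal(n) for c in conds]
            )

    def _effective(self, base, inc, counts):
        if self.spec.variance_mode == "constant":
            return np.full_like(counts, base)
        return base + inc * (counts - 1.0)

    def pmfs(self, values: Mapping[str, float]) -> np.ndarray:
        """(n_conditions, 4) predicted report pmf, lapse-mixed."""
        if _HAVE_NUMBA:
            return self._pmfs_numba(values)
        return self._pmfs_numpy(values)

    def _pmfs_numba(self, values: Mapping[str, float]) -> np.ndarray:
        mu_p = float(values["mu_p"])
        var_p = float(values["sigma_p"]) ** 2
        lapse = float(values["lapse"])
        causal = float(values["causal"])
        out = np.zeros((len(self.conditions), 4))
        if self._av_idx.size:
            sa = self._effective(values["sigma_a"], values.get("dsigma_a", 0.0), self._av_na)
            sv = self._effective(values["sigma_v"], values.get("dsigma_v", 0.0), self._av_nv)
            counts = np.zeros((self._av_idx.size, 4))
            _av_counts(
                self._av_za,
                self._av_zv,
                self._av_alpha,
                self._av_na,
                self._av_nv,
                sa,
                sv,
                self._av_task_a,
                _STRATEGY_CODE[self.spec.strategy],
                causal,
                mu_p,
                var_p,
                counts,
            )
            out[self._av_idx] = counts / self.n_sim
        if self._uni_idx.size:
            s = np.where(
                self._uni_is_a,
                self._effective(values["sigma_a"], values.get("dsigma_a", 0.0), self._uni_count),
                self._effective(values["sigma_v"], values.get("dsigma_v", 0.0), self._uni_count),
            )
            counts = np.zeros((self._uni_idx.size, 4))
            _uni_counts(self._uni_z, self._uni_count, s, mu_p, var_p, counts)
            out[self._uni_idx] = counts / self.n_sim
        return (1.0 - lapse) * out + lapse * 0.25

    def _pmfs_numpy(self, values: Mapping[str, float]) -> np.ndarray:
        mu_p = values["mu_p"]
        var_p = values["sigma_p"] ** 2
        lapse = values["lapse"]
        out = np.empty((len(self.conditions), 4))

        if self._av_idx.size:
            sa = self._effective(values["sigma_a"], values.get("dsigma_a", 0.0), self._av_na)
            sv = self._effective(values["sigma_v"], values.get("dsigma_v", 0.0), self._av_nv)
            x_a = self._av_na[:, None] + sa[:, None] * self._av_za
            x_v = self._av_nv[:, None] + sv[:, None] * self._av_zv
            wa = sa**-2
            wv = sv**-2
            wp = 1.0 / var_p
            fus = (x_a * wa[:, None] + x_v * wv[:, None] + mu_p * wp) / (
                wa + wv + wp
            )[:, None]
            seg_a = (x_a * wa[:, None] + mu_p * wp) / (wa + wp)[:, None]
            seg_v = (x_v * wv[:, None] + mu_p * wp) / (wv + wp)[:, None]
            seg = np.where(self._av_task_a[:, None], seg_a, seg_v)
            strat = self.spec.strategy
            c = values["causal"]
            if strat in ("MA", "MS", "PM"):
                va = (sa**2)[:, None]
                vv = (sv**2)[:, None]
                if c <= 0.0:
                    post = np.zeros_like(fus)
                elif c >= 1.0:
                    post = np.ones_like(fus)
                else:
                    d = (
                        _log_lik_c1(x_a, x_v, mu_p, var_p, va, vv)
                        - _log_lik_c2(x_a, x_v, mu_p, var_p, va, vv)
                        + np.log(c)
                        - np.log1p(-c)
                    )
                    # stable sigmoid
                    post = np.empty_like(d)
                    pos = d >= 0
                    post[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
                    ed = np.exp(d[~pos])
                    post[~pos] = ed / (1.0 + ed)
                if strat == "MA":
                    final = post * fus + (1.0 - post) * seg
                elif strat == "MS":
                    final = np.where(post > 0.5, fus, seg)
                else:
                    final = np.where(post > self._av_alpha, fus, seg)
            elif strat == "SF":
                final = np.where(c > self._av_alpha, fus, seg)
            else:  # FC
                final = np.where(np.abs(x_a - x_v) < c, fus, seg)
            out[self._av_idx] = self._count_pmf(final)

        if self._uni_idx.size:
            s = np.where(
                self._uni_is_a,
                self._effective(values["sigma_a"], values.get("dsigma_a", 0.0), self._uni_count),
                self._effective(values["sigma_v"], values.get("dsigma_v", 0.0), self._uni_count),
            )
            x = self._uni_count[:, None] + s[:, None] * self._uni_z
            w = (s**-2)[:, None]
            wp = 1.0 / var_p
            seg = (x * w + mu_p * wp) / (w + wp)
            out[self._uni_idx] = self._count_pmf(seg)

        return (1.0 - lapse) * out + lapse * 0.25

    @staticmethod
    def _count_pmf(estimates: np.ndarray) -> np.ndarray:
        reports = np.clip(np.floor(estimates + 0.5), 1, 4)
        pmf = np.empty((estimates.shape[0], 4))
        for r in range(4):
            pmf[:, r] = np.mean(reports == r + 1, axis=1)
        return pmf


def predict_response_pmf(
    cond: Condition,
    params: ObserverParams,
    spec: ModelSpec,
    state: SimulationState,
) -> np.ndarray:
    """Predicted pmf over the 4 reports for one condition (lapse-mixed)."""
    params.validate(spec)
    engine = LikelihoodEngine([cond], spec, state)
    return engine.pmfs(_params_to_dict(params, spec))[0]


def table_conditions(table: pd.DataFrame) -> tuple[list[Condition], np.ndarray]:
    """Unique conditions of a trial table and the (n_cond, 4) report counts."""
    grouped = table.groupby(["n_aud", "n_vis", "task"], sort=True)
    conditions, counts = [], []
    for (n_a, n_v, task), sub in grouped:
        conditions.append(Condition(int(n_a), int(n_v), str(task)))
        counts.append(np.bincount(sub["report"].to_numpy(dtype=int), minlength=5)[1:5])
    return conditions, np.array(counts, dtype=float)


def log_likelihood(
    table: pd.DataFrame,
    params: ObserverParams,
    spec: ModelSpec,
    state: SimulationState,
) -> float:
    """Summed log-likelihood of a single subject's reports."""
    if len(table) == 0:
        raise ValueError("empty trial table")
    if "subject" in table.columns and table["subject"].nunique() > 1:
        raise ValueError("log_likelihood expects a single subject's trials")
    params.validate(spec)
    conditions, counts = table_conditions(table)
    engine = LikelihoodEngine(conditions, spec, state)
    pmf = engine.pmfs(_params_to_dict(params, spec))
    return float(np.sum(counts * np.log(np.maximum(pmf, PMF_FLOOR))))


@dataclass
class FitResult:
    """Per-subject maximum-likelihood fit of one observer model."""

    params: ObserverParams
    spec: ModelSpec
    loglik: float
    n_trials: int
    n_free_params: int
    bic: float
    n_inits: int
    best_init_index: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        d["spec"] = {"strategy": self.spec.strategy, "variance_mode": self.spec.variance_mode}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        d["params"] = ObserverParams(**d["params"])
        d["spec"] = ModelSpec(**d["spec"])
        return cls(**d)


def _optimize_multistart(
    objective,
    names: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    n_inits: int,
    rng: np.random.Generator,
    maxfev: int | None,
    xtol: float,
    ftol: float,
):
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    opts = {"xtol": xtol, "ftol": ftol}
    if maxfev is not None:
        opts["maxfev"] = maxfev
    best = None
    best_idx = -1
    failures = []
    for i in range(n_inits):
        x0 = rng.uniform(lo, hi)
        try:
            res = minimize(
                objective,
                x0,
                method="Powell",
                bounds=list(zip(lo, hi)),
                options=opts,
            )
        except Exception as exc:  # pragma: no cover - optimizer pathology
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        if best is None or res.fun < best.fun:
            best, best_idx = res, i
    if best is None:
        raise RuntimeError(f"all {n_inits} optimizer starts failed: {failures[:3]}")
    return best, best_idx


class ObserverModelMLE(BaseEstimator):
    """Multi-start maximum-likelihood fit of one observer model to one
    subject's trial table.

    Parameters
    ----------
    strategy, variance_mode : the model-space cell to fit.
    n_inits : number of uniform-random starts within the bounds.
    n_sim : simulated trials per condition for the predicted pmfs.
    seed : seeds both the common random numbers and the starts.
    bounds : optional per-parameter overrides of the default box bounds.
    maxfev : cap on objective evaluations per start (None = optimizer default).
    """

    def __init__(
        self,
        strategy: str = "MA",
        variance_mode: str = "scalar",
        n_inits: int = 50,
        n_sim: int = 5000,
        seed: int = 0,
        bounds: dict | None = None,
        maxfev: int | None = None,
        xtol: float = 1e-3,
        ftol: float = 1e-4,
    ):
        self.strategy = strategy
        self.variance_mode = variance_mode
        self.n_inits = n_inits
        self.n_sim = n_sim
        self.seed = seed
        self.bounds = bounds
        self.maxfev = maxfev
        self.xtol = xtol
        self.ftol = ftol

    def fit(self, X: pd.DataFrame, y=None) -> "ObserverModelMLE":
        """Fit to a single-subject trial table (columns n_aud, n_vis, task,
        report)."""
        table = X
        if len(table) == 0:
            raise ValueError("empty trial table")
        if "subject" in table.columns and table["subject"].nunique() > 1:
            raise ValueError("fit expects a single subject's trials")
        spec = ModelSpec(self.strategy, self.variance_mode)
        conditions, counts = table_conditions(table)
        if len(conditions) < 2:
            raise ValueError("need at least 2 distinct conditions")
        state = SimulationState(self.seed, n_sim=self.n_sim)
        engine = LikelihoodEngine(conditions, spec, state)
        names = free_param_names(spec)
        bounds = default_bounds(spec)
        if self.bounds:
            bounds.update(self.bounds)

        def objective(vec):
            values = dict(zip(names, vec))
            pmf = engine.pmfs(values)
            return -float(np.sum(counts * np.log(np.maximum(pmf, PMF_FLOOR))))

        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0xF17)))
        best, best_idx = _optimize_multistart(
            objective, names, bounds, self.n_inits, rng, self.maxfev, self.xtol, self.ftol
        )
        values = dict(zip(names, best.x))
        n_trials = int(len(table))
        n_free = len(names)
        loglik = -float(best.fun)
        self.params_ = params_from_values(values, spec)
        self.spec_ = spec
        self.loglik_ = loglik
        self.n_trials_ = n_trials
        self.bic_ = n_free * np.log(n_trials) - 2.0 * loglik
        self.result_ = FitResult(
            params=self.params_,
            spec=spec,
            loglik=loglik,
            n_trials=n_trials,
            n_free_params=n_free,
            bic=float(self.bic_),
            n_inits=self.n_inits,
            best_init_index=best_idx,
        )
        return self


def fit_mle(
    table: pd.DataFrame,
    spec: ModelSpec,
    n_inits: int = 50,
    bounds: dict | None = None,
    state: SimulationState | None = None,
    maxfev: int | None = None,
) -> FitResult:
    """Functional wrapper over :class:`ObserverModelMLE`."""
    seed = state.seed if state is not None else 0
    n_sim = state.n_sim if state is not None else 5000
    est = ObserverModelMLE(
        strategy=spec.strategy,
        variance_mode=spec.variance_mode,
        n_inits=n_inits,
        n_sim=n_sim,
        seed=seed,
        bounds=bounds,
        maxfev=maxfev,
    )
    return est.fit(table).result_


def fit_subset(
    table: pd.DataFrame,
    spec: ModelSpec,
    base_params: ObserverParams,
    free_names: Sequence[str],
    state: SimulationState,
    n_inits: int = 20,
    bounds: dict | None = None,
    maxfev: int | None = None,
) -> tuple[ObserverParams, float]:
    """Re-optimize a subset of parameters with all others frozen at
    ``base_params``.  Used by the sequential-prior refits."""
    spec_names = free_param_names(spec)
    for n in free_names:
        if n not in spec_names:
            raise ValueError(f"{n!r} is not a free parameter of {spec.label}")
    conditions, counts = table_conditions(table)
    engine = LikelihoodEngine(conditions, spec, state)
    frozen = _params_to_dict(base_params, spec)
    all_bounds = default_bounds(spec)
    if bounds:
        all_bounds.update(bounds)

    def objective(vec):
        values = dict(frozen)
        values.update(zip(free_names, vec))
        pmf = engine.pmfs(values)
        return -float(np.sum(counts * np.log(np.maximum(pmf, PMF_FLOOR))))

    rng = np.random.default_rng(np.random.SeedSequence((state.seed, 0x5B)))
    best, _ = _optimize_multistart(
        objective, free_names, all_bounds, n_inits, rng, maxfev, 1e-3, 1e-4
    )
    values = dict(frozen)
    values.update(zip(free_names, best.x))
    return params_from_values(values, spec), -float(best.fun)
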