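"""Synthetic-data generation: the factorial flash-beep design, behavioral
cohorts simulated from any candidate observer model, and forward-modeled
EEG epochs with the model estimates linearly embedded.

The design mirrors the standard flash-beep session layout: audiovisual runs of 160 trials (16
count combinations x 10 repeats, randomized order) under auditory- or
visual-selective report, plus unisensory runs (4 conditions x 40 repeats),
with the button order counterbalanced across runs.  Cohort presets emulate
a healthy-control-like group and a patient-like group that differs in the
precision of the numeric prior (smaller sigma_p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .eeg import EEGEpochs, condition_mode_labels
from .observer import (
    Condition,
    ModelSpec,
    ObserverParams,
    SimulationState,
    causal_posterior,
    effective_sigma,
    fusion_estimate,
    segregation_estimate,
)

__all__ = [
    "SLOT_ONSETS_MS",
    "SOA_MS",
    "DesignPlan",
    "CohortSpec",
    "ForwardEEGSpec",
    "EstimateEmbedding",
    "make_design",
    "hc_preset",
    "scz_preset",
    "simulate_subject",
    "simulate_cohort",
    "synth_eeg",
    "default_channels",
]

SLOT_ONSETS_MS = (0.0, 66.7, 133.0, 200.0)
SOA_MS = 66.6


@dataclass
class DesignPlan:
    """Trial schedule plus stimulus-timing metadata."""

    trials: pd.DataFrame  # run, trial, task, n_aud, n_vis, button_map
    slot_onsets_ms: tuple = SLOT_ONSETS_MS
    soa_ms: float = SOA_MS

    @property
    def av_cells(self) -> int:
        av = self.trials[(self.trials["n_aud"] > 0) & (self.trials["n_vis"] > 0)]
        return av.groupby(["n_aud", "n_vis", "task"]).ngroups


def make_design(
    n_av_runs: int = 8, n_uni_runs: int = 2, state: SimulationState | None = None
) -> DesignPlan:
    """Build the run schedule: ``n_av_runs`` audiovisual runs (half auditory-,
    half visual-report; 16 conditions x 10 repeats each, shuffled) and
    ``n_uni_runs`` unisensory runs (4 conditions x 40 repeats)."""
    rng = (state or SimulationState(0)).rng
    rows = []
    run_id = 1
    av_tasks = ["A", "V"] * (n_av_runs // 2) + ["A"] * (n_av_runs % 2)
    for i, task in enumerate(av_tasks):
        conds = [(na, nv) for na in range(1, 5) for nv in range(1, 5)] * 10
        order = rng.permutation(len(conds))
        button_map = "ascending" if i % 2 == 0 else "descending"
        for t, j in enumerate(order, start=1):
            na, nv = conds[j]
            rows.append((run_id, t, task, na, nv, button_map))
        run_id += 1
    uni_tasks = ["A", "V"] * (n_uni_runs // 2) + ["A"] * (n_uni_runs % 2)
    for i, task in enumerate(uni_tasks):
        counts = list(range(1, 5)) * 40
        order = rng.permutation(len(counts))
        button_map = "ascending" if i % 2 == 0 else "descending"
        for t, j in enumerate(order, start=1):
            n = counts[j]
            na, nv = (n, 0) if task == "A" else (0, n)
            rows.append((run_id, t, task, na, nv, button_map))
        run_id += 1
    trials = pd.DataFrame(
        rows, columns=["run", "trial", "task", "n_aud", "n_vis", "button_map"]
    )
    return DesignPlan(trials=trials)


@dataclass
class CohortSpec:
    """Group of simulated observers drawn around preset parameter means."""

    group: str
    n_subjects: int
    spec: ModelSpec = field(default_factory=ModelSpec)
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)


_DEFAULT_MEANS = {
    "causal": 0.5,
    "mu_p": 2.5,
    "sigma_p": 1.5,
    "sigma_a": 0.4,
    "sigma_v": 1.0,
    "dsigma_a": 0.2,
    "dsigma_v": 0.5,
    "lapse": 0.05,
}
_DEFAULT_SDS = {
    "causal": 0.15,
    "mu_p": 0.3,
    "sigma_p": 0.25,
    "sigma_a": 0.1,
    "sigma_v": 0.2,
    "dsigma_a": 0.08,
    "dsigma_v": 0.15,
    "lapse": 0.03,
}
_DRAW_BOUNDS = {
    "causal": (0.05, 0.95),
    "mu_p": (1.0, 4.0),
    "sigma_p": (0.3, 4.0),
    "sigma_a": (0.1, 3.0),
    "sigma_v": (0.1, 3.0),
    "dsigma_a": (0.0, 2.0),
    "dsigma_v": (0.0, 2.0),
    "lapse": (0.0, 0.3),
}


def hc_preset(n_subjects: int = 23, spec: ModelSpec | None = None) -> CohortSpec:
    """Healthy-control-like cohort around mid-range observer parameters."""
    return CohortSpec(
        group="HC",
        n_subjects=n_subjects,
        spec=spec or ModelSpec("MA", "scalar"),
        means=dict(_DEFAULT_MEANS),
        sds=dict(_DEFAULT_SDS),
    )


def scz_preset(n_subjects: int = 17, spec: ModelSpec | None = None) -> CohortSpec:
    """Patient-like cohort: identical to the control preset except for a more
    precise numeric prior (smaller sigma_p)."""
    cohort = hc_preset(n_subjects, spec)
    cohort.group = "SCZ"
    cohort.means["sigma_p"] = 1.0
    return cohort


def _draw_params(cohort: CohortSpec, rng: np.random.Generator) -> ObserverParams:
    values = {}
    for name, mean in cohort.means.items():
        sd = cohort.sds.get(name, 0.0)
        lo, hi = _DRAW_BOUNDS[name]
        # a deliberately configured mean outside the plausible band wins
        lo, hi = min(lo, mean), max(hi, mean)
        v = rng.normal(mean, sd)
        for _ in range(20):
            if lo <= v <= hi:
                break
            v = rng.normal(mean, sd)
        else:
            warnings.warn(f"parameter draw for {name!r} clipped to bounds")
            v = float(np.clip(v, lo, hi))
        values[name] = float(v)
    if cohort.spec.variance_mode == "constant":
        values["dsigma_a"] = values["dsigma_v"] = 0.0
    kwargs = {k: v for k, v in values.items() if k != "causal"}
    kwargs[cohort.spec.causal_param_name] = values["causal"]
    return ObserverParams(**kwargs)


def simulate_subject(
    design: DesignPlan,
    params: ObserverParams,
    spec: ModelSpec,
    rng: np.random.Generator,
    pcommon_by_prev_disparity: Mapping[int, float] | None = None,
    mu_by_prev_count: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Simulate one observer through the design, trial by trial in schedule
    order.

    Optional mappings impose sequential prior updating: on audiovisual
    trials whose previous within-run trial had disparity ``d``, the causal
    prior is replaced by ``pcommon_by_prev_disparity[d]``; likewise
    ``mu_by_prev_count`` conditions the numeric-prior mean on the previous
    trial's task-relevant count.
    """
    params.validate(spec)
    reports = np.empty(len(design.trials), dtype=int)
    estimates = np.empty(len(design.trials))
    prev_disp: float | None = None
    prev_count: int | None = None
    prev_run = None
    for i, row in enumerate(design.trials.itertuples(index=False)):
        if row.run != prev_run:
            prev_disp = prev_count = None
            prev_run = row.run
        p = params
        if pcommon_by_prev_disparity is not None and prev_disp is not None:
            p = p.with_causal(spec, pcommon_by_prev_disparity[int(prev_disp)])
        if mu_by_prev_count is not None and prev_count is not None:
            p = replace(p, mu_p=mu_by_prev_count[int(prev_count)])
        na, nv, task = row.n_aud, row.n_vis, row.task
        x_a = x_v = None
        if na > 0:
            sa = effective_sigma(p, spec, na, "A")
            x_a = na + sa * rng.standard_normal()
        if nv > 0:
            sv = effective_sigma(p, spec, nv, "V")
            x_v = nv + sv * rng.standard_normal()
        if na > 0 and nv > 0:
            fus = fusion_estimate(x_a, x_v, p, sa, sv)
            seg = (
                segregation_estimate(x_a, p, sa)
                if task == "A"
                else segregation_estimate(x_v, p, sv)
            )
            if spec.uses_posterior:
                post = float(causal_posterior(x_a, x_v, p, sa, sv))
            if spec.strategy == "MA":
                est = post * fus + (1 - post) * seg
            elif spec.strategy == "MS":
                est = fus if post > 0.5 else seg
            elif spec.strategy == "PM":
                est = fus if post > rng.uniform() else seg
            elif spec.strategy == "SF":
                est = fus if p.causal_value(spec) > rng.uniform() else seg
            else:
                est = fus if abs(x_a - x_v) < p.causal_value(spec) else seg
        elif na > 0:
            est = float(segregation_estimate(x_a, p, sa))
        else:
            est = float(segregation_estimate(x_v, p, sv))
        est = float(est)
        report = int(np.clip(np.floor(est + 0.5), 1, 4))
        if p.lapse > 0 and rng.uniform() < p.lapse:
            report = int(rng.integers(1, 5))
        estimates[i] = est
        reports[i] = report
        prev_disp = abs(na - nv) if (na > 0 and nv > 0) else None
        prev_count = na if task == "A" else nv
        if prev_count == 0:
            prev_count = None
    out = design.trials.copy()
    out["estimate"] = estimates
    out["report"] = reports
    return out


def simulate_cohort(
    design: DesignPlan,
    cohort: CohortSpec,
    seed: int = 0,
    **history_kwargs,
) -> tuple[pd.DataFrame, dict[str, ObserverParams]]:
    """Simulate every subject of a cohort through the design.

    Returns the pooled trial table (CSV-ready columns: subject, group, run,
    trial, n_aud, n_vis, task, report, button_map) and the generating
    parameters per subject.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, hash(cohort.group) % 2**32)))
    tables = []
    params_by_subject: dict[str, ObserverParams] = {}
    for s in range(cohort.n_subjects):
        sid = f"{cohort.group}{s + 1:02d}"
        params = _draw_params(cohort, rng)
        params_by_subject[sid] = params
        table = simulate_subject(design, params, cohort.spec, rng, **history_kwargs)
        table.insert(0, "subject", sid)
        table.insert(1, "group", cohort.group)
        tables.append(table)
    return pd.concat(tables, ignore_index=True), params_by_subject


def default_channels(n: int = 64) -> list[str]:
    """A 64-name montage including the occipital set used by the ERP
    contrast."""
    named = [
        "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8", "F7", "F5", "F3",
        "F1", "Fz", "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1",
        "FCz", "FC2", "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "Cz",
        "C2", "C4", "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2",
        "CP4", "CP6", "TP8", "P7", "P5", "P3", "P1", "Pz", "P2", "P4",
        "P6", "P8", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
        "M1", "M2", "FT9", "FT10",
    ]
    return named[:n]


@dataclass
class EstimateEmbedding:
    """Linear embedding of one model estimate: Gaussian temporal bump times a
    fixed sensor pattern."""

    latency_ms: float
    width_ms: float
    gain: float
    pattern: np.ndarray | None = None  # 64-vector; seeded random if None


@dataclass
class ForwardEEGSpec:
    """Forward model for synthetic epochs."""

    embeddings: dict[str, EstimateEmbedding]
    noise_std: float = 1.0
    one_over_f_exponent: float = 1.0
    sfreq: float = 200.0
    tmin_ms: float = -100.0
    tmax_ms: float = 750.0
    n_channels: int = 64


def _pink_noise(rng, shape, exponent, sfreq):
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit std."""
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(white, axis=-1) * scale
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd < 1e-12, 1.0, sd)


def synth_eeg(
    table: pd.DataFrame,
    params: ObserverParams,
    spec: ModelSpec,
    fwd: ForwardEEGSpec,
    state: SimulationState,
    labels: pd.DataFrame | None = None,
) -> tuple[EEGEpochs, pd.DataFrame]:
    """Forward-model EEG epochs for one subject's audiovisual trials.

    Each epoch is the sum over embedded estimates of
    ``pattern (x) kernel(t) * (condition-mode value - grand mean)`` plus
    white/1-f channel noise.  Returns the epochs and the per-trial label
    table (one column per estimate).
    """
    av = table[(table["n_aud"] > 0) & (table["n_vis"] > 0)].reset_index(drop=True)
    if len(av) == 0:
        raise ValueError("no audiovisual trials to model")
    if labels is None:
        labels = condition_mode_labels(params, spec, state)
    rng = np.random.default_rng(np.random.SeedSequence((state.seed, 0xEE6)))

    n_samp = int(round((fwd.tmax_ms - fwd.tmin_ms) * fwd.sfreq / 1000.0)) + 1
    time_ms = fwd.tmin_ms + 1000.0 * np.arange(n_samp) / fwd.sfreq
    n_trials = len(av)
    data = fwd.noise_std * _pink_noise(
        rng, (n_trials, fwd.n_channels, n_samp), fwd.one_over_f_exponent, fwd.sfreq
    )

    keyed = labels.set_index(["n_aud", "n_vis", "task"])
    trial_labels = {}
    for name, emb in fwd.embeddings.items():
        values = np.array(
            [
                keyed.loc[(int(r.n_aud), int(r.n_vis), r.task), name]
                for r in av.itertuples(index=False)
            ]
        )
        trial_labels[name] = values
        if emb.gain == 0:
            continue
        pattern = emb.pattern
        if pattern is None:
            pattern = rng.standard_normal(fwd.n_channels)
            pattern /= np.linalg.norm(pattern)
        kernel = np.exp(-0.5 * ((time_ms - emb.latency_ms) / emb.width_ms) ** 2)
        centered = values - values.mean()
        data += (
            emb.gain
            * centered[:, None, None]
            * pattern[None, :, None]
            * kernel[None, None, :]
        )
    epochs = EEGEpochs(
        data=data,
        time_ms=time_ms,
        sfreq=fwd.sfreq,
        run=av["run"].to_numpy(),
        n_aud=av["n_aud"].to_numpy(),
        n_vis=av["n_vis"].to_numpy(),
        task=av["task"].to_numpy(),
        channels=default_channels(fwd.n_channels),
    )
    return epochs, pd.DataFrame(trial_labels)
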