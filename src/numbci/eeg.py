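"""Sliding-window multivariate decoding of observer-model estimates from
epoched EEG, the occipital audiovisual-interaction ERP contrast, and
cluster-corrected randomization statistics.

Epochs are trials x 64 channels x samples at 200 Hz (-100..750 ms).  For
decoding, single-trial data are binned into 60-ms windows advancing in 20-ms
steps; the 64-channel vectors of the 12 samples in a window are concatenated
into a 768-feature pattern.  A linear nu-SVR is trained per model estimate
and window under leave-one-run-out cross-validation with a nested grid
search over (C, nu); accuracy is the Fisher-z Pearson correlation between
held-out predictions and the model-derived labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.svm import NuSVR

from .behavior import fisher_z, _tstat_one, _tstat_two
from .observer import (
    Condition,
    ModelSpec,
    ObserverParams,
    SimulationState,
    av_conditions,
    effective_sigma,
    final_estimate,
    sample_sensory_inputs,
)

__all__ = [
    "EEGEpochs",
    "PatternWindows",
    "OCCIPITAL",
    "bin_patterns",
    "deconcatenate",
    "condition_mode_labels",
    "decode_estimates",
    "erp_av_interaction",
    "cluster_permutation",
]

OCCIPITAL = ("O1", "O2", "Oz", "PO3", "POz", "PO4")

ESTIMATE_NAMES = ("v_seg", "a_seg", "fusion", "final")


@dataclass
class EEGEpochs:
    """Epoched sensor data plus per-trial annotations."""

    data: np.ndarray  # trials x channels x samples, microvolts
    time_ms: np.ndarray
    sfreq: float
    run: np.ndarray
    n_aud: np.ndarray
    n_vis: np.ndarray
    task: np.ndarray  # 'A' / 'V'
    channels: list[str]

    def __post_init__(self) -> None:
        n, c, s = self.data.shape
        if len(self.time_ms) != s:
            raise ValueError("time axis length must match the sample dimension")
        if len(self.channels) != c:
            raise ValueError("channel list must match the channel dimension")
        for name in ("run", "n_aud", "n_vis", "task"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"annotation {name!r} must have one entry per trial")


@dataclass
class PatternWindows:
    """Spatiotemporal patterns per sliding window.

    ``X[w, t]`` is the 768-feature pattern of trial ``t`` in window ``w``:
    the 12 within-window 64-channel vectors concatenated sample by sample.
    """

    times_ms: np.ndarray  # window onsets (first sample of each window)
    X: np.ndarray  # windows x trials x features
    n_channels: int
    win_samples: int


def bin_patterns(
    epochs: EEGEpochs, win_ms: float = 60.0, step_ms: float = 20.0
) -> PatternWindows:
    """Bin epochs into overlapping windows of concatenated channel vectors."""
    win = int(round(win_ms * epochs.sfreq / 1000.0))
    step = int(round(step_ms * epochs.sfreq / 1000.0))
    n_trials, n_ch, n_samp = epochs.data.shape
    if n_samp < win:
        raise ValueError("epoch shorter than one window")
    starts = np.arange(0, n_samp - win + 1, step)
    # (windows, trials, samples-in-window, channels) -> concat sample-major
    windows = np.empty((len(starts), n_trials, n_ch * win))
    for i, s0 in enumerate(starts):
        block = epochs.data[:, :, s0 : s0 + win]  # trials x ch x win
        windows[i] = block.transpose(0, 2, 1).reshape(n_trials, win * n_ch)
    return PatternWindows(
        times_ms=epochs.time_ms[starts],
        X=windows,
        n_channels=n_ch,
        win_samples=win,
    )


def deconcatenate(pattern: np.ndarray, n_channels: int, win_samples: int) -> np.ndarray:
    """Invert the feature concatenation back to a channels x samples block."""
    return pattern.reshape(win_samples, n_channels).T


def condition_mode_labels(
    params: ObserverParams,
    spec: ModelSpec,
    state: SimulationState,
    conditions: Sequence[Condition] | None = None,
    n_sim: int = 10_000,
    grid_points: int = 512,
) -> pd.DataFrame:
    """Condition-wise modes of the four model estimates.

    For each audiovisual condition, simulate ``n_sim`` trials, compute the
    visual/auditory segregation, fusion, and final estimates, and take the
    mode of each Gaussian-KDE-smoothed distribution (Silverman bandwidth,
    512-point grid).
    """
    conditions = list(conditions) if conditions is not None else av_conditions()
    rows = []
    for cond in conditions:
        if not cond.audiovisual:
            raise ValueError("condition-mode labels are defined for audiovisual conditions")
        sub = SimulationState(state.seed, n_sim=n_sim)
        sub.rng = np.random.default_rng(
            np.random.SeedSequence((state.seed, cond.n_a, cond.n_v, cond.task == "V"))
        )
        samples = sample_sensory_inputs(cond, params, spec, sub)
        final_estimate(samples, cond, params, spec, sub)
        row = {"n_aud": cond.n_a, "n_vis": cond.n_v, "task": cond.task}
        for name, values in (
            ("v_seg", samples.n_hat_v_seg),
            ("a_seg", samples.n_hat_a_seg),
            ("fusion", samples.n_hat_fus),
            ("final", samples.n_hat_final),
        ):
            row[name] = _kde_mode(values, grid_points)
        rows.append(row)
    return pd.DataFrame(rows)


def _kde_mode(values: np.ndarray, grid_points: int) -> float:
    values = np.asarray(values, dtype=float)
    if np.std(values) < 1e-9:
        return float(np.mean(values))
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[np.argmax(kde(grid))])


def _zscore_train_apply(train: np.ndarray, test: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mean) / sd, (test - mean) / sd


DEFAULT_C_GRID = tuple(10.0**e for e in range(-3, 4))
DEFAULT_NU_GRID = tuple(round(0.1 * i, 1) for i in range(1, 9))


def _inner_grid_search(X, y, groups, c_grid, nu_grid):
    """Pick (C, nu) by leave-one-run-out MSE within the training runs."""
    if len(c_grid) == 1 and len(nu_grid) == 1:
        return c_grid[0], nu_grid[0]
    uruns = np.unique(groups)
    best, best_mse = None, np.inf
    for c in c_grid:
        for nu in nu_grid:
            errs = []
            for r in uruns:
                tr, te = groups != r, groups == r
                Xtr, Xte = _zscore_train_apply(X[tr], X[te])
                model = NuSVR(kernel="linear", C=c, nu=nu)
                model.fit(Xtr, y[tr])
                errs.append(np.mean((model.predict(Xte) - y[te]) ** 2))
            mse = float(np.mean(errs))
            if mse < best_mse:
                best, best_mse = (c, nu), mse
    return best


def decode_estimates(
    windows: PatternWindows,
    labels: Mapping[str, np.ndarray] | pd.DataFrame,
    runs: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    nu_grid: Sequence[float] = DEFAULT_NU_GRID,
) -> tuple[pd.DataFrame, list[dict]]:
    """Time-resolved decoding accuracy for each model estimate.

    Outer leave-one-run-out CV; within each training fold a nested
    leave-one-run-out grid search selects (C, nu).  Features are z-scored
    with training-fold statistics only.  Held-out predictions are pooled
    across folds and correlated with the labels (Fisher z).

    Returns the accuracy trace (long DataFrame: estimate, time_ms, z) and a
    fold log recording, per fold, the held-out run and the training runs.
    """
    runs = np.asarray(runs)
    uruns = np.unique(runs)
    if len(uruns) < 3:
        raise ValueError("leave-one-run-out decoding needs at least 3 runs")
    if isinstance(labels, pd.DataFrame):
        labels = {c: labels[c].to_numpy(dtype=float) for c in labels.columns}
    rows = []
    fold_log: list[dict] = []
    for name, y in labels.items():
        y = np.asarray(y, dtype=float)
        for w in range(windows.X.shape[0]):
            Xw = windows.X[w]
            pred = np.empty_like(y)
            for r in uruns:
                test = runs == r
                train = ~test
                c, nu = _inner_grid_search(
                    Xw[train], y[train], runs[train], c_grid, nu_grid
                )
                Xtr, Xte = _zscore_train_apply(Xw[train], Xw[test])
                model = NuSVR(kernel="linear", C=c, nu=nu)
                model.fit(Xtr, y[train])
                pred[test] = model.predict(Xte)
                fold_log.append(
                    {
                        "estimate": name,
                        "window": w,
                        "test_run": r,
                        "train_runs": tuple(int(x) for x in np.unique(runs[train])),
                        "C": c,
                        "nu": nu,
                    }
                )
            r_acc = np.corrcoef(pred, y)[0, 1]
            rows.append(
                {
                    "estimate": name,
                    "time_ms": float(windows.times_ms[w]),
                    "r": float(r_acc),
                    "z": float(fisher_z(r_acc)),
                }
            )
    return pd.DataFrame(rows), fold_log


def erp_av_interaction(
    epochs: EEGEpochs,
    occipital: Sequence[str] = OCCIPITAL,
    baseline: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Occipital audiovisual-interaction difference wave AV_congr - (A + V).

    ERPs are averaged over trials and the occipital channels per condition
    class (congruent audiovisual, auditory-only, visual-only).  Waves are
    baseline-corrected with the mean over the prestimulus samples.
    """
    missing = [ch for ch in occipital if ch not in epochs.channels]
    if missing:
        raise ValueError(f"missing occipital channels: {missing}")
    idx = [epochs.channels.index(ch) for ch in occipital]
    congr = (epochs.n_aud > 0) & (epochs.n_aud == epochs.n_vis)
    aud_only = (epochs.n_aud > 0) & (epochs.n_vis == 0)
    vis_only = (epochs.n_vis > 0) & (epochs.n_aud == 0)
    if not (congr.any() and aud_only.any() and vis_only.any()):
        raise ValueError("need congruent audiovisual and both unisensory classes")

    def erp(mask):
        wave = epochs.data[mask][:, idx, :].mean(axis=(0, 1))
        if baseline:
            pre = epochs.time_ms < 0
            wave = wave - wave[pre].mean()
        return wave

    diff = erp(congr) - (erp(aud_only) + erp(vis_only))
    return epochs.time_ms, diff


def cluster_permutation(
    series: np.ndarray,
    series2: np.ndarray | None = None,
    test: str = "one-sample",
    n_perm: int = 5000,
    t_thresh: float = 2.0,
    tail: str = "two-sided",
    seed: int = 0,
) -> list[dict]:
    """Cluster-based randomization test over subjects x time data.

    Supra-threshold contiguous time points form clusters whose mass is the
    sum of t values; the null distribution is the maximum cluster mass over
    sign flips (one-sample) or group-label permutations (two-sample);
    cluster p = (1 + #{null >= mass}) / (1 + n_perm).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)

    if test == "one-sample":
        t_obs = _tstat_one(series.T)

        def null_t():
            signs = rng.choice([-1.0, 1.0], size=(series.shape[0], 1))
            return _tstat_one((signs * series).T)

    elif test == "two-sample":
        if series2 is None:
            raise ValueError("two-sample test needs a second group")
        series2 = np.asarray(series2, dtype=float)
        t_obs = _tstat_two(series.T, series2.T)
        pooled = np.vstack([series, series2])
        n1 = series.shape[0]

        def null_t():
            perm = rng.permutation(pooled.shape[0])
            return _tstat_two(pooled[perm[:n1]].T, pooled[perm[n1:]].T)

    else:
        raise ValueError(f"unknown test {test!r}")

    clusters = _find_clusters(t_obs, t_thresh, tail)
    if not clusters:
        return []
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        tn = null_t()
        cn = _find_clusters(tn, t_thresh, tail)
        null_max[i] = max((abs(c["mass"]) for c in cn), default=0.0)
    for c in clusters:
        c["p"] = float((1.0 + np.sum(null_max >= abs(c["mass"]))) / (1.0 + n_perm))
    return sorted(clusters, key=lambda c: c["start"])


def _find_clusters(t: np.ndarray, thresh: float, tail: str) -> list[dict]:
    if tail == "two-sided":
        above = np.abs(t) > thresh
        sign = np.sign(t)
    elif tail == "greater":
        above = t > thresh
        sign = np.ones_like(t)
    elif tail == "less":
        above = t < -thresh
        sign = -np.ones_like(t)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    clusters = []
    i = 0
    n = len(t)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            clusters.append({"start": i, "end": j, "mass": float(np.sum(t[i : j + 1]))})
            i = j + 1
        else:
            i += 1
    return clusters
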