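"""GLM-style behavioral indices and randomization tests.

Covers response accuracy (Fisher-z Pearson correlation between reports and
the task-relevant count), the bias-adjusted crossmodal bias (CMB) for
incongruent audiovisual trials, fission/fusion illusion strength as a d'
difference against a unisensory baseline, and permutation t tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "fisher_z",
    "response_accuracy",
    "crossmodal_bias",
    "cmb_by_disparity",
    "illusion_dprime",
    "randomization_ttest",
]

_R_CLIP = 1.0 - 1e-8


def fisher_z(r) -> np.ndarray:
    """atanh with the argument clipped away from +-1 so perfect correlations
    (common in synthetic data) stay finite."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def response_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x modality-class x task accuracy.

    Accuracy is the Pearson correlation between the numeric report and the
    true task-relevant count, Fisher-z transformed.  Cells with fewer than 3
    trials or zero variance yield NaN (flagged via the ``valid`` column).
    Classes: ``unisensory`` and audiovisual-``congruent`` trials.
    """
    rows = []
    for subject, sub in table.groupby("subject"):
        uni = sub[(sub["n_aud"] == 0) | (sub["n_vis"] == 0)]
        congr = sub[(sub["n_aud"] > 0) & (sub["n_aud"] == sub["n_vis"])]
        for cls, block in (("unisensory", uni), ("congruent", congr)):
            for task, cell in block.groupby("task"):
                truth = cell["n_aud"] if task == "A" else cell["n_vis"]
                r = _pearson(truth, cell["report"])
                rows.append(
                    {
                        "subject": subject,
                        "class": cls,
                        "task": task,
                        "n_trials": len(cell),
                        "r": r,
                        "z": fisher_z(r) if np.isfinite(r) else np.nan,
                        "valid": bool(np.isfinite(r)),
                    }
                )
    return pd.DataFrame(rows)


def crossmodal_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Bias-adjusted crossmodal bias per subject x task x incongruent cell.

    Per subject and task modality, reports on congruent audiovisual trials
    are regressed on the true count (OLS); the fitted line maps each
    incongruent cell's ``n_a``/``n_v`` to adjusted counts, and

        CMB = (mean report - adj n_a) / (adj n_v - adj n_a)

    so CMB = 1 means purely visual and CMB = 0 purely auditory influence.
    """
    rows = []
    for (subject, task), sub in table.groupby(["subject", "task"]):
        av = sub[(sub["n_aud"] > 0) & (sub["n_vis"] > 0)]
        congr = av[av["n_aud"] == av["n_vis"]]
        incongr = av[av["n_aud"] != av["n_vis"]]
        if len(congr) < 2 or congr["n_aud"].nunique() < 2:
            raise ValueError(
                f"subject {subject!r} task {task!r}: congruent trials required for "
                "the bias-adjustment regression"
            )
        slope, intercept = np.polyfit(
            congr["n_aud"].to_numpy(dtype=float), congr["report"].to_numpy(dtype=float), 1
        )
        for (n_a, n_v), cell in incongr.groupby(["n_aud", "n_vis"]):
            adj_a = slope * n_a + intercept
            adj_v = slope * n_v + intercept
            denom = adj_v - adj_a
            valid = abs(denom) >= 1e-9
            cmb = (cell["report"].mean() - adj_a) / denom if valid else np.nan
            rows.append(
                {
                    "subject": subject,
                    "task": task,
                    "n_aud": int(n_a),
                    "n_vis": int(n_v),
                    "disparity": int(abs(n_a - n_v)),
                    "n_trials": len(cell),
                    "cmb": cmb,
                    "valid": valid,
                }
            )
    return pd.DataFrame(rows)


def cmb_by_disparity(cmb_cells: pd.DataFrame) -> pd.DataFrame:
    """Average cell-level CMB within subject x task x disparity."""
    return (
        cmb_cells[cmb_cells["valid"]]
        .groupby(["subject", "task", "disparity"], as_index=False)["cmb"]
        .mean()
    )


def _rate(count: int, n: int) -> float:
    # floor/ceiling correction at 1/(2N)
    lo = 1.0 / (2 * n)
    return float(np.clip(count / n, lo, 1.0 - lo))


def _dprime(hit_count, hit_n, fa_count, fa_n) -> float:
    return float(norm.ppf(_rate(hit_count, hit_n)) - norm.ppf(_rate(fa_count, fa_n)))


def illusion_dprime(table: pd.DataFrame) -> pd.DataFrame:
    """Fission/fusion illusion strength per subject.

    Visual-report trials with reports <= 2 only.  Sensitivity d' for
    discriminating 1 vs 2 flashes is computed in the unisensory baseline
    (V1A0 vs V2A0) and in the illusion conditions (fission: V1A2 vs V2A2
    with response "2" as signal; fusion: V1A1 vs V2A2 with response "1" as
    signal); illusion strength is d'_baseline - d'_illusion.  Hit and
    false-alarm rates are floored/ceilinged at 1/(2N).
    """
    rows = []
    vis = table[(table["task"] == "V") & (table["report"] <= 2)]
    for subject, sub in vis.groupby("subject"):
        def cell(n_v, n_a):
            return sub[(sub["n_vis"] == n_v) & (sub["n_aud"] == n_a)]

        def count_resp(block, resp):
            return int((block["report"] == resp).sum()), len(block)

        cells = {
            "V1A0": cell(1, 0),
            "V2A0": cell(2, 0),
            "V1A2": cell(1, 2),
            "V2A2": cell(2, 2),
            "V1A1": cell(1, 1),
        }
        if any(len(c) == 0 for c in cells.values()):
            rows.append({"subject": subject, "fission": np.nan, "fusion": np.nan, "valid": False})
            continue
        # fission: signal = response "2"
        d_base_fis = _dprime(*count_resp(cells["V2A0"], 2), *count_resp(cells["V1A0"], 2))
        d_ill_fis = _dprime(*count_resp(cells["V2A2"], 2), *count_resp(cells["V1A2"], 2))
        # fusion: signal = response "1"
        d_base_fus = _dprime(*count_resp(cells["V1A0"], 1), *count_resp(cells["V2A0"], 1))
        d_ill_fus = _dprime(*count_resp(cells["V1A1"], 1), *count_resp(cells["V2A2"], 1))
        rows.append(
            {
                "subject": subject,
                "fission": d_base_fis - d_ill_fis,
                "fusion": d_base_fus - d_ill_fus,
                "valid": True,
            }
        )
    return pd.DataFrame(rows)


def _tstat_one(data: np.ndarray) -> float:
    n = data.shape[-1]
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        return np.where(sd == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)


def _tstat_two(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.shape[-1], b.shape[-1]
    va = a.var(axis=-1, ddof=1)
    vb = b.var(axis=-1, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    diff = a.mean(axis=-1) - b.mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (sp * np.sqrt(1.0 / na + 1.0 / nb))
        return np.where(sp == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)


def randomization_ttest(
    a,
    b=None,
    mode: str = "two-sample",
    n_perm: int = 5000,
    alternative: str = "two-sided",
    seed: int = 0,
) -> dict:
    """Permutation t test.

    ``one-sample`` (and ``paired``, on the differences) flips signs;
    ``two-sample`` permutes group labels.  The permutation p-value includes
    the observed statistic: p = (1 + #{t* at least as extreme}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    if mode == "paired":
        if b is None:
            raise ValueError("paired mode needs two samples")
        a = a - np.asarray(b, dtype=float)
        mode, b = "one-sample", None
    if mode == "one-sample":
        if len(a) < 2:
            raise ValueError("need n >= 2")
        t_obs = float(_tstat_one(a))
        signs = rng.choice([-1.0, 1.0], size=(n_perm, len(a)))
        t_null = _tstat_one(signs * a)
    elif mode == "two-sample":
        if b is None:
            raise ValueError("two-sample mode needs two samples")
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        t_obs = float(_tstat_two(a, b))
        pooled = np.concatenate([a, b])
        perms = np.array([rng.permutation(pooled) for _ in range(n_perm)])
        t_null = _tstat_two(perms[:, : len(a)], perms[:, len(a):])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if alternative == "two-sided":
        extreme = np.abs(t_null) >= abs(t_obs)
    elif alternative == "greater":
        extreme = t_null >= t_obs
    elif alternative == "less":
        extreme = t_null <= t_obs
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + int(np.sum(extreme))) / (1.0 + n_perm)
    return {"t": t_obs, "p": float(p), "n_perm": n_perm}
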