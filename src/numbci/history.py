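"""Trial-history analysis: condition current trials on the previous trial
and selectively refit the causal or numeric prior.

Observers update their priors from recent stimuli: after a trial with large
audiovisual disparity the binding tendency (causal prior) drops, and after
many task-relevant events the numeric prior shifts upward.  These analyses
sort current trials by the previous trial's disparity (or task-relevant
count) and re-optimize only the prior parameter(s) of interest in each bin,
with all other parameters frozen at the subject's full-data fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitResult, fit_subset
from .observer import ModelSpec, SimulationState

__all__ = ["tag_history", "refit_conditional"]

LOW_POWER_TRIALS = 20


def tag_history(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``prev_disparity`` and ``prev_relevant_count`` columns.

    History is computed strictly within subject and run (runs break history);
    the first trial of each run is tagged undefined (NaN).  A unisensory
    previous trial yields an undefined previous disparity.
    """
    out = table.sort_values(["subject", "run", "trial"]).copy()
    prev = out.groupby(["subject", "run"])[["n_aud", "n_vis", "task"]].shift(1)
    both = (prev["n_aud"] > 0) & (prev["n_vis"] > 0)
    out["prev_disparity"] = np.where(both, (prev["n_aud"] - prev["n_vis"]).abs(), np.nan)
    relevant = np.where(prev["task"] == "A", prev["n_aud"], prev["n_vis"])
    out["prev_relevant_count"] = np.where(
        pd.notna(prev["task"]) & (relevant > 0), relevant, np.nan
    )
    return out


def refit_conditional(
    table: pd.DataFrame,
    base_fit: FitResult,
    which: str,
    state: SimulationState,
    n_inits: int = 20,
    maxfev: int | None = None,
) -> pd.DataFrame:
    """Per previous-condition bin, re-optimize only the causal prior
    (``which='causal'``) or the numeric prior's mean and std
    (``which='numeric'``); every other parameter stays frozen at
    ``base_fit``.

    Returns one row per bin with the refitted value(s), the bin size, and a
    low-power flag for bins under 20 trials.
    """
    if which == "causal":
        if base_fit.spec.causal_param_name != "p_common":
            raise ValueError("causal refit requires a p_common-based strategy")
        bin_col, bins, free = "prev_disparity", [0, 1, 2, 3], ["causal"]
    elif which == "numeric":
        bin_col, bins, free = "prev_relevant_count", [1, 2, 3, 4], ["mu_p", "sigma_p"]
    else:
        raise ValueError("which must be 'causal' or 'numeric'")

    tagged = tag_history(table) if bin_col not in table.columns else table
    rows = []
    for b in bins:
        sub = tagged[tagged[bin_col] == b]
        row = {"bin": b, "n_trials": len(sub), "low_power": len(sub) < LOW_POWER_TRIALS}
        if len(sub) == 0:
            for name in free:
                row[name] = np.nan
            row["loglik"] = np.nan
            rows.append(row)
            continue
        params, loglik = fit_subset(
            sub,
            base_fit.spec,
            base_fit.params,
            free,
            state,
            n_inits=n_inits,
            maxfev=maxfev,
        )
        if which == "causal":
            row["causal"] = params.causal_value(base_fit.spec)
        else:
            row["mu_p"] = params.mu_p
            row["sigma_p"] = params.sigma_p
        row["loglik"] = loglik
        row["params"] = params
        rows.append(row)
    return pd.DataFrame(rows)
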