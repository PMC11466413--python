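"""Reading and writing the package's on-disk formats: trial tables (CSV),
evidence matrices (CSV), and epoched EEG (HDF5)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eeg import EEGEpochs

__all__ = [
    "read_trials",
    "write_trials",
    "read_evidence",
    "write_evidence",
    "save_epochs",
    "load_epochs",
]

TRIAL_COLUMNS = ["subject", "group", "run", "trial", "n_aud", "n_vis", "task", "report", "button_map"]


def read_trials(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial CSV is missing columns: {missing}")
    bad = ~table["task"].isin(["A", "V"])
    if bad.any():
        raise ValueError("task must be 'A' or 'V'")
    if not table["report"].isin([1, 2, 3, 4]).all():
        raise ValueError("report must lie in 1..4")
    return table


def write_trials(table: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_evidence(path) -> pd.DataFrame:
    """Subjects x models log-evidence matrix; first column is the subject id."""
    return pd.read_csv(path, index_col=0)


def write_evidence(evidence: pd.DataFrame, path) -> None:
    evidence.to_csv(path)


def save_epochs(epochs: EEGEpochs, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("epochs", data=epochs.data)
        fh.create_dataset("time_ms", data=epochs.time_ms)
        fh.create_dataset("sfreq", data=epochs.sfreq)
        fh.create_dataset("run", data=np.asarray(epochs.run, dtype=int))
        fh.create_dataset("n_aud", data=np.asarray(epochs.n_aud, dtype=int))
        fh.create_dataset("n_vis", data=np.asarray(epochs.n_vis, dtype=int))
        fh.create_dataset("task", data=np.array([t.encode() for t in epochs.task]))
        fh.create_dataset("channels", data=np.array([c.encode() for c in epochs.channels]))


def load_epochs(path) -> EEGEpochs:
    import h5py

    with h5py.File(path, "r") as fh:
        return EEGEpochs(
            data=fh["epochs"][()],
            time_ms=fh["time_ms"][()],
            sfreq=float(fh["sfreq"][()]),
            run=fh["run"][()],
            n_aud=fh["n_aud"][()],
            n_vis=fh["n_vis"][()],
            task=np.array([t.decode() for t in fh["task"][()]]),
            channels=[c.decode() for c in fh["channels"][()]],
        )
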