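"""File formats: trial-table CSV, fit CSV, and EEG recordings.

Trial tables travel as plain CSV with the header
``subject_id,group,site,condition,comparison_period,reference_period,response,rt``
(periods in seconds, response in {0,1}, rt empty when missing).

EEG recordings are accepted in two dialects:

* EDF (read through :mod:`mne`, which must be installed) plus a JSON
  sidecar listing the stimulus events ``{"sample": int, "site": str,
  "condition": str}``;
* a raw float32 binary (channels x samples, row-major, microvolts) plus a
  JSON metadata file carrying channel names, sampling rate and the same
  event list.  This dialect is also what synthetic fixtures are written in.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EEGRecording, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
    "write_eeg_raw",
    "read_eeg_raw",
    "read_eeg_edf",
    "read_eeg",
]

TRIAL_COLUMNS = [
    "subject_id", "group", "site", "condition",
    "comparison_period", "reference_period", "response", "rt",
]


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Trial records -> tidy DataFrame in the canonical column order."""
    return pd.DataFrame(
        [
            {
                "subject_id": t.subject_id, "group": t.group, "site": t.site,
                "condition": t.condition,
                "comparison_period": t.comparison_period,
                "reference_period": t.reference_period,
                "response": int(t.response_comparison_longer),
                "rt": t.rt if t.rt is not None else np.nan,
            }
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    )


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """DataFrame (canonical schema) -> trial records; NaN rt becomes None."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        rt = float(row.rt) if pd.notna(row.rt) else None
        out.append(
            TrialRecord(
                subject_id=str(row.subject_id), group=str(row.group),
                site=str(row.site), condition=str(row.condition),
                comparison_period=float(row.comparison_period),
                reference_period=float(row.reference_period),
                response_comparison_longer=bool(int(row.response)),
                rt=rt,
            )
        )
    return out


def write_trials_csv(trials, path) -> None:
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    df.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trial table missing columns: {missing}")
    return df


def write_eeg_raw(recording: EEGRecording, data_path, meta_path) -> None:
    """Write the float32-binary + JSON-sidecar dialect."""
    np.asarray(recording.data, dtype="<f4").tofile(data_path)
    meta = {
        "channel_names": list(recording.channel_names),
        "sampling_rate": recording.sampling_rate,
        "n_channels": int(recording.data.shape[0]),
        "n_samples": int(recording.data.shape[1]),
        "dtype": "float32",
        "events": [
            {"sample": int(s), "site": site, "condition": cond}
            for s, site, cond in recording.events
        ],
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_eeg_raw(data_path, meta_path) -> EEGRecording:
    meta = json.loads(Path(meta_path).read_text())
    data = np.fromfile(data_path, dtype="<f4").astype(float)
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    if data.size != n_ch * n_s:
        raise ValueError(
            f"{data_path}: expected {n_ch * n_s} float32 samples, found {data.size}"
        )
    return EEGRecording(
        channel_names=list(meta["channel_names"]),
        sampling_rate=float(meta["sampling_rate"]),
        data=data.reshape(n_ch, n_s),
        events=[(e["sample"], e["site"], e["condition"]) for e in meta["events"]],
    )


def read_eeg_edf(edf_path, events_path) -> EEGRecording:
    """Read an EDF recording plus its JSON event sidecar (requires mne)."""
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    events = json.loads(Path(events_path).read_text())
    return EEGRecording(
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        data=raw.get_data() * 1e6,  # mne returns volts; store microvolts
        events=[(e["sample"], e["site"], e["condition"]) for e in events],
    )


def read_eeg(path, sidecar) -> EEGRecording:
    """Dispatch on extension: ``.edf`` -> EDF, anything else -> raw binary."""
    p = Path(path)
    if p.suffix.lower() == ".edf":
        return read_eeg_edf(p, sidecar)
    return read_eeg_raw(p, sidecar)
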