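"""CSV/JSON interchange for waveforms, references, features and truth.

Formats
-------
waveform CSV      header ``time_s,ch1,ch2,...``; one file per recording
references CSV    ``record_id,subject_id,sbp_mmHg,dbp_mmHg``
feature CSV       ``record_id,subject_id,<11 features>,sbp_mmHg,dbp_mmHg``
ground truth      JSON ledger, one entry per record (test oracle only)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pulsebp.features import FEATURE_NAMES
from pulsebp.records import WaveformRecording
from pulsebp.simulate import LANDMARKS, GroundTruth

__all__ = [
    "write_waveform_csv", "read_waveform_csv",
    "write_references_csv", "read_references_csv",
    "write_feature_csv", "read_feature_csv",
    "write_ground_truth", "read_ground_truth",
]

FEATURE_CSV_COLUMNS = (
    "record_id", "subject_id", *FEATURE_NAMES, "sbp_mmHg", "dbp_mmHg",
)


def write_waveform_csv(recording: WaveformRecording, path: str | Path) -> None:
    cols = {"time_s": recording.time_s}
    for k in range(recording.n_channels):
        cols[f"ch{k + 1}"] = recording.channels[k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def read_waveform_csv(path: str | Path,
                      record_id: str = "",
                      subject_id: str = "") -> WaveformRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or len(df) < 2:
        raise ValueError(f"{path}: not a waveform CSV (need time_s + data)")
    dt = np.diff(df["time_s"].to_numpy())
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling")
    channels = df.drop(columns="time_s").to_numpy(dtype=float).T
    return WaveformRecording(channels, 1.0 / float(dt[0]),
                             record_id=record_id, subject_id=subject_id)


def write_references_csv(references: pd.DataFrame, path: str | Path) -> None:
    references.to_csv(path, index=False)


def read_references_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"record_id", "subject_id", "sbp_mmHg", "dbp_mmHg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_feature_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.loc[:, list(FEATURE_CSV_COLUMNS)].to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_ground_truth(truths: list[GroundTruth], path: str | Path) -> None:
    blob = []
    for g in truths:
        blob.append({
            "record_id": g.record_id,
            "subject_id": g.subject_id,
            "sbp_mmHg": g.sbp_mmHg,
            "dbp_mmHg": g.dbp_mmHg,
            "aligned_channel": g.aligned_channel,
            "beat_onset_times_s": g.beat_onset_times_s.tolist(),
            "fiducials": {k: g.fiducials[k].tolist() for k in LANDMARKS},
        })
    Path(path).write_text(json.dumps(blob))


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    blob = json.loads(Path(path).read_text())
    return [
        GroundTruth(
            record_id=e["record_id"], subject_id=e["subject_id"],
            sbp_mmHg=e["sbp_mmHg"], dbp_mmHg=e["dbp_mmHg"],
            aligned_channel=e["aligned_channel"],
            beat_onset_times_s=np.asarray(e["beat_onset_times_s"]),
            fiducials={k: np.asarray(v) for k, v in e["fiducials"].items()},
        )
        for e in blob
    ]
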