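"""Reading user-supplied recordings (EDF) and stage-annotation tables.

Synthetic cohorts never touch disk as raw signals; this module exists for
users bringing their own clinical recordings.  The stage annotation is a
CSV with columns onset_s, duration_s, stage (N1 or N2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CHANNELS_1020, DataError, SleepRecording


def read_stage_annotation(path) -> list[tuple[float, float, str]]:
    table = pd.read_csv(path)
    required = {"onset_s", "duration_s", "stage"}
    if not required.issubset(table.columns):
        raise DataError(f"annotation file must have columns {sorted(required)}")
    bad = set(table["stage"]) - {"N1", "N2"}
    if bad:
        raise DataError(f"unknown stage labels: {sorted(bad)}")
    return [
        (float(r.onset_s), float(r.duration_s), str(r.stage)) for r in table.itertuples()
    ]


def read_edf_recording(path, annotation_path, subject_id: str | None = None) -> SleepRecording:
    """Load a 19-channel EDF and pair it with its stage annotation."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    missing = [ch for ch in CHANNELS_1020 if ch not in raw.ch_names]
    if missing:
        raise DataError(f"recording lacks required 10-20 channels: {missing}")
    raw.pick(list(CHANNELS_1020))
    if abs(raw.info["sfreq"] - 250.0) > 1e-6:
        raw.resample(250.0)
    data = raw.get_data() * 1e6  # volts -> microvolts
    return SleepRecording(
        subject_id=subject_id or str(path),
        sampling_rate=250.0,
        channels=tuple(CHANNELS_1020),
        data=np.asarray(data),
        stage_annotation=read_stage_annotation(annotation_path),
    )
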