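"""CSV/JSON serialisation of sessions, subjects, models and reports.

Waveforms travel as plain UTF-8 comma-separated text (one row per
1000 Hz sample; the 1 Hz heart rate is forward-filled onto the sample
grid), subjects and fitted models as JSON sidecars.  Floats are written
with 12 significant digits so a write/read round-trip is identical to
within 1e-9 relative error.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SessionTraces, SubjectProfile

__all__ = [
    "SESSION_COLUMNS",
    "ParseError",
    "write_session_csv",
    "read_session_csv",
    "write_subject_json",
    "read_subject_json",
]

_POSITIONS = ("c7", "l5", "ta")
SESSION_COLUMNS = ["time_s", "grf_v_N"] + [
    f"{pos}_{axis}_g" for pos in _POSITIONS for axis in "xyz"
] + ["hr_bpm"]


class ParseError(ValueError):
    """Malformed session file; carries the offending line where known."""


def write_session_csv(traces: SessionTraces, path) -> None:
    """Write synchronized session waveforms as a flat CSV."""
    n = traces.n_samples
    data = {"time_s": traces.time, "grf_v_N": traces.force_v}
    for pos in _POSITIONS:
        axes = traces.acc[pos]
        for i, axis in enumerate("xyz"):
            data[f"{pos}_{axis}_g"] = axes[:, i]
    hr_idx = np.minimum((traces.time * traces.fs_hr).astype(int), traces.hr.size - 1)
    data["hr_bpm"] = traces.hr[hr_idx]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_session_csv(path, fs_hr: float = 1.0) -> SessionTraces:
    """Read a session CSV back into :class:`SessionTraces`.

    The sampling rate is inferred from the (required uniform) time
    step; the heart-rate trace is recovered by sampling the
    forward-filled column on the 1/fs_hr grid.  Ground truth and
    protocol metadata are not part of the waveform file and come back
    empty.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing} (line 1)")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ParseError(f"{path}: non-monotone time at line {bad[0] + 3}")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 1e-6 * step + 1e-12:
        idx = int(np.argmax(np.abs(dt - step)))
        raise ParseError(f"{path}: non-uniform time step at line {idx + 3}")
    fs = 1.0 / step
    acc = {
        pos: np.column_stack([df[f"{pos}_{axis}_g"].to_numpy(dtype=float) for axis in "xyz"])
        for pos in _POSITIONS
    }
    hr_col = df["hr_bpm"].to_numpy(dtype=float)
    n_hr = int(np.floor(t[-1] * fs_hr)) + 1
    hr = hr_col[np.minimum(np.rint(np.arange(n_hr) / fs_hr * fs).astype(int), len(df) - 1)]
    return SessionTraces(
        time=t,
        force_v=df["grf_v_N"].to_numpy(dtype=float),
        acc=acc,
        hr=hr,
        subject_id=path.stem,
        fs=fs,
        fs_hr=fs_hr,
        ground_truth=pd.DataFrame(),
    )


def write_subject_json(subject: SubjectProfile, path) -> None:
    Path(path).write_text(json.dumps(asdict(subject), indent=2))


def read_subject_json(path) -> SubjectProfile:
    return SubjectProfile(**json.loads(Path(path).read_text()))
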