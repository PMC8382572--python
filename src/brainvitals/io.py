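"""Delimited-text serialization of recordings, markers and measurement tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .measures import LONG_COLUMNS, UNITS
from .pipeline import ErpMeasurementSet
from .recording import RawRecording, StimulusSequence


def write_recording(recording: RawRecording, data_path: str | Path,
                    markers_path: str | Path) -> None:
    """Write samples (one column per channel, uV) and a marker sidecar file."""
    frame = pd.DataFrame(recording.data.T, columns=recording.channels)
    frame.insert(0, "sample", np.arange(recording.n_samples))
    frame.to_csv(data_path, index=False, float_format="%.6f")
    markers = pd.DataFrame({
        "onset_sample": recording.marker_samples(),
        "kind": recording.markers.kinds,
        "condition": recording.markers.conditions,
    })
    markers.to_csv(markers_path, index=False, sep="\t")


def read_recording(data_path: str | Path, markers_path: str | Path,
                   sample_rate: float = 500.0) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    frame = pd.read_csv(data_path)
    channels = [c for c in frame.columns if c != "sample"]
    data = frame[channels].to_numpy(float).T
    markers = pd.read_csv(markers_path, sep="\t")
    seq = StimulusSequence(markers["onset_sample"].to_numpy(float) / sample_rate,
                           list(markers["kind"]), list(markers["condition"]))
    return RawRecording(sample_rate, channels, data, seq)


def measurements_to_long(results: list[ErpMeasurementSet], *, group: str = "",
                         age: float = float("nan"), sex: str = "unspecified",
                         meta: dict[str, dict] | None = None) -> pd.DataFrame:
    """ErpMeasurementSet objects -> the long-format measurement table.

    ``meta`` optionally maps participant_id to ``{"group", "age", "sex"}``
    overriding the scalar defaults.
    """
    rows = []
    for r in results:
        info = (meta or {}).get(r.participant_id, {})
        for m, v in r.as_dict().items():
            rows.append(dict(participant_id=r.participant_id,
                             group=info.get("group", group),
                             age=info.get("age", age), sex=info.get("sex", sex),
                             session=r.session, measure=m, value=v, unit=UNITS[m]))
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def write_measurements(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    return frame
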