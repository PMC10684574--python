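"""Readers and writers for every file the pipeline touches.

All interchange is plain delimited text: trace files carry a leading
``time_s`` column (seconds, zero-based) and one column per well or ROI;
plate maps have columns (well, group, is_control, plate); feature
tables are wells x parameters.  Floats are serialized with ``repr``
precision (17 significant digits) so a write/read round-trip recovers
values bit-exactly.  The delimiter is sniffed from a file prefix, and
the frame rate is inferred from the time column, which must be
monotone increasing and uniform to within 1%.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .peaks import Trace
from .simulate import GroundTruth, SimEvent, SimulatedTrace
from .synchrony import CorrelationMatrix, ROITraceSet


class ParseError(ValueError):
    """Raised for malformed trace/table files, with the offending line."""


_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path: Path) -> str:
    prefix = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
    try:
        return csv.Sniffer().sniff(prefix, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _read_timed_table(path: str | Path) -> tuple[pd.DataFrame, float]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")
    if df.columns[0] != "time_s":
        raise ParseError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # header + 1-based
        raise ParseError(f"{path}: ragged/missing values at line {bad}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 3
        raise ParseError(f"{path}: time column not monotone increasing at line {bad}")
    if dt.size and (dt.max() - dt.min()) > 0.01 * np.median(dt):
        bad = int(np.argmax(np.abs(dt - np.median(dt)) > 0.005 * np.median(dt))) + 3
        raise ParseError(f"{path}: non-uniform frame spacing at line {bad}")
    frame_rate = 1.0 / float(np.median(dt))
    return df, frame_rate


def write_traces(path: str | Path, traces: list[Trace]) -> None:
    """Write traces as delimited text: time_s column + one column per id."""
    if not traces:
        raise ValueError("no traces to write")
    fs = traces[0].frame_rate_hz
    n = traces[0].n_frames
    for tr in traces:
        if tr.frame_rate_hz != fs or tr.n_frames != n:
            raise ValueError("all traces in one file must share length and frame rate")
    df = pd.DataFrame({"time_s": np.arange(n) / fs})
    for tr in traces:
        df[tr.id] = tr.values
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traces(path: str | Path) -> list[Trace]:
    """Read a well-trace file back into :class:`Trace` objects."""
    df, fs = _read_timed_table(path)
    return [
        Trace(df[col].to_numpy(dtype=float), fs, id=str(col))
        for col in df.columns[1:]
    ]


def write_roi_set(path: str | Path, roi_set: ROITraceSet) -> None:
    df = pd.DataFrame({"time_s": np.arange(roi_set.n_frames) / roi_set.frame_rate_hz})
    for i, rid in enumerate(roi_set.roi_ids):
        df[rid] = roi_set.data[:, i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_roi_set(path: str | Path, spheroid_id: str | None = None) -> ROITraceSet:
    df, fs = _read_timed_table(path)
    ids = [str(c) for c in df.columns[1:]]
    return ROITraceSet(
        data=df[df.columns[1:]].to_numpy(dtype=float),
        frame_rate_hz=fs,
        roi_ids=ids,
        spheroid_id=spheroid_id or Path(path).stem,
    )


def write_plate_map(path: str | Path, plate_map: pd.DataFrame) -> None:
    plate_map.to_csv(path, index=False)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    required = {"well", "group", "is_control"}
    if not required.issubset(pm.columns):
        raise ParseError(f"{path}: plate map needs columns {sorted(required)}")
    if "plate" not in pm.columns:
        pm["plate"] = "plate1"
    pm["is_control"] = pm["is_control"].astype(bool)
    return pm


def write_features(path: str | Path, features: pd.DataFrame) -> None:
    features.to_csv(path, index=True, index_label="well", float_format=_FLOAT_FMT)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)), float_precision="round_trip")
    return df.set_index(df.columns[0])


def write_correlation_matrix(path: str | Path, cm: CorrelationMatrix) -> None:
    cm.to_frame().to_csv(path, index=True, index_label="roi", float_format=_FLOAT_FMT)


def read_correlation_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)), float_precision="round_trip")
    return df.set_index(df.columns[0])


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """Write the generator's event sidecar as JSON."""
    payload = {"n_events": truth.n_events, "events": [asdict(e) for e in truth.events]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(events=tuple(SimEvent(**e) for e in payload["events"]))


def sidecar_path(trace_path: str | Path, trace_id: str) -> Path:
    p = Path(trace_path)
    return p.with_name(f"{p.stem}.{trace_id}.truth.json")


def write_simulated_plate(
    out_dir: str | Path,
    traces: list[SimulatedTrace],
    plate_map: pd.DataFrame,
    stem: str = "plate",
) -> dict[str, Path]:
    """Write a simulated plate: trace table, plate map, truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace_path = out / f"{stem}_traces.csv"
    write_traces(trace_path, [s.trace for s in traces])
    map_path = out / f"{stem}_map.csv"
    write_plate_map(map_path, plate_map)
    for s in traces:
        write_ground_truth(sidecar_path(trace_path, s.trace.id), s.truth)
    return {"traces": trace_path, "plate_map": map_path}
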