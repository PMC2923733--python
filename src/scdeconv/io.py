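"""Readers and writers for traces, event tables, kernels and ground truth.

Traces are CSV with a ``time,conductance`` header (seconds, microsiemens);
events are tab-separated with the onset/duration/trial_type convention.
Writers mirror readers so every artifact round-trips.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CS_MINUS, CS_PLUS, Trial, TrialDesign
from .model_core import (
    GaussianBump,
    NeuralInputSet,
    ResponseFunction,
    SCTimeSeries,
    TimeGrid,
    ValidationError,
)

__all__ = [
    "read_trace", "write_trace", "read_events", "write_events",
    "design_to_events", "events_to_design", "read_rf", "write_rf",
    "read_ground_truth", "write_ground_truth",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "reinforced", "trial_index"]
EVENT_LABELS = (CS_MINUS, CS_PLUS, "US")

TIME_JITTER_TOL = 1e-6  # s


class ParseError(ValidationError):
    """A file failed validation; the message names the offending row."""


def read_trace(path, sampling_rate: float | None = None,
               units: str = "microsiemens") -> SCTimeSeries:
    """Read a trace CSV (``time,conductance`` or single column + rate)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "conductance" in df.columns and "time" in df.columns:
        t = df["time"].to_numpy(dtype=float)
        v = df["conductance"].to_numpy(dtype=float)
        nan_rows = np.where(~np.isfinite(v) | ~np.isfinite(t))[0]
        if len(nan_rows):
            raise ParseError(f"{path}: non-finite value at data row {nan_rows[0] + 1}")
        if len(t) < 2:
            raise ParseError(f"{path}: need at least 2 samples")
        dts = np.diff(t)
        if np.any(dts <= 0):
            bad = int(np.where(dts <= 0)[0][0])
            raise ParseError(f"{path}: non-monotonic time at data row {bad + 2}")
        dt = float(np.median(dts))
        if np.any(np.abs(dts - dt) > TIME_JITTER_TOL):
            bad = int(np.where(np.abs(dts - dt) > TIME_JITTER_TOL)[0][0])
            raise ParseError(f"{path}: non-uniform sampling at data row {bad + 2}")
        rate = 1.0 / dt
        if abs(rate - round(rate)) < 1e-6:  # undo write/read float jitter
            rate = float(round(rate))
        grid = TimeGrid(sampling_rate=rate, n_samples=len(v), t0=float(t[0]))
        return SCTimeSeries(grid=grid, values=v, units=units)
    if df.shape[1] == 1:
        if sampling_rate is None:
            raise ParseError(f"{path}: single-column trace needs an explicit sampling rate")
        v = df.iloc[:, 0].to_numpy(dtype=float)
        nan_rows = np.where(~np.isfinite(v))[0]
        if len(nan_rows):
            raise ParseError(f"{path}: non-finite value at data row {nan_rows[0] + 1}")
        grid = TimeGrid(sampling_rate=sampling_rate, n_samples=len(v))
        return SCTimeSeries(grid=grid, values=v, units=units)
    raise ParseError(f"{path}: expected columns 'time,conductance' or a single column")


def write_trace(series: SCTimeSeries, path) -> None:
    df = pd.DataFrame({"time": series.grid.times(), "conductance": series.values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_events(path, strict: bool = False) -> pd.DataFrame:
    """Read an events TSV; validates sorting and trial-type labels."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if strict:
        extra = set(df.columns) - set(EVENT_COLUMNS)
        if extra:
            raise ParseError(f"{path}: unexpected columns {sorted(extra)} (strict mode)")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        bad = int(np.where(np.diff(onsets) < 0)[0][0])
        raise ParseError(f"{path}: onsets not sorted at data row {bad + 2}")
    if np.any(onsets < 0):
        raise ParseError(f"{path}: negative onset")
    bad_types = set(df["trial_type"]) - set(EVENT_LABELS)
    if bad_types:
        raise ParseError(
            f"{path}: unknown trial_type {sorted(bad_types)}; allowed: {list(EVENT_LABELS)}"
        )
    return df


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def design_to_events(design: TrialDesign) -> pd.DataFrame:
    rows = []
    for t in design.trials:
        rows.append({"onset": t.cs_onset, "duration": t.soa, "trial_type": t.cs_type,
                     "reinforced": int(t.reinforced), "trial_index": t.index})
        if t.reinforced:
            rows.append({"onset": t.us_onset, "duration": 0.0, "trial_type": "US",
                         "reinforced": 1, "trial_index": t.index})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values(
        "onset", kind="stable").reset_index(drop=True)


def events_to_design(df: pd.DataFrame, session_end: float | None = None) -> TrialDesign:
    cs_rows = df[df["trial_type"].isin([CS_MINUS, CS_PLUS])]
    trials = []
    for _, row in cs_rows.iterrows():
        trials.append(Trial(
            index=int(row.get("trial_index", len(trials))),
            cs_onset=float(row["onset"]),
            soa=float(row["duration"]),
            cs_type=str(row["trial_type"]),
            reinforced=bool(int(row.get("reinforced", 0))),
        ))
    if session_end is None:
        session_end = (trials[-1].us_onset + 20.0) if trials else 0.0
    return TrialDesign(trials=trials, session_end=session_end)


def write_rf(rf: ResponseFunction, path, latency: float = 0.0) -> None:
    payload = {
        "kind": rf.kind,
        "shape_params": rf.shape_params,
        "support": rf.support,
        "sampling_rate": rf.sampling_rate,
        "norm_constant": rf.norm_constant,
        "latency": latency,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_rf(path) -> tuple[ResponseFunction, float]:
    from .model_core import canonical_rf

    payload = json.loads(Path(path).read_text())
    rf = canonical_rf(payload["kind"], payload["shape_params"],
                      sampling_rate=payload["sampling_rate"],
                      support=payload["support"])
    return rf, float(payload.get("latency", 0.0))


def write_ground_truth(inputs: NeuralInputSet, path) -> None:
    """One bump per row: class, amplitude, center, dispersion."""
    rows = []
    for cls in NeuralInputSet.CLASSES:
        for b in inputs.bumps(cls):
            rows.append({"class": cls, **asdict(b)})
    pd.DataFrame(rows, columns=["class", "amplitude", "center", "dispersion"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_ground_truth(path) -> NeuralInputSet:
    df = pd.read_csv(path, sep="\t")
    out = NeuralInputSet()
    for _, row in df.iterrows():
        cls = row["class"]
        if cls not in NeuralInputSet.CLASSES:
            raise ParseError(f"{path}: unknown input class {cls!r}")
        out.bumps(cls).append(GaussianBump(float(row["amplitude"]), float(row["center"]),
                                           float(row["dispersion"])))
    return out
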