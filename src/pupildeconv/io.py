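"""Reading and writing pupil recordings, event logs, pulse lists and epochs.

All formats are plain delimited text (comma-separated, header row, UTF-8):

* ``recording.csv`` — ``time_s,diameter_mm,gaze_x_deg,gaze_y_deg,confidence``
* ``events.csv``    — ``trial_id,event,onset_s,conditions,correct,rt_s`` with
  ``conditions`` encoded as ``factor=level;factor=level``
* ``pulses.csv``    — ``onset_s,scale_mm`` at full float precision

Recordings are resampled to a uniform grid at the nominal rate on read, by
linear interpolation; duplicated timestamps are averaged first and raw clock
gaps longer than two sample periods are flagged per grid sample so blink
logic downstream can see them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tepr import PulseList

__all__ = [
    "PupilRecording",
    "EventLog",
    "FormatError",
    "DataError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_pulses",
    "write_pulses",
    "resample_to_uniform",
]

log = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "time": "time_s",
    "diameter": "diameter_mm",
    "gaze_x": "gaze_x_deg",
    "gaze_y": "gaze_y_deg",
    "confidence": "confidence",
}


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


class DataError(ValueError):
    """The file parsed but its contents violate a data invariant."""


@dataclass
class PupilRecording:
    """Continuous pupil stream on a strictly increasing uniform time grid.

    time : s; diameter : mm; gaze_x/gaze_y : degrees visual angle from the
    screen centre; confidence : unitless in [0, 1]; gap_mask flags samples
    synthesised across raw clock gaps (> 2 sample periods).
    """

    time: np.ndarray
    diameter: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    confidence: np.ndarray
    rate_hz: float = 60.0
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("time", "diameter", "gaze_x", "gaze_y", "confidence"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.time.shape, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        if n < 2:
            raise DataError("recording needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise DataError("time grid must be strictly increasing")
        if np.any(np.abs(dt - dt[0]) > 1e-6):
            raise DataError("time grid must be uniform to within 1e-6 s")
        valid = self.confidence > 0
        if not np.all(np.isfinite(self.diameter[valid])):
            raise DataError("diameter must be finite wherever confidence > 0")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def copy(self) -> "PupilRecording":
        return PupilRecording(
            time=self.time.copy(), diameter=self.diameter.copy(),
            gaze_x=self.gaze_x.copy(), gaze_y=self.gaze_y.copy(),
            confidence=self.confidence.copy(), rate_hz=self.rate_hz,
            gap_mask=self.gap_mask.copy(),
        )


class EventLog:
    """Typed trial/event table with per-trial condition labels.

    Backed by a DataFrame with columns ``trial_id, event, onset_s, correct,
    rt_s, out_of_span`` plus one column per condition factor (strings).
    """

    CORE = ["trial_id", "event", "onset_s", "correct", "rt_s", "out_of_span"]

    def __init__(self, table: pd.DataFrame, condition_cols: list[str] | None = None):
        table = table.copy()
        for col, default in (("correct", pd.NA), ("rt_s", np.nan), ("out_of_span", False)):
            if col not in table.columns:
                table[col] = default
        if condition_cols is None:
            condition_cols = [c for c in table.columns if c not in self.CORE]
        self.condition_cols = list(condition_cols)
        table = table.sort_values(["trial_id", "onset_s"], kind="stable").reset_index(drop=True)
        self.table = table
        self._check()

    def _check(self) -> None:
        for tid, grp in self.table.groupby("trial_id"):
            if grp["onset_s"].is_monotonic_increasing is False:
                raise DataError(f"onsets decrease within trial {tid}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def trial_ids(self) -> np.ndarray:
        return self.table["trial_id"].unique()

    def events_named(self, name: str) -> pd.DataFrame:
        return self.table[self.table["event"] == name]

    def trial(self, trial_id: int) -> pd.DataFrame:
        return self.table[self.table["trial_id"] == trial_id]

    def conditions_for_trial(self, trial_id: int) -> dict:
        row = self.trial(trial_id).iloc[0]
        return {c: row[c] for c in self.condition_cols}


def resample_to_uniform(time, channels: dict, rate_hz: float):
    """Resample jittered samples onto a uniform grid by linear interpolation.

    Duplicated timestamps are averaged first (order-independent).  Returns
    ``(grid, resampled: dict, gap_mask)``.  An already-uniform input at
    ``rate_hz`` comes back unchanged (identity to float precision).
    """
    time = np.asarray(time, dtype=float)
    order = np.argsort(time, kind="stable")
    time = time[order]
    channels = {k: np.asarray(v, dtype=float)[order] for k, v in channels.items()}
    # average duplicates
    uniq, inv, counts = np.unique(time, return_inverse=True, return_counts=True)
    if uniq.size < time.size:
        n_dup = int(time.size - uniq.size)
        log.info("averaged %d duplicated timestamp(s)", n_dup)
        channels = {
            k: np.bincount(inv, weights=v) / counts for k, v in channels.items()
        }
        time = uniq
    if time.size < 2:
        raise DataError("need at least 2 distinct timestamps")
    if np.any(np.diff(time) <= 0):
        raise DataError("timestamps non-monotone after sorting")
    dt = 1.0 / rate_hz
    n = int(np.floor((time[-1] - time[0]) / dt + 0.5)) + 1
    grid = time[0] + dt * np.arange(n)
    grid = np.minimum(grid, time[-1])  # guard the last point against rounding
    out = {k: np.interp(grid, time, v) for k, v in channels.items()}
    # flag grid samples that fall inside raw clock gaps > 2 sample periods
    gaps = np.diff(time) > 2.0 * dt
    gap_mask = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(gaps):
        gap_mask |= (grid > time[i]) & (grid < time[i + 1])
    return grid, out, gap_mask


def read_recording(path, format_spec: dict | None = None, rate_hz: float = 60.0) -> PupilRecording:
    """Read a delimited recording and resample it to a uniform grid.

    ``format_spec`` maps the canonical channel names (time, diameter,
    gaze_x, gaze_y, confidence) to file column names; unmapped optional
    channels default to gaze 0 deg and confidence 1.
    """
    cols = dict(DEFAULT_COLUMNS)
    if format_spec:
        cols.update(format_spec)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("time", "diameter"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column '{cols[key]}'")
    n_raw = len(df)
    channels = {"diameter": df[cols["diameter"]].to_numpy(dtype=float)}
    for key, default in (("gaze_x", 0.0), ("gaze_y", 0.0), ("confidence", 1.0)):
        if cols[key] in df.columns:
            channels[key] = df[cols[key]].to_numpy(dtype=float)
        else:
            channels[key] = np.full(n_raw, default)
    grid, res, gap_mask = resample_to_uniform(
        df[cols["time"]].to_numpy(dtype=float), channels, rate_hz
    )
    log.info("read %d raw samples -> %d grid samples at %g Hz", n_raw, grid.size, rate_hz)
    return PupilRecording(
        time=grid, diameter=res["diameter"], gaze_x=res["gaze_x"],
        gaze_y=res["gaze_y"], confidence=res["confidence"],
        rate_hz=rate_hz, gap_mask=gap_mask,
    )


def write_recording(recording: PupilRecording, path) -> None:
    df = pd.DataFrame({
        "time_s": recording.time,
        "diameter_mm": recording.diameter,
        "gaze_x_deg": recording.gaze_x,
        "gaze_y_deg": recording.gaze_y,
        "confidence": recording.confidence,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def _parse_conditions(s) -> dict:
    if not isinstance(s, str) or not s.strip():
        return {}
    out = {}
    for part in s.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_events(path, recording_span: tuple[float, float] | None = None) -> EventLog:
    """Read an event log; onsets outside ``recording_span`` are flagged
    (retained) with a warning."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("trial_id", "event", "onset_s"):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}'")
    if len(df) == 0:
        return EventLog(pd.DataFrame(columns=["trial_id", "event", "onset_s"]))
    cond_maps = [_parse_conditions(s) for s in df.get("conditions", pd.Series([""] * len(df)))]
    factors: list[str] = []
    for m in cond_maps:
        for k in m:
            if k not in factors:
                factors.append(k)
    out = pd.DataFrame({
        "trial_id": df["trial_id"].astype(int),
        "event": df["event"].astype(str),
        "onset_s": df["onset_s"].astype(float),
    })
    out["correct"] = df["correct"].astype("boolean") if "correct" in df.columns else pd.NA
    out["rt_s"] = df["rt_s"].astype(float) if "rt_s" in df.columns else np.nan
    for f in factors:
        out[f] = [m.get(f, "") for m in cond_maps]
    out["out_of_span"] = False
    if recording_span is not None:
        lo, hi = recording_span
        bad = (out["onset_s"] < lo) | (out["onset_s"] > hi)
        if bad.any():
            log.warning("%d event(s) outside the recording span; flagged", int(bad.sum()))
            out["out_of_span"] = bad
    return EventLog(out, condition_cols=factors)


def write_events(events: EventLog, path) -> None:
    t = events.table
    cond = t[events.condition_cols].astype(str) if events.condition_cols else None
    df = pd.DataFrame({
        "trial_id": t["trial_id"],
        "event": t["event"],
        "onset_s": t["onset_s"],
        "conditions": (
            cond.apply(lambda r: ";".join(f"{k}={v}" for k, v in r.items()), axis=1)
            if cond is not None else ""
        ),
        "correct": t["correct"],
        "rt_s": t["rt_s"],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def write_pulses(pulses: PulseList, path) -> None:
    pd.DataFrame({"onset_s": pulses.onsets, "scale_mm": pulses.scales}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_pulses(path) -> PulseList:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("onset_s", "scale_mm"):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}'")
    return PulseList.from_arrays(df["onset_s"].to_numpy(float), df["scale_mm"].to_numpy(float))
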