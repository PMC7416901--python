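"""Preprocessing chain for continuous pupil recordings.

Steps, in the order a pipeline normally applies them:

1. ``detect_blinks`` — runs of low tracker confidence (or synthesised clock
   gaps) become blink intervals, padded and merged.
2. ``interpolate_blinks`` — the diameter inside each interval is replaced by
   a cubic spline through four anchor samples flanking it.
3. ``hampel_filter`` — five-point sliding-median despiker (scaled-MAD rule).
4. ``exclude_trials`` — drops trials with gaze excursions beyond a fixation
   limit between stimulus onset and response, or with blinks near a
   stimulus onset.
5. ``epoch_and_baseline`` — event-locked segmentation into epochs expressed
   as mm change from a short pre-stimulus baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EventLog, PupilRecording

__all__ = [
    "BlinkInterval",
    "BlinkReason",
    "EpochSet",
    "HampelFilter",
    "detect_blinks",
    "interpolate_blinks",
    "hampel_filter",
    "exclude_trials",
    "epoch_and_baseline",
    "preprocess_recording",
    "write_epochs",
    "read_epochs",
    "DEFAULT_STIMULUS_EVENTS",
]

log = logging.getLogger(__name__)

DEFAULT_STIMULUS_EVENTS = ("memory_array", "search_array", "memory_probe")

MAD_SCALE = 1.4826  # scaled-MAD consistency constant for a normal population


class BlinkReason(str, Enum):
    LOW_CONFIDENCE = "low_confidence"
    CLOCK_GAP = "clock_gap"


@dataclass(frozen=True)
class BlinkInterval:
    """A closed time interval [start, end] (s) treated as a blink artifact."""

    start: float
    end: float
    reason: BlinkReason = BlinkReason.LOW_CONFIDENCE

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("blink interval needs start < end")

    def intersects(self, lo: float, hi: float) -> bool:
        return self.start <= hi and self.end >= lo


@dataclass
class EpochSet:
    """Event-locked, baselined trace segments sharing one relative time axis.

    data : (n_epochs, n_samples) mm change from baseline
    times : seconds relative to the lock event
    meta : one row per epoch (trial_id, condition columns, participant when
        part of a cohort, lock onset on the recording clock)
    """

    times: np.ndarray
    data: np.ndarray
    meta: pd.DataFrame
    baseline_s: float = 0.1
    lock_event: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.times.size:
            raise ValueError("data must be (n_epochs, n_samples) matching times")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta must have one row per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan

    @staticmethod
    def concatenate(sets: list["EpochSet"]) -> "EpochSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        t0 = sets[0].times
        for s in sets[1:]:
            if s.times.size != t0.size or np.any(np.abs(s.times - t0) > 1e-9):
                raise ValueError("epoch sets must share one time axis")
        return EpochSet(
            times=t0,
            data=np.vstack([s.data for s in sets]),
            meta=pd.concat([s.meta for s in sets], ignore_index=True),
            baseline_s=sets[0].baseline_s,
            lock_event=sets[0].lock_event,
        )


# ---------------------------------------------------------------------------
# blink handling

def _runs(mask: np.ndarray):
    """Yield (i0, i1) inclusive index bounds of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    for a, b in zip(idx[::2], idx[1::2]):
        yield int(a), int(b - 1)


def detect_blinks(
    recording: PupilRecording,
    conf_threshold: float = 0.6,
    min_gap_merge: float = 0.05,
    pad_s: float = 0.033,
) -> list[BlinkInterval]:
    """Find maximal runs of confidence < threshold or clock-gap samples.

    Each run is padded by ``pad_s`` on both sides; runs whose padded
    intervals come within ``min_gap_merge`` seconds of each other are
    merged (eyelid closures at 60 Hz often fragment the confidence drop).
    """
    low = recording.confidence < conf_threshold
    mask = low | recording.gap_mask
    t = recording.time
    raw: list[BlinkInterval] = []
    for i0, i1 in _runs(mask):
        reason = BlinkReason.LOW_CONFIDENCE if low[i0:i1 + 1].any() else BlinkReason.CLOCK_GAP
        raw.append(BlinkInterval(t[i0] - pad_s, t[i1] + pad_s, reason))
    merged: list[BlinkInterval] = []
    for iv in raw:
        if merged and iv.start - merged[-1].end < min_gap_merge:
            prev = merged.pop()
            reason = (prev.reason if prev.reason == iv.reason
                      else BlinkReason.LOW_CONFIDENCE)
            iv = BlinkInterval(prev.start, max(prev.end, iv.end), reason)
        merged.append(iv)
    return merged


def interpolate_blinks(
    recording: PupilRecording,
    intervals: list[BlinkInterval],
    anchor_offset_s: float = 0.1,
) -> PupilRecording:
    """Replace the diameter inside each blink interval by a cubic spline.

    The spline is fitted through 4 anchor samples, two per side, taken
    ``anchor_offset_s`` and ``2 * anchor_offset_s`` outside the (padded)
    interval.  Samples outside the intervals are never altered.  Intervals
    at the recording edge fall back to a nearest-value hold (logged).
    """
    rec = recording.copy()
    t, d = rec.time, rec.diameter
    for iv in intervals:
        inside = (t >= iv.start) & (t <= iv.end)
        if not inside.any():
            continue
        anchor_times = [iv.start - 2 * anchor_offset_s, iv.start - anchor_offset_s,
                        iv.end + anchor_offset_s, iv.end + 2 * anchor_offset_s]
        if anchor_times[0] < t[0] or anchor_times[-1] > t[-1]:
            # not enough context on one side: hold the nearest valid value
            edge_idx = np.flatnonzero(~inside)
            if edge_idx.size == 0:
                log.warning("blink interval covers the whole recording; left as-is")
                continue
            first_in = int(np.flatnonzero(inside)[0])
            src = edge_idx[edge_idx < first_in]
            hold = d[src[-1]] if src.size else d[edge_idx[0]]
            d[inside] = hold
            log.info("blink at recording edge [%.3f, %.3f]: nearest-value hold",
                     iv.start, iv.end)
            continue
        idx = np.searchsorted(t, anchor_times)
        idx = np.clip(idx, 0, t.size - 1)
        idx = np.unique(idx)
        spline = CubicSpline(t[idx], d[idx])
        d[inside] = spline(t[inside])
    return rec


# ---------------------------------------------------------------------------
# despiking

def _hampel_once(x: np.ndarray, half_window: int, n_sigmas: float) -> np.ndarray:
    n = x.size
    out = x.copy()
    w = 2 * half_window + 1
    if n >= w:
        win = sliding_window_view(x, w)
        med = np.median(win, axis=1)
        mad = np.median(np.abs(win - med[:, None]), axis=1)
        dev = np.abs(x[half_window:n - half_window] - med)
        bad = dev > n_sigmas * MAD_SCALE * mad  # MAD = 0 => any deviation flagged
        core = out[half_window:n - half_window]
        core[bad] = med[bad]
    # edges: shrunken (asymmetric) windows
    for i in list(range(min(half_window, n))) + list(range(max(n - half_window, 0), n)):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        med = np.median(x[lo:hi])
        mad = np.median(np.abs(x[lo:hi] - med))
        if np.abs(x[i] - med) > n_sigmas * MAD_SCALE * mad:
            out[i] = med
    return out


def hampel_filter(series, half_window: int = 2, n_sigmas: float = 3.0) -> np.ndarray:
    """Five-point (for the default half_window=2) median Hampel despiker.

    A sample deviating from its window median by more than
    ``n_sigmas * 1.4826 * MAD`` is replaced by that median; when the window
    MAD is zero any deviation at all is replaced (limit behaviour of the
    scaled-MAD rule).  Window statistics come from the unmodified input
    (non-recursive), so the result is deterministic and order-independent.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * half_window + 1:
        raise ValueError("series shorter than the filter window")
    return _hampel_once(x, half_window, n_sigmas)


class HampelFilter(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer around :func:`hampel_filter`.

    ``transform`` accepts a 1-D series or a 2-D array filtered row-wise.
    """

    def __init__(self, half_window: int = 2, n_sigmas: float = 3.0):
        self.half_window = half_window
        self.n_sigmas = n_sigmas

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return hampel_filter(X, self.half_window, self.n_sigmas)
        return np.vstack([hampel_filter(row, self.half_window, self.n_sigmas) for row in X])


# ---------------------------------------------------------------------------
# trial exclusion and epoching

def exclude_trials(
    recording: PupilRecording,
    events: EventLog,
    blink_intervals: list[BlinkInterval],
    gaze_limit_deg: float = 2.8,
    blink_window_s: float = 0.3,
    stimulus_events: tuple[str, ...] = DEFAULT_STIMULUS_EVENTS,
    response_event: str = "response",
) -> pd.DataFrame:
    """Per-trial keep/exclude decisions with reasons.

    A trial is excluded iff (a) gaze eccentricity sqrt(x^2 + y^2) exceeds
    ``gaze_limit_deg`` at any sample between the first stimulus onset and
    the response, (b) a blink interval intersects the symmetric
    ``blink_window_s`` window around any stimulus onset, or (c) it has no
    response event.  Returns a DataFrame with columns
    ``trial_id, keep, reason``.
    """
    ecc = np.hypot(recording.gaze_x, recording.gaze_y)
    t = recording.time
    half = blink_window_s / 2.0
    rows = []
    for tid in events.trial_ids:
        trial = events.trial(tid)
        stim = trial[trial["event"].isin(stimulus_events)]
        resp = trial[trial["event"] == response_event]
        reasons: list[str] = []
        if len(resp) == 0:
            reasons.append("no_response")
        elif len(stim) > 0:
            t0 = float(stim["onset_s"].min())
            t1 = float(resp["onset_s"].max())
            sel = (t >= t0) & (t <= t1)
            if sel.any() and np.any(ecc[sel] > gaze_limit_deg):
                reasons.append("gaze")
        for onset in stim["onset_s"]:
            if any(iv.intersects(onset - half, onset + half) for iv in blink_intervals):
                reasons.append("blink")
                break
        rows.append({"trial_id": tid, "keep": not reasons, "reason": ",".join(reasons)})
    return pd.DataFrame(rows)


def epoch_and_baseline(
    recording: PupilRecording,
    events: EventLog,
    lock_event: str,
    epoch_len_s: float,
    baseline_s: float = 0.1,
    keep_mask: pd.DataFrame | None = None,
    correct_only: bool = True,
) -> EpochSet:
    """Segment the recording into baselined epochs locked to an event.

    One epoch per kept (and, by default, correct) trial, locked to the
    nearest grid sample of the ``lock_event`` onset; the mean over
    ``[onset - baseline_s, onset)`` is subtracted.  Epochs that would run
    past the recording end (or before its start) are dropped with a log
    entry.  Zero surviving trials yields an explicit empty set.
    """
    dt = recording.dt
    n_len = int(round(epoch_len_s / dt))
    n_base = max(int(round(baseline_s / dt)), 1)
    rel_times = np.arange(n_len) * dt
    kept = set(events.trial_ids)
    if keep_mask is not None:
        kept &= set(keep_mask.loc[keep_mask["keep"], "trial_id"])
    data_rows, meta_rows = [], []
    n_dropped = 0
    for tid in events.trial_ids:
        if tid not in kept:
            continue
        trial = events.trial(tid)
        if correct_only:
            correct = trial["correct"].dropna()
            if len(correct) and not correct.astype(bool).all():
                continue
        locks = trial[trial["event"] == lock_event]
        if len(locks) == 0:
            continue
        onset = float(locks["onset_s"].iloc[0])
        i0 = int(np.argmin(np.abs(recording.time - onset)))  # nearest sample
        if i0 - n_base < 0 or i0 + n_len > recording.time.size:
            n_dropped += 1
            continue
        base = float(np.mean(recording.diameter[i0 - n_base:i0]))
        data_rows.append(recording.diameter[i0:i0 + n_len] - base)
        meta = {"trial_id": tid, "lock_onset_s": onset}
        meta.update(events.conditions_for_trial(tid))
        meta_rows.append(meta)
    if n_dropped:
        log.info("dropped %d truncated epoch(s)", n_dropped)
    if not data_rows:
        return EpochSet(times=rel_times, data=np.empty((0, n_len)),
                        meta=pd.DataFrame(columns=["trial_id", "lock_onset_s"]),
                        baseline_s=baseline_s, lock_event=lock_event)
    return EpochSet(times=rel_times, data=np.vstack(data_rows),
                    meta=pd.DataFrame(meta_rows), baseline_s=baseline_s,
                    lock_event=lock_event)


def preprocess_recording(
    recording: PupilRecording,
    conf_threshold: float = 0.6,
    hampel_half_window: int = 2,
    hampel_n_sigmas: float = 3.0,
) -> tuple[PupilRecording, list[BlinkInterval]]:
    """Standard repair chain: blink detection, spline repair, Hampel filter."""
    blinks = detect_blinks(recording, conf_threshold=conf_threshold)
    rec = interpolate_blinks(recording, blinks)
    rec.diameter = hampel_filter(rec.diameter, hampel_half_window, hampel_n_sigmas)
    return rec, blinks


# ---------------------------------------------------------------------------
# epoch archive (delimited text: data matrix + sidecar metadata)

def write_epochs(epochs: EpochSet, data_path, meta_path) -> None:
    pd.DataFrame(epochs.data, columns=[f"{t:.9f}" for t in epochs.times]).to_csv(
        data_path, index=False, float_format="%.17g")
    meta = epochs.meta.copy()
    meta.attrs = {}
    header = meta.assign(_baseline_s=epochs.baseline_s, _lock_event=epochs.lock_event)
    header.to_csv(meta_path, index=False, float_format="%.17g")


def read_epochs(data_path, meta_path) -> EpochSet:
    data = pd.read_csv(data_path)
    times = np.array([float(c) for c in data.columns])
    meta = pd.read_csv(meta_path)
    baseline_s = float(meta["_baseline_s"].iloc[0]) if "_baseline_s" in meta and len(meta) else 0.1
    lock_event = str(meta["_lock_event"].iloc[0]) if "_lock_event" in meta and len(meta) else ""
    meta = meta.drop(columns=[c for c in ("_baseline_s", "_lock_event") if c in meta])
    return EpochSet(times=times, data=data.to_numpy(dtype=float), meta=meta,
                    baseline_s=baseline_s, lock_event=lock_event)
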