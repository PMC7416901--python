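"""Synthetic pupil recordings, event logs and behaviour with known truth.

The forward model is the package's own response model: a 60-Hz diameter
stream equals a tonic (luminance-dependent) baseline plus the superposition
of attentional pulses convolved with the impulse response, plus Gaussian
measurement noise, with blink artifacts carved out (diameter collapses,
confidence drops to zero).  Trials follow a dual-task timeline (fixation ->
memory array -> search array -> memory probe -> response) with a factorial
condition design; condition and participant effects act on pulse scales so
every downstream stage (preprocessing, deconvolution, mixed-model scans,
classification) can be validated against ground truth.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EventLog, PupilRecording, write_events, write_recording, write_pulses
from .preprocess import EpochSet
from .tepr import AttentionalPulse, ImpulseResponseParams, PulseList, reconstruct_trace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_cohort",
    "simulate_behavior",
    "simulate_epoch_cohort",
    "make_pulse_recording",
]


def _default_factors() -> dict:
    return {"vwm_load": ("low", "high"), "vs_difficulty": ("low", "high")}


def _default_timeline() -> tuple:
    return (("fixation", 0.0), ("memory_array", 1.1),
            ("search_array", 3.3), ("memory_probe", 5.5))


def _default_scale_effects() -> dict:
    return {
        "vwm_load": {"high": {"memory_array": 0.15, "memory_probe": 0.15}},
        "vs_difficulty": {"high": {"search_array": 0.10}},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Pulse scales (mm of peak dilation) are
    ``base_scale_mm + condition effects + participant intercept +
    participant slope + trial noise``, floored at 0.  Defaults emulate a
    60-Hz dual-task session at desk scale: 2x2 load design, ~8-s trials,
    0.25-mm baseline pulses with a 0.15-mm memory-load effect and a
    0.10-mm search-difficulty effect, 0.01-mm sample noise and 4
    blinks/min.
    """

    rate_hz: float = 60.0
    n_participants: int = 8
    trials_per_condition: int = 10
    factors: dict = field(default_factory=_default_factors)
    timeline: tuple = field(default_factory=_default_timeline)
    trial_len_s: float = 8.0
    lead_in_s: float = 2.0
    pulse_events: tuple = ("memory_array", "search_array", "memory_probe")
    base_scale_mm: float = 0.25
    scale_effects: dict = field(default_factory=_default_scale_effects)
    onset_jitter_sd_s: float = 0.02
    scale_sd_mm: float = 0.05
    participant_intercept_sd_mm: float = 0.05
    participant_slope_sd_mm: float = 0.05
    tonic_baseline_mm: dict = field(
        default_factory=lambda: {"dark": 4.6, "bright": 3.4})
    luminance: str = "dark"
    noise_sd_mm: float = 0.01
    blink_rate_per_min: float = 4.0
    blink_duration_range_s: tuple = (0.15, 0.35)
    plr_scale_mm: float = 0.0  # optional light-reflex constriction, off by default
    plr_t_max_s: float = 0.35
    accuracy: float = 0.9
    rt_median_s: float = 0.7
    rt_sigma: float = 0.25
    irf: ImpulseResponseParams = field(default_factory=ImpulseResponseParams)

    def __post_init__(self) -> None:
        for name in ("onset_jitter_sd_s", "scale_sd_mm", "noise_sd_mm",
                     "blink_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        onsets = [t for _, t in self.timeline]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("timeline events must be ordered")
        if onsets[-1] >= self.trial_len_s:
            raise ValueError("timeline longer than the trial")


@dataclass
class GroundTruth:
    """Latent state behind one simulated recording."""

    pulses: PulseList
    trial_truth: pd.DataFrame  # trial_id, event, pulse_t_s, pulse_scale_mm, conditions
    baseline_mm: float
    blink_spans: list  # (start_s, end_s)
    participant: int = 0


def _condition_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = list(config.factors)
    grids = np.meshgrid(*[np.arange(len(config.factors[f])) for f in names],
                        indexing="ij")
    cells = np.column_stack([g.ravel() for g in grids])
    cells = np.repeat(cells, config.trials_per_condition, axis=0)
    order = rng.permutation(len(cells))
    cells = cells[order]
    rows = [{f: config.factors[f][c[k]] for k, f in enumerate(names)}
            for c in cells]
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return df


def _participant_effects(config: SimulationConfig, rng: np.random.Generator) -> dict:
    eff = {"intercept": rng.normal(0.0, config.participant_intercept_sd_mm)}
    for f in config.factors:
        eff[f] = rng.normal(0.0, config.participant_slope_sd_mm)
    return eff


def simulate_recording(
    config: SimulationConfig | None = None,
    seed: int = 0,
    participant: int = 0,
    participant_effects: dict | None = None,
) -> tuple[PupilRecording, EventLog, GroundTruth]:
    """One participant's continuous recording, event log and ground truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, participant]))
    if participant_effects is None:
        participant_effects = _participant_effects(config, rng)
    trials = _condition_table(config, rng)
    n_trials = len(trials)
    duration = config.lead_in_s * 2 + n_trials * config.trial_len_s
    dt = 1.0 / config.rate_hz
    grid = dt * np.arange(int(round(duration / dt)) + 1)
    baseline = config.tonic_baseline_mm[config.luminance]

    pulses: list[AttentionalPulse] = []
    truth_rows = []
    event_rows = []
    plr_pulses: list[AttentionalPulse] = []
    factor_names = list(config.factors)
    for _, tr in trials.iterrows():
        t_start = config.lead_in_s + tr["trial_id"] * config.trial_len_s
        cond_str = ";".join(f"{f}={tr[f]}" for f in factor_names)
        stim_onsets = []
        for name, rel in config.timeline:
            onset = t_start + rel
            event_rows.append({"trial_id": tr["trial_id"], "event": name,
                               "onset_s": onset, "conditions": cond_str,
                               "correct": "", "rt_s": ""})
            if name in config.pulse_events:
                stim_onsets.append(onset)
                scale = (config.base_scale_mm
                         + participant_effects["intercept"]
                         + rng.normal(0.0, config.scale_sd_mm))
                for f in factor_names:
                    eff = config.scale_effects.get(f, {}).get(tr[f], {})
                    scale += eff.get(name, 0.0)
                    if eff:
                        scale += participant_effects[f]
                scale = max(scale, 0.0)
                p_t = onset + rng.normal(0.0, config.onset_jitter_sd_s)
                pulses.append(AttentionalPulse(p_t, scale))
                truth_rows.append({"trial_id": tr["trial_id"], "event": name,
                                   "pulse_t_s": p_t, "pulse_scale_mm": scale,
                                   **{f: tr[f] for f in factor_names}})
                if config.plr_scale_mm > 0:
                    plr_pulses.append(AttentionalPulse(onset, config.plr_scale_mm))
        rt = float(np.exp(rng.normal(np.log(config.rt_median_s), config.rt_sigma)))
        correct = bool(rng.random() < config.accuracy)
        event_rows.append({"trial_id": tr["trial_id"], "event": "response",
                           "onset_s": stim_onsets[-1] + rt if stim_onsets
                           else t_start + rt,
                           "conditions": cond_str, "correct": correct, "rt_s": rt})

    pulse_list = PulseList(pulses)
    trace = reconstruct_trace(pulse_list, grid, config.irf, baseline).diameter
    if plr_pulses:
        plr_irf = replace(config.irf, t_max=config.plr_t_max_s)
        trace = trace - (reconstruct_trace(PulseList(plr_pulses), grid, plr_irf,
                                           0.0).diameter)
    if config.noise_sd_mm > 0:
        trace = trace + rng.normal(0.0, config.noise_sd_mm, grid.size)

    confidence = np.ones(grid.size)
    blink_spans: list[tuple[float, float]] = []
    n_blinks = rng.poisson(config.blink_rate_per_min * duration / 60.0)
    lo, hi = config.blink_duration_range_s
    for _ in range(n_blinks):
        b_len = rng.uniform(lo, hi)
        b0 = rng.uniform(0.0, duration - b_len)
        sel = (grid >= b0) & (grid <= b0 + b_len)
        if not sel.any():
            continue
        idx = np.flatnonzero(sel)
        # linear collapse to 60% of the local diameter and back
        half = len(idx) // 2 + 1
        depth = np.ones(len(idx))
        depth[:half] = np.linspace(1.0, 0.6, half)
        depth[half - 1:] = np.linspace(0.6, 1.0, len(idx) - half + 1)
        trace[idx] *= depth
        confidence[idx] = 0.0
        blink_spans.append((b0, b0 + b_len))

    recording = PupilRecording(
        time=grid, diameter=trace, gaze_x=np.zeros(grid.size),
        gaze_y=np.zeros(grid.size), confidence=confidence,
        rate_hz=config.rate_hz,
    )
    ev = pd.DataFrame(event_rows)
    table = pd.DataFrame({
        "trial_id": ev["trial_id"].astype(int),
        "event": ev["event"],
        "onset_s": ev["onset_s"].astype(float),
        "correct": pd.array([c if c != "" else pd.NA for c in ev["correct"]],
                            dtype="boolean"),
        "rt_s": pd.to_numeric(ev["rt_s"], errors="coerce"),
    })
    for f in factor_names:
        table[f] = [dict(kv.split("=") for kv in s.split(";"))[f]
                    for s in ev["conditions"]]
    events = EventLog(table, condition_cols=factor_names)
    truth = GroundTruth(
        pulses=pulse_list,
        trial_truth=pd.DataFrame(truth_rows),
        baseline_mm=baseline,
        blink_spans=blink_spans,
        participant=participant,
    )
    return recording, events, truth


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> list[tuple[int, PupilRecording, EventLog, GroundTruth]]:
    """One recording + events + truth per participant.

    Participant-level random effects (intercept and per-factor slope on
    pulse scales) are drawn once per participant.  When ``out_dir`` is
    given, per-participant ``recording.csv``, ``events.csv`` and
    ``pulses_true.csv`` plus a ``manifest.csv`` are written.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10 ** 6]))
    cohort = []
    manifest = []
    for p in range(config.n_participants):
        effects = _participant_effects(config, rng)
        rec, ev, truth = simulate_recording(config, seed=seed, participant=p,
                                            participant_effects=effects)
        cohort.append((p, rec, ev, truth))
        manifest.append({"participant": p, "n_trials": len(ev.trial_ids),
                         "duration_s": rec.duration})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p, rec, ev, truth in cohort:
            d = out / f"participant_{p:02d}"
            d.mkdir(exist_ok=True)
            write_recording(rec, d / "recording.csv")
            write_events(ev, d / "events.csv")
            write_pulses(truth.pulses, d / "pulses_true.csv")
        pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    return cohort


def simulate_behavior(
    n_trials: int = 200,
    n_items: dict | None = None,
    hit_rate: dict | None = None,
    fa_rate: dict | None = None,
    rt_median_s: dict | None = None,
    rt_sigma: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Behavioural table for a change-detection memory task.

    Per trial and load level: a change is present with probability 0.5;
    the observer reports "change" with probability ``hit_rate`` when
    present and ``fa_rate`` when absent (so empirical Cowan's K tends to
    N * (hit - fa)); RTs are lognormal with a per-level median.
    """
    n_items = n_items or {"low": 1, "high": 4}
    hit_rate = hit_rate or {"low": 0.95, "high": 0.8}
    fa_rate = fa_rate or {"low": 0.05, "high": 0.25}
    rt_median_s = rt_median_s or {"low": 0.6, "high": 0.85}
    rng = np.random.default_rng(seed)
    rows = []
    for level in n_items:
        present = rng.random(n_trials) < 0.5
        p_resp = np.where(present, hit_rate[level], fa_rate[level])
        said_change = rng.random(n_trials) < p_resp
        rt = np.exp(rng.normal(np.log(rt_median_s[level]), rt_sigma, n_trials))
        for i in range(n_trials):
            rows.append({
                "trial_id": i, "vwm_load": level, "n_items": n_items[level],
                "change_present": bool(present[i]),
                "said_change": bool(said_change[i]),
                "correct": bool(said_change[i] == present[i]),
                "rt_s": float(rt[i]),
            })
    return pd.DataFrame(rows)


def simulate_epoch_cohort(
    n_participants: int = 20,
    trials_per_level: int = 30,
    epoch_len_s: float = 2.5,
    rate_hz: float = 60.0,
    effect_mm: float = 0.0,
    effect_window: tuple[float, float] = (1.0, 2.0),
    noise_sd_mm: float = 0.05,
    participant_intercept_sd_mm: float = 0.05,
    participant_slope_sd_mm: float = 0.0,
    factor: str = "load",
    seed: int = 0,
) -> EpochSet:
    """Epoch-level cohort generator for the mixed-model scan.

    Baselined epochs are zero-mean noise plus a participant intercept
    (shared by both levels), plus, for the high level only, a fixed offset
    ``effect_mm`` inside ``effect_window`` with a per-participant slope
    deviation.  Under the null (``effect_mm = 0``,
    ``participant_slope_sd_mm = 0``) the two levels are draws from the
    same distribution.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    times = dt * np.arange(int(round(epoch_len_s / dt)))
    win = (times >= effect_window[0]) & (times < effect_window[1])
    data, meta = [], []
    for p in range(n_participants):
        intercept = rng.normal(0.0, participant_intercept_sd_mm)
        slope = effect_mm + rng.normal(0.0, participant_slope_sd_mm)
        for level, has_effect in (("low", False), ("high", True)):
            for k in range(trials_per_level):
                tr = intercept + rng.normal(0.0, noise_sd_mm, times.size)
                if has_effect:
                    tr[win] += slope
                data.append(tr)
                meta.append({"participant": p, factor: level,
                             "trial_id": p * 10000 + k})
    return EpochSet(times=times, data=np.vstack(data), meta=pd.DataFrame(meta))


def make_pulse_recording(
    onsets,
    scales,
    duration_s: float,
    baseline_mm: float = 4.0,
    noise_sd_mm: float = 0.01,
    rate_hz: float = 60.0,
    seed: int = 0,
    irf: ImpulseResponseParams | None = None,
) -> PupilRecording:
    """Minimal pulse-train recording (no trials, no blinks): baseline +
    pulses + Gaussian noise.  The workhorse of parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    grid = dt * np.arange(int(round(duration_s / dt)) + 1)
    pulses = PulseList.from_arrays(np.asarray(onsets, float), np.asarray(scales, float))
    d = reconstruct_trace(pulses, grid, irf, baseline_mm).diameter
    if noise_sd_mm > 0:
        d = d + rng.normal(0.0, noise_sd_mm, grid.size)
    return PupilRecording(time=grid, diameter=d, gaze_x=np.zeros(grid.size),
                          gaze_y=np.zeros(grid.size),
                          confidence=np.ones(grid.size), rate_hz=rate_hz)
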