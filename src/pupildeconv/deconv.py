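"""Frame-wise online deconvolution of a pupil stream into attentional pulses.

The algorithm runs a curve-matching feedback loop over the incoming samples:
at each frame it compares the observed diameter Z[t] with the current
modelled trace M[t] (a static baseline plus the superposition of already
inserted pulses).  When the residual Z - M exceeds a detection threshold
(a fraction of a reference diameter, default 0.25%) persistently, a new
attentional pulse is inserted, back-projected ``back_offset_s`` (default
500 ms) before the detection time stamp, and the scales of recent pulses
are re-fitted to the observed prefix by nonnegative least squares.  The
loop is strictly causal: no step ever reads samples past the current frame.

Two robustness refinements beyond the bare threshold rule are built in and
individually switchable:

* persistence — the residual must stay super-threshold for
  ``persistence_frames`` consecutive frames before an insertion (single
  noisy frames at a ~1-sigma threshold would otherwise fire constantly);
* onset refinement — the threshold-crossing time depends on pulse
  amplitude, so a fixed back-projection places weak pulses too early; the
  inserted onset is refined by a causal grid search (scale refit per
  candidate) while the pulse is young.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .io import PupilRecording, EventLog
from .preprocess import DEFAULT_STIMULUS_EVENTS
from .tepr import (
    ImpulseResponseParams,
    ModeledTrace,
    PulseList,
    impulse_response,
)

__all__ = [
    "DeconvConfig",
    "DeconvState",
    "DeconvResult",
    "OnlinePupilDeconvolver",
    "choose_baseline",
    "run",
    "strongest_pulse_offsets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeconvConfig:
    """Tunables of the online loop.

    residual_threshold_frac : detection threshold as a fraction of the
        reference diameter (the recording's median raw diameter).
    back_offset_s : back-projection of a fresh pulse before detection time.
    refractory_s : minimum spacing between insertions and between onsets.
    opt_window_s : trailing window of the least-squares scale fit; pulses
        with onsets older than this are frozen.
    baseline_mode : "percentile" (percentile of the diameter, clamped to
        <= min) or "fixed" (use ``baseline_value``).
    persistence_frames : consecutive super-threshold frames required to
        trigger an insertion (1 restores the literal single-frame rule).
    refine_onset : enable the causal onset grid search.
    refine_window_s : half-width of the initial onset search around
        ``t - back_offset_s``.
    refine_age_s : keep re-refining the newest pulse's onset until it is
        this old.
    settle_age_s : keep re-fitting scales (every ``reopt_stride`` frames)
        until the newest pulse is this old.
    min_scale_mm : pulses fitted below this scale are dropped from the
        final list (noise floor of the NNLS fit).
    warmup_s : initial stretch used to calibrate the static tonic offset
        between the chosen baseline and the quiet diameter level (the
        baseline is deliberately below every observation, so the raw gap
        would otherwise read as a permanent super-threshold residual).
        The median residual over the warm-up is folded into the baseline
        once, after which the level is static; no detection happens during
        the warm-up.
    """

    residual_threshold_frac: float = 0.0025
    back_offset_s: float = 0.5
    refractory_s: float = 0.1
    opt_window_s: float = 4.0
    baseline_mode: str = "percentile"
    baseline_value: float | None = None
    baseline_percentile: float = 1.0
    persistence_frames: int = 8
    refine_onset: bool = True
    refine_window_s: float = 0.3
    refine_age_s: float = 1.5
    settle_age_s: float = 2.0
    reopt_stride: int = 3
    min_scale_mm: float = 0.02
    warmup_s: float = 0.5
    ridge_penalty: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 < self.residual_threshold_frac < 1):
            raise ValueError("residual_threshold_frac must be in (0, 1)")
        for name in ("back_offset_s", "refractory_s", "opt_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_mode not in ("percentile", "fixed"):
            raise ValueError("baseline_mode must be 'percentile' or 'fixed'")
        if self.baseline_mode == "fixed" and self.baseline_value is None:
            raise ValueError("fixed baseline_mode requires baseline_value")


def choose_baseline(recording: PupilRecording, config: DeconvConfig) -> float:
    """Static baseline, guaranteed not to exceed the observed diameters.

    Percentile mode takes the configured percentile of the diameter and
    clamps it down to min(diameter) if needed; fixed mode takes the given
    value as-is (it may legitimately sit below the observed minimum).
    """
    if config.baseline_mode == "fixed":
        return float(config.baseline_value)
    b = float(np.percentile(recording.diameter, config.baseline_percentile))
    lo = float(np.min(recording.diameter))
    if b > lo:
        log.info("baseline percentile %.3f clamped to min diameter %.3f", b, lo)
        b = lo
    return b


@dataclass
class DeconvResult:
    """Outcome of one online run; reproducible bit-for-bit from its inputs."""

    pulses: PulseList
    modeled: ModeledTrace
    residuals: np.ndarray
    baseline: float
    reference_mm: float
    threshold_mm: float
    config: DeconvConfig
    insertions: pd.DataFrame
    irf_params: ImpulseResponseParams


class DeconvState:
    """Causal per-frame state of the deconvolution loop.

    Samples are pushed in grid order via :meth:`push`; the state only ever
    reads observations up to the current frame.  The modelled array extends
    past the current frame only with contributions of already-decided
    pulses (no lookahead).
    """

    def __init__(
        self,
        t0: float,
        dt: float,
        baseline: float,
        reference_mm: float,
        config: DeconvConfig | None = None,
        irf_params: ImpulseResponseParams | None = None,
        n_hint: int = 1024,
    ) -> None:
        self.config = config or DeconvConfig()
        self.irf = irf_params or ImpulseResponseParams()
        self.t0 = float(t0)
        self.dt = float(dt)
        self.baseline = float(baseline)
        self.reference_mm = float(reference_mm)
        self.threshold_mm = self.config.residual_threshold_frac * self.reference_mm
        self.support_n = int(round(self.irf.support_s / self.dt))
        self.h_grid = impulse_response(np.arange(self.support_n) * self.dt, self.irf)
        self.i = 0  # next frame index
        cap = max(n_hint, 64) + self.support_n
        self.observed = np.zeros(cap)
        self.modeled = np.full(cap, self.baseline)
        self.residuals = np.zeros(cap)
        self.onset_idx: list[int] = []
        self.scales: list[float] = []
        self._run_len = 0
        self._last_insert_i = -(10 ** 9)
        self.insertions: list[dict] = []
        # precomputed frame counts
        self._refractory_n = max(int(round(self.config.refractory_s / self.dt)), 1)
        self._back_n = int(round(self.config.back_offset_s / self.dt))
        self._opt_n = int(round(self.config.opt_window_s / self.dt))
        self._refine_n = int(round(self.config.refine_window_s / self.dt))
        self._warmup_n = int(round(self.config.warmup_s / self.dt))

    # -- buffers -----------------------------------------------------------
    def _ensure_capacity(self, n: int) -> None:
        if n <= self.observed.size:
            return
        old = self.observed.size
        new = max(n, 2 * old)
        for name, fill in (("observed", 0.0), ("modeled", self.baseline), ("residuals", 0.0)):
            arr = getattr(self, name)
            grown = np.full(new, fill)
            grown[:old] = arr
            setattr(self, name, grown)
        # replay pulse-support tails that were clipped at the old capacity
        for j, s in zip(self.onset_idx, self.scales):
            hi = min(j + self.support_n, new)
            if hi > old and s != 0.0:
                self.modeled[old:hi] += s * self.h_grid[old - j: hi - j]

    # -- kernel bookkeeping ------------------------------------------------
    def _add_contribution(self, j: int, delta_scale: float) -> None:
        if delta_scale == 0.0:
            return
        hi = min(j + self.support_n, self.modeled.size)
        self.modeled[j:hi] += delta_scale * self.h_grid[: hi - j]

    def _design_column(self, j: int, w0: int, w1: int) -> np.ndarray:
        """Kernel column for a pulse at grid index j over frames [w0, w1)."""
        col = np.zeros(w1 - w0)
        a = max(j, w0)
        b = min(j + self.support_n, w1)
        if b > a:
            col[a - w0: b - w0] = self.h_grid[a - j: b - j]
        return col

    # -- optimisation ------------------------------------------------------
    def _free_pulse_indices(self) -> list[int]:
        cutoff = self.i - self._opt_n
        return [k for k, j in enumerate(self.onset_idx) if j >= cutoff]

    def _window(self) -> tuple[int, int]:
        return max(0, self.i + 1 - self._opt_n), self.i + 1

    def optimize_scales(self) -> None:
        """NNLS re-fit of free pulse scales on the trailing window.

        Earlier pulses are frozen; their contribution (and the baseline) is
        subtracted from the observed prefix before the fit.  The windowed
        error is never increased by this call.
        """
        free = self._free_pulse_indices()
        if not free:
            return
        w0, w1 = self._window()
        A = np.column_stack([self._design_column(self.onset_idx[k], w0, w1) for k in free])
        free_contrib = A @ np.array([self.scales[k] for k in free])
        target = self.observed[w0:w1] - (self.modeled[w0:w1] - free_contrib)
        try:
            sol, _ = nnls(A, target)
        except RuntimeError:
            lam = np.sqrt(self.config.ridge_penalty)
            A_r = np.vstack([A, lam * np.eye(A.shape[1])])
            b_r = np.concatenate([target, np.zeros(A.shape[1])])
            sol, _ = nnls(A_r, b_r)
            log.info("singular design at frame %d: ridge fallback", self.i)
        for k, s in zip(free, sol):
            self._add_contribution(self.onset_idx[k], float(s) - self.scales[k])
            self.scales[k] = float(s)

    def _refit_newest_onset(self, half_n: int) -> None:
        """Causal grid search over the newest pulse's onset (scale refit per
        candidate with the other pulses held fixed)."""
        k = len(self.onset_idx) - 1
        j_cur = self.onset_idx[k]
        lo = j_cur - half_n
        hi = j_cur + half_n
        if k > 0:
            lo = max(lo, self.onset_idx[k - 1] + self._refractory_n)
        lo = max(lo, 0)
        hi = min(hi, self.i)
        if hi < lo:
            return
        w0, w1 = self._window()
        others = self.modeled[w0:w1] - self._design_column(j_cur, w0, w1) * self.scales[k]
        resid = self.observed[w0:w1] - others
        best = (np.inf, j_cur, self.scales[k])
        for j in range(lo, hi + 1):
            g = self._design_column(j, w0, w1)
            gg = g @ g
            s = max(0.0, (g @ resid) / gg) if gg > 0 else 0.0
            d = resid - s * g
            eps = d @ d
            if eps < best[0] - 1e-15:
                best = (eps, j, s)
        _, j_new, s_new = best
        if j_new != j_cur or s_new != self.scales[k]:
            self._add_contribution(j_cur, -self.scales[k])
            self.onset_idx[k] = j_new
            self.scales[k] = s_new
            self._add_contribution(j_new, s_new)

    # -- the per-frame step ------------------------------------------------
    def step(self, z: float) -> None:
        """Advance one frame with observation ``z`` (diameter, mm)."""
        i = self.i
        self._ensure_capacity(i + 1 + self.support_n)
        if i == self._warmup_n and i > 0:
            # fold the calibrated tonic gap into the static baseline, once
            tonic = float(np.median(self.residuals[:i]))
            if tonic != 0.0:
                self.baseline += tonic
                self.modeled += tonic
        self.observed[i] = z
        r = z - self.modeled[i]
        self.residuals[i] = r
        if i < self._warmup_n:
            self.i = i + 1
            return
        self._run_len = self._run_len + 1 if r > self.threshold_mm else 0
        inserted = False
        if (self._run_len >= self.config.persistence_frames
                and i - self._last_insert_i >= self._refractory_n):
            self._insert(i, r)
            self._last_insert_i = i
            self._run_len = 0
            inserted = True
        if not inserted and self.onset_idx and i % self.config.reopt_stride == 0:
            age = (i - self.onset_idx[-1]) * self.dt
            if age <= self.config.settle_age_s:
                if self.config.refine_onset and age <= self.config.refine_age_s:
                    self._refit_newest_onset(max(int(round(0.15 / self.dt)), 2))
                self.optimize_scales()
        self.i = i + 1

    def push(self, t: float, z: float) -> None:
        """Streaming entry point; ``t`` must be the next grid time."""
        expected = self.t0 + self.i * self.dt
        if abs(t - expected) > 1e-6:
            raise ValueError(
                f"out-of-order sample: got t={t:.6f}, expected {expected:.6f}")
        self.step(z)

    def _insert(self, i: int, trigger_residual: float) -> None:
        j_center = max(i - self._back_n, 0)
        w0, w1 = self._window()
        if self.config.refine_onset:
            lo, hi = max(j_center - self._refine_n, 0), min(j_center + self._refine_n, i)
        else:
            lo = hi = min(j_center, i)
        if self.onset_idx:
            lo = max(lo, self.onset_idx[-1] + self._refractory_n)
        if lo > hi:
            # nowhere to put a distinct pulse; just re-fit what is there
            self.optimize_scales()
            return
        resid = self.observed[w0:w1] - self.modeled[w0:w1]
        best = (np.inf, lo, 0.0)
        for j in range(lo, hi + 1):
            g = self._design_column(j, w0, w1)
            gg = g @ g
            s = max(0.0, (g @ resid) / gg) if gg > 0 else 0.0
            d = resid - s * g
            eps = d @ d
            if eps < best[0] - 1e-15:
                best = (eps, j, s)
        _, j_star, s0 = best
        self.onset_idx.append(j_star)
        self.scales.append(s0)
        self._add_contribution(j_star, s0)
        self.insertions.append({
            "frame": i,
            "t_detect_s": self.t0 + i * self.dt,
            "trigger_residual_mm": trigger_residual,
            "proposed_onset_s": self.t0 + j_center * self.dt,
            "onset_s": self.t0 + j_star * self.dt,
        })
        self.optimize_scales()

    # -- results -----------------------------------------------------------
    def finalize(self) -> DeconvResult:
        """Final scale fit, pruning of sub-floor pulses, result assembly."""
        self.optimize_scales()
        keep = [k for k, s in enumerate(self.scales) if s >= self.config.min_scale_mm]
        for k in range(len(self.scales)):
            if k not in keep:
                self._add_contribution(self.onset_idx[k], -self.scales[k])
        self.onset_idx = [self.onset_idx[k] for k in keep]
        self.scales = [self.scales[k] for k in keep]
        n = self.i
        time = self.t0 + self.dt * np.arange(n)
        pulses = PulseList.from_arrays(
            self.t0 + self.dt * np.asarray(self.onset_idx, dtype=float),
            np.asarray(self.scales, dtype=float),
        )
        return DeconvResult(
            pulses=pulses,
            modeled=ModeledTrace(time=time, diameter=self.modeled[:n].copy(),
                                 baseline=self.baseline),
            residuals=self.residuals[:n].copy(),
            baseline=self.baseline,
            reference_mm=self.reference_mm,
            threshold_mm=self.threshold_mm,
            config=self.config,
            insertions=pd.DataFrame(
                self.insertions,
                columns=["frame", "t_detect_s", "trigger_residual_mm",
                         "proposed_onset_s", "onset_s"]),
            irf_params=self.irf,
        )


def run(
    recording: PupilRecording,
    config: DeconvConfig | None = None,
    irf_params: ImpulseResponseParams | None = None,
) -> DeconvResult:
    """Fold the online step over every frame of a preprocessed recording."""
    config = config or DeconvConfig()
    baseline = choose_baseline(recording, config)
    reference = float(np.median(recording.diameter))
    state = DeconvState(
        t0=float(recording.time[0]), dt=recording.dt, baseline=baseline,
        reference_mm=reference, config=config, irf_params=irf_params,
        n_hint=recording.time.size,
    )
    for z in recording.diameter:
        state.step(float(z))
    return state.finalize()


def strongest_pulse_offsets(
    result: DeconvResult | PulseList,
    events: EventLog,
    window_s: float = 1.0,
    group_by: list[str] | None = None,
    stimulus_events: tuple[str, ...] = DEFAULT_STIMULUS_EVENTS,
) -> pd.DataFrame:
    """Per-condition mean timing of the strongest pulse around each onset.

    For every stimulus event the maximum-scale pulse within ``+-window_s``
    is located; its offset (pulse time minus onset, negative = pulse
    precedes the stimulus) is averaged per (event, condition-group).
    Events with no pulse in the window are skipped and counted.
    """
    pulses = result.pulses if isinstance(result, DeconvResult) else result
    onsets = pulses.onsets
    scales = pulses.scales
    if group_by is None:
        group_by = events.condition_cols
    rows = []
    tab = events.table
    stim = tab[tab["event"].isin(stimulus_events)]
    for _, ev in stim.iterrows():
        sel = np.abs(onsets - ev["onset_s"]) <= window_s
        row = {"event": ev["event"], **{g: ev[g] for g in group_by}}
        if not sel.any():
            row["offset_s"] = np.nan
        else:
            k = np.flatnonzero(sel)[np.argmax(scales[sel])]
            row["offset_s"] = onsets[k] - float(ev["onset_s"])
        rows.append(row)
    per_event = pd.DataFrame(rows)
    if per_event.empty:
        return pd.DataFrame(columns=["event", *group_by, "mean_offset_s",
                                     "n_events", "n_skipped"])
    grouped = per_event.groupby(["event", *group_by], dropna=False)["offset_s"]
    out = grouped.agg(
        mean_offset_s="mean",
        n_events="size",
        n_skipped=lambda s: int(s.isna().sum()),
    ).reset_index()
    return out


class OnlinePupilDeconvolver(BaseEstimator):
    """Scikit-learn-style estimator wrapping the online deconvolution loop.

    ``fit(recording)`` runs the causal loop over the stream and exposes the
    outcome through fitted attributes; ``transform`` returns the modelled
    trace for a recording.  All constructor arguments mirror
    :class:`DeconvConfig` and the impulse-response parameters, so the
    estimator composes with sklearn's ``get_params``/``set_params``
    machinery (e.g. for grid search over thresholds).

    Attributes (after fit)
    ----------------------
    pulses_ : PulseList
    modeled_ : ModeledTrace
    residuals_ : ndarray
    baseline_ : float
    result_ : DeconvResult
    """

    def __init__(
        self,
        residual_threshold_frac: float = 0.0025,
        back_offset_s: float = 0.5,
        refractory_s: float = 0.1,
        opt_window_s: float = 4.0,
        baseline_mode: str = "percentile",
        baseline_value: float | None = None,
        baseline_percentile: float = 1.0,
        persistence_frames: int = 8,
        refine_onset: bool = True,
        min_scale_mm: float = 0.02,
        irf_n: float = 10.1,
        irf_t_max: float = 0.93,
    ) -> None:
        self.residual_threshold_frac = residual_threshold_frac
        self.back_offset_s = back_offset_s
        self.refractory_s = refractory_s
        self.opt_window_s = opt_window_s
        self.baseline_mode = baseline_mode
        self.baseline_value = baseline_value
        self.baseline_percentile = baseline_percentile
        self.persistence_frames = persistence_frames
        self.refine_onset = refine_onset
        self.min_scale_mm = min_scale_mm
        self.irf_n = irf_n
        self.irf_t_max = irf_t_max

    def _config(self) -> DeconvConfig:
        return DeconvConfig(
            residual_threshold_frac=self.residual_threshold_frac,
            back_offset_s=self.back_offset_s,
            refractory_s=self.refractory_s,
            opt_window_s=self.opt_window_s,
            baseline_mode=self.baseline_mode,
            baseline_value=self.baseline_value,
            baseline_percentile=self.baseline_percentile,
            persistence_frames=self.persistence_frames,
            refine_onset=self.refine_onset,
            min_scale_mm=self.min_scale_mm,
        )

    def fit(self, recording: PupilRecording, y=None) -> "OnlinePupilDeconvolver":
        params = ImpulseResponseParams(n=self.irf_n, t_max=self.irf_t_max)
        result = run(recording, self._config(), params)
        self.result_ = result
        self.pulses_ = result.pulses
        self.modeled_ = result.modeled
        self.residuals_ = result.residuals
        self.baseline_ = result.baseline
        return self

    def transform(self, recording: PupilRecording) -> np.ndarray:
        return run(recording, self._config(),
                   ImpulseResponseParams(n=self.irf_n, t_max=self.irf_t_max)
                   ).modeled.diameter

    def fit_transform(self, recording: PupilRecording, y=None) -> np.ndarray:
        return self.fit(recording).modeled_.diameter
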