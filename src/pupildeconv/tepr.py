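"""Impulse-response model of the task-evoked pupillary response (TEPR).

The transient pupil dilation elicited by a discrete processing event is
modelled as an Erlang/gamma-shaped kernel

    h(t) = t^n * exp(-n * t / t_max),      t >= 0

with shape ``n`` (dimensionless) and peak latency ``t_max`` (seconds).
Analytically ``h`` attains its maximum exactly at ``t = t_max``.  The
defaults ``n = 10.1`` and ``t_max = 0.93 s`` are the empirical values for
human pupil responses to attention-demanding events.

A latent *attentional pulse* ``w_i = (t_i, s_i)`` contributes
``s_i * h(t - t_i)`` to the modelled trace; a trace is the superposition of
all pulses plus a static baseline.  With ``normalize_peak`` (the default)
``h`` is rescaled to unit peak so pulse scales ``s_i`` read directly as
millimetres of peak dilation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ImpulseResponseParams",
    "AttentionalPulse",
    "PulseList",
    "ModeledTrace",
    "impulse_response",
    "reconstruct_trace",
    "model_error",
]


@dataclass(frozen=True)
class ImpulseResponseParams:
    """Parameters of the pupillary impulse response h(t).

    Attributes
    ----------
    n : float
        Shape parameter (dimensionless), > 0.
    t_max : float
        Time-to-peak in seconds, > 0.
    normalize_peak : bool
        If True, rescale h so that max h = 1 (pulse scales are then mm of
        peak dilation).
    support_s : float
        Truncation point in seconds; h is treated as zero beyond this.  At
        the defaults h(5)/h(t_max) ~ 2e-12, so truncation error is
        negligible.
    """

    n: float = 10.1
    t_max: float = 0.93
    normalize_peak: bool = True
    support_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.t_max <= 0 or self.support_s <= 0:
            raise ValueError("n, t_max and support_s must be positive")


@dataclass(frozen=True)
class AttentionalPulse:
    """A latent dilation-driving event with onset t_i (s) and scale s_i (mm)."""

    t: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("pulse scales are nonnegative")


class PulseList:
    """Ordered list of attentional pulses, sorted by onset."""

    def __init__(self, pulses: Sequence[AttentionalPulse] = ()) -> None:
        self.pulses = sorted(pulses, key=lambda p: p.t)

    def __len__(self) -> int:
        return len(self.pulses)

    def __iter__(self):
        return iter(self.pulses)

    def __getitem__(self, i):
        return self.pulses[i]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([p.t for p in self.pulses], dtype=float)

    @property
    def scales(self) -> np.ndarray:
        return np.array([p.scale for p in self.pulses], dtype=float)

    @classmethod
    def from_arrays(cls, onsets, scales) -> "PulseList":
        onsets = np.asarray(onsets, dtype=float)
        scales = np.asarray(scales, dtype=float)
        if onsets.shape != scales.shape:
            raise ValueError("onsets and scales must have equal length")
        return cls([AttentionalPulse(float(t), float(s)) for t, s in zip(onsets, scales)])

    def __repr__(self) -> str:
        return f"PulseList(n={len(self)})"


@dataclass
class ModeledTrace:
    """Modelled pupil trace M[t] on a shared uniform grid.

    ``diameter`` includes the static baseline; ``baseline`` records it.
    """

    time: np.ndarray
    diameter: np.ndarray
    baseline: float = 0.0

    @property
    def above_baseline(self) -> np.ndarray:
        return self.diameter - self.baseline


def impulse_response(t, params: ImpulseResponseParams | None = None) -> np.ndarray:
    """Evaluate the pupillary impulse response h at times ``t`` (seconds).

    Negative times map to 0 (causality); beyond ``support_s`` h is truncated
    to 0.  Computed in log space for numerical safety.
    """
    if params is None:
        params = ImpulseResponseParams()
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    valid = (t > 0) & (t <= params.support_s)
    tv = t[valid]
    if params.normalize_peak:
        # h(t)/h(t_max) = exp(n*log(t/t_max) - n*(t - t_max)/t_max)
        log_h = params.n * (np.log(tv / params.t_max) - (tv - params.t_max) / params.t_max)
    else:
        log_h = params.n * np.log(tv) - params.n * tv / params.t_max
    out[valid] = np.exp(log_h)
    return float(out[0]) if scalar else out


def reconstruct_trace(
    pulses: PulseList | Sequence[AttentionalPulse],
    grid: np.ndarray,
    params: ImpulseResponseParams | None = None,
    baseline: float = 0.0,
) -> ModeledTrace:
    """Forward map: M[t] = baseline + sum_i s_i * h(t - t_i) on ``grid``.

    ``grid`` must be uniform.  Pulse onsets need not lie on the grid; h is
    evaluated continuously.
    """
    if params is None:
        params = ImpulseResponseParams()
    grid = np.asarray(grid, dtype=float)
    if grid.size >= 2:
        dt = np.diff(grid)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
            raise ValueError("grid must be uniform")
    m = np.full(grid.shape, float(baseline))
    dt0 = float(grid[1] - grid[0]) if grid.size >= 2 else 1.0
    for p in pulses:
        # restrict to the kernel's support for speed
        i0 = int(np.searchsorted(grid, p.t))
        i1 = int(np.searchsorted(grid, p.t + params.support_s, side="right"))
        if i1 <= i0:
            continue
        m[i0:i1] += p.scale * impulse_response(grid[i0:i1] - p.t, params)
    return ModeledTrace(time=grid, diameter=m, baseline=float(baseline))


def model_error(modeled, observed, window: tuple[float, float] | None = None,
                time: np.ndarray | None = None) -> float:
    """Least-squares error eps = sum_w (M[t] - Z[t])^2 over a time window.

    Parameters
    ----------
    modeled, observed : array-like or ModeledTrace
        Traces on the same grid (mm).
    window : (t0, t1) or None
        Inclusive time window in seconds; None means the full overlap.
    time : array, optional
        Time axis; required when ``window`` is given and ``modeled`` is a
        bare array.
    """
    if isinstance(modeled, ModeledTrace):
        time = modeled.time if time is None else time
        modeled = modeled.diameter
    modeled = np.asarray(modeled, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if modeled.shape != observed.shape:
        raise ValueError("modeled and observed must share a grid")
    if window is not None:
        if time is None:
            raise ValueError("window requires a time axis")
        mask = (time >= window[0]) & (time <= window[1])
        if not mask.any():
            raise ValueError("empty error window")
        modeled = modeled[mask]
        observed = observed[mask]
    if modeled.size == 0:
        raise ValueError("empty error window")
    d = modeled - observed
    return float(d @ d)
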