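"""Downstream oculometric analyses of tracking logs.

Two read-outs are covered:

* **Pupillary light reflex (PLR)** — a sine wave mapped onto monitor
  brightness entrains pupil area by inverse proportionality; constriction
  speed ``v_c`` and dilation speed ``v_d`` are obtained from the sign-split
  first derivative of the (lightly smoothed) pupil-area trace, per
  stimulus cycle.
* **Optokinetic reflex (OKR)** — full-field drifting gratings evoke slow
  tracking phases with rapid resets, a sawtooth azimuth trace.  The
  response is quantified as eye-tracking movements per minute (ETMs):
  contiguous excursions of the azimuth derivative beyond a speed
  threshold, merged when closer than a refractory interval.

Azimuth calibration (degrees per pixel) is user-supplied; uncalibrated
traces are analyzed in pixels and the units recorded in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import wilcoxon

from .core import TrackingRecord
from .errors import ConfigError, InsufficientDataError

__all__ = [
    "PupilTrace",
    "SineStimulus",
    "ReactivityResult",
    "EtmResult",
    "GratingEpoch",
    "sine_brightness",
    "trace_from_records",
    "reactivity_speeds",
    "compute_etm",
    "grating_schedule",
]


@dataclass
class PupilTrace:
    """Time series of pupil area and (optionally) horizontal eye angle.

    Blink gaps are NaN, flagged rather than interpolated.
    """

    time_s: np.ndarray
    area: np.ndarray
    azimuth: np.ndarray | None = None
    azimuth_units: str = "px"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if len(self.time_s) != len(self.area):
            raise ValueError("time_s and area must have equal length")
        if self.azimuth is not None:
            self.azimuth = np.asarray(self.azimuth, dtype=float)
            if len(self.azimuth) != len(self.time_s):
                raise ValueError("azimuth must match time_s in length")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def blink_fraction(self) -> float:
        return float(np.isnan(self.area).mean())


def trace_from_records(
    records: Iterable[TrackingRecord],
    fps: float | None = None,
    deg_per_px: float | None = None,
    azimuth_origin: float | None = None,
) -> PupilTrace:
    """Build a trace from engine records.

    Azimuth is derived from the pupil-center x coordinate relative to
    ``azimuth_origin`` (default: the first tracked center), scaled by
    ``deg_per_px`` when a calibration is given.
    """
    recs = list(records)
    if not recs:
        raise InsufficientDataError("no records")
    t, area, cx = [], [], []
    for i, r in enumerate(recs):
        if r.time_s is not None:
            t.append(r.time_s)
        elif fps:
            t.append(r.frame_index / fps)
        else:
            t.append(float(i))
        if r.pupil is None:
            area.append(np.nan)
            cx.append(np.nan)
        else:
            area.append(r.pupil.area)
            cx.append(r.pupil.cx)
    cx_arr = np.asarray(cx, dtype=float)
    if azimuth_origin is None:
        tracked = cx_arr[~np.isnan(cx_arr)]
        azimuth_origin = float(tracked[0]) if len(tracked) else 0.0
    az = cx_arr - azimuth_origin
    units = "px"
    if deg_per_px is not None:
        az = az * deg_per_px
        units = "deg"
    return PupilTrace(time_s=np.asarray(t), area=np.asarray(area), azimuth=az, azimuth_units=units)


@dataclass(frozen=True)
class SineStimulus:
    """Sine-wave brightness drive; frequency in cycles per minute."""

    freq: float
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("stimulus frequency must be positive")
        if self.duration_s <= 0:
            raise ValueError("stimulus duration must be positive")

    @property
    def period_s(self) -> float:
        return 60.0 / self.freq

    def brightness(self, t) -> np.ndarray:
        return sine_brightness(t, self.freq)


def sine_brightness(t, freq: float):
    """Monitor brightness in [0, 1]: ``0.5 * (1 + sin(2*pi*freq*t/60))``."""
    if freq <= 0:
        raise ValueError("freq must be positive (cycles/min)")
    return 0.5 * (1.0 + np.sin(2.0 * math.pi * freq * np.asarray(t, dtype=float) / 60.0))


def _masked_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Moving average that ignores NaNs; NaN where the window is empty."""
    if window <= 1:
        return x.copy()
    good = np.isfinite(x)
    filled = np.where(good, x, 0.0)
    kernel = np.ones(window)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(good.astype(float), kernel, mode="same")
    out = np.full_like(x, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[~good] = np.nan  # keep blink gaps flagged
    return out


def _central_derivative(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Central-difference derivative; NaN propagates from gaps."""
    dy = np.full_like(y, np.nan)
    if len(y) >= 3:
        dy[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    if len(y) >= 2:
        dy[0] = (y[1] - y[0]) / (t[1] - t[0])
        dy[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return dy


@dataclass
class ReactivityResult:
    """Constriction/dilation speeds from the pupil-area derivative.

    Speeds are reported positive, in area units per second.  ``p_value``
    is a one-sided paired rank test of constriction dominating dilation
    across cycles, provided as a convenience.
    """

    v_c: float
    v_d: float
    per_cycle_vc: np.ndarray = field(default_factory=lambda: np.array([]))
    per_cycle_vd: np.ndarray = field(default_factory=lambda: np.array([]))
    vc_quartiles: tuple[float, float, float] = (math.nan,) * 3
    vd_quartiles: tuple[float, float, float] = (math.nan,) * 3
    p_value: float = math.nan


MAX_BLINK_FRACTION = 0.2


def reactivity_speeds(
    trace: PupilTrace, stimulus: SineStimulus, smooth_window: int = 5
) -> ReactivityResult:
    """Per-cycle constriction and dilation speeds of the pupil area.

    The area trace is smoothed by a short moving average (blink gaps
    masked, never interpolated), differentiated by central differences,
    and split by derivative sign: negative samples pool into constriction,
    positive into dilation.  Within each stimulus cycle the speed is the
    mean ``|dA/dt|`` of that phase; the headline ``v_c``/``v_d`` are
    medians across cycles.
    """
    if trace.duration_s < 2 * stimulus.period_s:
        raise InsufficientDataError(
            f"trace covers {trace.duration_s:.1f}s; need >= 2 cycles ({2 * stimulus.period_s:.1f}s)"
        )
    if trace.blink_fraction >= MAX_BLINK_FRACTION:
        raise InsufficientDataError(
            f"blink gaps cover {trace.blink_fraction:.0%} of samples (max {MAX_BLINK_FRACTION:.0%})"
        )
    area = _masked_moving_average(trace.area, smooth_window)
    dadt = _central_derivative(area, trace.time_s)

    t0 = trace.time_s[0]
    cycle = np.floor((trace.time_s - t0) / stimulus.period_s).astype(int)
    vc_list, vd_list = [], []
    for c in range(cycle.max() + 1):
        sel = cycle == c
        d = dadt[sel]
        d = d[np.isfinite(d)]
        if len(d) == 0:
            continue
        neg = d[d < 0]
        pos = d[d > 0]
        vc_list.append(float(np.abs(neg).mean()) if len(neg) else 0.0)
        vd_list.append(float(pos.mean()) if len(pos) else 0.0)
    vc = np.asarray(vc_list)
    vd = np.asarray(vd_list)
    if len(vc) < 2:
        raise InsufficientDataError("fewer than 2 analyzable cycles")

    p = math.nan
    diffs = vc - vd
    if np.any(diffs != 0):
        try:
            p = float(wilcoxon(vc, vd, alternative="greater").pvalue)
        except ValueError:
            p = math.nan

    def quart(v: np.ndarray) -> tuple[float, float, float]:
        q = np.percentile(v, [25, 50, 75])
        return (float(q[0]), float(q[1]), float(q[2]))

    return ReactivityResult(
        v_c=float(np.median(vc)),
        v_d=float(np.median(vd)),
        per_cycle_vc=vc,
        per_cycle_vd=vd,
        vc_quartiles=quart(vc),
        vd_quartiles=quart(vd),
        p_value=p,
    )


@dataclass
class EtmResult:
    """Eye-tracking movements: event intervals and rate per minute."""

    rate_per_min: float
    events: list[tuple[float, float]]
    threshold: float
    units: str = "deg/s"


def compute_etm(
    trace: PupilTrace,
    threshold: float = 10.0,
    min_interval_s: float = 0.1,
) -> EtmResult:
    """Count eye-tracking movements by thresholding the azimuth derivative.

    An event is a contiguous run of samples with ``|d(azimuth)/dt|`` above
    ``threshold``; events separated by less than ``min_interval_s`` merge
    into one.  The default threshold (10 deg/s) is twice the commanded
    grating slow-phase speed of 5 deg/s, so slow tracking never triggers.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if trace.azimuth is None:
        raise InsufficientDataError("trace carries no azimuth channel")
    t = trace.time_s
    vel = _central_derivative(trace.azimuth, t)
    above = np.isfinite(vel) & (np.abs(vel) > threshold)

    events: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = t[i]
        elif not flag and start is not None:
            events.append((start, t[i - 1]))
            start = None
    if start is not None:
        events.append((start, t[-1]))

    merged: list[tuple[float, float]] = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] < min_interval_s:
            merged[-1] = (merged[-1][0], ev[1])
        else:
            merged.append(ev)

    duration_min = trace.duration_s / 60.0
    rate = len(merged) / duration_min if duration_min > 0 else 0.0
    units = f"{trace.azimuth_units}/s"
    return EtmResult(rate_per_min=rate, events=merged, threshold=threshold, units=units)


@dataclass(frozen=True)
class GratingEpoch:
    t_start: float
    t_end: float
    direction_deg: float
    spatial_freq_cpd: float
    speed_deg_s: float


def grating_schedule(
    directions: Sequence[float] = (0.0, 180.0),
    trials: int = 8,
    on_s: float = 30.0,
    gap_s: float = 4.0,
    sf: float = 0.05,
    speed: float = 5.0,
) -> list[GratingEpoch]:
    """Drifting-grating presentation timeline with gray-screen gaps.

    Defaults follow the standard OKR protocol: eight 30 s trials separated
    by 4 s of gray, directions alternating along the horizontal axis,
    0.05 cycles/degree at 5 degrees/second.
    """
    if not directions:
        raise ConfigError("at least one grating direction is required")
    if trials <= 0 or on_s <= 0 or gap_s < 0 or sf <= 0 or speed <= 0:
        raise ConfigError("schedule parameters must be positive")
    epochs = []
    t = 0.0
    for i in range(trials):
        d = directions[i % len(directions)]
        epochs.append(GratingEpoch(t, t + on_s, float(d), sf, speed))
        t += on_s
        if i < trials - 1:
            t += gap_s
    return epochs
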