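"""From annotated O2 traces to background-corrected oxygen-uptake rates.

Each sealed measurement period yields one ordinary-least-squares slope of
O2 concentration against time (mg L^-1 h^-1).  The first and last minute
of each period are excluded so the recirculation loop can stabilise after
flushing.  Slopes are converted to whole-animal uptake

    MO2 = -slope * V_eff        (mg O2 h^-1, consumption positive),

where V_eff is the chamber water volume net of fish body volume.
Bacterial respiration, measured in empty chambers before and after the
trial, is subtracted assuming a linear increase over the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .chamber import ChamberSpec
from .errors import (InsufficientDataError, InvalidIntervalError,
                     SingularFitError)
from .traceio import O2Trace

DEFAULT_EXCLUSION_S = 60.0
DEFAULT_MIN_WINDOW_S = 120.0
DEFAULT_QC_R2 = 0.97


@dataclass(frozen=True)
class Window:
    """One trimmed measurement window: samples retained for a slope fit."""

    period_index: int
    start_s: float
    end_s: float
    time_s: np.ndarray
    o2_mgL: np.ndarray

    @property
    def t_mid_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass(frozen=True)
class SlopeEstimate:
    """Regression result for one measurement period.

    ``slope`` is in mg O2 L^-1 h^-1 (negative while the fish consumes);
    ``mo2`` in mg O2 h^-1 with consumption positive.  ``corrected`` marks
    whether background respiration has been subtracted from ``mo2``.
    """

    period_index: int
    window_start: float
    window_end: float
    slope: float
    intercept: float
    r_squared: float
    n_samples: int
    mo2: float = np.nan
    corrected: bool = False
    qc_pass: bool = False

    @property
    def t_mid_s(self) -> float:
        return 0.5 * (self.window_start + self.window_end)


@dataclass(frozen=True)
class BackgroundModel:
    """Linear-in-time bacterial respiration: pre rate anchored at trial
    start, post rate at trial end."""

    rate_pre: float
    rate_post: float

    def __post_init__(self) -> None:
        if self.rate_pre < 0 or self.rate_post < 0:
            raise ValueError("background rates must be non-negative "
                             "(clamp negative fits before constructing)")

    def rate_at(self, t_s: float, trial_start: float, trial_end: float) -> float:
        """Interpolated background rate (mg O2 h^-1) at time ``t_s``."""
        if trial_end <= trial_start:
            raise InvalidIntervalError("trial_end must exceed trial_start")
        frac = (t_s - trial_start) / (trial_end - trial_start)
        return self.rate_pre + (self.rate_post - self.rate_pre) * frac


def extract_windows(trace: O2Trace, exclusion_s: float = DEFAULT_EXCLUSION_S,
                    min_window_s: float = DEFAULT_MIN_WINDOW_S) -> list[Window]:
    """Cut the trace into trimmed measurement windows.

    A period is a maximal run of ``measure``-labelled samples; its span is
    taken as [first sample, last sample + sample interval).  ``exclusion_s``
    is removed from both ends; windows shorter than ``min_window_s`` are
    dropped with a warning.
    """
    is_meas = trace.phase == "measure"
    if not is_meas.any():
        return []
    # boundaries of contiguous measure runs
    padded = np.concatenate(([False], is_meas, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive sample index
    dt = (trace.chamber.sample_interval if trace.chamber is not None
          else float(np.median(np.diff(trace.time_s))))
    windows: list[Window] = []
    dropped = 0
    for k, (i0, i1) in enumerate(zip(starts, ends)):
        p_start = trace.time_s[i0]
        p_end = trace.time_s[i1 - 1] + dt
        w_start = p_start + exclusion_s
        w_end = p_end - exclusion_s
        if w_end - w_start < min_window_s:
            dropped += 1
            continue
        sel = slice(*np.searchsorted(trace.time_s[i0:i1], [w_start, w_end]))
        tsel = trace.time_s[i0:i1][sel]
        osel = trace.o2_mgL[i0:i1][sel]
        windows.append(Window(k, float(w_start), float(w_end), tsel, osel))
    if dropped:
        warnings.warn(f"{dropped} measurement period(s) shorter than "
                      f"{min_window_s:.0f} s after trimming; dropped",
                      stacklevel=2)
    return windows


def fit_slope(window: Window, qc_threshold: float = DEFAULT_QC_R2) -> SlopeEstimate:
    """Ordinary least squares of O2 concentration on time for one window.

    The slope is rescaled to mg L^-1 h^-1 and r-squared is the squared
    Pearson correlation.  A zero-variance (flat) response gives slope 0
    and r-squared defined as 0, failing QC: a flat trace carries no rate
    information.
    """
    t, o2 = window.time_s, window.o2_mgL
    if len(t) < 3:
        raise InsufficientDataError(f"window {window.period_index}: "
                                    f"{len(t)} samples (< 3)")
    if np.ptp(t) == 0:
        raise SingularFitError("all timestamps identical; slope undefined")
    if np.ptp(o2) == 0:
        return SlopeEstimate(window.period_index, window.start_s, window.end_s,
                             slope=0.0, intercept=float(o2[0]), r_squared=0.0,
                             n_samples=len(t), qc_pass=False)
    res = stats.linregress(t, o2)
    r2 = float(res.rvalue**2)
    return SlopeEstimate(window.period_index, window.start_s, window.end_s,
                         slope=float(res.slope) * 3600.0,
                         intercept=float(res.intercept),
                         r_squared=r2, n_samples=len(t),
                         qc_pass=r2 > qc_threshold)


def slope_to_mo2(est: SlopeEstimate, chamber: ChamberSpec, fish_mass_g: float,
                 subtract_fish_volume: bool = True) -> SlopeEstimate:
    """Convert a concentration slope to whole-animal oxygen uptake (mg O2 h^-1)."""
    v_eff = chamber.effective_volume(fish_mass_g, subtract_fish_volume)
    return replace(est, mo2=-est.slope * v_eff, corrected=False)


def fit_background(pre_trace: O2Trace, post_trace: O2Trace,
                   chamber: ChamberSpec,
                   exclusion_s: float = DEFAULT_EXCLUSION_S) -> BackgroundModel:
    """Estimate bacterial respiration from empty-chamber runs.

    Each trace contributes the mean MO2 of its (up to three) measurement
    windows, using the full chamber volume (no fish).  Negative fitted
    rates are clamped to zero with a warning.
    """
    rates = []
    for label, trace in (("pre", pre_trace), ("post", post_trace)):
        windows = extract_windows(trace, exclusion_s=exclusion_s)
        if not windows:
            raise InsufficientDataError(
                f"{label}-trial background trace has no usable window")
        mo2 = [slope_to_mo2(fit_slope(w), chamber, 0.0).mo2 for w in windows]
        rate = float(np.mean(mo2))
        if rate < 0:
            warnings.warn(f"negative fitted {label}-trial background rate "
                          f"({rate:.4g} mg O2/h); clamped to 0", stacklevel=2)
            rate = 0.0
        rates.append(rate)
    return BackgroundModel(rate_pre=rates[0], rate_post=rates[1])


def correct_background(estimates: list[SlopeEstimate], bg: BackgroundModel,
                       trial_start: float, trial_end: float) -> list[SlopeEstimate]:
    """Subtract time-interpolated background respiration from each MO2 value.

    Corrected values are floored at zero (a fish cannot produce oxygen);
    the number of floored estimates is reported in a warning.
    """
    if trial_end <= trial_start:
        raise InvalidIntervalError("trial_end must exceed trial_start")
    out: list[SlopeEstimate] = []
    floored = 0
    for est in estimates:
        if not (trial_start <= est.t_mid_s <= trial_end):
            raise InvalidIntervalError(
                f"window midpoint {est.t_mid_s:.0f} s outside trial span")
        corrected = est.mo2 - bg.rate_at(est.t_mid_s, trial_start, trial_end)
        if corrected < 0:
            corrected = 0.0
            floored += 1
        out.append(replace(est, mo2=corrected, corrected=True))
    if floored:
        warnings.warn(f"{floored} corrected MO2 value(s) below zero; "
                      "floored at 0", stacklevel=2)
    return out


def process_trial(trace: O2Trace, pre_trace: O2Trace, post_trace: O2Trace,
                  chamber: ChamberSpec, fish_mass_g: float,
                  exclusion_s: float = DEFAULT_EXCLUSION_S,
                  min_window_s: float = DEFAULT_MIN_WINDOW_S,
                  qc_threshold: float = DEFAULT_QC_R2,
                  subtract_fish_volume: bool = True,
                  trial_start: float | None = None,
                  trial_end: float | None = None) -> pd.DataFrame:
    """Full per-trial pipeline: windows -> slopes -> MO2 -> background correction.

    Returns one row per measurement period with columns ``period_index``,
    ``t_mid_s``, ``slope``, ``r2``, ``mo2_raw``, ``mo2_corrected``,
    ``qc_pass``.
    """
    if trial_start is None:
        trial_start = float(trace.meta.get("trial_start_s", trace.time_s[0]))
    if trial_end is None:
        trial_end = float(trace.meta.get("trial_end_s", trace.time_s[-1]))
    windows = extract_windows(trace, exclusion_s=exclusion_s,
                              min_window_s=min_window_s)
    if not windows:
        raise InsufficientDataError("trace yields zero usable measurement windows")
    raw = [slope_to_mo2(fit_slope(w, qc_threshold), chamber, fish_mass_g,
                        subtract_fish_volume) for w in windows]
    bg = fit_background(pre_trace, post_trace, chamber, exclusion_s=exclusion_s)
    corrected = correct_background(raw, bg, trial_start, trial_end)
    return pd.DataFrame({
        "period_index": [e.period_index for e in raw],
        "t_mid_s": [e.t_mid_s for e in raw],
        "slope": [e.slope for e in raw],
        "r2": [e.r_squared for e in raw],
        "mo2_raw": [e.mo2 for e in raw],
        "mo2_corrected": [e.mo2 for e in corrected],
        "qc_pass": [e.qc_pass for e in raw],
    })
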