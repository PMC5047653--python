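"""Metabolic summary statistics from a per-period oxygen-uptake series.

Three quantities summarise each overnight trial:

* **MR_min** — minimum metabolic rate, the mean of the lowest decile of
  per-period MO2 values over the whole trial (the usual proxy for
  standard metabolic rate in intermittent-flow respirometry).
* **RMR** — routine metabolic rate, the mean MO2 after discarding the
  first hours in the respirometer while the animal settles.
* **ISR** — initial stress response, the first post-transfer MO2 minus
  MR_min; indexes the handling/isolation stress reaction.

A stabilization-time detector locates when the settling transient has
decayed: the earliest window from which a k-period rolling mean stays
within a tolerance band around the end-of-trial level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

DEFAULT_SETTLE_CUTOFF_H = 5.0


@dataclass(frozen=True)
class StabilizationResult:
    """Detected settling time (hours from trial start) and whether the
    series ever stabilised; unstabilised series report the trace end."""

    time_h: float
    stabilized: bool


@dataclass(frozen=True)
class MetabolicSummary:
    """Per fish-by-testing-condition metabolic phenotype."""

    fish_id: str
    testing: str
    mr_min: float
    rmr: float
    isr: float | None
    isr_missing_reason: str | None
    stabilization_time_h: float
    stabilized: bool
    n_periods_total: int
    n_periods_used: int


def mr_min(values, method: str = "decile_mean", q: float = 0.10) -> float:
    """Minimum metabolic rate: the lowest 10th percentile of MO2 values.

    ``method='decile_mean'`` (default) averages every value at or below
    the empirical q-quantile — at least the single smallest value is
    always included.  ``method='quantile'`` returns the interpolated
    quantile point estimate instead.  Requires >= 10 values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise InsufficientDataError(
            f"MR_min needs at least 10 values, got {v.size}")
    qv = float(np.quantile(v, q))
    if method == "quantile":
        return qv
    if method != "decile_mean":
        raise ValueError(f"unknown method {method!r}")
    low = v[v <= qv]
    if low.size == 0:  # unreachable: min(v) <= quantile by construction
        low = v[[int(np.argmin(v))]]
    return float(low.mean())


def rmr(values, t_mid_h, settle_cutoff_h: float = DEFAULT_SETTLE_CUTOFF_H,
        trial_start_h: float = 0.0) -> float:
    """Routine metabolic rate: mean MO2 of periods after the settling cutoff."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(t_mid_h, dtype=float)
    sel = t - trial_start_h > settle_cutoff_h
    if not sel.any():
        raise InsufficientDataError(
            f"no periods after the {settle_cutoff_h} h settling cutoff")
    return float(v[sel].mean())


def isr(first_period_mo2: float, mr_min_value: float) -> float:
    """Initial stress response: first post-transfer MO2 minus MR_min."""
    return float(first_period_mo2) - float(mr_min_value)


def stabilization_time(values, t_mid_h, k: int = 3, delta: float = 0.10,
                       reference_span_h: float = 3.0) -> StabilizationResult:
    """Earliest time from which the series stays near its settled level.

    The reference level is the mean over the final ``reference_span_h``
    hours.  The detector reports the earliest window midpoint t* whose
    k-period rolling mean — and every later rolling mean — lies within
    ``delta`` (relative) of the reference.  Series that never satisfy
    this are flagged unstabilised and report the last midpoint.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(t_mid_h, dtype=float)
    if v.size < k or t[-1] - t[0] < 3.0:
        raise InsufficientDataError("stabilization detection needs >= 3 h of data")
    ref_sel = t >= t[-1] - reference_span_h
    ref = float(v[ref_sel].mean())
    roll = np.convolve(v, np.ones(k) / k, mode="valid")  # roll[j] starts at j
    tol = delta * abs(ref) if ref != 0 else delta
    ok = np.abs(roll - ref) <= tol
    # earliest j such that ok[j:] is all True
    ok_from_here = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.flatnonzero(ok_from_here)
    if hits.size == 0:
        return StabilizationResult(float(t[-1]), stabilized=False)
    return StabilizationResult(float(t[hits[0]]), stabilized=True)


def summarize_trial(slopes: pd.DataFrame, fish_id: str, testing: str,
                    settle_cutoff_h: float = DEFAULT_SETTLE_CUTOFF_H,
                    use_corrected: bool = True, qc_filter: bool = True,
                    isr_use_corrected: bool = True,
                    mr_min_method: str = "decile_mean") -> MetabolicSummary:
    """Compute the full metabolic summary from a processed slope table.

    ``slopes`` is the output of :func:`shoalresp.slopes.process_trial`.
    QC-failing periods are excluded from every statistic by default but
    remain visible through the period counts.  ISR uses the corrected
    first slope by default (``isr_use_corrected=False`` switches to raw);
    if the first period fails QC, ISR is reported missing, not imputed.
    """
    col = "mo2_corrected" if use_corrected else "mo2_raw"
    used = slopes[slopes["qc_pass"]] if qc_filter else slopes
    values = used[col].to_numpy(dtype=float)
    t_h = used["t_mid_s"].to_numpy(dtype=float) / 3600.0
    mrmin = mr_min(values, method=mr_min_method)
    rmr_val = rmr(values, t_h, settle_cutoff_h=settle_cutoff_h)
    stab = stabilization_time(values, t_h)

    first_idx = slopes["period_index"].idxmin()
    first = slopes.loc[first_idx]
    isr_val: float | None
    reason: str | None = None
    if qc_filter and not bool(first["qc_pass"]):
        isr_val, reason = None, "first period failed QC"
    else:
        first_col = "mo2_corrected" if isr_use_corrected else "mo2_raw"
        isr_val = isr(float(first[first_col]), mrmin)
    return MetabolicSummary(
        fish_id=fish_id, testing=testing, mr_min=mrmin, rmr=rmr_val,
        isr=isr_val, isr_missing_reason=reason,
        stabilization_time_h=stab.time_h, stabilized=stab.stabilized,
        n_periods_total=len(slopes), n_periods_used=len(used))


def summary_table(summaries: list[MetabolicSummary]) -> pd.DataFrame:
    """One row per fish x testing condition."""
    return pd.DataFrame([{
        "fish_id": s.fish_id, "testing": s.testing, "mr_min": s.mr_min,
        "rmr": s.rmr, "isr": s.isr, "stabilization_time_h": s.stabilization_time_h,
        "stabilized": s.stabilized, "n_periods_total": s.n_periods_total,
        "n_periods_used": s.n_periods_used,
    } for s in summaries])
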