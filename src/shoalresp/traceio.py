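"""Oxygen-trace and metadata I/O: canonical CSV format, validation, phase annotation.

The canonical trace format is a plain CSV with columns ``time_s``,
``o2_mgL``, ``o2_percent_sat`` and ``phase`` (``measure``/``flush``/
``unknown``), one file per trial.  A thin adapter maps Fire-Sting-style
optode exports (key-value header block followed by tab-separated data)
onto the same in-memory representation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chamber import ChamberSpec
from .errors import TraceFormatError, TraceValidationError

PHASES = ("measure", "flush", "unknown")


@dataclass
class O2Trace:
    """One trial's dissolved-oxygen time series with phase annotations.

    Attributes
    ----------
    time_s : np.ndarray
        Sample times in seconds from trial start, strictly increasing.
    o2_mgL : np.ndarray
        Dissolved O2 concentration at each sample, mg L^-1 (>= 0).
    phase : np.ndarray
        Per-sample phase label, one of ``measure``, ``flush``, ``unknown``.
    chamber : ChamberSpec | None
        Geometry/timing context for downstream volume and cycle logic.
    meta : dict
        Trial metadata (fish_id, testing condition, start timestamp, ...).
    """

    time_s: np.ndarray
    o2_mgL: np.ndarray
    phase: np.ndarray
    chamber: ChamberSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_mgL = np.asarray(self.o2_mgL, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time_s) == len(self.o2_mgL) == len(self.phase)):
            raise TraceValidationError("time, o2 and phase arrays differ in length")
        self.validate()

    def validate(self) -> None:
        if self.time_s.size == 0:
            raise TraceValidationError("trace contains no samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise TraceValidationError(
                f"time not strictly increasing at row {row} "
                f"(t={self.time_s[row]!r} after t={self.time_s[row - 1]!r})")
        if np.any(self.o2_mgL < 0):
            row = int(np.argmax(self.o2_mgL < 0))
            raise TraceValidationError(f"negative O2 concentration at row {row}")
        bad = set(np.unique(self.phase)) - set(PHASES)
        if bad:
            raise TraceValidationError(f"unknown phase labels: {sorted(bad)}")
        if self.chamber is not None and dt.size:
            gaps = int(np.sum(dt > 2 * self.chamber.sample_interval))
            if gaps:
                warnings.warn(f"{gaps} sampling gap(s) exceed twice the "
                              "nominal sample interval", stacklevel=2)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def is_annotated(self) -> bool:
        return bool(np.any(self.phase != "unknown"))

    def percent_saturation(self) -> np.ndarray:
        """O2 as percent of air saturation (requires a chamber context)."""
        if self.chamber is None:
            raise TraceValidationError("percent saturation needs a ChamberSpec")
        return 100.0 * self.o2_mgL / self.chamber.o2_full_saturation

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s, "o2_mgL": self.o2_mgL})
        if self.chamber is not None:
            df["o2_percent_sat"] = self.percent_saturation()
        df["phase"] = self.phase.astype(str)
        return df


def write_trace(trace: O2Trace, path: str | Path) -> None:
    """Write a trace to canonical CSV (UTF-8, header row, full float precision)."""
    df = trace.to_frame()
    df.to_csv(path, index=False, encoding="utf-8",
              float_format=None)  # repr precision: bit-exact round trip


def read_trace(path: str | Path, chamber: ChamberSpec | None = None,
               units: str = "mgL", meta: Mapping | None = None) -> O2Trace:
    """Read a canonical trace CSV.

    Parameters
    ----------
    units : str
        ``"mgL"`` reads the ``o2_mgL`` column; ``"percent_sat"`` reads
        ``o2_percent_sat`` and converts through the chamber's
        ``o2_full_saturation``.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise TraceValidationError(f"{path}: no data rows")
    if "time_s" not in df.columns:
        raise TraceFormatError(f"{path}: missing required column 'time_s'")
    if units == "mgL":
        if "o2_mgL" not in df.columns:
            raise TraceFormatError(f"{path}: missing column 'o2_mgL'")
        o2 = df["o2_mgL"].to_numpy(dtype=float)
    elif units == "percent_sat":
        if "o2_percent_sat" not in df.columns:
            raise TraceFormatError(f"{path}: missing column 'o2_percent_sat'")
        if chamber is None:
            raise TraceFormatError("percent_sat units require a ChamberSpec")
        o2 = df["o2_percent_sat"].to_numpy(dtype=float) / 100.0 * chamber.o2_full_saturation
    else:
        raise ValueError(f"unknown units {units!r}")
    if "phase" in df.columns:
        phase = df["phase"].astype(str).to_numpy(dtype=object)
    else:
        phase = np.full(len(df), "unknown", dtype=object)
    return O2Trace(df["time_s"].to_numpy(dtype=float), o2, phase,
                   chamber=chamber, meta=dict(meta or {}))


def read_firesting(path: str | Path, chamber: ChamberSpec | None = None,
                   meta: Mapping | None = None) -> O2Trace:
    """Adapter for Fire-Sting-style optode exports.

    Accepts a text file with an arbitrary header block (lines starting
    with ``#`` or containing ``:``-separated key/value pairs) followed by
    a tab-separated data table whose header row contains ``Time`` and an
    oxygen column (``O2`` / ``Oxygen``, assumed mg L^-1).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    start = None
    for i, line in enumerate(lines):
        cells = line.split("\t")
        if len(cells) >= 2 and any(c.strip().lower().startswith("time") for c in cells):
            start = i
            break
    if start is None:
        raise TraceFormatError(f"{path}: no tab-separated data header found")
    df = pd.read_csv(io.StringIO("\n".join(lines[start:])), sep="\t")
    df.columns = [c.strip() for c in df.columns]
    time_col = next(c for c in df.columns if c.lower().startswith("time"))
    o2_col = next((c for c in df.columns
                   if c.lower().startswith(("o2", "oxygen"))), None)
    if o2_col is None:
        raise TraceFormatError(f"{path}: no oxygen column found")
    phase = np.full(len(df), "unknown", dtype=object)
    return O2Trace(df[time_col].to_numpy(dtype=float),
                   df[o2_col].to_numpy(dtype=float), phase,
                   chamber=chamber, meta=dict(meta or {}))


def annotate_phases(trace: O2Trace, chamber: ChamberSpec | None = None,
                    t0_offset: float = 0.0, force: bool = False) -> O2Trace:
    """Label every sample measure/flush by position in the repeating cycle.

    ``t0_offset`` is the time (s) already elapsed within the
    measure-then-flush cycle at the trace's first timestamp: 0 means the
    trace opens at the start of a measurement period;
    ``t0_offset == measure_duration`` means it opens at the start of a
    flush.  Phase intervals are half-open ``[start, end)``, so a sample
    exactly on a transition belongs to the later phase.

    Already-annotated traces are returned unchanged unless ``force=True``.
    """
    chamber = chamber or trace.chamber
    if chamber is None:
        raise TraceValidationError("phase annotation needs a ChamberSpec")
    if trace.is_annotated and not force:
        return trace
    if trace.duration_s < chamber.cycle_duration:
        warnings.warn("trace shorter than one full cycle; downstream "
                      "window extraction may yield zero periods", stacklevel=2)
    pos = np.mod(trace.time_s - trace.time_s[0] + t0_offset,
                 chamber.cycle_duration)
    phase = np.where(pos < chamber.measure_duration, "measure", "flush")
    return replace(trace, time_s=trace.time_s.copy(), o2_mgL=trace.o2_mgL.copy(),
                   phase=phase.astype(object), chamber=chamber,
                   meta=dict(trace.meta))


@dataclass
class FishRecord:
    """Identity, morphometrics and treatment assignment of one focal fish.

    ``weeks`` maps week index (0, 1, 2) to a ``(mass_g, length_cm)`` pair;
    ``mass_g``/``length_cm`` are the week-0 (respirometry) values.
    """

    fish_id: str
    mass_g: float
    length_cm: float
    holding: str = "shoal"
    weeks: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_g <= 0 or self.length_cm <= 0:
            raise ValueError("mass and length must be positive")
        if self.holding not in ("shoal", "solitary"):
            raise ValueError("holding must be 'shoal' or 'solitary'")
        if not self.weeks:
            self.weeks = {0: (self.mass_g, self.length_cm)}
        if not set(self.weeks) <= {0, 1, 2}:
            raise ValueError("week indices must be within {0, 1, 2}")
        for mass, length in self.weeks.values():
            if mass <= 0 or length <= 0:
                raise ValueError("weekly mass and length must be positive")


def fish_table(fish: list[FishRecord]) -> pd.DataFrame:
    """Long-format morphometric table: one row per fish x week."""
    rows = []
    for f in fish:
        for week in sorted(f.weeks):
            mass, length = f.weeks[week]
            rows.append({"fish_id": f.fish_id, "holding": f.holding,
                         "week": week, "mass_g": mass, "length_cm": length})
    return pd.DataFrame(rows)


def read_fish_table(path: str | Path) -> list[FishRecord]:
    """Inverse of :func:`fish_table` (week 0 row required per fish)."""
    df = pd.read_csv(path)
    needed = {"fish_id", "holding", "week", "mass_g", "length_cm"}
    if not needed <= set(df.columns):
        raise TraceFormatError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    fish = []
    for fid, grp in df.groupby("fish_id", sort=False):
        weeks = {int(r.week): (float(r.mass_g), float(r.length_cm))
                 for r in grp.itertuples()}
        if 0 not in weeks:
            raise TraceValidationError(f"fish {fid}: no week-0 morphometrics")
        mass, length = weeks[0]
        fish.append(FishRecord(str(fid), mass, length,
                               holding=str(grp["holding"].iloc[0]), weeks=weeks))
    return fish
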