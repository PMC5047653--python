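"""Synthetic dual-chamber intermittent-flow respirometry trials with known truth.

The generator emulates an overnight metabolic-phenotyping trial on a small
gregarious reef fish: a sealed 100 mL inner chamber sampled every 2 s by an
optode, alternating 9 min measurement and 3 min flush periods for ~11.5 h.
Instantaneous oxygen uptake of the fish is

    MO2(t) = floor * (mass/ref_mass)^b  +  A * exp(-t / tau)  +  activity,

i.e. an allometrically scaled minimum rate plus a handling-stress component
that decays over the first hours, plus per-period random activity.  The
floor is multiplied by ``1 - shoal_effect`` when shoal-mates occupy the
outer chamber (the calming effect).  Bacterial (background) respiration
rises linearly over the trial and is observable through empty-chamber
trials run before and after.  Every random draw is seeded, so identical
configurations give bit-identical traces and each trial carries a
:class:`TruthRecord` for parameter-recovery tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chamber import ChamberSpec
from .errors import PhysicallyImpossibleError
from .traceio import FishRecord, O2Trace, fish_table

CONDITIONS = ("solitary", "shoal")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic cohort.

    Units: masses g, lengths cm, metabolic rates mg O2 h^-1, times as
    noted.  Defaults describe the study conditions the generator emulates:
    8 fish per holding treatment (1.84 +- g mass, 3.69 cm standard
    length), a shoal-testing effect averaging a 25.9% reduction of the
    metabolic floor (per-fish values spanning 5-60%), a stress component
    that stabilises around 4.6 h, and background respiration drifting
    upward overnight.
    """

    n_fish_per_treatment: int = 8
    mass_mean: float = 1.84
    mass_sd: float = 0.12
    length_mean: float = 3.69
    length_sd: float = 0.09
    reference_mass: float = 1.84
    mass_exponent: float = 0.89          # allometric exponent b
    baseline_mo2_ref: float = 0.35       # solitary floor at reference mass
    shoal_effect_mean: float = 0.259
    shoal_effect_range: tuple[float, float] = (0.05, 0.60)
    shoal_effect_beta_a: float = 2.0
    shoal_effect_fixed: float | None = None   # overrides the distribution
    stress_amplitude: float = 0.25       # extra MO2 at t=0, reference mass
    stress_tau: float = 2.34             # h; 2.34*ln(0.25/0.035) ~= 4.6 h
    activity_noise_sd: float = 0.01      # mg O2 h^-1, one draw per period
    background_rate_start: float = 0.002
    background_rate_end: float = 0.010
    optode_noise_sd: float = 0.004       # mg L^-1 per sample
    trial_duration: float = 11.5         # h
    flush_time_constant: float = 40.0    # s; reaches >99% sat in 180 s
    subtract_fish_volume: bool = True
    mass_loss_solitary_week1: float = 0.05
    growth_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stress_tau <= 0:
            raise ValueError("stress_tau must be positive")
        if self.trial_duration < 6:
            raise ValueError("trial_duration must be at least 6 h (the 5 h "
                             "settling exclusion plus usable periods)")
        lo, hi = self.shoal_effect_range
        if not (0 <= lo < hi < 1):
            raise ValueError("shoal_effect_range must satisfy 0 <= lo < hi < 1")
        eff = self.shoal_effect_fixed
        if eff is not None and not (0 <= eff < 1):
            raise ValueError("shoal_effect must lie in [0, 1)")
        if self.shoal_effect_fixed is None and not (lo <= self.shoal_effect_mean <= hi):
            raise ValueError("shoal_effect_mean must lie within shoal_effect_range")

    def draw_shoal_effect(self, rng: np.random.Generator) -> float:
        """Per-fish fractional reduction of the metabolic floor under shoal testing.

        Beta(a, b) rescaled onto ``shoal_effect_range`` with b solved so
        the rescaled mean equals ``shoal_effect_mean``.
        """
        if self.shoal_effect_fixed is not None:
            return float(self.shoal_effect_fixed)
        lo, hi = self.shoal_effect_range
        m = (self.shoal_effect_mean - lo) / (hi - lo)
        a = self.shoal_effect_beta_a
        b = a * (1 - m) / m
        return float(lo + (hi - lo) * rng.beta(a, b))


@dataclass(frozen=True)
class TruthRecord:
    """Generator ground truth for one fish (both testing conditions)."""

    fish_id: str
    floor_solitary: float
    floor_shoal: float
    shoal_effect: float
    stress_amplitude: float
    stress_tau_h: float
    background_start: float
    background_end: float

    def floor(self, condition: str) -> float:
        return self.floor_shoal if condition == "shoal" else self.floor_solitary

    def stabilization_time(self, condition: str, delta: float = 0.10) -> float:
        """Hours until the stress component falls below ``delta`` of the floor."""
        f = self.floor(condition)
        if self.stress_amplitude <= delta * f:
            return 0.0
        return self.stress_tau_h * math.log(self.stress_amplitude / (delta * f))


def _crc(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


def _fish_rng(config: SimulationConfig, fish_id: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _crc(fish_id), 101])


def _trial_rng(config: SimulationConfig, fish_id: str, condition: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, _crc(fish_id), CONDITIONS.index(condition), 202])


def fish_truth(config: SimulationConfig, fish: FishRecord) -> TruthRecord:
    """Ground-truth floors and stress parameters for one fish.

    Deterministic in (config.seed, fish_id): both of a fish's trials and
    any repeated call see the same truth.
    """
    scale = (fish.mass_g / config.reference_mass) ** config.mass_exponent
    floor_sol = config.baseline_mo2_ref * scale
    effect = config.draw_shoal_effect(_fish_rng(config, fish.fish_id))
    return TruthRecord(
        fish_id=fish.fish_id,
        floor_solitary=floor_sol,
        floor_shoal=floor_sol * (1 - effect),
        shoal_effect=effect,
        stress_amplitude=config.stress_amplitude * scale,
        stress_tau_h=config.stress_tau,
        background_start=config.background_rate_start,
        background_end=config.background_rate_end,
    )


def _integrate_trial(chamber: ChamberSpec, *, v_eff: float, floor: float,
                     amplitude: float, tau_h: float, bg0: float, bg1: float,
                     duration_s: float, activity: np.ndarray,
                     flush_tau_s: float, rng: np.random.Generator | None,
                     optode_sd: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form oxygen mass balance over alternating measure/flush cycles.

    Measure phases integrate d[O2]/dt = -(MO2(t) + B(t))/V_eff exactly;
    flush phases relax exponentially toward the (slightly
    consumption-depressed) saturation level.  Returns (time_s, o2_mgL,
    phase).
    """
    dt = chamber.sample_interval
    cyc = chamber.cycle_duration
    meas = chamber.measure_duration
    sat = chamber.o2_full_saturation
    t = np.arange(0.0, duration_s, dt)
    phase = np.where(np.mod(t, cyc) < meas, "measure", "flush").astype(object)
    o2 = np.empty_like(t)

    bg_h = duration_s / 3600.0  # background drift spans the whole trial

    def bg_rate(th):
        return bg0 + (bg1 - bg0) * th / bg_h

    def consumed(th0, th, a_p):
        # mg of O2 consumed on [th0, th] (hours): linear + stress + drift terms
        lin = (floor + a_p) * (th - th0)
        stress = amplitude * tau_h * (math.exp(-th0 / tau_h) - np.exp(-th / tau_h))
        drift = bg0 * (th - th0) + (bg1 - bg0) * (th**2 - th0**2) / (2 * bg_h)
        return lin + stress + drift

    n_cycles = int(np.ceil(duration_s / cyc))
    o2_start = sat
    for p in range(n_cycles):
        t0 = p * cyc
        t1 = min(t0 + meas, duration_s)
        sel = (t >= t0) & (t < t1)
        a_p = activity[p] if p < len(activity) else 0.0
        o2[sel] = o2_start - consumed(t0 / 3600.0, t[sel] / 3600.0, a_p) / v_eff
        o2_end = o2_start - float(consumed(t0 / 3600.0, t1 / 3600.0, a_p)) / v_eff
        if o2_end < 0:
            raise PhysicallyImpossibleError(
                "configuration draws chamber oxygen below zero "
                f"(period {p}: {o2_end:.3f} mg/L)")
        t2 = min(t0 + cyc, duration_s)
        if t2 > t1:
            fsel = (t >= t1) & (t < t2)
            thm = (t1 + t2) / 2 / 3600.0
            mo2_flush = floor + amplitude * math.exp(-thm / tau_h) + bg_rate(thm)
            s_eq = sat - mo2_flush * (flush_tau_s / 3600.0) / v_eff
            o2[fsel] = s_eq + (o2_end - s_eq) * np.exp(-(t[fsel] - t1) / flush_tau_s)
            o2_start = s_eq + (o2_end - s_eq) * math.exp(-(t2 - t1) / flush_tau_s)
        else:
            o2_start = o2_end
    if rng is not None and optode_sd > 0:
        o2 = o2 + rng.normal(0.0, optode_sd, size=o2.shape)
    np.clip(o2, 0.0, None, out=o2)
    return t, o2, phase


def simulate_trial(chamber: ChamberSpec, fish: FishRecord, condition: str,
                   config: SimulationConfig) -> tuple[O2Trace, TruthRecord]:
    """Simulate one overnight trial of a focal fish under one testing condition.

    Returns the optode trace (phase-annotated) and the generator's ground
    truth.  Deterministic in (chamber, fish, condition, config): repeated
    calls give byte-identical traces.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    v_eff = chamber.effective_volume(fish.mass_g, config.subtract_fish_volume)
    truth = fish_truth(config, fish)
    rng = _trial_rng(config, fish.fish_id, condition)
    duration_s = config.trial_duration * 3600.0
    n_cycles = int(np.ceil(duration_s / chamber.cycle_duration))
    floor = truth.floor(condition)
    activity = rng.normal(0.0, config.activity_noise_sd, size=n_cycles)
    np.maximum(activity, -floor, out=activity)  # total MO2 stays >= 0
    t, o2, phase = _integrate_trial(
        chamber, v_eff=v_eff, floor=floor, amplitude=truth.stress_amplitude,
        tau_h=truth.stress_tau_h, bg0=config.background_rate_start,
        bg1=config.background_rate_end, duration_s=duration_s,
        activity=activity, flush_tau_s=config.flush_time_constant,
        rng=rng, optode_sd=config.optode_noise_sd)
    trace = O2Trace(t, o2, phase, chamber=chamber,
                    meta={"fish_id": fish.fish_id, "testing": condition,
                          "trial_start_s": 0.0, "trial_end_s": duration_s,
                          "fish_mass_g": fish.mass_g})
    return trace, truth


def simulate_background_trial(chamber: ChamberSpec, config: SimulationConfig,
                              when: str, seed_key: int = 0) -> O2Trace:
    """Empty-chamber trial: three measurement periods of bacterial respiration only.

    ``when='pre'`` consumes at ``background_rate_start``, ``when='post'``
    at ``background_rate_end`` (rates are anchored to trial start/end).
    ``seed_key`` distinguishes the background runs of different trials.
    """
    if when not in ("pre", "post"):
        raise ValueError("when must be 'pre' or 'post'")
    rate = (config.background_rate_start if when == "pre"
            else config.background_rate_end)
    rng = np.random.default_rng([config.seed, 404, seed_key,
                                 0 if when == "pre" else 1])
    duration_s = 3 * chamber.measure_duration + 2 * chamber.flush_duration
    t, o2, phase = _integrate_trial(
        chamber, v_eff=chamber.inner_volume, floor=rate, amplitude=0.0,
        tau_h=1.0, bg0=0.0, bg1=0.0, duration_s=duration_s,
        activity=np.zeros(3), flush_tau_s=config.flush_time_constant,
        rng=rng, optode_sd=config.optode_noise_sd)
    return O2Trace(t, o2, phase, chamber=chamber, meta={"background": when})


@dataclass
class TrialSim:
    """One fish-by-condition trial bundle with its background runs and truth."""

    fish: FishRecord
    condition: str
    trace: O2Trace
    bg_pre: O2Trace
    bg_post: O2Trace
    truth: TruthRecord


@dataclass
class CohortSim:
    """A full simulated study: trials, ground truth, and morphometrics."""

    config: SimulationConfig
    chamber: ChamberSpec
    fish: list[FishRecord]
    trials: list[TrialSim]
    truth_table: pd.DataFrame
    fish_table: pd.DataFrame


def _draw_cohort_fish(config: SimulationConfig) -> list[FishRecord]:
    rng = np.random.default_rng([config.seed, 303])
    fish: list[FishRecord] = []
    for holding, prefix in (("shoal", "sh"), ("solitary", "so")):
        for i in range(config.n_fish_per_treatment):
            mass = float(np.clip(rng.normal(config.mass_mean, config.mass_sd),
                                 0.2 * config.mass_mean, None))
            length = float(np.clip(rng.normal(config.length_mean, config.length_sd),
                                   0.2 * config.length_mean, None))
            g1, g2 = rng.normal(0.0, config.growth_noise_sd, size=2)
            loss = config.mass_loss_solitary_week1 if holding == "solitary" else 0.0
            m1 = mass * (1 - loss) * (1 + g1)
            m2 = m1 * (1 + g2)
            fish.append(FishRecord(
                fish_id=f"{prefix}{i + 1:02d}", mass_g=mass, length_cm=length,
                holding=holding,
                weeks={0: (mass, length), 1: (m1, length), 2: (m2, length)}))
    return fish


def simulate_cohort(config: SimulationConfig,
                    chamber: ChamberSpec | None = None) -> CohortSim:
    """Simulate the whole study: each fish tested once solitary and once with a shoal.

    Every fish trial gets its own pre/post empty-chamber background pair
    (2 fish trials and 4 background traces per fish).
    """
    chamber = chamber or ChamberSpec()
    fish = _draw_cohort_fish(config)
    trials: list[TrialSim] = []
    truth_rows = []
    for f in fish:
        truth = fish_truth(config, f)
        for condition in CONDITIONS:
            key = (_crc(f.fish_id) + CONDITIONS.index(condition)) % (2**31)
            bg_pre = simulate_background_trial(chamber, config, "pre", seed_key=key)
            bg_post = simulate_background_trial(chamber, config, "post", seed_key=key)
            trace, _ = simulate_trial(chamber, f, condition, config)
            trials.append(TrialSim(f, condition, trace, bg_pre, bg_post, truth))
        truth_rows.append({
            "fish_id": f.fish_id, "holding": f.holding, "mass_g": f.mass_g,
            "length_cm": f.length_cm,
            "floor_solitary": truth.floor_solitary,
            "floor_shoal": truth.floor_shoal,
            "shoal_effect": truth.shoal_effect,
            "stress_amplitude": truth.stress_amplitude,
            "stress_tau_h": truth.stress_tau_h,
            "stabilization_solitary_h": truth.stabilization_time("solitary"),
            "stabilization_shoal_h": truth.stabilization_time("shoal"),
            "background_start": truth.background_start,
            "background_end": truth.background_end,
        })
    return CohortSim(config=config, chamber=chamber, fish=fish, trials=trials,
                     truth_table=pd.DataFrame(truth_rows),
                     fish_table=fish_table(fish))


def write_cohort(sim: CohortSim, outdir: str | Path) -> None:
    """Write a simulated cohort to disk: trace CSVs, truth/fish tables, config YAML."""
    from .traceio import write_trace

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for trial in sim.trials:
        stem = f"{trial.fish.fish_id}_{trial.condition}"
        write_trace(trial.trace, out / f"{stem}.csv")
        write_trace(trial.bg_pre, out / f"{stem}_bg_pre.csv")
        write_trace(trial.bg_post, out / f"{stem}_bg_post.csv")
    sim.truth_table.to_csv(out / "truth.csv", index=False)
    sim.fish_table.to_csv(out / "fish.csv", index=False)
    config_to_yaml(sim.config, out / "config.yaml")
    config_to_yaml(sim.chamber, out / "chamber.yaml")


def config_to_yaml(obj, path: str | Path) -> None:
    """Serialise a ChamberSpec or SimulationConfig to YAML."""
    data = asdict(obj)
    data["__type__"] = type(obj).__name__
    Path(path).write_text(yaml.safe_dump(_pytypes(data)), encoding="utf-8")


def _pytypes(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, np.generic):
            v = v.item()
        out[k] = v
    return out


def config_from_yaml(path: str | Path):
    """Inverse of :func:`config_to_yaml`."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    kind = data.pop("__type__", "SimulationConfig")
    cls = {"ChamberSpec": ChamberSpec, "SimulationConfig": SimulationConfig}[kind]
    if "shoal_effect_range" in data and isinstance(data["shoal_effect_range"], list):
        data["shoal_effect_range"] = tuple(data["shoal_effect_range"])
    return cls(**data)
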