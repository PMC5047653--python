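"""Respirometry chamber geometry and cycle timing.

The measurement apparatus is a two-chamber intermittent-flow respirometer:
an inner chamber holding the focal fish (sealed during measurement periods,
flushed with oxygen-saturated water between them) and an outer chamber that
can hold shoal-mates supplying visual and olfactory cues.  Only the inner
chamber enters the oxygen mass balance; the outer chamber acts through the
treatment effect alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PhysicallyImpossibleError

#: Dissolved O2 concentration (mg L^-1) of air-saturated seawater at
#: 29 degC and 35 ppt salinity, from the Garcia & Gordon (1992) solubility
#: fit.  Defines the 100% air-saturation scale; override via ChamberSpec
#: for other temperatures or salinities.
O2_SAT_29C_35PPT = 6.236


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and timing of one intermittent-flow respirometry setup.

    Parameters
    ----------
    inner_volume : float
        Volume of the sealed respirometry chamber plus tubing, litres.
    outer_volume : float
        Volume of the shoal-mate holding chamber, litres (context only).
    measure_duration : float
        Length of each sealed measurement period, seconds.
    flush_duration : float
        Length of each flush period, seconds.
    sample_interval : float
        Optode sampling interval, seconds.
    temperature : float
        Water temperature, degrees Celsius.
    o2_full_saturation : float
        Dissolved O2 at 100% air saturation, mg L^-1.
    """

    inner_volume: float = 0.100
    outer_volume: float = 1.10
    measure_duration: float = 540.0
    flush_duration: float = 180.0
    sample_interval: float = 2.0
    temperature: float = 29.0
    o2_full_saturation: float = O2_SAT_29C_35PPT

    def __post_init__(self) -> None:
        for name in ("inner_volume", "outer_volume", "measure_duration",
                     "flush_duration", "sample_interval", "o2_full_saturation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sample_interval > self.measure_duration / 10:
            raise ValueError(
                "sample_interval must not exceed measure_duration/10 "
                "(too few samples per period for a slope fit)")

    @property
    def cycle_duration(self) -> float:
        """Length of one full measure+flush cycle, seconds."""
        return self.measure_duration + self.flush_duration

    def effective_volume(self, fish_mass_g: float = 0.0,
                         subtract_fish_volume: bool = True) -> float:
        """Water volume of the sealed chamber with a fish inside, litres.

        Fish body volume is subtracted assuming a tissue density of
        1 g mL^-1; set ``subtract_fish_volume=False`` to use the raw
        chamber volume.
        """
        if fish_mass_g < 0:
            raise ValueError("fish mass must be non-negative")
        if fish_mass_g >= self.inner_volume * 1000.0:
            raise PhysicallyImpossibleError(
                f"fish of {fish_mass_g} g cannot fit in a "
                f"{self.inner_volume * 1000:.0f} mL chamber")
        if not subtract_fish_volume:
            return self.inner_volume
        return self.inner_volume - fish_mass_g / 1000.0
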