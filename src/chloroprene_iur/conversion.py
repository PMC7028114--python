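"""Dose and exposure conversions.

Two distinct conversion jobs live here:

* turning an internal-dose point of departure (µmole chloroprene
  metabolized per g lung per day) into a human-equivalent continuous air
  concentration, via the PBPK-derived per-ppm factor; and
* turning occupational cumulative exposures (ppm-years) into
  lifetime-average residential concentrations (µg/m³) for the
  excess-cancer reality check.

All conversions are linear; display rounding (3 significant figures for
ppm, nearest integer for µg/m³) is applied only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ExposureScenario",
    "internal_to_human_ppm",
    "ppm_to_ugm3",
    "derive_conversion_factor",
    "lifetime_concentration",
    "PPM_TO_UGM3",
]

#: µg/m³ per ppm of chloroprene.
PPM_TO_UGM3 = 3620.0


@dataclass(frozen=True)
class ExposureScenario:
    """Occupational-to-continuous adjustment fractions.

    ``ventilation_fraction`` is the occupational share of daily air intake
    (10 of 20 m³), ``days_fraction`` the work-week share (5/7), and
    ``hours_fraction`` the work-day share (8/24) used for the
    continuous-equivalent form of the PBPK conversion factor.  Cumulative
    ppm-years are spread over ``lifetime_years``.
    """

    ventilation_fraction: float = 10.0 / 20.0
    days_fraction: float = 5.0 / 7.0
    lifetime_years: float = 70.0
    hours_fraction: float = 8.0 / 24.0

    def __post_init__(self) -> None:
        for name in ("ventilation_fraction", "days_fraction", "hours_fraction"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.lifetime_years <= 0:
            raise ValueError("lifetime_years must be > 0")


def internal_to_human_ppm(pod: float, factor: float = 0.0106) -> float:
    """Human-equivalent continuous concentration (ppm) for an internal-dose POD.

    ``factor`` is the internal dose produced by 1 ppm of continuous human
    exposure (µmole/g-lung/day per ppm).
    """
    if pod < 0:
        raise ValueError("pod must be >= 0")
    if factor <= 0:
        raise ValueError("conversion factor must be > 0")
    return pod / factor


def ppm_to_ugm3(x: float, constant: float = PPM_TO_UGM3) -> float:
    """Convert a chloroprene air concentration from ppm to µg/m³."""
    if x < 0:
        raise ValueError("concentration must be >= 0")
    return x * constant


def derive_conversion_factor(
    occupational_internal: float,
    occupational_ppm: float,
    scenario: ExposureScenario | None = None,
) -> float:
    """Per-ppm continuous conversion factor from an occupational PBPK simulation.

    An occupational exposure of ``occupational_ppm`` (8 h/day equivalent)
    producing ``occupational_internal`` µmole/g-lung/day corresponds to a
    continuous exposure of ``occupational_ppm * hours_fraction`` ppm, so
    the continuous factor is internal dose over that equivalent.
    """
    scenario = scenario or ExposureScenario()
    if occupational_internal <= 0 or occupational_ppm <= 0:
        raise ValueError("occupational inputs must be > 0")
    denom = occupational_ppm * scenario.hours_fraction
    if denom == 0:
        raise ZeroDivisionError("zero continuous-equivalent exposure")
    return occupational_internal / denom


def lifetime_concentration(
    cumulative_ppm_years: float, scenario: ExposureScenario | None = None
) -> float:
    """Lifetime-average residential concentration (µg/m³) for a cumulative
    occupational exposure in ppm-years."""
    scenario = scenario or ExposureScenario()
    if cumulative_ppm_years < 0:
        raise ValueError("cumulative exposure must be >= 0")
    ppm = (
        cumulative_ppm_years
        * scenario.ventilation_fraction
        * scenario.days_fraction
        / scenario.lifetime_years
    )
    return ppm_to_ugm3(ppm)
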