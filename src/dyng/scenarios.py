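"""Step-change scenario presets for the simulator.

Two protocols mirror the benchmark experiment used to stress-test the
calibration: step changes in wind speed (0.1, 0.4, 0.9 m s⁻¹ in darkness)
and in light intensity (0, 100, 300, 500 µmol m⁻² s⁻¹ at constant fan
speed). In the light protocol the lamp also warms and dries the air in the
enclosure — the dominant reason the raw conductance index drifts under
light — so air temperature rises and relative humidity falls modestly with
each PPFD step.
"""

from __future__ import annotations

from .ebalance import ScenarioStep

__all__ = ["wind_step_scenario", "light_step_scenario",
           "reference_protocol"]

BASE_T_AIR_C = 20.0
BASE_RH = 0.40

#: per-step air warming (K) and drying (RH fraction) under the lamp
_LIGHT_STEPS = (
    (0.0, 0.0, 0.0),
    (100.0, 0.6, -0.01),
    (300.0, 1.5, -0.03),
    (500.0, 2.4, -0.05),
)


def wind_step_scenario(duration: float = 120.0, noise_sd: float = 0.03,
                       T_air_C: float = BASE_T_AIR_C,
                       RH_air: float = BASE_RH) -> list[ScenarioStep]:
    """Wind steps 0.1 → 0.4 → 0.9 m s⁻¹ in darkness."""
    return [
        ScenarioStep(duration=duration, wind=w, PPFD=0.0,
                     T_air=T_air_C + 273.15, RH_air=RH_air,
                     noise_sd=noise_sd)
        for w in (0.1, 0.4, 0.9)
    ]


def light_step_scenario(duration: float = 120.0, noise_sd: float = 0.03,
                        wind: float = 0.4, T_air_C: float = BASE_T_AIR_C,
                        RH_air: float = BASE_RH) -> list[ScenarioStep]:
    """PPFD steps 0 → 100 → 300 → 500 µmol m⁻² s⁻¹ at constant wind, with
    lamp-driven air warming/drying per step."""
    return [
        ScenarioStep(duration=duration, wind=wind, PPFD=ppfd,
                     T_air=T_air_C + dT + 273.15,
                     RH_air=RH_air + dRH, noise_sd=noise_sd)
        for ppfd, dT, dRH in _LIGHT_STEPS
    ]


def reference_protocol(duration: float = 120.0,
                       noise_sd: float = 0.03) -> list[ScenarioStep]:
    """Wind steps in darkness followed by light steps at 0.4 m s⁻¹."""
    return (wind_step_scenario(duration, noise_sd)
            + light_step_scenario(duration, noise_sd))
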