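"""Astroglial-coverage scenarios.

Four patterns of perisynaptic glutamate-transporter arrangement, one per
sector of the extrasynaptic environment:

* ``baseline`` — transporters at reference density over the full occupied belt.
* ``i``  — partial astroglial withdrawal conserving transporter number: the
  occupied membrane area is halved (the remaining coverage sits on the
  postsynaptic flank, beside the extrasynaptic NMDAR cluster) and the local
  density doubles.
* ``ii`` — withdrawal with transporter loss: area halved as in (i) but density
  unchanged, so the total number halves.
* ``iii`` — lateral re-arrangement: area and number conserved, but the
  occupied patch shifts azimuthally to one flank of the NMDAR cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import ConfigurationError

__all__ = ["ScenarioSpec", "SCENARIOS", "get_scenario"]


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    density_multiplier: float
    area_multiplier: float
    lateral_shift: bool = False

    def __post_init__(self) -> None:
        expected = {
            "baseline": (1.0, 1.0, False),
            "i": (2.0, 0.5, False),
            "ii": (1.0, 0.5, False),
            "iii": (1.0, 1.0, True),
        }
        if self.scenario_id in expected:
            if (
                self.density_multiplier,
                self.area_multiplier,
                self.lateral_shift,
            ) != expected[self.scenario_id]:
                raise ConfigurationError(
                    f"scenario {self.scenario_id!r} must have "
                    f"(density, area, shift) = {expected[self.scenario_id]}"
                )
        if self.density_multiplier < 0 or self.area_multiplier <= 0:
            raise ConfigurationError("invalid scenario multipliers")


SCENARIOS: dict[str, ScenarioSpec] = {
    "baseline": ScenarioSpec("baseline", 1.0, 1.0, False),
    "i": ScenarioSpec("i", 2.0, 0.5, False),
    "ii": ScenarioSpec("ii", 1.0, 0.5, False),
    "iii": ScenarioSpec("iii", 1.0, 1.0, True),
}


def get_scenario(scenario_id: str) -> ScenarioSpec:
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {scenario_id!r}; choose from {sorted(SCENARIOS)}"
        ) from None
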