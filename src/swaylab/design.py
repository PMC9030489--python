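"""Factorial study design: postures, surfaces, loads, sensor placements.

The study design is a full factorial within-subject layout with three
work-related factors: Working Posture (WP, six levels P1..P6), Surface
Slope (SS, flat vs. inclined) and Load Carriage (LC, 0 kg vs. 10 kg),
giving 24 distinct task conditions. Eight accelerometer placements are
analysed: pelvis, sternum (T8), both shoulders, both upper legs and both
lower legs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

POSTURES: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "P6")
SURFACES: tuple[str, ...] = ("flat", "inclined")
LOADS: tuple[str, ...] = ("0kg", "10kg")

#: Default accelerometer placements (body segments).
SENSORS: tuple[str, ...] = (
    "pelvis",
    "T8",
    "shoulder_L",
    "shoulder_R",
    "upper_leg_L",
    "upper_leg_R",
    "lower_leg_L",
    "lower_leg_R",
)

#: Sensor configurations used by the classification stage.
SENSOR_CONFIGS: dict[str, tuple[str, ...]] = {
    "SC1": SENSORS,
    "SC2": ("pelvis", "T8", "shoulder_L", "shoulder_R"),
    "SC3": ("pelvis", "T8"),
    "pelvis": ("pelvis",),
}


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the 6 (posture) x 2 (surface) x 2 (load) factorial."""

    posture: str
    surface: str
    load: str

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface {self.surface!r}")
        if self.load not in LOADS:
            raise ValueError(f"unknown load {self.load!r}")

    @property
    def inclined(self) -> bool:
        return self.surface == "inclined"

    @property
    def loaded(self) -> bool:
        return self.load == "10kg"

    @property
    def posture_index(self) -> int:
        return POSTURES.index(self.posture)

    def label(self) -> str:
        return f"{self.posture}_{self.surface}_{self.load}"


def enumerate_conditions() -> list[Condition]:
    """All 24 task conditions in deterministic posture-major order.

    Ordering is posture-major, then surface (flat first), then load
    (0 kg first), so the first condition is (P1, flat, 0kg) and the last
    (P6, inclined, 10kg).
    """
    return [
        Condition(p, s, l) for p, s, l in product(POSTURES, SURFACES, LOADS)
    ]
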