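"""Simulation parameters and the 12-condition preset grid.

Conditions are labelled ``<row>-<level>`` where the row encodes the physics
switches (1: isotropic, no motors; 2: anisotropic friction, no motors;
3: isotropic with motors; 4: anisotropic friction with motors) and the level
the crosslinker count (L/M/H).  Condition 4-M is the one that self-organizes
periodic circumferential cables; 1-M/1-H give isolated elliptical
nanoclusters; 3-M/3-H give a labyrinth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

#: side of one rendering box (µm); 69 boxes cover the 3 µm simulation patch
RENDER_PITCH_UM = 0.04325
#: pixels per rendered frame side
RENDER_GRID = 69


@dataclass
class SimulationParams:
    """Physical and numerical parameters of the overdamped filament model.

    Lengths are in µm, times in s.  Drag coefficients set the unit of force;
    only ratios force/drag enter the dynamics.  ``gamma_y > gamma_x`` models
    higher friction along the circumferential axis (anisotropic cortical
    tension); ``temperature_noise`` is an effective kT so each bead diffuses
    with D = temperature_noise / gamma along each axis.
    """

    box_size: float = 3.0
    n_filaments: int = 400
    beads_per_filament: int = 6
    bead_spacing: float = 0.05           # filament length 0.25 µm
    n_crosslinkers: int = 800
    n_motors: int = 0
    k_stretch: float = 100.0
    k_bend: float = 2.0
    k_connector: float = 25.0
    connector_rest_length: float = 0.035  # alpha-actinin crosslink span
    motor_rest_length: float = 0.035      # motor attachment span
    motor_capture_radius: float = 0.1
    motor_end_dwell: bool = False         # dwell at the barbed end vs detach
    bind_rate: float = 50.0
    unbind_rate_crosslinker: float = 0.5
    unbind_rate_motor: float = 2.0
    capture_radius: float = 0.1
    motor_speed: float = 0.2              # toward barbed end, µm/s
    filament_turnover_rate: float = 0.05
    crosslinker_turnover_rate: float = 0.0
    gamma_x: float = 1.0
    gamma_y: float = 1.0
    temperature_noise: float = 5.0e-4
    dt: float = 1.0e-3
    duration: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_size <= 0:
            raise ValueError("box_size must be positive")
        if self.beads_per_filament < 2:
            raise ValueError("beads_per_filament must be >= 2")
        if self.gamma_x <= 0 or self.gamma_y <= 0:
            raise ValueError("drag coefficients must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("bind_rate", "unbind_rate_crosslinker",
                     "unbind_rate_motor", "filament_turnover_rate",
                     "crosslinker_turnover_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_filaments < 0 or self.n_crosslinkers < 0 or self.n_motors < 0:
            raise ValueError("counts must be non-negative")

    @property
    def filament_length(self) -> float:
        return (self.beads_per_filament - 1) * self.bead_spacing

    @property
    def anisotropy(self) -> float:
        return self.gamma_y / self.gamma_x

    def replace(self, **overrides) -> "SimulationParams":
        return dataclasses.replace(self, **overrides)


#: crosslinker counts for the Low / Moderate / High columns
CROSSLINKER_LEVELS = {"L": 60, "M": 800, "H": 1600}
#: motor count used whenever a row includes motors
MOTOR_COUNT = 400
#: drag ratio gamma_y / gamma_x in the anisotropic rows
ANISOTROPY_FACTOR = 40.0


@dataclass(frozen=True)
class ConditionPreset:
    """One cell of the condition grid: row switches x crosslinker level."""

    label: str                 # e.g. "4-M"
    anisotropy: bool
    motors: bool
    crosslinker_level: str     # "L" | "M" | "H"

    def params(self, **overrides) -> SimulationParams:
        base = SimulationParams(
            n_crosslinkers=CROSSLINKER_LEVELS[self.crosslinker_level],
            n_motors=MOTOR_COUNT if self.motors else 0,
            gamma_y=ANISOTROPY_FACTOR if self.anisotropy else 1.0,
        )
        return base.replace(**overrides)


def _build_grid() -> dict[str, ConditionPreset]:
    rows = {
        "1": (False, False),
        "2": (True, False),
        "3": (False, True),
        "4": (True, True),
    }
    grid = {}
    for row, (aniso, motors) in rows.items():
        for level in ("L", "M", "H"):
            label = f"{row}-{level}"
            grid[label] = ConditionPreset(label, aniso, motors, level)
    return grid


PRESETS: dict[str, ConditionPreset] = _build_grid()


def get_preset(label: str) -> ConditionPreset:
    try:
        return PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown condition {label!r}; expected one of {sorted(PRESETS)}"
        ) from None
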