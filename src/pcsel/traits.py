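"""Trait metadata: names, units, desirability direction, valid ranges.

Every downstream stage (validation, index orientation, selection-gain
direction flags) looks up traits here.  The packaged default registry covers
the six fall-armyworm resistance parameters scored in screen-house maize
trials — leaf feeding damage at 7/14/21 days after infestation (LD1–LD3,
ordinal 1–9), ear damage (ED, 1–9), ear rot incidence (ER, percent of
harvested ears), grain yield (GY, t/ha at 12.5 % moisture) — plus the derived
mean leaf-damage score LD_AV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "Direction",
    "TraitSpec",
    "default_registry",
    "load_registry",
    "save_registry",
]


class Direction(str, Enum):
    """Desirability direction of a trait."""

    lower_better = "lower_better"
    higher_better = "higher_better"


@dataclass(frozen=True)
class TraitSpec:
    """Metadata for a single trait.

    Parameters
    ----------
    name : str
        Trait identifier, used as the CSV column name.
    units : str
        Measurement units (free text, e.g. ``"t/ha"`` or ``"score 1-9"``).
    direction : Direction
        Whether smaller or larger values are desirable.
    valid_range : tuple of float
        Closed interval of admissible values on the measurement scale.
    score_scale : bool
        True for ordinal visual-rating scores (1–9 scales).
    """

    name: str
    units: str
    direction: Direction
    valid_range: tuple[float, float]
    score_scale: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(
                f"trait {self.name!r}: valid_range lower bound must be < upper "
                f"bound, got {self.valid_range}"
            )

    @property
    def lower_better(self) -> bool:
        return self.direction is Direction.lower_better

    def in_range(self, value: float) -> bool:
        lo, hi = self.valid_range
        return lo <= value <= hi


def default_registry() -> dict[str, TraitSpec]:
    """Packaged trait registry for FAW screening trials.

    Damage and rot traits are lower-better; grain yield is higher-better.
    Ear rot is kept on the 0–100 percent scale.
    """
    specs = [
        TraitSpec("LD1", "score 1-9", Direction.lower_better, (1.0, 9.0), True),
        TraitSpec("LD2", "score 1-9", Direction.lower_better, (1.0, 9.0), True),
        TraitSpec("LD3", "score 1-9", Direction.lower_better, (1.0, 9.0), True),
        TraitSpec("LD_AV", "score 1-9", Direction.lower_better, (1.0, 9.0), True),
        TraitSpec("ED", "score 1-9", Direction.lower_better, (1.0, 9.0), True),
        TraitSpec("ER", "%", Direction.lower_better, (0.0, 100.0)),
        TraitSpec("GY", "t/ha", Direction.higher_better, (0.0, 30.0)),
    ]
    return {s.name: s for s in specs}


def load_registry(path: str | Path) -> dict[str, TraitSpec]:
    """Read a trait registry from a YAML or JSON mapping.

    Expected form::

        GY: {units: "t/ha", direction: higher_better, range: [0, 30]}
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"trait registry in {path} must be a mapping")
    registry: dict[str, TraitSpec] = {}
    for name, cfg in raw.items():
        registry[name] = TraitSpec(
            name=name,
            units=str(cfg.get("units", "")),
            direction=Direction(cfg["direction"]),
            valid_range=tuple(float(v) for v in cfg["range"]),
            score_scale=bool(cfg.get("score_scale", False)),
        )
    return registry


def save_registry(registry: dict[str, TraitSpec], path: str | Path) -> Path:
    path = Path(path)
    raw = {
        s.name: {
            "units": s.units,
            "direction": s.direction.value,
            "range": list(s.valid_range),
            "score_scale": s.score_scale,
        }
        for s in registry.values()
    }
    path.write_text(yaml.safe_dump(raw, sort_keys=False))
    return path
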