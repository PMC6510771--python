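"""Pool and platform geometry for Morris water-maze trials.

Coordinates are in centimetres with the pool centre at the origin and the
y axis pointing up.  Camera trackers that export pixel coordinates must be
converted upstream (the CLI exposes a linear scale + offset calibration).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple


class Point(NamedTuple):
    """A 2-D position in centimetres."""

    x: float
    y: float

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other[0], self.y - other[1])


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of one water-maze setup.

    Defaults describe a 160 cm diameter pool with a 10 cm hidden platform
    centred in one quadrant and a 60 s trial cap.  Animals that never reach
    the platform are scored with the full ``max_trial_s``.
    """

    pool_center: Point = Point(0.0, 0.0)
    pool_radius: float = 80.0
    platform_center: Point = Point(28.28, 28.28)
    platform_radius: float = 5.0
    max_trial_s: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pool_center", Point(*self.pool_center))
        object.__setattr__(self, "platform_center", Point(*self.platform_center))
        if not self.pool_radius > self.platform_radius > 0:
            raise ValueError(
                "require pool_radius > platform_radius > 0, got "
                f"{self.pool_radius} and {self.platform_radius}"
            )
        reach = self.pool_center.distance_to(self.platform_center) + self.platform_radius
        if reach > self.pool_radius + 1e-9:
            raise ValueError("platform is not fully inside the pool")
        if not self.max_trial_s > 0:
            raise ValueError("max_trial_s must be positive")

    @classmethod
    def from_json(cls, path: str) -> "ArenaConfig":
        """Load an arena description from a JSON file.

        Expected keys: ``pool_center`` ([x, y]), ``pool_radius``,
        ``platform_center`` ([x, y]), ``platform_radius``, ``max_trial_s``.
        Missing keys fall back to the defaults above.
        """
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        kwargs = {}
        for key in ("pool_center", "platform_center"):
            if key in raw:
                kwargs[key] = Point(*raw[key])
        for key in ("pool_radius", "platform_radius", "max_trial_s"):
            if key in raw:
                kwargs[key] = float(raw[key])
        return cls(**kwargs)

    def to_json(self, path: str) -> None:
        payload = {
            "pool_center": list(self.pool_center),
            "pool_radius": self.pool_radius,
            "platform_center": list(self.platform_center),
            "platform_radius": self.platform_radius,
            "max_trial_s": self.max_trial_s,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
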