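"""The four swim-path deviation indices.

Each index compares the actual unit-time displacement C_n -> C_{n+1} with the
*optimal route* — the straight segment from the current position C_n (or, for
index 4, from the fixed entry point C_0) to the platform centre B — and sums
the per-step deviation over the whole search period:

* **index 1** (cm): lateral deviation — length of the displacement component
  perpendicular to the current optimal route.
* **index 2** (degrees): offset angle — angle between the displacement and
  the current optimal route, in [0, 180].
* **index 3** (cm): correction length — length of the vector needed to rotate
  the displacement onto the optimal route at equal length; the chord
  2 L sin(theta / 2) for a step of length L at offset angle theta.
* **index 4** (cm): lateral deviation relative to the *initial* optimal route
  C_0 -> B, whose direction is fixed for the whole trial.

Sums run from trial start up to (and including the step ending at) the first
platform contact, or over the whole capped trial for non-finders.  A low sum
indicates a goal-directed, map-guided search; thigmotaxis and random search
accumulate large deviations.

Degenerate steps (zero displacement, or a step taken from the platform centre
itself) contribute 0 to every index by default: a stationary float adds no
directional deviation.  ``strict_angles=True`` instead scores the offset
angle of such steps as 90 degrees, reading the defining case expression of
the angle's cosine literally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .arena import ArenaConfig, Point
from .trajectory import Trajectory, resample_unit_time, truncate_at_escape

#: default analysis time step (s); any input rate is resampled onto it
DEFAULT_UNIT_TIME_S = 0.2

#: column order of the per-trial indices table
INDEX_COLUMNS = (
    "animal_id",
    "trial_id",
    "escape_latency_s",
    "index1_cm",
    "index2_deg",
    "index3_cm",
    "index4_cm",
    "path_length_cm",
    "mean_speed_cm_s",
)

#: the five per-trial measures compared throughout the evaluation layer
MEASURES = ("escape_latency_s", "index1_cm", "index2_deg", "index3_cm", "index4_cm")


@dataclass(frozen=True)
class StepGeometry:
    """One unit-time step C_n -> C_{n+1} with its reference points."""

    c_n: Point
    c_next: Point
    b: Point
    c0: Point

    @property
    def step_length(self) -> float:
        return Point(*self.c_n).distance_to(self.c_next)


@dataclass(frozen=True)
class IndexResult:
    """Per-trial deviation indices plus classical path statistics."""

    escape_latency_s: float
    index1_cm: float
    index2_deg: float
    index3_cm: float
    index4_cm: float
    path_length_cm: float
    mean_speed_cm_s: float
    escaped: bool = True
    n_steps: int = 0
    animal_id: str = ""
    trial_id: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def _cross_dot(step: StepGeometry, ref: Point) -> tuple[float, float, float]:
    """(cross, dot, |ref - c_n... |) of the step against the route c->ref."""
    dx = step.c_next[0] - step.c_n[0]
    dy = step.c_next[1] - step.c_n[1]
    rx = ref[0] - step.c_n[0]
    ry = ref[1] - step.c_n[1]
    return dx * ry - dy * rx, dx * rx + dy * ry, math.hypot(rx, ry)


def lateral_deviation(step: StepGeometry) -> float:
    """Index-1 summand: |step component perpendicular to the route C_n -> B|.

    Zero when the animal sits exactly on the platform centre (the route is
    undefined there).
    """
    cross, _, dist_b = _cross_dot(step, step.b)
    if dist_b == 0.0:
        return 0.0
    return abs(cross) / dist_b


def offset_angle(step: StepGeometry, strict: bool = False) -> float:
    """Index-2 summand: angle between the step and the route C_n -> B (deg).

    Computed as atan2(|cross|, dot), the well-conditioned equivalent of the
    arccos of the normalised dot product.  Degenerate steps score 0 by
    default, 90 with ``strict=True`` (see module docstring).
    """
    cross, dot, dist_b = _cross_dot(step, step.b)
    if step.step_length == 0.0 or dist_b == 0.0:
        return 90.0 if strict else 0.0
    return math.degrees(math.atan2(abs(cross), dot))


def correction_length(step: StepGeometry, strict: bool = False) -> float:
    """Index-3 summand: chord 2 L sin(theta/2) rotating the step onto the route.

    Degenerate steps contribute 0 (their defining zero branch), under either
    angle convention.
    """
    length = step.step_length
    cross, dot, dist_b = _cross_dot(step, step.b)
    if length == 0.0 or dist_b == 0.0:
        return 0.0
    theta = math.atan2(abs(cross), dot)
    return 2.0 * length * math.sin(theta / 2.0)


def initial_lateral_deviation(step: StepGeometry) -> float:
    """Index-4 summand: |step component perpendicular to the entry route C_0 -> B|.

    The reference direction is fixed at the entry point for the whole trial.
    """
    dx = step.c_next[0] - step.c_n[0]
    dy = step.c_next[1] - step.c_n[1]
    rx = step.b[0] - step.c0[0]
    ry = step.b[1] - step.c0[1]
    dist = math.hypot(rx, ry)
    if dist == 0.0:
        raise ValueError("entry point coincides with the platform centre; not a valid trial")
    return abs(dx * ry - dy * rx) / dist


def compute_indices(
    traj: Trajectory,
    config: ArenaConfig,
    unit_time_s: float = DEFAULT_UNIT_TIME_S,
    strict_angles: bool = False,
    resample: bool = True,
) -> IndexResult:
    """Compute the four deviation indices and classical measures for one trial.

    The trajectory is resampled onto the analysis grid (``resample=False``
    skips this for data already on the grid), truncated at first platform
    contact or at the trial cap, and the per-step deviations are summed over
    the remaining unit-time steps.  Mean speed is path length over escape
    latency, the same search period the indices cover.
    """
    if resample:
        traj = resample_unit_time(traj, unit_time_s)
    traj, outcome = truncate_at_escape(traj, config)

    xy = traj.xy
    b = np.asarray(config.platform_center, dtype=float)
    c0 = xy[0]
    if math.hypot(*(b - c0)) == 0.0:
        raise ValueError("entry point coincides with the platform centre; not a valid trial")

    d = np.diff(xy, axis=0)                      # steps C_n -> C_{n+1}
    length = np.hypot(d[:, 0], d[:, 1])
    rb = b - xy[:-1]                             # routes C_n -> B
    dist_b = np.hypot(rb[:, 0], rb[:, 1])
    cross = d[:, 0] * rb[:, 1] - d[:, 1] * rb[:, 0]
    dot = d[:, 0] * rb[:, 0] + d[:, 1] * rb[:, 1]

    on_platform_center = dist_b == 0.0
    degenerate = (length == 0.0) | on_platform_center

    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(on_platform_center, 0.0, np.abs(cross) / np.where(dist_b == 0, 1.0, dist_b))
        theta = np.where(
            degenerate,
            math.pi / 2.0 if strict_angles else 0.0,
            np.arctan2(np.abs(cross), dot),
        )
    corr = np.where(degenerate, 0.0, 2.0 * length * np.sin(theta / 2.0))

    u0 = b - c0
    lat0 = np.abs(d[:, 0] * u0[1] - d[:, 1] * u0[0]) / math.hypot(*u0)

    path_length = float(length.sum())
    latency = outcome.escape_latency_s
    return IndexResult(
        escape_latency_s=latency,
        index1_cm=float(lat.sum()),
        index2_deg=float(np.degrees(theta).sum()),
        index3_cm=float(corr.sum()),
        index4_cm=float(lat0.sum()),
        path_length_cm=path_length,
        mean_speed_cm_s=path_length / latency,
        escaped=outcome.escaped,
        n_steps=int(length.size),
        animal_id=traj.animal_id,
        trial_id=traj.trial_id,
    )


def indices_table(results: list[IndexResult]) -> pd.DataFrame:
    """Stack per-trial results into the standard indices table."""
    rows = [r.as_dict() for r in results]
    df = pd.DataFrame(rows)
    return df[list(INDEX_COLUMNS)]
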