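"""Synthetic swim-path generator.

Because raw water-maze tracking data are rarely deposited, this module
provides a seeded stand-in: a three-mode switching biased random walk that
reproduces the qualitative phenotypes seen in hidden-platform training —
goal-directed map-guided search (control-like), and wall-hugging /
poorly-oriented search with occasional floating (dementia-model-like).

Per unit-time step the animal is in one of three modes:

* **swim** — heading drawn from a von Mises distribution centred on the
  direction to the platform (concentration ``goal_bias_kappa``; 0 means a
  uniformly random heading), blended with the previous heading by
  ``turn_inertia``;
* **thigmotaxis** — heading along the pool-wall tangent nearest the current
  heading (wall following);
* **float** — near-zero speed, heading unchanged.

Speeds are truncated-normal draws; the position advances one step and is
reflected specularly off the pool wall.  A trial ends at first platform
contact or at the trial cap.  Everything is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arena import ArenaConfig, Point
from .trajectory import Trajectory


@dataclass(frozen=True)
class SwimParams:
    """Behavioural parameters of the switching biased walk."""

    mean_speed_cm_s: float = 20.0
    speed_sd: float = 3.0
    goal_bias_kappa: float = 2.5
    thigmotaxis_prob: float = 0.05
    float_prob: float = 0.02
    turn_inertia: float = 0.4
    unit_time_s: float = 0.2
    float_speed_cm_s: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.thigmotaxis_prob <= 1 and 0 <= self.float_prob <= 1):
            raise ValueError("mode probabilities must lie in [0, 1]")
        if self.thigmotaxis_prob + self.float_prob > 1:
            raise ValueError("thigmotaxis_prob + float_prob must not exceed 1")
        if self.mean_speed_cm_s < 0 or self.speed_sd < 0 or self.float_speed_cm_s < 0:
            raise ValueError("speeds must be non-negative")
        if self.goal_bias_kappa < 0:
            raise ValueError("goal_bias_kappa must be non-negative")
        if not 0 <= self.turn_inertia < 1:
            raise ValueError("turn_inertia must lie in [0, 1)")
        if self.unit_time_s <= 0:
            raise ValueError("unit_time_s must be positive")


#: goal-directed preset: strong platform bias, little wall following
CONTROL_PARAMS = SwimParams(goal_bias_kappa=2.5, thigmotaxis_prob=0.05, float_prob=0.02)

#: impaired preset: weak platform bias, frequent wall following and floating.
#: swim speed is slightly above the control preset so that, with the extra
#: floating, the realised group mean speeds match (studies report no
#: significant speed difference between lesioned and control animals)
MODEL_PARAMS = SwimParams(
    mean_speed_cm_s=21.0, goal_bias_kappa=0.5, thigmotaxis_prob=0.35, float_prob=0.08
)

#: per-training multiplicative growth of goal_bias_kappa (spatial learning);
#: control animals learn from kappa 2.5 to ~8 over 20 trainings, the
#: dementia-model preset only from 0.5 to ~1.2
CONTROL_LEARNING_RATE = (8.0 / 2.5) ** (1.0 / 19.0)
MODEL_LEARNING_RATE = (1.2 / 0.5) ** (1.0 / 19.0)


def _default_entries(arena: ArenaConfig) -> tuple[Point, ...]:
    """One release point per quadrant, on the pool wall."""
    cx, cy = arena.pool_center
    r = arena.pool_radius
    return tuple(
        Point(cx + r * math.cos(a), cy + r * math.sin(a))
        for a in (math.radians(deg) for deg in (135.0, 225.0, 315.0, 45.0))
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """A full simulated study: two groups trained repeatedly.

    Defaults mirror a typical vascular-dementia study design: 19 model and
    20 control animals, 4 rotating entry quadrants, 20 trainings over 5
    days, yielding 780 trials.
    """

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    n_model: int = 19
    n_control: int = 20
    n_trainings: int = 20
    seed: int = 0
    control_params: SwimParams = CONTROL_PARAMS
    model_params: SwimParams = MODEL_PARAMS
    control_learning_rate: float = CONTROL_LEARNING_RATE
    model_learning_rate: float = MODEL_LEARNING_RATE
    entry_points: tuple[Point, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_trainings < 1:
            raise ValueError("n_trainings must be at least 1")
        if self.n_model < 1 or self.n_control < 1:
            raise ValueError("need at least one animal per group")
        if self.entry_points is not None:
            pts = tuple(Point(*p) for p in self.entry_points)
            object.__setattr__(self, "entry_points", pts)

    def entries(self) -> tuple[Point, ...]:
        return self.entry_points or _default_entries(self.arena)

    @classmethod
    def from_json(cls, path: str) -> "ScenarioConfig":
        import json

        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        kwargs = {}
        if "arena" in raw:
            a = raw["arena"]
            kwargs["arena"] = ArenaConfig(
                pool_center=Point(*a.get("pool_center", (0.0, 0.0))),
                pool_radius=a.get("pool_radius", 80.0),
                platform_center=Point(*a.get("platform_center", (28.28, 28.28))),
                platform_radius=a.get("platform_radius", 5.0),
                max_trial_s=a.get("max_trial_s", 60.0),
            )
        for key in ("n_model", "n_control", "n_trainings", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("control_learning_rate", "model_learning_rate"):
            if key in raw:
                kwargs[key] = float(raw[key])
        for key in ("control_params", "model_params"):
            if key in raw:
                kwargs[key] = SwimParams(**raw[key])
        if "entry_points" in raw:
            kwargs["entry_points"] = tuple(Point(*p) for p in raw["entry_points"])
        return cls(**kwargs)


def _blend_heading(previous: float, target: float, inertia: float) -> float:
    """Weighted circular mean of the previous and target headings."""
    sx = inertia * math.cos(previous) + (1 - inertia) * math.cos(target)
    sy = inertia * math.sin(previous) + (1 - inertia) * math.sin(target)
    if sx == 0.0 and sy == 0.0:
        return target
    return math.atan2(sy, sx)


def simulate_trial(
    params: SwimParams,
    arena: ArenaConfig,
    entry: Point,
    seed: int | np.random.SeedSequence | np.random.Generator,
    animal_id: str = "",
    trial_id: str = "",
) -> Trajectory:
    """Simulate one trial; identical seed gives an identical trajectory."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cx, cy = arena.pool_center
    bx, by = arena.platform_center
    dt = params.unit_time_s
    px, py = float(entry[0]), float(entry[1])
    if math.hypot(px - cx, py - cy) > arena.pool_radius * (1 + 1e-9):
        raise ValueError("entry point lies outside the pool")

    heading = math.atan2(cy - py, cx - px)  # released facing away from the wall
    times = [0.0]
    points = [(px, py)]
    n_steps = int(round(arena.max_trial_s / dt))
    thig_noise_kappa = 15.0

    for k in range(1, n_steps + 1):
        mode = rng.random()
        if mode < params.float_prob:
            speed = max(rng.normal(params.float_speed_cm_s, params.float_speed_cm_s / 2), 0.0)
            # heading unchanged: the animal drifts
        elif mode < params.float_prob + params.thigmotaxis_prob:
            phi = math.atan2(py - cy, px - cx)
            tangents = (phi + math.pi / 2, phi - math.pi / 2)
            target = max(tangents, key=lambda a: math.cos(heading - a))
            target += rng.vonmises(0.0, thig_noise_kappa)
            heading = _blend_heading(heading, target, params.turn_inertia)
            speed = max(rng.normal(params.mean_speed_cm_s, params.speed_sd), 0.0)
        else:
            goal = math.atan2(by - py, bx - px)
            if params.goal_bias_kappa > 1e-9:
                target = goal + rng.vonmises(0.0, params.goal_bias_kappa)
            else:
                target = rng.uniform(-math.pi, math.pi)
            heading = _blend_heading(heading, target, params.turn_inertia)
            speed = max(rng.normal(params.mean_speed_cm_s, params.speed_sd), 0.0)

        px += speed * dt * math.cos(heading)
        py += speed * dt * math.sin(heading)
        r = math.hypot(px - cx, py - cy)
        if r > arena.pool_radius:
            # specular reflection: fold the radial overshoot back inside and
            # mirror the heading about the wall tangent
            new_r = max(min(2 * arena.pool_radius - r, arena.pool_radius), 0.0)
            ux, uy = (px - cx) / r, (py - cy) / r
            px, py = cx + ux * new_r, cy + uy * new_r
            vn = math.cos(heading) * ux + math.sin(heading) * uy
            vx = math.cos(heading) - 2 * vn * ux
            vy = math.sin(heading) - 2 * vn * uy
            heading = math.atan2(vy, vx)
        times.append(k * dt)
        points.append((px, py))
        if math.hypot(px - bx, py - by) <= arena.platform_radius:
            break

    return Trajectory(
        t=np.asarray(times),
        xy=np.asarray(points),
        record_frequency=1.0 / dt,
        animal_id=animal_id,
        trial_id=trial_id,
    )


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial with its provenance."""

    group: str
    animal_id: str
    training: int
    trajectory: Trajectory


def simulate_study(cfg: ScenarioConfig) -> list[TrialRecord]:
    """Simulate the full two-group training study.

    Entry quadrants rotate per training; ``goal_bias_kappa`` grows by the
    group's learning rate each training.  Each trial draws its random stream
    from ``SeedSequence(cfg.seed)`` keyed by (group, animal, training), so
    the whole study is reproducible and insensitive to iteration order.
    """
    entries = cfg.entries()
    records: list[TrialRecord] = []
    groups = (
        ("model", cfg.n_model, cfg.model_params, cfg.model_learning_rate),
        ("control", cfg.n_control, cfg.control_params, cfg.control_learning_rate),
    )
    for gi, (group, n_animals, params, rate) in enumerate(groups):
        for ai in range(n_animals):
            for ti in range(cfg.n_trainings):
                trained = replace(params, goal_bias_kappa=params.goal_bias_kappa * rate**ti)
                ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(gi, ai, ti))
                traj = simulate_trial(
                    trained,
                    cfg.arena,
                    entries[ti % len(entries)],
                    np.random.default_rng(ss),
                    animal_id=f"{group}_{ai + 1:02d}",
                    trial_id=f"t{ti + 1:02d}",
                )
                records.append(
                    TrialRecord(group=group, animal_id=traj.animal_id, training=ti + 1, trajectory=traj)
                )
    return records


def study_manifest(records: list[TrialRecord]) -> pd.DataFrame:
    """Manifest table (group, animal, training, trial id, file name)."""
    return pd.DataFrame(
        {
            "group": [r.group for r in records],
            "animal_id": [r.animal_id for r in records],
            "training": [r.training for r in records],
            "trial_id": [r.trajectory.trial_id for r in records],
            "file": [f"{r.animal_id}_{r.trajectory.trial_id}.csv" for r in records],
        }
    )
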