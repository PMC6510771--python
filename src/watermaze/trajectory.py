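"""Swim trajectories: container, CSV I/O, resampling and escape detection.

A trajectory is an ordered series of (t, x, y) samples for one animal in one
trial.  Times are seconds from water entry; positions are centimetres in the
arena frame (see :mod:`watermaze.arena`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arena import ArenaConfig, Point

log = logging.getLogger(__name__)

#: column names expected in a trajectory CSV
CSV_COLUMNS = ("time_s", "x_cm", "y_cm")

#: tracking gaps longer than this trigger a warning when validating (s)
GAP_WARN_S = 1.0


class TrajectoryParseError(ValueError):
    """A trajectory file could not be parsed."""


class TrajectoryValidationError(ValueError):
    """A trajectory violates a structural invariant."""


@dataclass
class Trajectory:
    """Ordered (t, x, y) samples for one trial.

    ``record_frequency`` is the nominal sampling rate in Hz; for raw imports
    it is inferred as 1/median(dt).  The entry point is the first sample.
    """

    t: np.ndarray
    xy: np.ndarray
    record_frequency: float
    animal_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise TrajectoryValidationError("t must be (n,), xy must be (n, 2)")
        if self.t.size < 2:
            raise TrajectoryValidationError("a trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise TrajectoryValidationError("non-finite sample values")
        if self.t[0] != 0.0:
            raise TrajectoryValidationError("time must start at 0")
        if not np.all(np.diff(self.t) > 0):
            raise TrajectoryValidationError("times must be strictly increasing")

    @property
    def entry(self) -> Point:
        """Water-entry position (first sample)."""
        return Point(*self.xy[0])

    @property
    def duration_s(self) -> float:
        return float(self.t[-1])

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def path_length_cm(self) -> float:
        return float(np.hypot(*np.diff(self.xy, axis=0).T).sum())

    def validate_in_arena(self, config: ArenaConfig, clamp: bool = False) -> "Trajectory":
        """Check (or clamp) samples against the pool boundary.

        With ``clamp=False`` any point further than ``pool_radius`` from the
        pool centre raises; with ``clamp=True`` such points are pulled
        radially back onto the wall.  Gaps longer than ``GAP_WARN_S`` are
        logged as probable tracking dropouts.
        """
        center = np.asarray(config.pool_center)
        offset = self.xy - center
        r = np.hypot(offset[:, 0], offset[:, 1])
        outside = r > config.pool_radius * (1 + 1e-12)
        xy = self.xy
        if outside.any():
            if not clamp:
                i = int(np.argmax(outside))
                raise TrajectoryValidationError(
                    f"sample {i} at t={self.t[i]:g}s lies {r[i]:.1f} cm from the pool "
                    f"centre (pool radius {config.pool_radius:g} cm)"
                )
            xy = xy.copy()
            scale = config.pool_radius / r[outside]
            xy[outside] = center + offset[outside] * scale[:, None]
            log.warning("clamped %d out-of-pool samples onto the wall", int(outside.sum()))
        gaps = np.diff(self.t)
        if (gaps > GAP_WARN_S).any():
            log.warning(
                "trajectory %s/%s has %d sampling gaps > %gs (tracking dropouts?)",
                self.animal_id, self.trial_id, int((gaps > GAP_WARN_S).sum()), GAP_WARN_S,
            )
        return replace(self, xy=xy)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"time_s": self.t, "x_cm": self.xy[:, 0], "y_cm": self.xy[:, 1]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class EscapeOutcome:
    """Whether and when the platform was first reached.

    Non-finders are scored with the full trial cap, following standard
    water-maze practice.
    """

    escaped: bool
    escape_latency_s: float


def read_trajectory_csv(
    path: str,
    config: ArenaConfig | None = None,
    clamp: bool = False,
    animal_id: str = "",
    trial_id: str = "",
) -> Trajectory:
    """Read a tracker export with columns ``time_s,x_cm,y_cm``.

    The record frequency is inferred as 1/median(dt).  If ``config`` is
    given, samples are validated against (or clamped to) the pool boundary.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    values = {}
    for col in CSV_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbers
            line = int(np.argmax(bad.to_numpy())) + 2
            raise TrajectoryParseError(f"{path}: malformed value in column {col!r}, line {line}")
        values[col] = numeric.to_numpy(dtype=float)
    t = values["time_s"]
    if t.size >= 2:
        dt = np.diff(t)
        freq = 1.0 / float(np.median(dt)) if np.all(dt > 0) else float("nan")
    else:
        freq = float("nan")
    traj = Trajectory(
        t=t,
        xy=np.column_stack([values["x_cm"], values["y_cm"]]),
        record_frequency=freq,
        animal_id=animal_id,
        trial_id=trial_id,
    )
    if config is not None:
        traj = traj.validate_in_arena(config, clamp=clamp)
    return traj


def resample_unit_time(traj: Trajectory, unit_time_s: float) -> Trajectory:
    """Linearly interpolate a trajectory onto a uniform grid 0, t, 2t, ...

    The final raw sample is always retained as the last point, so the
    resampled trajectory spans the full recorded duration.  Already-uniform
    input on the same grid passes through unchanged, and interior gaps
    (tracking dropouts) are bridged by the same interpolation.
    """
    if unit_time_s <= 0:
        raise ValueError("unit_time_s must be positive")
    duration = traj.duration_s
    if unit_time_s > duration:
        raise ValueError(
            f"unit_time_s={unit_time_s:g} exceeds the trajectory duration {duration:g}s"
        )
    n_whole = int(np.floor(duration / unit_time_s + 1e-9))
    times = np.arange(n_whole + 1) * unit_time_s
    if times[-1] > duration:  # float overshoot of the final grid point
        times[-1] = duration
    elif duration - times[-1] > 1e-9 * max(1.0, duration):
        times = np.append(times, duration)
    x = np.interp(times, traj.t, traj.xy[:, 0])
    y = np.interp(times, traj.t, traj.xy[:, 1])
    return replace(
        traj,
        t=times,
        xy=np.column_stack([x, y]),
        record_frequency=1.0 / unit_time_s,
    )


def detect_escape(traj: Trajectory, config: ArenaConfig) -> EscapeOutcome:
    """Find the first platform contact (distance <= platform radius, inclusive).

    Returns the contact time, or ``escaped=False`` with the full
    ``max_trial_s`` when the platform is never reached within the cap.
    """
    d = np.hypot(
        traj.xy[:, 0] - config.platform_center.x,
        traj.xy[:, 1] - config.platform_center.y,
    )
    inside = (d <= config.platform_radius) & (traj.t <= config.max_trial_s + 1e-9)
    hits = np.flatnonzero(inside)
    if hits.size:
        return EscapeOutcome(escaped=True, escape_latency_s=float(traj.t[hits[0]]))
    return EscapeOutcome(escaped=False, escape_latency_s=float(config.max_trial_s))


def truncate_at_escape(
    traj: Trajectory, config: ArenaConfig
) -> tuple[Trajectory, EscapeOutcome]:
    """Cut a trajectory at first platform contact or at the trial cap.

    The sample of first contact is kept; everything after it is dropped so
    index sums cover exactly the search period.  For non-finders, samples
    beyond ``max_trial_s`` are dropped.
    """
    outcome = detect_escape(traj, config)
    if outcome.escaped:
        keep = traj.t <= outcome.escape_latency_s + 1e-12
    else:
        keep = traj.t <= config.max_trial_s + 1e-9
    n = int(keep.sum())
    if n < 2:
        raise TrajectoryValidationError("trajectory starts on the platform or has no search period")
    return replace(traj, t=traj.t[:n].copy(), xy=traj.xy[:n].copy()), outcome
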