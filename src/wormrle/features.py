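"""Step decomposition of a centroid trajectory.

A raw centroid track is (1) resampled onto a regular Δt grid (default 1 s,
linear interpolation), (2) scanned for *turning events* — samples where the
current movement heading deviates by more than a threshold Θ (default 40°)
from the reference heading established at the previous turning event — and
(3) reduced to a *step table*: one row per line segment between consecutive
turning events, with step length (mm), traversal speed (mm/s), and the
interior angle (degrees) the step forms with the preceding step.

Angle convention: the interior angle at the shared turning event lies in
[0, 180], where 180° is straight continuation and 0° a full reversal; angles
< 90° are *sharp turns*, angles ≥ 90° *shallow turns*.  The first step of a
path has no preceding step and therefore no angle.

The reference heading at a turning event is the direction of the first
displacement after the event (initialized from the first two sampled
points); zero-displacement intervals inherit the previous heading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateFeatureWarning, EmptyResultWarning, InputError
from .synthetic import Trajectory

__all__ = [
    "SampledPath",
    "TurningEvents",
    "StepTable",
    "resample_path",
    "detect_turning_events",
    "compute_steps",
    "normalize_features",
    "extract_step_tables",
]

_STEP_COLUMNS = ("t_start", "t_end", "length_mm", "angle_deg", "speed_mm_s")
_NORM_COLUMNS = ("length_norm", "angle_norm", "speed_norm")
_FEATURES = {"length": "length_mm", "angle": "angle_deg", "speed": "speed_mm_s"}

# Displacements below this are treated as "no movement" when deriving
# headings (they inherit the previous heading instead of producing noise).
_ZERO_DISP_MM = 1e-12


@dataclass
class SampledPath:
    """Centroid positions on a regular Δt grid."""

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    delta_t_s: float
    animal_id: str = ""
    group_label: str = ""

    @property
    def n_points(self) -> int:
        return int(self.t_s.size)


@dataclass
class TurningEvents:
    """Ordered turning events of a sampled path.

    ``indices`` are ordinals into the sampled path; the first sampled point
    is always the initial event.
    """

    indices: np.ndarray
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    theta_deg: float
    animal_id: str = ""
    group_label: str = ""

    @property
    def n_events(self) -> int:
        return int(self.indices.size)


@dataclass
class StepTable:
    """Ordered steps of one animal.

    ``steps`` has columns t_start, t_end, length_mm, angle_deg, speed_mm_s
    and, after :func:`normalize_features`, length_norm/angle_norm/speed_norm.
    The first row's angle is NaN (no preceding step).
    """

    animal_id: str
    group_label: str
    steps: pd.DataFrame
    degenerate_features: tuple[str, ...] = ()

    @property
    def n_steps(self) -> int:
        return int(len(self.steps))

    def angle_bearing(self) -> pd.DataFrame:
        """Rows whose angle is defined (all but the first step)."""
        return self.steps[np.isfinite(self.steps["angle_deg"].to_numpy())]


def resample_path(traj: Trajectory, delta_t_s: float = 1.0) -> SampledPath:
    """Resample a raw track onto the regular Δt grid.

    Grid points sit at ``t0 + i*Δt`` up to the last raw timestamp; positions
    are linearly interpolated between the bracketing raw samples, which makes
    the operation robust to jittered frame timestamps.  Raw samples already
    on the grid are reproduced exactly.
    """
    if delta_t_s <= 0:
        raise InputError("delta_t_s must be > 0")
    span = traj.t_s[-1] - traj.t_s[0]
    if span < 2 * delta_t_s:
        raise InputError(
            f"track of {span:.3f} s is shorter than 2*delta_t "
            f"({2 * delta_t_s:.3f} s)"
        )
    n = int(np.floor(span / delta_t_s + 1e-9)) + 1
    grid = traj.t_s[0] + np.arange(n) * delta_t_s
    x = np.interp(grid, traj.t_s, traj.x_mm)
    y = np.interp(grid, traj.t_s, traj.y_mm)
    return SampledPath(
        grid, x, y, float(delta_t_s), traj.animal_id, traj.group_label
    )


def _segment_headings(x: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Heading (deg) of each inter-sample segment, with zero-displacement
    segments inheriting the nearest defined heading.  None if nothing moves.
    """
    dx = np.diff(x)
    dy = np.diff(y)
    moved = np.hypot(dx, dy) > _ZERO_DISP_MM
    if not moved.any():
        return None
    h = np.degrees(np.arctan2(dy, dx))
    # forward-fill stationary segments from the previous heading; leading
    # stationary segments take the first defined heading
    idx = np.where(moved, np.arange(h.size), -1)
    np.maximum.accumulate(idx, out=idx)
    first = int(np.argmax(moved))
    idx[idx < 0] = first
    return h[idx]


def _circular_diff_deg(a: float, b: float) -> float:
    """Absolute circular difference |a-b| wrapped to [0, 180]."""
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


def detect_turning_events(
    path: SampledPath, theta_deg: float = 40.0
) -> TurningEvents:
    """Scan a sampled path for turning events at threshold Θ.

    The first sampled point is the initial event.  Scanning i = 1, 2, …, the
    current heading (segment i−1 → i) is compared with the reference heading
    (direction of the first displacement after the most recent event); if the
    absolute circular difference exceeds Θ, point i becomes an event and the
    reference resets to the direction of the segment leaving point i.
    """
    if path.n_points < 2:
        raise InputError("need at least 2 sampled points")
    if not 0.0 < theta_deg < 180.0:
        raise InputError("theta_deg must be in (0, 180)")

    h = _segment_headings(path.x_mm, path.y_mm)
    if h is None:
        warnings.warn(
            f"no movement in path {path.animal_id!r}; only the initial "
            "turning event is returned",
            EmptyResultWarning,
            stacklevel=2,
        )
        events = [0]
    else:
        n = path.n_points
        events = [0]
        ref = h[0]
        for i in range(1, n):
            cur = h[i - 1]
            if _circular_diff_deg(cur, ref) > theta_deg:
                events.append(i)
                ref = h[i] if i < n - 1 else cur
    idx = np.asarray(events, dtype=int)
    return TurningEvents(
        indices=idx,
        t_s=path.t_s[idx],
        x_mm=path.x_mm[idx],
        y_mm=path.y_mm[idx],
        theta_deg=float(theta_deg),
        animal_id=path.animal_id,
        group_label=path.group_label,
    )


def _interior_angle_deg(
    vx1: float, vy1: float, vx2: float, vy2: float
) -> float:
    """Interior angle in [0, 180] between two vectors (NaN if either is 0)."""
    n1 = np.hypot(vx1, vy1)
    n2 = np.hypot(vx2, vy2)
    if n1 <= _ZERO_DISP_MM or n2 <= _ZERO_DISP_MM:
        return float("nan")
    c = (vx1 * vx2 + vy1 * vy2) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_steps(events: TurningEvents) -> StepTable:
    """Build the step table from consecutive turning events.

    Step j spans events j−1 → j: length is the Euclidean displacement,
    speed the displacement over elapsed time.  The interior angle at the
    junction of steps j and j+1 (at the shared event, between the vectors to
    the previous and to the next event) is attached to the *later* step, so
    the first step carries no angle.
    """
    if events.n_events < 2:
        warnings.warn(
            f"fewer than 2 turning events for {events.animal_id!r}; "
            "empty step table",
            EmptyResultWarning,
            stacklevel=2,
        )
        steps = pd.DataFrame(
            {c: pd.Series(dtype=float) for c in _STEP_COLUMNS}
        )
        return StepTable(events.animal_id, events.group_label, steps)

    ex, ey, et = events.x_mm, events.y_mm, events.t_s
    dx = np.diff(ex)
    dy = np.diff(ey)
    dt = np.diff(et)
    lengths = np.hypot(dx, dy)
    speeds = lengths / dt

    n_steps = lengths.size
    angles = np.full(n_steps, np.nan)
    for j in range(1, n_steps):
        # junction event is events[j]; vectors point to neighbours
        angles[j] = _interior_angle_deg(
            ex[j - 1] - ex[j],
            ey[j - 1] - ey[j],
            ex[j + 1] - ex[j],
            ey[j + 1] - ey[j],
        )

    steps = pd.DataFrame(
        {
            "t_start": et[:-1],
            "t_end": et[1:],
            "length_mm": lengths,
            "angle_deg": angles,
            "speed_mm_s": speeds,
        },
        columns=list(_STEP_COLUMNS),
    )
    return StepTable(events.animal_id, events.group_label, steps)


def normalize_features(tables: list[StepTable]) -> list[StepTable]:
    """Min-max normalize length/angle/speed, pooled across all animals.

    All steps of all tables share one scale per feature (the downstream
    clustering is pooled, which requires a common scale).  A zero-range
    feature maps to 0 everywhere and is flagged on every returned table and
    via :class:`DegenerateFeatureWarning`.  NaN angles stay NaN.
    """
    pooled = [t.steps for t in tables if len(t.steps)]
    if not pooled:
        raise InputError("no steps to normalize")
    allsteps = pd.concat(pooled, ignore_index=True)
    if len(allsteps) < 2:
        raise InputError("need at least 2 pooled steps to normalize")

    bounds: dict[str, tuple[float, float]] = {}
    degenerate: list[str] = []
    for feat, col in _FEATURES.items():
        vals = allsteps[col].to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise InputError(f"feature {feat!r} has no finite values")
        lo, hi = float(finite.min()), float(finite.max())
        bounds[feat] = (lo, hi)
        if hi == lo:
            degenerate.append(feat)
            warnings.warn(
                f"feature {feat!r} has zero range; normalized to 0",
                DegenerateFeatureWarning,
                stacklevel=2,
            )

    out = []
    for t in tables:
        steps = t.steps.copy()
        for feat, col in _FEATURES.items():
            lo, hi = bounds[feat]
            norm_col = f"{feat}_norm"
            if hi == lo:
                steps[norm_col] = np.where(
                    np.isfinite(steps[col].to_numpy()), 0.0, np.nan
                )
            else:
                steps[norm_col] = (steps[col] - lo) / (hi - lo)
        out.append(
            StepTable(
                t.animal_id,
                t.group_label,
                steps,
                degenerate_features=tuple(degenerate),
            )
        )
    return out


def extract_step_tables(
    trajectories: list[Trajectory],
    delta_t_s: float = 1.0,
    theta_deg: float = 40.0,
) -> list[StepTable]:
    """Trajectories → normalized step tables (resample, detect, steps)."""
    tables = []
    for traj in trajectories:
        path = resample_path(traj, delta_t_s)
        events = detect_turning_events(path, theta_deg)
        tables.append(compute_steps(events))
    return normalize_features(tables)
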