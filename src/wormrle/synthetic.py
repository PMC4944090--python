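"""Synthetic single-worm centroid trajectories.

Generates centroid tracks that emulate a crawling nematode filmed at ~30 Hz:
long roaming bouts of nearly straight movement interrupted by turning bouts
of discrete reorientations.  A two-state (roam/turn) discrete-time process,
evaluated on a 1-second clock, drives the heading; per-frame displacement is
speed/frame_rate along the current heading.

The regime process, per second:

* in the roam state the heading receives a small Gaussian jitter; with
  probability ``p_roam_to_turn`` the animal instead enters the turn state and
  immediately reorients;
* in the turn state the heading receives a discrete reorientation drawn
  uniformly from ``±[turn_angle_min_deg, turn_angle_max_deg]`` (direction a
  fair coin, reversals realized as turns near 180°) on every second spent in
  the state; after the draw the animal leaves the state with probability
  ``p_turn_to_roam``.

Two module-level presets realize the two phenotypes the downstream analysis
is designed to separate: a sharp-turn-rich track (frequent large
reorientations, interior step angles mostly < 90°) and a shallow-turn-rich
track (rare moderate reorientations, interior angles mostly ≥ 90°).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "SimParams",
    "Trajectory",
    "simulate_path",
    "simulate_cohort",
    "SHARP_TURN_PRESET",
    "SHALLOW_TURN_PRESET",
    "bimodal_step_tables",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-state centroid-track simulator.

    Attributes
    ----------
    duration_s:
        Track duration in seconds.
    frame_rate_hz:
        Sampling rate of the synthetic camera (default 30 frames/s).
    speed_mean_mm_s, speed_sd_mm_s:
        Per-frame crawling speed is drawn from a normal distribution with
        this mean and SD and truncated at 0 (speeds are magnitudes).
    p_roam_to_turn, p_turn_to_roam:
        Per-second regime-switch probabilities, both in [0, 1].
    roam_heading_sd_deg:
        SD of the per-second Gaussian heading jitter while roaming.
    turn_angle_min_deg, turn_angle_max_deg:
        Magnitude range of the discrete reorientations in the turn regime.
    seed:
        Seed of the per-animal random stream.
    """

    duration_s: float = 300.0
    frame_rate_hz: float = 30.0
    speed_mean_mm_s: float = 0.12
    speed_sd_mm_s: float = 0.03
    p_roam_to_turn: float = 0.1
    p_turn_to_roam: float = 0.5
    roam_heading_sd_deg: float = 12.0
    turn_angle_min_deg: float = 50.0
    turn_angle_max_deg: float = 180.0
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be > 0")
        if not self.frame_rate_hz > 0:
            raise ParameterError("frame_rate_hz must be > 0")
        for name in ("speed_sd_mm_s", "roam_heading_sd_deg"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("p_roam_to_turn", "p_turn_to_roam"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.turn_angle_min_deg < 0:
            raise ParameterError("turn_angle_min_deg must be >= 0")
        if self.turn_angle_max_deg > 180:
            raise ParameterError("turn_angle_max_deg must be <= 180")
        if self.turn_angle_min_deg > self.turn_angle_max_deg:
            raise ParameterError(
                "turn_angle_min_deg must not exceed turn_angle_max_deg"
            )


@dataclass
class Trajectory:
    """Raw timestamped centroid track for one animal.

    ``t_s`` is strictly increasing, coordinates are in mm and finite.
    """

    animal_id: str
    group_label: str
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if self.t_s.size < 2:
            raise ParameterError("Trajectory needs at least 2 samples")
        if self.t_s.size != self.x_mm.size or self.t_s.size != self.y_mm.size:
            raise ParameterError("t_s, x_mm, y_mm must have equal length")
        if not np.all(np.diff(self.t_s) > 0):
            raise ParameterError("t_s must be strictly increasing")
        if not (
            np.all(np.isfinite(self.t_s))
            and np.all(np.isfinite(self.x_mm))
            and np.all(np.isfinite(self.y_mm))
        ):
            raise ParameterError("Trajectory samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)


# Phenotype presets: the study conditions for the parameter-recovery and
# monotonicity analyses.  The sharp preset produces a sharp-symbol fraction
# around 0.6, the shallow preset around 0.1.
SHARP_TURN_PRESET = SimParams(
    p_roam_to_turn=0.22,
    p_turn_to_roam=0.7,
    roam_heading_sd_deg=20.0,
    turn_angle_min_deg=115.0,
    turn_angle_max_deg=180.0,
)
SHALLOW_TURN_PRESET = SimParams(
    p_roam_to_turn=0.06,
    p_turn_to_roam=0.8,
    roam_heading_sd_deg=18.0,
    turn_angle_min_deg=50.0,
    turn_angle_max_deg=130.0,
)


def simulate_path(
    params: SimParams,
    animal_id: str = "sim_001",
    group_label: str = "sim",
) -> Trajectory:
    """Simulate one centroid track under the two-state regime model.

    The track has ``round(duration_s * frame_rate_hz) + 1`` samples starting
    at the origin.  Identical ``params`` (including the seed) give bitwise
    identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_frames = int(round(params.duration_s * params.frame_rate_hz))
    if n_frames < 1:
        raise ParameterError("duration_s too short for one frame")
    # second index of each displacement frame
    sec_of_frame = np.floor(
        np.arange(n_frames) / params.frame_rate_hz + 1e-12
    ).astype(int)
    n_sec = int(sec_of_frame[-1]) + 1

    heading = np.empty(n_sec)
    heading[0] = rng.uniform(0.0, 360.0)
    ROAM, TURN = 0, 1
    regime = ROAM

    def turn_draw() -> float:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * rng.uniform(
            params.turn_angle_min_deg, params.turn_angle_max_deg
        )

    for s in range(1, n_sec):
        h = heading[s - 1]
        if regime == TURN:
            h += turn_draw()
            if rng.random() < params.p_turn_to_roam:
                regime = ROAM
        else:
            if rng.random() < params.p_roam_to_turn:
                regime = TURN
                h += turn_draw()
            else:
                h += rng.normal(0.0, params.roam_heading_sd_deg)
        heading[s] = h

    speeds = rng.normal(params.speed_mean_mm_s, params.speed_sd_mm_s, n_frames)
    np.clip(speeds, 0.0, None, out=speeds)
    step = speeds / params.frame_rate_hz
    h_rad = np.deg2rad(heading[sec_of_frame])
    x = np.concatenate(([0.0], np.cumsum(step * np.cos(h_rad))))
    y = np.concatenate(([0.0], np.cumsum(step * np.sin(h_rad))))
    t = np.arange(n_frames + 1) / params.frame_rate_hz
    return Trajectory(animal_id, group_label, t, x, y)


def simulate_cohort(
    group_specs: list[tuple[str, SimParams, int]],
    seed: int = 0,
) -> list[Trajectory]:
    """Simulate a labeled cohort of animals.

    ``group_specs`` lists ``(group_label, params, n_animals)`` triples.
    Per-animal seeds are derived deterministically from the cohort seed, so
    the same cohort seed reproduces the same cohort exactly.
    """
    if not group_specs:
        raise ParameterError("group_specs must not be empty")
    rng = np.random.default_rng(seed)
    cohort: list[Trajectory] = []
    for group_label, params, n_animals in group_specs:
        if n_animals < 1:
            raise ParameterError(
                f"n_animals must be >= 1 for group {group_label!r}"
            )
        for a in range(n_animals):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            traj = simulate_path(
                dataclasses.replace(params, seed=sub_seed),
                animal_id=f"{group_label}_{a + 1:03d}",
                group_label=group_label,
            )
            cohort.append(traj)
    return cohort


def bimodal_step_tables(
    n_animals: int = 10,
    steps_per_animal: int = 120,
    seed: int = 0,
    sharp_mode_deg: float = 20.0,
    shallow_mode_deg: float = 160.0,
    mode_sd_deg: float = 8.0,
    sharp_fraction: float = 0.5,
):
    """Step tables with a bimodal inter-step angle distribution.

    A fixture generator for the symbolization stage: angles are drawn from
    two well-separated Gaussian modes (one below, one above 90°) truncated
    to [0, 180]; lengths and speeds are i.i.d. positive draws independent of
    the mode.  Returns a list of :class:`~wormrle.features.StepTable` with
    raw features only (normalize afterwards).
    """
    from .features import StepTable, _STEP_COLUMNS
    import pandas as pd

    if n_animals < 1 or steps_per_animal < 2:
        raise ParameterError("need n_animals >= 1 and steps_per_animal >= 2")
    rng = np.random.default_rng(seed)
    tables = []
    for a in range(n_animals):
        n = steps_per_animal
        is_sharp = rng.random(n) < sharp_fraction
        angles = np.where(
            is_sharp,
            rng.normal(sharp_mode_deg, mode_sd_deg, n),
            rng.normal(shallow_mode_deg, mode_sd_deg, n),
        )
        angles = np.clip(angles, 0.0, 180.0)
        angles[0] = np.nan  # first step of a path has no angle
        lengths = np.abs(rng.normal(1.0, 0.3, n)) + 1e-3
        speeds = np.abs(rng.normal(0.5, 0.15, n)) + 1e-3
        t_start = np.arange(n, dtype=float)
        steps = pd.DataFrame(
            {
                "t_start": t_start,
                "t_end": t_start + 1.0,
                "length_mm": lengths,
                "angle_deg": angles,
                "speed_mm_s": speeds,
            },
            columns=list(_STEP_COLUMNS),
        )
        tables.append(
            StepTable(
                animal_id=f"bimodal_{a + 1:03d}",
                group_label="bimodal",
                steps=steps,
            )
        )
    return tables
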