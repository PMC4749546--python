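"""Two-state organelle transport simulator.

Each organelle is either long-lived stationary (probability
``1 - motile_prob``) or motile.  Motile organelles alternate exponentially
distributed runs and pauses; each run draws a speed from a
truncated-positive Gaussian and reverses direction with
``direction_switch_prob``.  Positions are sampled on a fixed frame grid
(default 0.9 fps) and reflected at the ends of the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..tracks import TrackSet, STATIONARY, RUN, PAUSE
from .truth import GroundTruth

DEFAULT_FRAME_INTERVAL = 1.0 / 0.9  # s


@dataclass(frozen=True)
class MotilityParams:
    motile_prob: float = 0.3
    run_duration_mean: float = 5.0       # s
    pause_duration_mean: float = 3.0     # s
    run_speed_mean: float = 0.5          # µm/s
    run_speed_sd: float = 0.15           # µm/s
    direction_switch_prob: float = 0.5   # per run
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    duration: float = 120.0              # s
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.motile_prob <= 1:
            raise ValueError("motile_prob must be in [0, 1]")
        if min(self.run_duration_mean, self.pause_duration_mean,
               self.run_speed_mean) <= 0:
            raise ValueError("durations and speeds must be > 0")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be > 0")


def _draw_speed(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return v


def simulate_tracks(path_length: float, params: MotilityParams,
                    n_organelles: int = 10) -> tuple[TrackSet, GroundTruth]:
    """Simulate organelle tracks on a path of ``path_length`` µm.

    Returns the sampled :class:`TrackSet` (with per-frame state labels) and
    the :class:`GroundTruth` bundle.  Deterministic given ``params.seed``.
    """
    if path_length <= 0:
        raise ValueError("path_length must be > 0")
    n_frames = int(np.floor(params.duration / params.frame_interval)) + 1
    if n_frames < 2:
        raise ValueError("duration / frame_interval must give at least 2 frames")
    rng = np.random.default_rng(params.seed)
    t_grid = np.arange(n_frames) * params.frame_interval

    positions = np.empty((n_organelles, n_frames))
    states = np.zeros((n_organelles, n_frames), dtype=np.int8)
    motile = rng.uniform(size=n_organelles) < params.motile_prob
    true_runs: list[float] = []
    true_pauses: list[float] = []
    true_speeds: list[float] = []

    p_run = params.run_duration_mean / (params.run_duration_mean
                                        + params.pause_duration_mean)
    for i in range(n_organelles):
        x0 = rng.uniform(0.0, path_length)
        if not motile[i]:
            positions[i] = x0
            states[i] = STATIONARY
            continue
        # event-driven bout sequence covering [0, duration]
        t = 0.0
        x = x0
        in_run = rng.uniform() < p_run
        direction = rng.choice([-1.0, 1.0])
        bt, bx, bstate, bspeed = [0.0], [x], [], []
        while t < params.duration:
            if in_run:
                dur = rng.exponential(params.run_duration_mean)
                speed = _draw_speed(rng, params.run_speed_mean, params.run_speed_sd)
                if bstate and rng.uniform() < params.direction_switch_prob:
                    direction = -direction
                bstate.append(RUN)
                bspeed.append(direction * speed)
            else:
                dur = rng.exponential(params.pause_duration_mean)
                bstate.append(PAUSE)
                bspeed.append(0.0)
            if t + dur <= params.duration:  # complete (untruncated) bout
                if in_run:
                    true_runs.append(dur)
                    true_speeds.append(abs(bspeed[-1]))
                else:
                    true_pauses.append(dur)
            t += dur
            x += bspeed[-1] * dur
            bt.append(t)
            bx.append(x)
            in_run = not in_run
        bt = np.array(bt)
        bx = np.array(bx)
        # sample the piecewise-linear trajectory on the frame grid
        pos = np.interp(t_grid, bt, bx)
        # reflect into [0, path_length]
        period = 2.0 * path_length
        pos = np.mod(pos, period)
        pos = np.where(pos > path_length, period - pos, pos)
        positions[i] = pos
        idx = np.clip(np.searchsorted(bt, t_grid, side="right") - 1, 0, len(bstate) - 1)
        states[i] = np.array(bstate, dtype=np.int8)[idx]

    tracks = TrackSet(positions=positions, frame_interval=params.frame_interval,
                      states=states, source="ground_truth", path_length=path_length)
    truth = GroundTruth(tracks=tracks, motile=motile, params=params,
                        run_durations=np.asarray(true_runs),
                        pause_durations=np.asarray(true_pauses),
                        run_speeds=np.asarray(true_speeds))
    return tracks, truth
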